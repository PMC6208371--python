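#!/usr/bin/env python
"""Animal-cohort sizing for the in-vivo follow-up.

How many mice per group does a bioluminescence endpoint need?  With a
1 log10-flux difference between groups and an SD of about 0.5 log10
units, the standardized effect size is d = 2.  The exact noncentral-t
computation below gives the minimal equal group size for 80% power at
two-sided alpha 0.05, plus the power curve around it.

Writes results/cohort_power.json.
"""

import argparse
import json
from pathlib import Path

from sensiscreen.power_stats import PowerSpec, min_n, power_at_n

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--d", type=float, default=2.0)
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--power", type=float, default=0.80)
    args = parser.parse_args()

    spec = PowerSpec(args.d, args.alpha, args.power)
    n = min_n(spec)
    curve = {k: power_at_n(spec, k) for k in range(max(2, n - 3), n + 4)}

    report = {
        "effect_size_d": args.d,
        "alpha": args.alpha,
        "target_power": args.power,
        "n_per_group": n,
        "achieved_power": curve[n],
        "power_curve": curve,
    }
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    (outdir / "cohort_power.json").write_text(json.dumps(report, indent=2))

    print(f"d = {args.d}, two-sided alpha = {args.alpha}, target power = {args.power:.0%}")
    print(f"-> at least {n} animals per group (achieved power {curve[n]:.1%})")
    for k, p in curve.items():
        marker = " <-" if k == n else ""
        print(f"   n = {k}: power {p:.1%}{marker}")


if __name__ == "__main__":
    main()
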