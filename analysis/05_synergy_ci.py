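#!/usr/bin/env python
"""Combination-index synergy scoring of mimic + drug dose matrices.

Fits median-effect lines to each agent's simulated single-agent data,
then scores two combination matrices: one constructed under exact
Loewe additivity (every CI should be 1) and one in which the mimic
doubles the drug's effective potency in combination (every CI should
fall below 1 - synergy at all combinations).

Writes results/ci_additive.csv, results/ci_boosted.csv and
results/ci_summary.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from sensiscreen.synergy_ci import ci_matrix, ci_summary, fit_median_effect
from sensiscreen.synthetic_data import simulate_combination, simulate_dose_response

SEED = 1902
ROOT = Path(__file__).resolve().parents[1]

# median-effect parameters of the two agents (m, Dm)
MIMIC = (1.2, 1.0)   # Dm in nM-equivalents of mimic
DRUG = (1.0, 6.0)    # Dm in nM


def me_curve_table(params, doses, seed, agent):
    """Single-agent fa data simulated from the 4PL equivalent of (m, Dm)."""
    m, dm = params
    table = simulate_dose_response((0.0, 1.0, dm, m), doses, 3, 0.05, seed, agent)
    # fa outside (0,1) (noise pushing viability past 1) is excluded by the fitter
    return table.doses, 1.0 - table.viability_fraction


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=SEED)
    args = parser.parse_args()

    doses1 = np.geomspace(0.1, 10, 8)
    doses2 = np.geomspace(0.6, 60, 8)
    fit1 = fit_median_effect(*me_curve_table(MIMIC, doses1, args.seed, "mimic"),
                             agent="mimic")
    fit2 = fit_median_effect(*me_curve_table(DRUG, doses2, args.seed + 1, "drug"),
                             agent="drug")

    grid = [(d1, d2) for d1 in (0.5, 1.0, 2.0, 4.0) for d2 in (1.5, 3.0, 6.0, 12.0)]
    additive = ci_matrix(fit1, fit2, simulate_combination(MIMIC, DRUG, grid))
    boosted = ci_matrix(fit1, fit2,
                        simulate_combination(MIMIC, DRUG, grid, mode="boost", boost=2.0))

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    additive.to_csv(outdir / "ci_additive.csv", index=False, float_format="%.6g")
    boosted.to_csv(outdir / "ci_boosted.csv", index=False, float_format="%.6g")
    summary = {
        "seed": args.seed,
        "mimic_fit": {"m": fit1.m, "dm": fit1.dm, "r2": fit1.r2},
        "drug_fit": {"m": fit2.m, "dm": fit2.dm, "r2": fit2.r2},
        "additive": ci_summary(additive) | {"median_ci": float(additive["ci"].median())},
        "boosted": ci_summary(boosted) | {"median_ci": float(boosted["ci"].median())},
    }
    (outdir / "ci_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"mimic fit: m {fit1.m:.2f}, Dm {fit1.dm:.2f} (r2 {fit1.r2:.3f}); "
          f"drug fit: m {fit2.m:.2f}, Dm {fit2.dm:.2f} (r2 {fit2.r2:.3f})")
    print(f"Loewe-additive matrix: median CI {summary['additive']['median_ci']:.2f} "
          f"({summary['additive']['synergy']:.0%} of points called synergy)")
    print(f"potency-boosted matrix: median CI {summary['boosted']['median_ci']:.2f} "
          f"({summary['boosted']['synergy']:.0%} of points called synergy)")


if __name__ == "__main__":
    main()
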