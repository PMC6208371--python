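#!/usr/bin/env python
"""Generate the full-scale synthetic mimic screen used by the later steps.

Simulates 1902 library entries in 96-well triplicate plates (84 test +
8 NC + 4 PC wells per plate) under a vehicle arm and a drug arm dosed
at the drug's IC20 (2 nM on a 4PL with IC50 8 nM), with 5% CV
multiplicative noise and sparse planted effects (2% sensitizers, 1%
desensitizers, 2% vehicle-toxic entries).

Writes the raw screen to scratch/screen/ (large) and a small class
summary to results/simulation_summary.json.  Every later step
regenerates the same screen from the same seed, so this step is for
inspection, not a hard dependency.
"""

import argparse
import json
from pathlib import Path

from sensiscreen.screen_model import write_screen
from sensiscreen.synthetic_data import GeneratorConfig, simulate_screen

SEED = 1902

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=SEED)
    args = parser.parse_args()

    cfg = GeneratorConfig(seed=args.seed)
    dataset, truth = simulate_screen(cfg)

    outdir = ROOT / "scratch" / "screen"
    outdir.mkdir(parents=True, exist_ok=True)
    write_screen(dataset, outdir / "signals.csv", outdir / "maps.csv")
    truth.to_csv(outdir / "truth.csv", index=False)

    summary = {
        "seed": args.seed,
        "n_mimics": cfg.n_mimics,
        "n_plates": cfg.n_plates,
        "n_measurements": int(len(dataset.measurements)),
        "drug_surviving_fraction": cfg.drug_surviving_fraction,
        "true_class_counts": truth["class"].value_counts().to_dict(),
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "simulation_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"simulated {cfg.n_mimics} mimics on {cfg.n_plates} plates "
          f"({summary['n_measurements']} measurements)")
    print(f"drug alone leaves {cfg.drug_surviving_fraction:.0%} viability at "
          f"{cfg.drug_dose} nM (an IC20 dose)")
    print("true classes:", summary["true_class_counts"])
    print(f"raw screen -> {outdir}, summary -> {results/'simulation_summary.json'}")


if __name__ == "__main__":
    main()
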