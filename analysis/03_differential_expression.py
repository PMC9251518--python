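#!/usr/bin/env python
"""Pairwise differential expression between disease stages.

Quantifies FPKM from the simulated counts, keeps genes detected in more
than 8 of the 24 samples, and calls DEGs for the three stage contrasts
(IML vs NCA, AMI vs NCA, AMI vs IML) with fold change >= 1.5 or <= 0.67 and
BH-adjusted p < 0.05 (Welch's t on log2(FPKM+1)). Writes one table per
contrast plus a summary under results/deg/.
"""

import warnings
from pathlib import Path

import pandas as pd

from tipnet.deg import differential_expression
from tipnet.expression import filter_expressed
from tipnet.simulate import SimulationConfig, simulate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "deg"
SEED = 0


def main() -> None:
    study = simulate_study(SimulationConfig(seed=SEED))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = filter_expressed(study.expression, 8)
    print(f"{expr.values.shape[0]} of {study.expression.values.shape[0]} genes "
          "pass the detection filter")

    OUT.mkdir(parents=True, exist_ok=True)
    summary = []
    for a, b in [("NCA", "IML"), ("NCA", "AMI"), ("IML", "AMI")]:
        table = differential_expression(expr, a, b)
        name = f"{b}_vs_{a}"
        table.to_csv(OUT / f"deg_{name}.tsv", sep="\t")
        n_up = int((table["direction"] == "up").sum())
        n_down = int((table["direction"] == "down").sum())
        summary.append({"contrast": name, "deg": n_up + n_down,
                        "up": n_up, "down": n_down})
        print(f"{name}: {n_up + n_down} DEGs ({n_up} up, {n_down} down)")
    out = pd.DataFrame(summary)
    out.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    widest = out.loc[out["deg"].idxmax(), "contrast"]
    print(f"the {widest} contrast yields the most DEGs; adjacent-stage "
          "contrasts share a per-sample latent factor, so their calls are "
          "noisier at 8 samples per group")


if __name__ == "__main__":
    main()
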