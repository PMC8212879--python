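#!/usr/bin/env python
"""SHG circular dichroism: exact recovery and the shot-noise floor.

Recovers injected CD asymmetries from noise-free and Poisson-noised LHCP/RHCP
pairs and quantifies the positive shot-noise bias of |L−R| at ε = 0 as a
function of base counts. Writes results/analysis/shg_cd.csv.
"""

from pathlib import Path

import pandas as pd

from shgmetrics.chirality import cd_field
from shgmetrics.synth import SyntheticScene, gen_chiral_pair

OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for eps in (0.0, 0.2, 0.4, 1.0):
        for noise, base in (("none", 1000.0), ("poisson", 1000.0)):
            pair = gen_chiral_pair(SyntheticScene(cd_epsilon=eps, amplitude=base,
                                                  noise=noise, seed=404,
                                                  shape=(64, 64)))
            res = cd_field(pair, threshold=0.0)
            rows.append({"epsilon": eps, "noise": noise, "base_counts": base,
                         "mean_cd": res.mean_cd, "sum_cd": res.sum_cd,
                         "n_valid": res.n_valid})
    for base in (100.0, 1000.0, 10000.0):
        pair = gen_chiral_pair(SyntheticScene(cd_epsilon=0.0, amplitude=base,
                                              noise="poisson", seed=405,
                                              shape=(64, 64)))
        res = cd_field(pair, threshold=0.0)
        rows.append({"epsilon": 0.0, "noise": "poisson", "base_counts": base,
                     "mean_cd": res.mean_cd, "sum_cd": res.sum_cd,
                     "n_valid": res.n_valid})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "shg_cd.csv", index=False)
    clean = df[df.noise == "none"]
    print("noise-free recovery is exact:",
          ", ".join(f"ε={r.epsilon:g}→{r.mean_cd:.3f}" for r in clean.itertuples()))
    floor = df[(df.epsilon == 0.0) & (df.noise == "poisson")]
    print("shot-noise floor at ε=0 falls with counts:",
          ", ".join(f"{r.base_counts:g}cts→{r.mean_cd:.4f}"
                    for r in floor.itertuples()))


if __name__ == "__main__":
    main()
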