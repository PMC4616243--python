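#!/usr/bin/env python
"""Drift-diffusion simulations of the sensitivity-vs-bound dissociation.

Simulates fixed-duration bounded diffusion psychometric functions while
varying the bound B (at fixed sensitivity k) and varying k (at fixed B).
Raising either steepens the psychometric slope, but only raising k shrinks
the stimulation-induced PSE shift -- the signature that lets choice data with
an injected evidence signal tell the two apart.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rewardstim.ddm import DDMConfig, fit_logistic_curve, psychometric_curve

OUT = Path("results/ddm")
SEED = 20_250_923


def sweep(configs, grid, n_paths=8000):
    rows = []
    for name, cfg in configs:
        fits = {}
        for ms in (False, True):
            curve = psychometric_curve(cfg, grid, ms)
            fits[ms] = fit_logistic_curve(curve[:, 0], curve[:, 1], cfg.n_paths)
        rows.append({
            "condition": name, "k": cfg.k, "bound": cfg.bound,
            "slope_nonstim": fits[False][0],
            "mc_pse_shift": fits[False][1] - fits[True][1],
            "analytic_shift": cfg.stim_evidence / cfg.k,
        })
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = np.linspace(-1, 1, 9)
    configs = [
        ("baseline", DDMConfig(k=2.0, bound=0.8, n_paths=8000, dt=2e-3, seed=SEED)),
        ("bound x2", DDMConfig(k=2.0, bound=1.6, n_paths=8000, dt=2e-3, seed=SEED + 1)),
        ("k x2", DDMConfig(k=4.0, bound=0.8, n_paths=8000, dt=2e-3, seed=SEED + 2)),
    ]
    table = sweep(configs, grid)
    table.to_csv(OUT / "dissociation.tsv", sep="\t", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    base, bound2, k2 = table.iloc[0], table.iloc[1], table.iloc[2]
    print(f"\ndoubling the bound steepens the slope x{bound2['slope_nonstim']/base['slope_nonstim']:.2f} "
          f"and leaves the shift at {bound2['mc_pse_shift']:.3f} (analytic {base['analytic_shift']:.3f})")
    print(f"doubling k steepens the slope x{k2['slope_nonstim']/base['slope_nonstim']:.2f} "
          f"and halves the shift to {k2['mc_pse_shift']:.3f} (analytic {k2['analytic_shift']:.3f})")


if __name__ == "__main__":
    main()
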