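#!/usr/bin/env python
"""Equilibrium binding: K_d recovery and shared-site competition.

Fits noisy synthetic anisotropy titrations at the RNA (3.9 nM), ssDNA
(8.3 nM) and dsDNA (18.9 nM) ground-truth affinities and reports median
recovered K_d over 200 replicates each. Then solves the two-ligand
shared-site competition exactly and compares the apparent dsDNA K_d with
the closed form K_d(1 + C/K_dC): the closed form holds in the
negligible-depletion limit; at the experimental concentrations (100 nM
competitor of K_d 3.9 nM) the titrated protein consumes the competitor and
the exact half-saturation is far lower. The empirically observed fold
change is larger than the ideal single-site prediction of ~27x and is not
a model output.

Writes results/kd_recovery.csv and results/competition_curves.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rnpq import binding, simulate

OUT = Path(__file__).resolve().parents[1] / "results"
GRID = np.geomspace(0.1, 1000, 12)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-replicates", type=int, default=200)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    rows = []
    for substrate, kd_truth in (("30-nt RNA", 3.9), ("30-nt ssDNA", 8.3),
                                ("30-bp dsDNA", 18.9)):
        kds = []
        for i in range(args.n_replicates):
            curve, _ = simulate.gen_anisotropy_curve(
                kd_truth, 1.0, 0.0, 1.0, GRID, noise_sd=0.05,
                seed=args.seed * 10_000 + i)
            kds.append(binding.fit_hill_binding(binding.normalize_anisotropy(curve)).kd)
        rows.append({"substrate": substrate, "kd_truth_nM": kd_truth,
                     "kd_median_nM": float(np.median(kds)),
                     "kd_iqr_nM": float(np.subtract(*np.percentile(kds, [75, 25])))})
        print(f"{substrate}: median K_d {rows[-1]['kd_median_nM']:.2f} nM"
              f" (truth {kd_truth} nM, {args.n_replicates} replicates)")
    pd.DataFrame(rows).to_csv(OUT / "kd_recovery.csv", index=False)

    # competition of labeled dsDNA with unlabeled RNA for the same site
    grid = np.geomspace(0.5, 5000, 200)
    direct = binding.hill(grid, 18.9, 1.0)
    exact = binding.solve_competition(
        binding.CompetitionSystem(18.9, 3.9, 1.0, 100.0, grid))
    scale = 1000.0
    limit = binding.solve_competition(
        binding.CompetitionSystem(18.9, 3.9 * scale, 1.0, 100.0 * scale, grid))
    pd.DataFrame({"protein_total_nM": grid, "bound_direct": direct,
                  "bound_competed_exact": exact,
                  "bound_competed_depletion_free": limit}).to_csv(
        OUT / "competition_curves.csv", index=False)

    closed = binding.competitive_apparent_kd(18.9, 3.9, 100.0)
    half_exact = float(np.interp(0.5, exact, grid))
    half_limit = float(np.interp(0.5, limit, grid))
    print(f"\ncompetition (100 nM RNA vs 1 nM labeled dsDNA):")
    print(f"  closed form K_d,app = {closed:.0f} nM (fold {closed / 18.9:.1f}x)")
    print(f"  depletion-free limit solver: {half_limit:.0f} nM "
          f"({abs(half_limit - closed) / closed * 100:.1f}% from closed form)")
    print(f"  exact solver at experimental concentrations: {half_exact:.0f} nM"
          " (competitor consumed by the titrated protein)")


if __name__ == "__main__":
    main()
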