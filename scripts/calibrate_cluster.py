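"""Re-run the grid search that fixed the cluster-coupling defaults.

The defaults for the G-actin consumption coefficient µ and the diffusion
constant Da were calibrated so that the reference random-init continuum
run (30×30 µm, ±30% initial heights, 4000 s) reproduces the observed wave
magnitudes: a pair-correlation decay length ξ ≈ 3 µm and a kymograph
patch lifetime ≈ 5 min.  This script evaluates a (µ, Da) grid around the
frozen point with the same estimators the acceptance script uses and
prints the scores, so the calibration is reproducible and auditable.

Usage:
    python scripts/calibrate_cluster.py [--seeds 3] [--out calibration.csv]
"""

from __future__ import annotations

import argparse
import warnings

import numpy as np
import pandas as pd

from podowave import (
    ClusterConfig,
    ModelParams,
    correlation_vs_distance,
    kymograph,
    pattern_lifetime,
    simulate_cluster,
)

MU_GRID = (1.9, 1.95, 2.0, 2.05)
DA_GRID = (0.025, 0.0275, 0.03)


def evaluate(mu: float, Da: float, seed: int) -> tuple[float, float, bool]:
    params = ModelParams().replace(mu=mu, Da=Da)
    cfg = ClusterConfig(init="random", seed=seed, t_end=4000.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        field = simulate_cluster(params, cfg)
    rng = np.random.default_rng(seed)
    pos = rng.uniform([1.5, 1.5], [28.5, 28.5], size=(100, 2))
    traces = field.height_traces_at(pos)
    n = traces.shape[1]
    curve = correlation_vs_distance(traces[:, n - 100 :], pos, window=100)
    lifetimes = []
    for yc in (8.0, 15.0, 22.0):
        kym = kymograph(field, (5.0, 25.0, yc - 1.0, yc + 1.0))
        try:
            lifetimes.append(pattern_lifetime(kym, field.steady_height))
        except ValueError:
            pass
    lt = float(np.mean(lifetimes)) if lifetimes else float("nan")
    return float(curve.xi), lt, field.clip_warnings > 0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seeds", type=int, default=3, help="replicates per grid point")
    ap.add_argument("--out", default=None, help="optional CSV output path")
    args = ap.parse_args()

    rows = []
    for mu in MU_GRID:
        for Da in DA_GRID:
            xis, lts, clipped = [], [], 0
            for seed in range(1, args.seeds + 1):
                xi, lt, clip = evaluate(mu, Da, seed)
                if np.isfinite(xi):
                    xis.append(xi)
                if np.isfinite(lt):
                    lts.append(lt)
                clipped += clip
            row = {
                "mu": mu,
                "Da": Da,
                "xi_median_um": float(np.median(xis)),
                "lifetime_mean_min": float(np.mean(lts)),
                "clipped_runs": clipped,
            }
            rows.append(row)
            print(
                f"mu={mu:5.2f} Da={Da:6.4f}: xi={row['xi_median_um']:5.2f} um, "
                f"lifetime={row['lifetime_mean_min']:5.2f} min, "
                f"clipped={clipped}/{args.seeds}"
            )
    df = pd.DataFrame(rows)
    if args.out:
        df.to_csv(args.out, index=False)
        print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
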