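"""Choice-conditioned posteriors over the accumulator.

Computes the posterior mean trace for every trial (used downstream for
change-of-mind detection) and full posterior grids for a subset of
trials (used for tuning maps), writing mean traces as CSV and grids as
HDF5 under results/posterior/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dynclicks.io import read_trials, write_posterior_h5
from dynclicks.posterior import posterior_grid, posterior_mean_analytic

from _common import load_fit_theta


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--fitdir", default="results/fit")
    ap.add_argument("--outdir", default="results/posterior")
    ap.add_argument("--n-grids", type=int, default=300,
                    help="trials for which the full (a, t) grid is kept")
    ap.add_argument("--grid-dt", type=float, default=5e-3)
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    trials = read_trials(Path(args.datadir) / "trials.jsonl")
    theta = load_fit_theta(Path(args.fitdir) / "fit.json")

    rows = []
    crossings = 0
    for tr in trials:
        times, m = posterior_mean_analytic(tr, theta, tr.choice)
        crossings += int(np.any(np.sign(m[1:] - theta.B) != np.sign(m[:-1] - theta.B)))
        rows.append(pd.DataFrame({"trial_id": tr.trial_id, "time": times,
                                  "posterior_mean": m}))
    pd.concat(rows, ignore_index=True).to_csv(out / "mean_traces.csv", index=False)

    grids = {tr.trial_id: posterior_grid(tr, theta, tr.choice, dt_eval=args.grid_dt)
             for tr in trials[: args.n_grids]}
    write_posterior_h5(out / "grids.h5", grids)

    print(f"posterior mean traces for {len(trials)} trials "
          f"({crossings} trials with at least one boundary crossing)")
    print(f"full grids for {len(grids)} trials at dt={args.grid_dt*1e3:.0f} ms, "
          "da=0.1")


if __name__ == "__main__":
    main()
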