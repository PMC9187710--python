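"""Behavioral assays on the simulated dataset.

Computes the psychometric curve against ideal-observer log-odds, the
final-state chronometric curves, and the choice-conditioned reverse
correlation kernels, writing one CSV per curve under results/behavior/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dynclicks.behavior import chronometric, psychometric, reverse_correlation
from dynclicks.io import read_trials
from dynclicks.synth import TaskParams

from _common import load_agent_theta


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results/behavior")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    trials = read_trials(Path(args.datadir) / "trials.jsonl")
    task = TaskParams()
    theta = load_agent_theta(Path(args.datadir) / "generative.json")

    psy = psychometric(trials, task=task, theta=theta)
    psy.to_csv(out / "psychometric.csv", index=False)
    print("psychometric: P(right) spans "
          f"{psy['p_right'].min():.2f}-{psy['p_right'].max():.2f} across "
          f"{len(psy)} log-odds bins; model overlay within CI in "
          f"{((psy.p_model >= psy.ci_lo) & (psy.p_model <= psy.ci_hi)).mean():.0%} of bins")

    chron = chronometric(trials)
    chron.to_csv(out / "chronometric.csv", index=False)
    for grp in ("0", "1", ">1"):
        sub = chron[chron.group == grp].sort_values("bin")
        if len(sub) > 1:
            print(f"chronometric [{grp} changes]: accuracy "
                  f"{sub.accuracy.iloc[0]:.2f} -> {sub.accuracy.iloc[-1]:.2f} "
                  "with final-state duration")

    kc = reverse_correlation(trials, task=task)
    rows = []
    for ch, label in ((1, "right"), (-1, "left")):
        for t, m, s, nrm in zip(kc.time_to_end, kc.mean[ch], kc.sd[ch],
                                kc.normalized[ch]):
            rows.append({"choice": label, "time_to_end": t, "mean_excess": m,
                         "sd": s, "normalized": nrm})
    pd.DataFrame(rows).to_csv(out / "reverse_correlation.csv", index=False)
    k = kc.mean[1]
    third = k.size // 3
    print(f"reverse correlation (right choices): excess click rate "
          f"{k[:third].mean():+.2f} Hz early -> {k[-third:].mean():+.2f} Hz "
          "late - late clicks dominate, the signature of leaky integration")


if __name__ == "__main__":
    main()
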