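"""Simulate the synthetic study dataset.

Generates trials of the dynamic clicks task (hazard 1 Hz, click rates
38/2 Hz, durations U(0.5, 2) s), choices from a leaky accumulation agent
(lambda < 0), and spike trains from a mixed population of
accumulator-tuned and untuned units, then writes the trial and spike
tables under results/data/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dynclicks.accumulation import ModelParams
from dynclicks.io import write_latents_h5, write_spikes, write_trials
from dynclicks.synth import SyntheticNeuronSpec, TaskParams, generate_dataset

AGENT = ModelParams(sigma_i2=0.3, sigma_a2=1.0, sigma_s2=1.5, lam=-2.0,
                    phi=0.6, tau_phi=0.15, B=0.1, lapse=0.05)


def population(n_tuned=8, n_untuned=4):
    specs = [SyntheticNeuronSpec(unit_id=u, baseline=8.0, gain=35.0, slope=1.2,
                                 sign=1 if u % 2 == 0 else -1)
             for u in range(n_tuned)]
    specs += [SyntheticNeuronSpec(unit_id=n_tuned + u, baseline=10.0, gain=0.0)
              for u in range(n_untuned)]
    return specs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-trials", type=int, default=800)
    ap.add_argument("--outdir", default="results/data")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    specs = population()
    ds = generate_dataset(args.n_trials, len(specs), task=TaskParams(),
                          theta=AGENT, specs=specs, seed=args.seed)
    write_trials(out / "trials.jsonl", ds.trials)
    write_spikes(out / "spikes.csv", ds.spikes)
    write_latents_h5(out / "latents.h5", ds.latents)
    (out / "generative.json").write_text(json.dumps({
        "seed": args.seed,
        "agent": {k: getattr(AGENT, k) for k in
                  ("sigma_i2", "sigma_a2", "sigma_s2", "lam", "phi",
                   "tau_phi", "B", "lapse")},
        "units": [{"unit_id": s.unit_id, "preferred_side": s.preferred_side,
                   "baseline": s.baseline, "gain": s.gain} for s in specs],
    }, indent=2))

    n_changes = np.array([t.n_changes() for t in ds.trials])
    acc = np.mean([t.hit for t in ds.trials])
    print(f"simulated {args.n_trials} trials, {len(specs)} units "
          f"({len(ds.spikes)} spikes)")
    print(f"state changes/trial: mean {n_changes.mean():.2f}; "
          f"0/1/>1 fractions {np.mean(n_changes == 0):.2f}/"
          f"{np.mean(n_changes == 1):.2f}/{np.mean(n_changes > 1):.2f}")
    print(f"agent accuracy: {acc:.3f}")
    print(f"wrote {out}/trials.jsonl, spikes.csv, latents.h5, generative.json")


if __name__ == "__main__":
    main()
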