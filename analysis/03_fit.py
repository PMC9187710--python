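"""Fit the accumulation model to the simulated choices.

Maximum-likelihood fit of the eight-parameter accumulation model
(noise variances, discounting rate, adaptation, boundary, lapse) to the
agent's choices, with half-Gaussian priors on the initial and memory
noise variances and standard errors from the inverse numeric Hessian.
"""

import argparse
import json
from pathlib import Path

from dynclicks.accumulation import ModelParams, fit_parameters
from dynclicks.io import read_trials

from _common import load_agent_theta


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results/fit")
    ap.add_argument("--n-starts", type=int, default=2)
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    trials = read_trials(Path(args.datadir) / "trials.jsonl")
    theta_true = load_agent_theta(Path(args.datadir) / "generative.json")

    fit = fit_parameters(trials, theta0=ModelParams(), n_starts=args.n_starts,
                         seed=args.seed)
    rec = {"theta_hat": {k: getattr(fit.theta_hat, k) for k in
                         ("sigma_i2", "sigma_a2", "sigma_s2", "lam", "phi",
                          "tau_phi", "B", "lapse")},
           "se": fit.se, "nll": fit.nll, "converged": fit.converged,
           "n_trials": fit.n_trials}
    (out / "fit.json").write_text(json.dumps(rec, indent=2))

    print(f"fit {fit.n_trials} trials, NLL {fit.nll:.1f}, "
          f"converged={fit.converged}")
    for name in ("lam", "B", "lapse", "phi", "tau_phi"):
        est = getattr(fit.theta_hat, name)
        true = getattr(theta_true, name)
        se = fit.se[name]
        print(f"  {name:8s} {est:8.3f} +- {se:6.3f}   (generative {true:.3f})")
    sign = "leaky (lambda < 0)" if fit.theta_hat.lam < 0 else "unstable (lambda > 0)"
    print(f"recovered integration regime: {sign}")


if __name__ == "__main__":
    main()
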