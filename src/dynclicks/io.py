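"""File formats, configuration, and the end-to-end pipeline driver.

Conventions used project-wide: times in seconds with 0 at stimulus
onset; half-open bin intervals [left, right) labeled by their centers;
trial tables as JSON-lines (one record per trial, arrays for click and
state-change times); spike tables as long-format CSV
(unit_id, trial_id, spike_time_s); gridded outputs as HDF5.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accumulation import ModelParams
from .synth import TaskParams, Trial, stage_seed

__all__ = [
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_spikes",
    "write_spikes",
    "write_latents_h5",
    "write_posterior_h5",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("dynclicks")

_TRIAL_FIELDS = {
    "trial_id": int,
    "duration": float,
    "left_clicks": list,
    "right_clicks": list,
    "state_changes": list,
    "initial_state": int,
    "final_state": int,
}


def write_trials(path, trials) -> None:
    """Write a trial table as JSON-lines."""
    path = Path(path)
    with path.open("w") as fh:
        for t in trials:
            rec = {
                "trial_id": int(t.trial_id),
                "duration": float(t.duration),
                "left_clicks": np.asarray(t.left_clicks, dtype=float).tolist(),
                "right_clicks": np.asarray(t.right_clicks, dtype=float).tolist(),
                "state_changes": np.asarray(t.state_changes, dtype=float).tolist(),
                "initial_state": int(t.initial_state),
                "final_state": int(t.final_state),
                "choice": None if t.choice is None else int(t.choice),
                "hit": None if t.hit is None else bool(t.hit),
                "movement": None if t.movement is None else float(t.movement),
            }
            fh.write(json.dumps(rec) + "\n")


def read_trials(path) -> list:
    """Read and schema-validate a JSON-lines trial table."""
    path = Path(path)
    trials = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{lineno}: malformed JSON record: {e}") from e
            for name, typ in _TRIAL_FIELDS.items():
                if name not in rec:
                    raise ValueError(f"{path}:{lineno}: missing field '{name}'")
                if typ is list and not isinstance(rec[name], list):
                    raise ValueError(f"{path}:{lineno}: field '{name}' must be an array")
            tr = Trial(
                trial_id=int(rec["trial_id"]),
                duration=float(rec["duration"]),
                left_clicks=np.asarray(rec["left_clicks"], dtype=float),
                right_clicks=np.asarray(rec["right_clicks"], dtype=float),
                state_changes=np.asarray(rec["state_changes"], dtype=float),
                initial_state=int(rec["initial_state"]),
                final_state=int(rec["final_state"]),
                choice=rec.get("choice"),
                hit=rec.get("hit"),
                movement=rec.get("movement"),
            )
            try:
                tr.validate()
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
            trials.append(tr)
    return trials


def write_spikes(path, spikes: pd.DataFrame) -> None:
    spikes.to_csv(path, index=False)


def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"unit_id", "trial_id", "spike_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing spike columns {sorted(missing)}")
    if len(df) and (df["trial_id"] < 0).any():
        bad = int(df.index[df["trial_id"] < 0][0])
        raise ValueError(f"{path}: negative trial reference at row {bad}")
    return df.sort_values(["unit_id", "trial_id", "spike_time_s"]).reset_index(drop=True)


def write_latents_h5(path, latents: dict) -> None:
    """Ground-truth accumulator paths, one HDF5 group per trial."""
    import h5py

    with h5py.File(path, "w") as f:
        for tid, (t_grid, a_path) in latents.items():
            g = f.create_group(f"trial_{tid}")
            g.create_dataset("times", data=np.asarray(t_grid))
            g.create_dataset("a", data=np.asarray(a_path))


def write_posterior_h5(path, posteriors: dict) -> None:
    """HDF5 with one group per trial holding the posterior grid."""
    import h5py

    with h5py.File(path, "w") as f:
        for tid, pg in posteriors.items():
            g = f.create_group(f"trial_{tid}")
            g.create_dataset("times", data=pg.times)
            g.create_dataset("a_edges", data=pg.a_edges)
            g.create_dataset("mass", data=pg.mass)
            g.attrs["choice"] = pg.choice
            g.attrs["B"] = pg.B


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    n_trials: int = 500
    n_units: int = 5
    task: dict = field(default_factory=dict)
    agent: dict = field(default_factory=dict)
    fit: dict = field(default_factory=lambda: {"n_starts": 1})
    analysis: dict = field(default_factory=dict)

    def task_params(self) -> TaskParams:
        return TaskParams(**self.task)

    def agent_params(self) -> ModelParams:
        return ModelParams(**self.agent)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> fit -> posterior -> behavior -> neural -> tuning -> str.

    Writes stage outputs and a manifest (seeds and per-file hashes) under
    ``config.outdir``; returns the manifest dict.
    """
    from . import behavior, neural, statechange, tuning
    from .accumulation import fit_parameters
    from .posterior import posterior_grid, posterior_mean_analytic
    from .synth import generate_dataset

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "hashes": {}}

    log.info("stage simulate: %d trials, %d units", config.n_trials, config.n_units)
    ds = generate_dataset(config.n_trials, config.n_units,
                          task=config.task_params(), theta=config.agent_params(),
                          seed=stage_seed(config.seed, "simulate"))
    write_trials(out / "trials.jsonl", ds.trials)
    write_spikes(out / "spikes.csv", ds.spikes)
    manifest["stages"]["simulate"] = {"n_trials": config.n_trials, "n_units": config.n_units}

    log.info("stage fit")
    fit = fit_parameters(ds.trials, theta0=ds.theta,
                         n_starts=config.fit.get("n_starts", 1),
                         seed=stage_seed(config.seed, "fit"))
    theta_hat = fit.theta_hat
    (out / "fit.json").write_text(json.dumps(
        {"theta_hat": {k: v for k, v in asdict(theta_hat).items()},
         "nll": fit.nll, "se": fit.se, "converged": fit.converged}, indent=2))

    log.info("stage posterior (mean traces)")
    mean_traces = {}
    for tr in ds.trials:
        times, m = posterior_mean_analytic(tr, theta_hat, tr.choice)
        mean_traces[tr.trial_id] = (times, m)

    log.info("stage behavior")
    psy = behavior.psychometric(ds.trials, task=ds.task, theta=theta_hat)
    psy.to_csv(out / "psychometric.csv", index=False)
    behavior.chronometric(ds.trials).to_csv(out / "chronometric.csv", index=False)

    log.info("stage neural")
    rates = neural.compute_rates(ds.spikes, ds.trials)
    cls = neural.classify_cells(ds.spikes, ds.trials)
    pd.DataFrame([asdict(c) for c in cls.values()]).to_csv(
        out / "classification.csv", index=False)

    log.info("stage tuning (subset of trials)")
    n_post = min(len(ds.trials), config.analysis.get("n_posterior_trials", 150))
    dt_eval = config.analysis.get("posterior_dt", 5e-3)
    a_cap = config.analysis.get("posterior_a_max", 40.0)
    posteriors = {tr.trial_id: posterior_grid(tr, theta_hat, tr.choice,
                                              dt_eval=dt_eval, a_max=a_cap)
                  for tr in ds.trials[:n_post]}
    sel_units = [u for u, c in cls.items() if c.selective]
    rank_rows = []
    for u in sel_units:
        joint = tuning.build_joint(rates[u], posteriors, ds.trials)
        tm = tuning.tuning_map(joint)
        try:
            r1 = tuning.rank1(tm, preferred_side=cls[u].preferred_side)
        except ValueError:
            continue
        rank_rows.append({"unit_id": u, "variance_explained": r1.variance_explained})
    pd.DataFrame(rank_rows).to_csv(out / "rank1.csv", index=False)

    log.info("stage state changes")
    events = []
    for tr in ds.trials:
        times, m = mean_traces[tr.trial_id]
        events.extend(statechange.detect_model_changes(
            times, m, theta_hat.B, trial_id=tr.trial_id, duration=tr.duration))
    ev_df = pd.DataFrame([{"trial_id": e.trial_id, "time": e.time,
                           "direction": e.direction, "included": e.included}
                          for e in events])
    ev_df.to_csv(out / "model_state_changes.csv", index=False)
    manifest["stages"]["state_changes"] = {"n_events": int(len(ev_df)),
                                           "n_included": int(ev_df["included"].sum()) if len(ev_df) else 0}

    log.info("stage str")
    rng = np.random.default_rng(stage_seed(config.seed, "str"))
    str_rows = []
    for u, c in cls.items():
        if not c.selective:
            continue
        res = statechange.compute_str(rates[u], events, c.preferred_side, rng=rng)
        if res is None:
            continue
        for lag_s, sp, sn, d in zip(res.lags, res.str_pref, res.str_nonpref,
                                    res.dprime):
            str_rows.append({"unit_id": u, "lag": lag_s, "str_pref": sp,
                             "str_nonpref": sn, "dprime": d})
    pd.DataFrame(str_rows).to_csv(out / "str.csv", index=False)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["hashes"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
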