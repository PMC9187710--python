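"""Synthetic task, agent, and spike-train generator.

Emulates the dynamic clicks task: a hidden two-state telegraph process
switching at hazard rate h (1 Hz by default) selects which speaker emits
clicks at the high rate (38 Hz) versus the low rate (2 Hz); the trial
duration is uniform on [0.5, 2] s, and reward is baited on the side
matching the final hidden state.  Choices are produced by simulating the
accumulation SDE, and spike trains by inhomogeneous Poisson units whose
rate is a baseline plus a temporal gain times a bounded sigmoid of the
(lagged) accumulator value — the separable code the tuning analyses are
designed to recover.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accumulation import ModelParams, adapt_clicks, _expm1_over_x

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "TaskParams",
    "Trial",
    "SyntheticNeuronSpec",
    "SpikeTrain",
    "Dataset",
    "generate_trial",
    "generate_trials",
    "simulate_agent",
    "simulate_agent_ensemble",
    "agent_choice",
    "generate_spikes",
    "default_population",
    "generate_dataset",
    "stage_seed",
]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage RNG seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class TaskParams:
    """Generative task parameters (defaults are the study conditions)."""

    hazard_rate: float = 1.0    # state switches per second
    rate_high: float = 38.0     # clicks/s on the favored side
    rate_low: float = 2.0       # clicks/s on the unfavored side
    duration_min: float = 0.5   # s
    duration_max: float = 2.0   # s

    def __post_init__(self) -> None:
        if self.hazard_rate < 0:
            raise ValueError("hazard_rate must be >= 0")
        if not self.rate_high > self.rate_low >= 0:
            raise ValueError("need rate_high > rate_low >= 0")
        if not 0 < self.duration_min <= self.duration_max:
            raise ValueError("need 0 < duration_min <= duration_max")


@dataclass
class Trial:
    """One behavioral trial; times in seconds from stimulus onset.

    ``initial_state``/``final_state`` use 1 = go-right, 2 = go-left.
    ``choice`` is +1 (right) / -1 (left) or None if undefined.
    """

    trial_id: int
    duration: float
    left_clicks: np.ndarray
    right_clicks: np.ndarray
    state_changes: np.ndarray
    initial_state: int
    final_state: int
    choice: int | None = None
    hit: bool | None = None
    movement: float | None = None  # time of movement onset (>= duration)

    def n_changes(self) -> int:
        return int(np.asarray(self.state_changes).size)

    def state_at(self, t: float) -> int:
        """Hidden state at time t (constant after the go cue)."""
        k = int(np.searchsorted(self.state_changes, min(t, self.duration), side="right"))
        return self.initial_state if k % 2 == 0 else 3 - self.initial_state

    def final_state_duration(self) -> float:
        last = self.state_changes[-1] if self.n_changes() else 0.0
        return self.duration - float(last)

    def validate(self) -> None:
        for name in ("left_clicks", "right_clicks", "state_changes"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > self.duration):
                raise ValueError(f"{name} outside [0, duration] in trial {self.trial_id}")
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} not ascending in trial {self.trial_id}")
        expected_final = self.initial_state if self.n_changes() % 2 == 0 else 3 - self.initial_state
        if self.final_state != expected_final:
            raise ValueError(f"final_state inconsistent with change count in trial {self.trial_id}")


@dataclass
class SyntheticNeuronSpec:
    """Rate model: r(t) = max(0, baseline + m(t) * f(a(t - lag))).

    f is a sigmoid bounded in [-0.5, 0.5]; the temporal gain m(t) ramps
    linearly from 0 to ``gain`` over ``ramp_dur`` seconds after stimulus
    onset and then plateaus (mirroring the rise-then-plateau gain the
    population analyses look for).  ``gain`` = 0 gives an untuned unit.
    """

    unit_id: int
    baseline: float = 10.0      # spikes/s
    gain: float = 20.0          # spikes/s at full modulation
    slope: float = 1.0          # sigmoid slope in 1/a units
    midpoint: float = 0.0       # sigmoid midpoint (a units)
    sign: int = 1               # +1 right-preferring, -1 left-preferring
    response_lag: float = 0.1   # s
    ramp_dur: float = 0.5       # s

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline rate must be >= 0")

    @property
    def preferred_side(self) -> str:
        if self.gain == 0:
            return "none"
        return "right" if self.sign > 0 else "left"

    def tuning(self, a) -> np.ndarray:
        return self.sign * (1.0 / (1.0 + np.exp(-self.slope * (np.asarray(a) - self.midpoint))) - 0.5)

    def gain_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.gain * np.clip(t / self.ramp_dur, 0.0, 1.0)

    def rate(self, t, a_lagged) -> np.ndarray:
        return np.maximum(0.0, self.baseline + self.gain_at(t) * self.tuning(a_lagged))


@dataclass
class SpikeTrain:
    unit_id: int
    trial_id: int
    spike_times: np.ndarray  # s, relative to stimulus onset


@dataclass
class Dataset:
    trials: list
    spikes: pd.DataFrame            # columns unit_id, trial_id, spike_time_s
    specs: list
    task: TaskParams
    theta: ModelParams
    latents: dict = field(default_factory=dict)  # trial_id -> (t_grid, a_path)
    seed: int | None = None


def generate_trial(task: TaskParams, rng, trial_id: int = 0,
                   with_clicks: bool = True) -> Trial:
    """Draw one trial: telegraph state path and per-epoch Poisson clicks.

    State-change times are exact exponential inter-event waits; within
    each state epoch the left/right click counts are Poisson at the
    state-appropriate rate with uniform placement.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    duration = rng.uniform(task.duration_min, task.duration_max)
    initial_state = int(rng.integers(1, 3))
    changes = []
    t = 0.0
    if task.hazard_rate > 0:
        while True:
            t += rng.exponential(1.0 / task.hazard_rate)
            if t >= duration:
                break
            changes.append(t)
    changes = np.asarray(changes)
    final_state = initial_state if changes.size % 2 == 0 else 3 - initial_state

    left, right = np.empty(0), np.empty(0)
    if with_clicks:
        edges = np.concatenate([[0.0], changes, [duration]])
        lefts, rights = [], []
        state = initial_state
        for k in range(edges.size - 1):
            span = edges[k + 1] - edges[k]
            r_right = task.rate_high if state == 1 else task.rate_low
            r_left = task.rate_low if state == 1 else task.rate_high
            nr = rng.poisson(r_right * span)
            nl = rng.poisson(r_left * span)
            rights.append(edges[k] + np.sort(rng.uniform(0, span, nr)))
            lefts.append(edges[k] + np.sort(rng.uniform(0, span, nl)))
            state = 3 - state
        left = np.concatenate(lefts)
        right = np.concatenate(rights)
    return Trial(trial_id=trial_id, duration=float(duration),
                 left_clicks=left, right_clicks=right, state_changes=changes,
                 initial_state=initial_state, final_state=final_state)


def generate_trials(n: int, task: TaskParams, rng, with_clicks: bool = True) -> list:
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    return [generate_trial(task, rng, trial_id=i, with_clicks=with_clicks) for i in range(n)]


def simulate_agent(trial: Trial, theta: ModelParams, dt: float = 1e-3,
                   rng=None, n_paths: int = 1):
    """Sample accumulator paths of the SDE on a uniform grid.

    Uses the exact Ornstein-Uhlenbeck transition between grid points
    (decay e^{lam dt}, exact diffusion variance) and applies each click at
    its true time (decayed to the end of the enclosing step) with adapted
    magnitude and per-click noise following ``theta.click_noise``.  The
    sampled path distribution at grid times therefore matches the
    continuous-time solution exactly.

    Returns (t_grid, a_paths, choices, hits); a_paths has shape
    (n_paths, n_steps + 1); choices are +1/-1 per path.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_steps = int(round(trial.duration / dt))
    t_grid = np.linspace(0.0, n_steps * dt, n_steps + 1)
    ac = adapt_clicks(trial, phi=theta.phi, tau_phi=theta.tau_phi)
    # pre-bin clicks into steps: click s in (t_k, t_{k+1}]  -> applied at k+1
    step_of = np.clip(np.ceil(ac.times / dt - 1e-12).astype(int), 1, n_steps) if ac.times.size else np.empty(0, int)
    decay = math.exp(theta.lam * dt)
    step_var = theta.sigma_a2 * dt * float(_expm1_over_x(2.0 * theta.lam * dt))
    step_sd = math.sqrt(step_var)
    w = ac.magnitudes**2 if theta.click_noise == "quadratic" else ac.magnitudes
    click_sd = np.sqrt(theta.sigma_s2 * w)

    # deterministic per-step click drift (clicks decayed to end of step)
    click_dec = np.exp(theta.lam * (t_grid[step_of] - ac.times)) if ac.times.size else np.empty(0)
    drift = np.zeros(n_steps + 1)
    if ac.times.size:
        np.add.at(drift, step_of, ac.signs * ac.magnitudes * click_dec)

    clicks_in_step = [[] for _ in range(n_steps + 1)]
    for j, st in enumerate(step_of):
        clicks_in_step[st].append(j)

    a = rng.normal(0.0, math.sqrt(theta.sigma_i2), size=n_paths)
    store = np.empty((n_steps + 1, n_paths))  # row-major in time for fast writes
    store[0] = a
    block = max(1, min(n_steps, int(4e6 // max(n_paths, 1)) + 1))
    k = 1
    while k <= n_steps:
        k_hi = min(k + block, n_steps + 1)
        noise = (rng.normal(0.0, step_sd, size=(k_hi - k, n_paths))
                 if step_sd > 0 else None)
        for kk in range(k, k_hi):
            a = a * decay
            if noise is not None:
                a += noise[kk - k]
            if clicks_in_step[kk]:
                a += drift[kk]
                for j in clicks_in_step[kk]:
                    if click_sd[j] > 0:
                        a += rng.normal(0.0, click_sd[j] * click_dec[j], size=n_paths)
            store[kk] = a
        k = k_hi
    paths = store.T
    a_end = paths[:, -1]
    lapse_mask = rng.random(n_paths) < theta.lapse
    coin = rng.integers(0, 2, size=n_paths) * 2 - 1
    sign_choice = np.where(a_end > theta.B, 1, -1)
    tie = a_end == theta.B
    if np.any(tie):
        sign_choice = np.where(tie, rng.integers(0, 2, size=n_paths) * 2 - 1, sign_choice)
    choices = np.where(lapse_mask, coin, sign_choice).astype(int)
    hits = (choices == 1) == (trial.final_state == 1)
    return t_grid, paths, choices, hits


@njit(cache=True)
def _ensemble_kernel(n_paths, n_steps, dt, decay, step_sd, sigma_i,
                     click_step, click_inc, click_sd_dec, store_idx,
                     B, lapse, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    out = np.empty((n_paths, store_idx.size))
    a_end = np.empty(n_paths)
    choices = np.empty(n_paths, dtype=np.int64)
    n_clicks = click_step.size
    for p in range(n_paths):
        a = sigma_i * np.random.normal()
        c = 0
        s = 0
        if s < store_idx.size and store_idx[s] == 0:
            out[p, s] = a
            s += 1
        for k in range(1, n_steps + 1):
            a = a * decay
            if step_sd > 0.0:
                a += step_sd * np.random.normal()
            while c < n_clicks and click_step[c] == k:
                inc = click_inc[c]
                if click_sd_dec[c] > 0.0:
                    inc += click_sd_dec[c] * np.random.normal()
                a += inc
                c += 1
            if s < store_idx.size and store_idx[s] == k:
                out[p, s] = a
                s += 1
        a_end[p] = a
        if np.random.random() < lapse:
            choices[p] = 1 if np.random.random() < 0.5 else -1
        elif a > B:
            choices[p] = 1
        elif a < B:
            choices[p] = -1
        else:
            choices[p] = 1 if np.random.random() < 0.5 else -1
    return out, a_end, choices


def simulate_agent_ensemble(trial: Trial, theta: ModelParams, dt: float = 1e-3,
                            seed: int = 0, n_paths: int = 10000,
                            store_times=None):
    """Many SDE paths at once, storing only the requested checkpoint times.

    Same exact-transition scheme as :func:`simulate_agent`, organized
    path-major for speed; the full 1 ms path is not kept.  Returns
    (store_times, samples (n_paths, n_store), a_end, choices).
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    n_steps = int(round(trial.duration / dt))
    t_grid = np.linspace(0.0, n_steps * dt, n_steps + 1)
    if store_times is None:
        store_times = t_grid[:: max(1, n_steps // 50)]
    store_idx = np.unique(np.clip(np.round(np.asarray(store_times) / dt), 0, n_steps)).astype(np.int64)
    ac = adapt_clicks(trial, phi=theta.phi, tau_phi=theta.tau_phi)
    step_of = (np.clip(np.ceil(ac.times / dt - 1e-12).astype(np.int64), 1, n_steps)
               if ac.times.size else np.empty(0, np.int64))
    click_dec = np.exp(theta.lam * (t_grid[step_of] - ac.times)) if ac.times.size else np.empty(0)
    click_inc = ac.signs * ac.magnitudes * click_dec
    w = ac.magnitudes**2 if theta.click_noise == "quadratic" else ac.magnitudes
    click_sd_dec = np.sqrt(theta.sigma_s2 * w) * click_dec
    decay = math.exp(theta.lam * dt)
    step_sd = math.sqrt(theta.sigma_a2 * dt * float(_expm1_over_x(2.0 * theta.lam * dt)))
    samples, a_end, choices = _ensemble_kernel(
        n_paths, n_steps, dt, decay, step_sd, math.sqrt(theta.sigma_i2),
        step_of, click_inc, click_sd_dec, store_idx,
        theta.B, theta.lapse, seed % (2**31 - 1))
    return t_grid[store_idx], samples, a_end, choices


def agent_choice(trial: Trial, theta: ModelParams, dt: float = 1e-3, rng=None):
    """Simulate one agent path and return the trial with choice/hit filled in."""
    t_grid, paths, choices, hits = simulate_agent(trial, theta, dt=dt, rng=rng, n_paths=1)
    return replace(trial, choice=int(choices[0]), hit=bool(hits[0])), (t_grid, paths[0])


def generate_spikes(trial: Trial, t_grid, a_path, spec: SyntheticNeuronSpec,
                    rng=None, pre_window: float = 1.0, post_window: float = 0.5) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes via thinning from the unit's rate model.

    The accumulator is taken as 0 before stimulus onset and frozen at its
    final value after the go cue (persistent choice-related activity).
    Spikes span [-pre_window, duration + post_window].
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t0, t1 = -pre_window, trial.duration + post_window
    r_max = spec.baseline + abs(spec.gain) * 0.5 + 1e-9
    n = rng.poisson(r_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    ta = cand - spec.response_lag
    a_at = np.interp(ta, t_grid, a_path, left=0.0, right=a_path[-1])
    a_at = np.where(ta < 0, 0.0, a_at)
    rate = spec.rate(cand, a_at)
    keep = rng.random(n) < rate / r_max
    return SpikeTrain(unit_id=spec.unit_id, trial_id=trial.trial_id,
                      spike_times=cand[keep])


def default_population(n_units: int, rng, tuned_frac: float = 0.6,
                       baseline_range=(5.0, 15.0), gain_range=(15.0, 30.0),
                       slope_range=(0.5, 1.5)) -> list:
    """Default synthetic population: 60% tuned (half right-, half
    left-preferring), 40% untuned."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n_tuned = int(round(tuned_frac * n_units))
    specs = []
    for u in range(n_units):
        baseline = rng.uniform(*baseline_range)
        if u < n_tuned:
            sign = 1 if u % 2 == 0 else -1
            gain = rng.uniform(*gain_range)
            slope = rng.uniform(*slope_range)
        else:
            sign, gain, slope = 1, 0.0, 1.0
        specs.append(SyntheticNeuronSpec(unit_id=u, baseline=baseline, gain=gain,
                                         slope=slope, sign=sign))
    return specs


def generate_dataset(n_trials: int, n_units: int, task: TaskParams | None = None,
                     theta: ModelParams | None = None, specs=None, seed: int = 0,
                     dt: float = 1e-3, keep_latents: bool = True,
                     movement_delay=(0.1, 0.3)) -> Dataset:
    """Full synthetic dataset: trials + agent choices + spike trains.

    Deterministic given ``seed``; ground-truth accumulator paths are kept
    in ``latents`` for recovery tests.
    """
    task = task or TaskParams()
    theta = theta or ModelParams()
    rng_task = np.random.default_rng(stage_seed(seed, "task"))
    rng_agent = np.random.default_rng(stage_seed(seed, "agent"))
    rng_spk = np.random.default_rng(stage_seed(seed, "spikes"))
    if specs is None:
        specs = default_population(n_units, np.random.default_rng(stage_seed(seed, "units")))
    trials, latents, rows = [], {}, []
    for i in range(n_trials):
        tr = generate_trial(task, rng_task, trial_id=i)
        tr, (t_grid, a_path) = agent_choice(tr, theta, dt=dt, rng=rng_agent)
        tr = replace(tr, movement=tr.duration + rng_task.uniform(*movement_delay))
        trials.append(tr)
        if keep_latents:
            latents[i] = (t_grid, a_path)
        for spec in specs:
            st = generate_spikes(tr, t_grid, a_path, spec, rng=rng_spk)
            for s in st.spike_times:
                rows.append((spec.unit_id, i, s))
    spikes = pd.DataFrame(rows, columns=["unit_id", "trial_id", "spike_time_s"])
    if len(spikes):
        spikes = spikes.sort_values(["unit_id", "trial_id", "spike_time_s"]).reset_index(drop=True)
    return Dataset(trials=trials, spikes=spikes, specs=specs, task=task,
                   theta=theta, latents=latents, seed=seed)
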