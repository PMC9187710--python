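"""Behavioral assays: ideal-observer log-odds, psychometric and
chronometric curves, and the psychophysical reverse correlation.

The ideal observer for the dynamic clicks task is the exact discrete-time
Bayes filter on the two-state telegraph process: each click carries
kappa = log(r_high / r_low) of log-likelihood evidence (the no-click
terms cancel because the summed click rate is the same in both states),
and between observations the hazard rate pulls the log-odds toward zero
(the nonlinear discounting  dL/dt = kappa (dR - dL) - 2 h sinh(L) in the
continuum limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .accumulation import ModelParams, choice_prob
from .synth import TaskParams, Trial

__all__ = [
    "IdealObserverTrace",
    "KernelCurve",
    "ideal_observer_logodds",
    "ideal_observer_final",
    "psychometric",
    "chronometric",
    "reverse_correlation",
    "causal_gaussian_kernel",
]


@dataclass
class IdealObserverTrace:
    times: np.ndarray
    logodds: np.ndarray  # log P(state=1 | clicks so far) / P(state=2 | ...)
    kappa: float

    @property
    def final(self) -> float:
        return float(self.logodds[-1])


@dataclass
class KernelCurve:
    """Choice-conditioned excess click rate vs time until trial end."""

    time_to_end: np.ndarray          # ascending, s before trial end (negative axis)
    mean: dict                        # choice (+1/-1) -> mean excess rate
    sd: dict                          # choice -> SD across trials
    normalized: dict                  # choice -> kernel scaled to integrate to 1
    n_trials: dict


def _hazard_update(logodds: np.ndarray | float, p_switch: float):
    """One telegraph transition step applied to log-odds (exact)."""
    if p_switch <= 0:
        return logodds
    L = np.asarray(logodds, dtype=float)
    a = np.logaddexp(L + math.log1p(-p_switch), math.log(p_switch))
    b = np.logaddexp(np.float64(math.log1p(-p_switch)), L + math.log(p_switch))
    return a - b


def ideal_observer_logodds(trial: Trial, task: TaskParams, dt: float = 1e-3) -> IdealObserverTrace:
    """Exact discrete-time filter for the hidden state from clicks.

    Per step: hazard transition (switch probability h*dt), then the
    click-count log-likelihood ratio kappa * (nR - nL) for clicks in the
    step.  Starts from the symmetric prior (log-odds 0).
    """
    if task.rate_low <= 0:
        raise ValueError("rate_low must be positive for a finite ideal observer")
    kappa = math.log(task.rate_high / task.rate_low)
    n_steps = max(1, int(round(trial.duration / dt)))
    edges = np.linspace(0.0, trial.duration, n_steps + 1)
    nR = np.histogram(trial.right_clicks, bins=edges)[0]
    nL = np.histogram(trial.left_clicks, bins=edges)[0]
    p_switch = task.hazard_rate * trial.duration / n_steps
    L = np.empty(n_steps + 1)
    L[0] = 0.0
    cur = 0.0
    for k in range(n_steps):
        cur = float(_hazard_update(cur, p_switch))
        cur += kappa * (nR[k] - nL[k])
        L[k + 1] = cur
    return IdealObserverTrace(times=edges, logodds=L, kappa=kappa)


def ideal_observer_final(trials, task: TaskParams, dt: float = 1e-3) -> np.ndarray:
    return np.array([ideal_observer_logodds(t, task, dt).final for t in trials])


def psychometric(trials, choices=None, predictor=None, n_bins: int = 10,
                 task: TaskParams | None = None, theta: ModelParams | None = None,
                 dt: float = 1e-3) -> pd.DataFrame:
    """Binned P(choose right) vs ideal-observer log-odds with Wilson CIs.

    If ``theta`` is given, a model overlay column is added using each
    trial's analytic choice probability in place of the observed choice.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if choices is None:
        choices = np.array([t.choice for t in trials])
    choices = np.asarray(choices)
    if predictor is None:
        if task is None:
            raise ValueError("need predictor or task parameters")
        predictor = ideal_observer_final(trials, task, dt)
    predictor = np.asarray(predictor, dtype=float)
    qs = np.quantile(predictor, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    idx = np.clip(np.searchsorted(qs, predictor, side="right") - 1, 0, n_bins - 1)
    went_right = (choices == 1).astype(float)
    p_model = np.array([choice_prob(t, theta) for t in trials]) if theta is not None else None
    rows = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        k = int(went_right[m].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append({
            "bin": b, "x": float(predictor[m].mean()), "n": n,
            "p_right": k / n, "ci_lo": lo, "ci_hi": hi,
            "p_model": float(p_model[m].mean()) if p_model is not None else np.nan,
        })
    return pd.DataFrame(rows)


def chronometric(trials, duration_bins=(0.0, 0.5, 1.0, 1.5, 2.0)) -> pd.DataFrame:
    """Accuracy vs final-state duration, grouped by state-change count.

    Groups are 0, 1, and >1 changes; final-state duration is the time
    from the last hidden-state change (or stimulus onset) to the go cue.
    """
    duration_bins = np.asarray(duration_bins, dtype=float)
    rows = []
    for group_label, pred in (("0", lambda n: n == 0), ("1", lambda n: n == 1), (">1", lambda n: n > 1)):
        sub = [t for t in trials if pred(t.n_changes()) and t.hit is not None]
        if not sub:
            continue
        fsd = np.array([t.final_state_duration() for t in sub])
        hits = np.array([t.hit for t in sub], dtype=float)
        idx = np.clip(np.searchsorted(duration_bins, fsd, side="right") - 1, 0,
                      duration_bins.size - 2)
        for b in range(duration_bins.size - 1):
            m = idx == b
            n = int(m.sum())
            if n == 0:
                continue
            k = int(hits[m].sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append({"group": group_label, "bin": b,
                         "x": float(fsd[m].mean()), "n": n,
                         "accuracy": k / n, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def causal_gaussian_kernel(sd: float, dt: float, n_sd: float = 4.0) -> np.ndarray:
    """One-sided (current + past) Gaussian kernel, normalized to sum 1."""
    if sd <= 0 or dt <= 0:
        raise ValueError("sd and dt must be positive")
    n = max(1, int(math.ceil(n_sd * sd / dt)))
    k = np.exp(-0.5 * (np.arange(n + 1) * dt / sd) ** 2)
    return k / k.sum()


def reverse_correlation(trials, choices=None, task: TaskParams | None = None,
                        kernel_sd: float = 0.005, window: float = 0.5,
                        dt: float = 1e-3) -> KernelCurve:
    """Psychophysical reverse correlation aligned to trial end.

    Click trains are causally smoothed (Gaussian SD ``kernel_sd``); the
    state-conditional expected click-rate difference is subtracted using
    the generative hidden-state trajectory; the excess rate is averaged
    over trials by choice on a common ``window`` before trial end, and
    each mean kernel is also returned normalized to integrate to 1.
    """
    task = task or TaskParams()
    if choices is None:
        choices = [t.choice for t in trials]
    kern = causal_gaussian_kernel(kernel_sd, dt)
    n_bins = int(round(window / dt))
    t_axis = -(np.arange(n_bins)[::-1] + 0.5) * dt  # time until trial end, ascending to 0
    acc = {1: [], -1: []}
    for tr, ch in zip(trials, choices):
        if ch not in (1, -1) or tr.duration < window - 1e-9:
            continue
        if tr.state_changes is None:
            raise ValueError("reverse correlation needs the hidden-state trajectory")
        n_tr = int(round(tr.duration / dt))
        edges = np.linspace(0.0, tr.duration, n_tr + 1)
        dR = np.histogram(tr.right_clicks, bins=edges)[0] / dt
        dL = np.histogram(tr.left_clicks, bins=edges)[0] / dt
        sR = np.convolve(dR, kern)[: n_tr]
        sL = np.convolve(dL, kern)[: n_tr]
        d = sR - sL
        centers = 0.5 * (edges[:-1] + edges[1:])
        state1 = np.array([tr.state_at(t) == 1 for t in centers])
        expected = np.where(state1, task.rate_high - task.rate_low,
                            -(task.rate_high - task.rate_low))
        e = d - expected
        acc[ch].append(e[-n_bins:])
    mean, sd, norm, n_tr_d = {}, {}, {}, {}
    for ch, lst in acc.items():
        if not lst:
            continue
        arr = np.asarray(lst)
        m = arr.mean(axis=0)
        mean[ch] = m
        sd[ch] = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(m)
        integral = np.trapezoid(m, dx=dt)
        norm[ch] = m / integral if integral != 0 else np.full_like(m, np.nan)
        n_tr_d[ch] = arr.shape[0]
    return KernelCurve(time_to_end=t_axis, mean=mean, sd=sd, normalized=norm,
                       n_trials=n_tr_d)
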