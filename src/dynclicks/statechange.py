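"""Model-predicted changes of mind and state-change-triggered responses.

A model-predicted state change is a crossing of the decision boundary B
by the 100 ms running average of the posterior mean accumulator value.
Crossings within 200 ms of the trial edges are excluded, as are changes
that are immediately reversed, identified by two strength criteria:
(i) the running-average means in the 100 ms before / after the crossing
must lie on the pre- / post-change side of B, and (ii) the slope of the
running average at the crossing must have the sign of the new state.

Residual firing rates (rate minus the unit's trial-averaged rate at each
time point) are realigned to the change time plus a 100 ms response lag,
masked outside the neighboring state changes, averaged by change
direction (into the unit's preferred vs non-preferred state), and the
per-bin discriminability d' is tested against a permutation distribution
of direction labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neural import RateMatrix, nanmean_quiet, nanstd_quiet, permutation_pvalue

__all__ = [
    "StateChangeEvent",
    "STRResult",
    "detect_model_changes",
    "detect_generative_changes",
    "align_residuals",
    "compute_str",
    "dprime",
    "dprime_significance",
    "fraction_significant",
    "residual_rates",
    "state_change_tuning_events",
]


@dataclass
class StateChangeEvent:
    trial_id: int
    time: float            # s from stimulus onset
    direction: int         # state entered: 1 (go-right / a above B) or 2
    source: str            # "model" or "generative"
    included: bool = True
    prev_time: float | None = None   # neighboring change times (for masking)
    next_time: float | None = None


@dataclass
class STRResult:
    lags: np.ndarray               # s relative to change (+ response lag applied)
    str_pref: np.ndarray           # mean residual trace, changes into preferred state
    str_nonpref: np.ndarray
    sem_pref: np.ndarray
    sem_nonpref: np.ndarray
    n_pref: int
    n_nonpref: int
    dprime: np.ndarray | None = None
    p_values: np.ndarray | None = None
    significant: np.ndarray | None = None


def _running_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered boxcar over n samples, truncated and renormalized at edges."""
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_model_changes(times: np.ndarray, mean_trace: np.ndarray, B: float,
                         trial_id: int = 0, duration: float | None = None,
                         edge: float = 0.2, run_avg_bins: int = 100,
                         strength_window: float = 0.1,
                         slope_halfwidth: float = 0.01) -> list:
    """Boundary crossings of the smoothed posterior mean, with exclusions.

    ``times`` must be a uniform grid (1 ms by default upstream).  Returns
    all crossings as events; those failing the edge or strength criteria
    carry ``included=False``.
    """
    times = np.asarray(times, dtype=float)
    x = _running_average(np.asarray(mean_trace, dtype=float), run_avg_bins)
    if duration is None:
        duration = float(times[-1])
    dt = times[1] - times[0] if times.size > 1 else 1e-3
    if times.size < 2 or duration < 2 * edge:
        return []
    above = x > B
    flips = np.nonzero(above[1:] != above[:-1])[0] + 1  # first sample past B
    events = []
    cross_times = times[flips]
    for i, k in enumerate(flips):
        t_c = times[k]
        direction = 1 if above[k] else 2
        included = edge <= t_c <= duration - edge
        if included:
            pre = x[(times >= t_c - strength_window) & (times < t_c)]
            post = x[(times > t_c) & (times <= t_c + strength_window)]
            sign_new = 1.0 if direction == 1 else -1.0
            if pre.size == 0 or post.size == 0:
                included = False
            else:
                if not (np.sign(pre.mean() - B) == -sign_new and
                        np.sign(post.mean() - B) == sign_new):
                    included = False
            if included:
                k_lo = max(0, k - max(1, int(round(slope_halfwidth / dt))))
                k_hi = min(times.size - 1, k + max(1, int(round(slope_halfwidth / dt))))
                slope = (x[k_hi] - x[k_lo]) / (times[k_hi] - times[k_lo])
                if np.sign(slope) != sign_new:
                    included = False
        ev = StateChangeEvent(trial_id=trial_id, time=float(t_c),
                              direction=direction, source="model", included=included,
                              prev_time=float(cross_times[i - 1]) if i > 0 else None,
                              next_time=float(cross_times[i + 1]) if i + 1 < len(flips) else None)
        events.append(ev)
    return events


def detect_generative_changes(trial, edge: float = 0.2) -> list:
    """True hidden-state change times as events (same edge window)."""
    changes = np.asarray(trial.state_changes, dtype=float)
    events = []
    state = trial.initial_state
    for i, t_c in enumerate(changes):
        state = 3 - state
        events.append(StateChangeEvent(
            trial_id=trial.trial_id, time=float(t_c), direction=state,
            source="generative",
            included=bool(edge <= t_c <= trial.duration - edge),
            prev_time=float(changes[i - 1]) if i > 0 else None,
            next_time=float(changes[i + 1]) if i + 1 < changes.size else None))
    return events


def residual_rates(rate: RateMatrix) -> np.ndarray:
    """Rate minus the unit's trial-averaged rate at each time point."""
    mean = nanmean_quiet(rate.rates, axis=0)
    return rate.rates - mean[None, :]


def align_residuals(rate: RateMatrix, events, lag: float = 0.1,
                    window: float = 0.55):
    """Sample residual rates around each included event.

    Neural time is sampled at t_c + lag + tau for tau in [-window,
    window] on the rate matrix's bin grid (nearest bin); samples beyond
    the neighboring state changes (or the trial's valid bins) are NaN.
    Returns (lags, matrix (n_events, n_lags), directions).
    """
    resid = residual_rates(rate)
    bw = rate.bin_width
    n_half = int(round(window / bw))
    lags = bw * np.arange(-n_half, n_half + 1)
    row_of = {tid: i for i, tid in enumerate(rate.trial_ids)}
    rows, dirs = [], []
    for ev in events:
        if not ev.included:
            continue
        i = row_of.get(ev.trial_id)
        if i is None:
            continue
        sample_t = ev.time + lag + lags
        idx = np.round((sample_t - rate.bin_centers[0]) / bw).astype(int)
        ok = (idx >= 0) & (idx < rate.bin_centers.size)
        vals = np.full(lags.size, np.nan)
        vals[ok] = resid[i, idx[ok]]
        # neighbor masking in event time (lag applied consistently)
        if ev.prev_time is not None:
            vals[sample_t < ev.prev_time + lag] = np.nan
        if ev.next_time is not None:
            vals[sample_t > ev.next_time + lag] = np.nan
        rows.append(vals)
        dirs.append(ev.direction)
    if not rows:
        return lags, np.empty((0, lags.size)), np.empty(0, dtype=int)
    return lags, np.asarray(rows), np.asarray(dirs, dtype=int)


def _group_moments(x: np.ndarray):
    """NaN-aware per-column (n, mean, ddof-1 variance)."""
    finite = np.isfinite(x)
    n = finite.sum(axis=0)
    safe = np.where(finite, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = safe.sum(axis=0) / n
        var = (np.where(finite, (x - mean[None, :]) ** 2, 0.0).sum(axis=0)
               / np.maximum(n - 1, 1))
    return n, mean, var


def dprime(mat: np.ndarray, is_pref: np.ndarray) -> np.ndarray:
    """Per-column d' = (mean_pref - mean_nonpref) / pooled SD.

    Pooled SD weights each direction by its event count; columns with
    fewer than two finite samples per direction are NaN; zero pooled SD
    gives d' = 0 by convention.
    """
    n1, m1, v1 = _group_moments(mat[is_pref])
    n2, m2, v2 = _group_moments(mat[~is_pref])
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
        out = np.where(s2 > 0, (m1 - m2) / np.sqrt(np.where(s2 > 0, s2, 1.0)), 0.0)
    out = np.where((n1 < 2) | (n2 < 2), np.nan, out)
    return out


def dprime_significance(mat: np.ndarray, is_pref: np.ndarray, n_perm: int = 250,
                        alpha: float = 0.05, rng=None):
    """d'(t) with two-tailed permutation significance over direction labels."""
    rng = np.random.default_rng(rng)
    if is_pref.sum() < 2 or (~is_pref).sum() < 2:
        raise ValueError("need at least two events per direction")
    obs = dprime(mat, is_pref)
    perm = np.empty((n_perm, mat.shape[1]))
    for p in range(n_perm):
        perm[p] = dprime(mat, rng.permutation(is_pref))
    finite = np.isfinite(obs)
    pvals = np.full(mat.shape[1], np.nan)
    pvals[finite] = permutation_pvalue(obs[finite], perm[:, finite])
    return obs, pvals, pvals < alpha


def compute_str(rate: RateMatrix, events, preferred_side: str, lag: float = 0.1,
                window: float = 0.55, n_perm: int = 250, min_events: int = 5,
                rng=None) -> STRResult | None:
    """State-change-triggered residual response for one unit.

    ``preferred_side`` ("right"/"left") maps change directions onto
    preferred (into state 1 for right-preferring units) vs non-preferred.
    Returns None when fewer than ``min_events`` per direction survive.
    """
    lags, mat, dirs = align_residuals(rate, events, lag=lag, window=window)
    pref_state = 1 if preferred_side == "right" else 2
    is_pref = dirs == pref_state
    if is_pref.sum() < min_events or (~is_pref).sum() < min_events:
        return None
    def _stats(m):
        mean = nanmean_quiet(m, axis=0)
        n = np.sum(np.isfinite(m), axis=0)
        sem = nanstd_quiet(m, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        return mean, sem
    mp, sp = _stats(mat[is_pref])
    mn, sn = _stats(mat[~is_pref])
    d, p, sig = dprime_significance(mat, is_pref, n_perm=n_perm, rng=rng)
    return STRResult(lags=lags, str_pref=mp, str_nonpref=mn, sem_pref=sp,
                     sem_nonpref=sn, n_pref=int(is_pref.sum()),
                     n_nonpref=int((~is_pref).sum()), dprime=d, p_values=p,
                     significant=sig)


def fraction_significant(str_results: list) -> tuple[np.ndarray, np.ndarray]:
    """Population fraction of units with significant d' per peri-change bin."""
    usable = [r for r in str_results if r is not None]
    if not usable:
        raise ValueError("no usable STR results")
    lags = usable[0].lags
    sig = np.array([np.where(np.isfinite(r.p_values), r.significant, np.nan)
                    for r in usable], dtype=float)
    return lags, nanmean_quiet(sig, axis=0)


def state_change_tuning_events(posteriors: dict, events, rate: RateMatrix,
                               a_edges=None, n_rate_bins: int = 100,
                               lag: float = 0.1, window: float = 0.55,
                               mask_half: float = 0.3):
    """Joint (t - t_c, a, r) distribution for state-change-aligned tuning.

    Same construction as :func:`dynclicks.tuning.build_joint` but with
    time measured relative to each included change; the +-``mask_half``
    interval around the change is excluded (the accumulator distribution
    is too narrow there to estimate tuning), as are samples beyond the
    neighboring changes.  Rates are sampled with the response lag.
    """
    from .tuning import JointDistribution, default_a_edges

    a_edges = default_a_edges() if a_edges is None else np.asarray(a_edges, dtype=float)
    bw = rate.bin_width
    n_half = int(round(window / bw))
    rel_centers = bw * np.arange(-n_half, n_half + 1)
    n_t, n_a = rel_centers.size, a_edges.size - 1
    sub = rate.rates
    finite = np.isfinite(sub)
    r_lo, r_hi = np.nanmin(sub), np.nanmax(sub)
    if r_hi <= r_lo:
        r_hi = r_lo + 1e-9
    r_edges = np.linspace(r_lo, r_hi, n_rate_bins + 1)
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    mass = np.zeros((n_t, n_a, n_rate_bins))
    counts = np.zeros(n_t)
    row_of = {tid: i for i, tid in enumerate(rate.trial_ids)}
    for ev in events:
        if not ev.included or ev.trial_id not in posteriors:
            continue
        i = row_of.get(ev.trial_id)
        if i is None:
            continue
        pg = posteriors[ev.trial_id]
        fine_centers = pg.a_centers
        a_idx = np.clip(np.searchsorted(a_edges, fine_centers, side="right") - 1, 0, n_a - 1)
        for k, tau in enumerate(rel_centers):
            if abs(tau) < mask_half:
                continue
            t_abs = ev.time + tau
            if ev.prev_time is not None and t_abs < ev.prev_time:
                continue
            if ev.next_time is not None and t_abs > ev.next_time:
                continue
            lo, hi = t_abs - bw / 2, t_abs + bw / 2
            m = (pg.times >= lo) & (pg.times < hi)
            if not m.any() or hi > pg.times[-1] + 1e-9 or lo < -1e-9:
                continue
            slab_fine = pg.mass[m].mean(axis=0)
            slab = np.zeros(n_a)
            np.add.at(slab, a_idx, slab_fine)
            r_t = ev.time + lag + tau
            b_idx = int(round((r_t - rate.bin_centers[0]) / bw))
            if not (0 <= b_idx < rate.bin_centers.size):
                continue
            r_val = sub[i, b_idx]
            if not np.isfinite(r_val):
                continue
            r_idx = min(max(int(np.searchsorted(r_edges, r_val, side="right") - 1), 0),
                        n_rate_bins - 1)
            mass[k, :, r_idx] += slab
            counts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mass = np.where(counts[:, None, None] > 0,
                        mass / np.maximum(counts, 1)[:, None, None], 0.0)
    return JointDistribution(mass=mass, time_centers=rel_centers, a_edges=a_edges,
                             rate_centers=r_centers, counts=counts)
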