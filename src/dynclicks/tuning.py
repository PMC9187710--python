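"""Evidence-tuning maps and their rank-1 decomposition.

For each unit, the joint distribution P(r, a, t) is built by pushing each
trial's posterior accumulator mass p(a) (1 ms / 0.1-a resolution,
downsampled) into coarse bins of time (25 ms), accumulation value
(10 bins: 8 inner bins of width 1.625 symmetric about 0 plus two
unbounded tail bins), and the unit's firing rate (100 bins spanning its
min-max).  Each time slab is normalized by the number of contributing
trials.  The conditional map E[r | a, t] and its residual
E[dr | a, t] = E[r | a, t] - E[r | t] follow, and the residual map is
approximated by a rank-1 outer product m(t) * f(a) via the SVD, with
variance explained s1 / sum(s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .neural import RateMatrix, nanmean_quiet

__all__ = [
    "JointDistribution",
    "TuningMap",
    "Rank1Decomposition",
    "default_a_edges",
    "downsample_posterior",
    "build_joint",
    "tuning_map",
    "rank1",
    "zscore_rates",
    "population_map",
]


def default_a_edges(n_inner: int = 8, width: float = 1.625) -> np.ndarray:
    """Accumulator bin edges: n_inner central bins plus two unbounded tails."""
    half = n_inner / 2.0 * width
    inner = np.linspace(-half, half, n_inner + 1)
    return np.concatenate([[-np.inf], inner, [np.inf]])


def _a_centers(a_edges: np.ndarray) -> np.ndarray:
    centers = 0.5 * (a_edges[:-1] + a_edges[1:])
    w = a_edges[2] - a_edges[1]
    if not np.isfinite(centers[0]):
        centers[0] = a_edges[1] - 0.5 * w
    if not np.isfinite(centers[-1]):
        centers[-1] = a_edges[-2] + 0.5 * w
    return centers


@dataclass
class JointDistribution:
    """P(r, a, t) as (n_t, n_a, n_r) mass, slab-normalized by trial count."""

    mass: np.ndarray
    time_centers: np.ndarray
    a_edges: np.ndarray
    rate_centers: np.ndarray
    counts: np.ndarray  # contributing trials per time bin


@dataclass
class TuningMap:
    time_centers: np.ndarray
    a_edges: np.ndarray
    e_r: np.ndarray        # (n_t, n_a) conditional expectation E[r|a,t]
    residual: np.ndarray   # E[dr|a,t]
    p_a_given_t: np.ndarray
    valid: np.ndarray      # boolean (n_t, n_a)
    time_avg: np.ndarray   # E[dr|a] averaged over unmasked slices
    counts: np.ndarray | None = None  # contributing trials per time bin

    @property
    def a_centers(self) -> np.ndarray:
        return _a_centers(self.a_edges)


@dataclass
class Rank1Decomposition:
    m_t: np.ndarray                # temporal gain, units of the map
    f_a: np.ndarray                # tuning curve, range exactly 1
    variance_explained: float      # s1 / sum(s)
    time_centers: np.ndarray
    a_centers: np.ndarray

    def reconstruction(self) -> np.ndarray:
        return np.outer(self.m_t, self.f_a)


def downsample_posterior(pg, time_edges: np.ndarray, a_edges: np.ndarray):
    """Average fine posterior slices into coarse (t, a) slabs.

    A slab contributes only if fully covered by the trial (slab end <=
    final posterior time).  Returns (slab_mass (n_t, n_a), covered mask).
    """
    n_t = time_edges.size - 1
    n_a = a_edges.size - 1
    fine_centers = pg.a_centers
    a_idx = np.clip(np.searchsorted(a_edges, fine_centers, side="right") - 1, 0, n_a - 1)
    coarse = np.zeros((pg.mass.shape[0], n_a))
    for j in range(n_a):
        cols = a_idx == j
        if cols.any():
            coarse[:, j] = pg.mass[:, cols].sum(axis=1)
    out = np.zeros((n_t, n_a))
    covered = np.zeros(n_t, dtype=bool)
    t_end = pg.times[-1]
    for k in range(n_t):
        if time_edges[k + 1] > t_end + 1e-9:
            continue
        m = (pg.times >= time_edges[k]) & (pg.times < time_edges[k + 1])
        if not m.any():
            continue
        out[k] = coarse[m].mean(axis=0)
        covered[k] = True
    return out, covered


def build_joint(rate: RateMatrix, posteriors: dict, trials, a_edges=None,
                n_rate_bins: int = 100, t_max: float | None = None) -> JointDistribution:
    """Accumulate posterior mass into the (t, a, r) joint for one unit.

    ``posteriors`` maps trial_id -> PosteriorGrid.  Time bins are the
    rate matrix's stimulus-aligned 25 ms bins from 0 to ``t_max``; the
    rate bin per (trial, time bin) is the unit's smoothed rate in that
    bin, binned over its min-max range.
    """
    if rate.alignment != "stimulus_onset":
        raise ValueError("joint distribution requires stimulus-aligned rates")
    a_edges = default_a_edges() if a_edges is None else np.asarray(a_edges, dtype=float)
    bw = rate.bin_width
    sel = rate.bin_centers >= 0
    if t_max is not None:
        sel &= rate.bin_centers <= t_max
    tc = rate.bin_centers[sel]
    time_edges = np.concatenate([tc - bw / 2, [tc[-1] + bw / 2]])
    sub_rates = rate.rates[:, sel]
    finite = np.isfinite(sub_rates)
    if not finite.any():
        raise ValueError("no unmasked rates to bin")
    r_lo, r_hi = np.nanmin(sub_rates), np.nanmax(sub_rates)
    if r_hi <= r_lo:
        r_hi = r_lo + 1e-9
    r_edges = np.linspace(r_lo, r_hi, n_rate_bins + 1)
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    n_t, n_a = tc.size, a_edges.size - 1
    mass = np.zeros((n_t, n_a, n_rate_bins))
    counts = np.zeros(n_t)
    row_of = {tid: i for i, tid in enumerate(rate.trial_ids)}
    for tid, pg in posteriors.items():
        i = row_of.get(tid)
        if i is None:
            raise ValueError(f"posterior for unknown trial {tid}")
        slab, covered = downsample_posterior(pg, time_edges, a_edges)
        for k in np.nonzero(covered)[0]:
            r_val = sub_rates[i, k]
            if not np.isfinite(r_val):
                continue
            r_idx = min(int(np.searchsorted(r_edges, r_val, side="right") - 1),
                        n_rate_bins - 1)
            r_idx = max(r_idx, 0)
            mass[k, :, r_idx] += slab[k]
            counts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mass = np.where(counts[:, None, None] > 0, mass / np.maximum(counts, 1)[:, None, None], 0.0)
    return JointDistribution(mass=mass, time_centers=tc, a_edges=a_edges,
                             rate_centers=r_centers, counts=counts)


def tuning_map(joint: JointDistribution, min_trials: int = 1) -> TuningMap:
    """Conditional expectation map and its residual from the joint."""
    p_at = joint.mass.sum(axis=2)                      # (t, a)
    p_t = p_at.sum(axis=1, keepdims=True)
    valid = (p_at > 1e-12) & (joint.counts[:, None] >= min_trials)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_r = np.where(valid, (joint.mass @ joint.rate_centers) / np.where(p_at > 0, p_at, 1.0), np.nan)
        p_a_given_t = np.where(p_t > 0, p_at / np.where(p_t > 0, p_t, 1.0), 0.0)
    e_r_t = np.nansum(np.where(valid, p_a_given_t * e_r, 0.0), axis=1)
    # renormalize the slice mean over the valid cells only
    w_valid = np.where(valid, p_a_given_t, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_r_t = np.where(w_valid > 0, e_r_t / np.where(w_valid > 0, w_valid, 1.0), np.nan)
    residual = e_r - e_r_t[:, None]
    slice_ok = w_valid > 0
    time_avg = nanmean_quiet(np.where(valid & slice_ok[:, None], residual, np.nan), axis=0)
    return TuningMap(time_centers=joint.time_centers, a_edges=joint.a_edges,
                     e_r=e_r, residual=residual, p_a_given_t=p_a_given_t,
                     valid=valid, time_avg=time_avg, counts=joint.counts.copy())


def rank1(tmap: TuningMap, preferred_side: str = "right",
          max_masked_frac: float = 0.05) -> Rank1Decomposition:
    """Rank-1 SVD approximation of the residual map.

    Masked cells are zero-filled when they cover less than
    ``max_masked_frac`` of the map; otherwise time rows containing
    masked cells are dropped.  The sign is fixed so the tuning curve
    increases toward the unit's preferred side, and f(a) is scaled to
    unit range (m(t) absorbs the scale: m = u1 s1 range(v1)).
    """
    M = tmap.residual.copy()
    valid = tmap.valid & np.isfinite(M)
    rows_any = valid.any(axis=1)
    M = M[rows_any]
    valid = valid[rows_any]
    times = tmap.time_centers[rows_any]
    if M.size == 0 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("tuning map too masked for a rank-1 decomposition")
    masked_frac = 1.0 - valid.mean()
    if masked_frac <= max_masked_frac:
        M = np.where(valid, M, 0.0)
    else:
        keep = valid.all(axis=1)
        if keep.sum() < 2:
            cols = valid.all(axis=0)
            if cols.sum() < 2:
                raise ValueError("tuning map too masked for a rank-1 decomposition")
            M = np.where(valid, M, 0.0)[:, cols]
            a_centers = tmap.a_centers[cols]
            u, s, vt = np.linalg.svd(M, full_matrices=False)
            return _assemble_rank1(u, s, vt, times, a_centers, preferred_side)
        M = M[keep]
        times = times[keep]
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    return _assemble_rank1(u, s, vt, times, tmap.a_centers, preferred_side)


def _assemble_rank1(u, s, vt, times, a_centers, preferred_side):
    u1, s1, v1 = u[:, 0], s[0], vt[0]
    # orient f to increase toward the preferred side
    slope = np.polyfit(a_centers, v1, 1)[0]
    want_positive = preferred_side != "left"
    if (slope < 0) == want_positive:
        u1, v1 = -u1, -v1
    rng_v = float(v1.max() - v1.min())
    if rng_v == 0:
        rng_v = 1.0
    m_t = u1 * s1 * rng_v
    f_a = v1 / rng_v
    ve = float(s1 / s.sum()) if s.sum() > 0 else float("nan")
    return Rank1Decomposition(m_t=m_t, f_a=f_a, variance_explained=ve,
                              time_centers=times, a_centers=np.asarray(a_centers))


def zscore_rates(rate: RateMatrix) -> RateMatrix:
    """Z-score a unit's rates over all unmasked stimulus-to-movement bins."""
    window = rate.valid & (rate.bin_centers[None, :] >= 0)
    vals = rate.rates[window]
    vals = vals[np.isfinite(vals)]
    mu = float(vals.mean()) if vals.size else 0.0
    sd = float(vals.std(ddof=0)) if vals.size else 1.0
    if sd == 0:
        sd = 1.0
    return dc_replace(rate, rates=(rate.rates - mu) / sd)


def population_map(maps: dict, classification: dict, min_trials: int = 10,
                   min_cells: int = 1):
    """Cell-averaged z-scored residual map and its rank-1 decomposition.

    ``maps`` maps unit_id -> TuningMap built from z-scored rates.  The
    accumulation axis is inverted for left-preferring cells before
    averaging; cells contribute to a (t, a) cell only where their map is
    valid and supported by >= ``min_trials`` trials.
    """
    sel = [u for u, c in classification.items() if c.selective and u in maps]
    if not sel:
        raise ValueError("no selective cells with tuning maps")
    ref = maps[sel[0]]
    acc = np.zeros_like(ref.residual)
    n = np.zeros_like(ref.residual)
    for u in sel:
        tm = maps[u]
        use = tm.valid & np.isfinite(tm.residual)
        if tm.counts is not None:
            use &= (tm.counts >= min_trials)[:, None]
        r = tm.residual
        if classification[u].preferred_side == "left":
            r = r[:, ::-1]
            use = use[:, ::-1]
        acc += np.where(use, r, 0.0)
        n += use
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(n >= min_cells, acc / np.maximum(n, 1), np.nan)
    pop = TuningMap(time_centers=ref.time_centers, a_edges=ref.a_edges,
                    e_r=avg, residual=avg, p_a_given_t=ref.p_a_given_t,
                    valid=np.isfinite(avg),
                    time_avg=nanmean_quiet(avg, axis=0))
    return pop, rank1(pop, preferred_side="right")
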