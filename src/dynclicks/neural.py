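"""Firing-rate construction and choice-selectivity analyses.

Rates are spike counts in 25 ms bins smoothed with a causal (one-sided,
renormalized) Gaussian of SD 100 ms.  Stimulus-onset-aligned rates are
masked after movement; movement-aligned rates are masked before stimulus
onset.  Cells are "active" if their mean rate from 1 s before stimulus
onset to movement exceeds 1 Hz, and "pre-movement side-selective" if
per-trial spike counts between stimulus onset and movement differ by
final choice (two-tailed Welch t-test, p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import causal_gaussian_kernel

__all__ = [
    "RateMatrix",
    "CellClassification",
    "compute_rates",
    "classify_cells",
    "auc_timecourse",
    "choice_outcome_psth",
    "population_psth",
    "permutation_pvalue",
]


@dataclass
class RateMatrix:
    """Binned, causally smoothed, event-aligned rates for one unit."""

    unit_id: int
    alignment: str                 # "stimulus_onset" or "movement"
    bin_centers: np.ndarray        # s relative to the alignment event
    rates: np.ndarray              # (n_trials, n_bins), NaN where masked
    valid: np.ndarray              # boolean mask, same shape
    trial_ids: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass
class CellClassification:
    unit_id: int
    active: bool
    selective: bool
    preferred_side: str            # "right", "left", or "none"
    t_stat: float
    p_value: float
    mean_rate: float


def nanmean_quiet(x, axis=None):
    """np.nanmean without the all-NaN-slice RuntimeWarning (masked bins)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(x, axis=axis)


def nanstd_quiet(x, axis=None, ddof=0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanstd(x, axis=axis, ddof=ddof)


def _movement_time(trial) -> float:
    return trial.movement if trial.movement is not None else trial.duration


def compute_rates(spikes: pd.DataFrame, trials, alignment: str = "stimulus_onset",
                  bin_width: float = 0.025, smooth_sd: float = 0.1,
                  t_start: float = -1.0, t_stop: float | None = None,
                  units=None) -> dict:
    """Per-unit smoothed rate matrices aligned to an event.

    Spike times in ``spikes`` are relative to stimulus onset; for
    movement alignment they are re-referenced per trial.  Returns
    {unit_id: RateMatrix}.
    """
    if bin_width <= 0 or smooth_sd <= 0:
        raise ValueError("bin_width and smooth_sd must be positive")
    if alignment not in ("stimulus_onset", "movement"):
        raise ValueError(f"unknown alignment {alignment!r}")
    moves = np.array([_movement_time(t) for t in trials])
    if t_stop is None:
        t_stop = (float(moves.max()) + 2 * bin_width if alignment == "stimulus_onset"
                  else 2 * bin_width)
    n_bins = int(round((t_stop - t_start) / bin_width))
    edges = t_start + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kern = causal_gaussian_kernel(smooth_sd, bin_width)
    trial_ids = np.array([t.trial_id for t in trials])
    row_of = {tid: i for i, tid in enumerate(trial_ids)}
    if units is None:
        units = sorted(spikes["unit_id"].unique()) if len(spikes) else []
    out = {}
    grouped = dict(tuple(spikes.groupby("unit_id"))) if len(spikes) else {}
    for u in units:
        counts = np.zeros((len(trials), n_bins))
        sub = grouped.get(u)
        if sub is not None:
            for tid, g in sub.groupby("trial_id"):
                i = row_of.get(tid)
                if i is None:
                    continue
                st = g["spike_time_s"].to_numpy()
                if alignment == "movement":
                    st = st - moves[i]
                counts[i] = np.histogram(st, bins=edges)[0]
        sm = np.apply_along_axis(lambda c: np.convolve(c, kern)[:n_bins], 1, counts)
        rates = sm / bin_width
        valid = np.ones_like(rates, dtype=bool)
        for i, tr in enumerate(trials):
            if alignment == "stimulus_onset":
                valid[i] = edges[:-1] < moves[i]          # masked after movement
            else:
                valid[i] = edges[1:] > -moves[i]          # masked before stimulus onset
        rates = np.where(valid, rates, np.nan)
        out[u] = RateMatrix(unit_id=u, alignment=alignment, bin_centers=centers,
                            rates=rates, valid=valid, trial_ids=trial_ids)
    return out


def classify_cells(spikes: pd.DataFrame, trials, rate_threshold: float = 1.0,
                   alpha: float = 0.05, units=None) -> dict:
    """Active / pre-movement side-selective classification per unit.

    Activity uses the mean rate over [-1 s, movement]; selectivity is a
    Welch two-tailed t-test on per-trial spike counts in [0, movement]
    split by final choice.  Selectivity requires activity and at least
    two trials per side.
    """
    moves = np.array([_movement_time(t) for t in trials])
    choices = np.array([t.choice if t.choice is not None else 0 for t in trials])
    trial_ids = np.array([t.trial_id for t in trials])
    row_of = {tid: i for i, tid in enumerate(trial_ids)}
    if units is None:
        units = sorted(spikes["unit_id"].unique()) if len(spikes) else []
    grouped = dict(tuple(spikes.groupby("unit_id"))) if len(spikes) else {}
    out = {}
    for u in units:
        counts_act = np.zeros(len(trials))
        counts_sel = np.zeros(len(trials))
        sub = grouped.get(u)
        if sub is not None:
            for tid, g in sub.groupby("trial_id"):
                i = row_of.get(tid)
                if i is None:
                    continue
                st = g["spike_time_s"].to_numpy()
                counts_act[i] = np.count_nonzero((st >= -1.0) & (st < moves[i]))
                counts_sel[i] = np.count_nonzero((st >= 0.0) & (st < moves[i]))
        mean_rate = float(np.mean(counts_act / (moves + 1.0)))
        active = mean_rate > rate_threshold
        right = counts_sel[choices == 1]
        left = counts_sel[choices == -1]
        t_stat, p, selective, side = math.nan, math.nan, False, "none"
        if right.size >= 2 and left.size >= 2:
            t_stat, p = stats.ttest_ind(right, left, equal_var=False)
            t_stat, p = float(t_stat), float(p)
            if active and p < alpha:
                selective = True
                side = "right" if right.mean() > left.mean() else "left"
        out[u] = CellClassification(unit_id=u, active=active, selective=selective,
                                    preferred_side=side, t_stat=t_stat, p_value=p,
                                    mean_rate=mean_rate)
    return out


def _auc_from_ranks(ranks: np.ndarray, is_pos: np.ndarray) -> np.ndarray:
    """AUC from midranks; ``is_pos`` can be (n,) or a (P, n) label stack."""
    if is_pos.ndim == 1:
        n_pos = is_pos.sum()
        n_neg = is_pos.size - n_pos
        rank_sum = float(ranks[is_pos].sum())
        return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    n_pos = is_pos.sum(axis=1)
    n_neg = is_pos.shape[1] - n_pos
    rank_sum = is_pos.astype(float) @ ranks
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def permutation_pvalue(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Two-tailed permutation p via min-tail doubling, (1+k)/(P+1) form."""
    n_perm = perm.shape[0]
    ge = (perm >= obs[None]).sum(axis=0)
    le = (perm <= obs[None]).sum(axis=0)
    p = 2.0 * np.minimum((1.0 + ge) / (n_perm + 1.0), (1.0 + le) / (n_perm + 1.0))
    return np.minimum(p, 1.0)


def auc_timecourse(rate: RateMatrix, choices, n_perm: int = 250, run_len: int = 8,
                   alpha: float = 0.05, rng=None):
    """Choice-classification AUC per time bin with permutation significance.

    AUC treats the bin's rate as a classifier of right vs left choice
    (ties count 1/2; degenerate bins give 0.5).  Significance per bin is
    a two-tailed permutation test shuffling choice labels; the latency is
    the start of the first run of ``run_len`` consecutive significant
    bins.  Returns (auc, p_values, significant, latency_s).
    """
    rng = np.random.default_rng(rng)
    choices = np.asarray(choices)
    n_trials, n_bins = rate.rates.shape
    auc = np.full(n_bins, 0.5)
    pvals = np.full(n_bins, np.nan)
    is_right = choices == 1
    for b in range(n_bins):
        col = rate.rates[:, b]
        ok = np.isfinite(col)
        r_n = int((is_right & ok).sum())
        l_n = int((~is_right & ok).sum())
        if r_n < 2 or l_n < 2:
            continue
        vals = col[ok]
        if np.all(vals == vals[0]):
            auc[b] = 0.5
            pvals[b] = 1.0
            continue
        ranks = stats.rankdata(vals)
        pos = is_right[ok]
        auc[b] = float(_auc_from_ranks(ranks, pos))
        perm_labels = np.empty((n_perm, vals.size), dtype=bool)
        for p in range(n_perm):
            perm_labels[p] = rng.permutation(pos)
        perm_auc = _auc_from_ranks(ranks, perm_labels)
        pvals[b] = permutation_pvalue(np.atleast_1d(auc[b]), perm_auc[:, None])[0]
    significant = pvals < alpha
    latency = np.nan
    run = 0
    for b in range(n_bins):
        run = run + 1 if significant[b] else 0
        if run >= run_len:
            latency = float(rate.bin_centers[b - run_len + 1])
            break
    return auc, pvals, significant, latency


def choice_outcome_psth(rate: RateMatrix, trials) -> pd.DataFrame:
    """Trial-averaged traces for one unit split by choice x outcome."""
    choices = np.array([t.choice if t.choice is not None else 0 for t in trials])
    hits = np.array([bool(t.hit) if t.hit is not None else False for t in trials])
    rows = []
    for ch, ch_label in ((1, "right"), (-1, "left")):
        for hit in (True, False):
            m = (choices == ch) & (hits == hit)
            if m.sum() == 0:
                continue
            sub = rate.rates[m]
            mean = nanmean_quiet(sub, axis=0)
            n_valid = np.sum(np.isfinite(sub), axis=0)
            sem = nanstd_quiet(sub, axis=0, ddof=1) / np.sqrt(np.maximum(n_valid, 1))
            rows.append({"unit_id": rate.unit_id, "choice": ch_label,
                         "outcome": "hit" if hit else "error",
                         "n_trials": int(m.sum()), "mean": mean, "sem": sem})
    return pd.DataFrame(rows)


def population_psth(rate_matrices: dict, trials, classification: dict,
                    duration_bins=(0.0, 0.5, 1.0, 1.5, 2.0)) -> pd.DataFrame:
    """Condition-averaged PSTH over pre-movement side-selective cells.

    Averages trials by (final-state-duration bin x whether the choice
    was to the cell's preferred side); rows carry mean and SEM traces.
    """
    duration_bins = np.asarray(duration_bins, dtype=float)
    choices = np.array([t.choice if t.choice is not None else 0 for t in trials])
    fsd = np.array([t.final_state_duration() for t in trials])
    dbin = np.clip(np.searchsorted(duration_bins, fsd, side="right") - 1, 0,
                   duration_bins.size - 2)
    rows = []
    sel_units = [u for u, c in classification.items() if c.selective]
    for u in sel_units:
        rm = rate_matrices[u]
        pref = 1 if classification[u].preferred_side == "right" else -1
        to_pref = choices == pref
        for b in range(duration_bins.size - 1):
            for is_pref, label in ((True, "preferred"), (False, "nonpreferred")):
                m = (dbin == b) & (to_pref == is_pref) & (choices != 0)
                if m.sum() == 0:
                    continue
                sub = rm.rates[m]
                mean = nanmean_quiet(sub, axis=0)
                n_valid = np.sum(np.isfinite(sub), axis=0)
                sem = nanstd_quiet(sub, axis=0, ddof=1) / np.sqrt(np.maximum(n_valid, 1))
                rows.append({"unit_id": u, "duration_bin": b, "condition": label,
                             "n_trials": int(m.sum()), "mean": mean, "sem": sem})
    return pd.DataFrame(rows)
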