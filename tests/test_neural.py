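"""Rate construction, cell classification, AUC timecourse, PSTHs."""

import numpy as np
import pandas as pd
import pytest

from dynclicks import neural
from dynclicks.neural import (RateMatrix, auc_timecourse, classify_cells,
                              compute_rates, population_psth)


def spikes_df(rows):
    return pd.DataFrame(rows, columns=["unit_id", "trial_id", "spike_time_s"])


class TestComputeRates:
    def test_empty_spike_train_gives_zero_rates(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.2, trial_id=0)]
        rm = compute_rates(spikes_df([]), trials, units=[0])[0]
        assert np.nansum(rm.rates) == 0.0

    def test_single_spike_unit_mass(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.2, trial_id=0)]
        rm = compute_rates(spikes_df([(0, 0, 0.4)]), trials)[0]
        total = np.nansum(rm.rates) * rm.bin_width  # spikes
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_causal_smoother_no_acausal_leakage(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.2, trial_id=0)]
        rm = compute_rates(spikes_df([(0, 0, 0.5)]), trials)[0]
        before = rm.bin_centers < 0.5 - rm.bin_width
        assert np.nansum(rm.rates[0, before]) == 0.0

    def test_constant_rate_unit_recovered(self, trial_factory):
        rng = np.random.default_rng(51)
        trials = [trial_factory(duration=1.0, movement=1.2, trial_id=i)
                  for i in range(300)]
        rows = []
        for i in range(300):
            n = rng.poisson(10.0 * 2.2)
            for t in np.sort(rng.uniform(-1.0, 1.2, n)):
                rows.append((0, i, t))
        rm = compute_rates(spikes_df(rows), trials)[0]
        sel = (rm.bin_centers > -0.5) & (rm.bin_centers < 0.9)
        mean_rate = np.nanmean(rm.rates[:, sel])
        assert mean_rate == pytest.approx(10.0, abs=0.5)

    def test_masking_by_alignment(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.1, trial_id=0)]
        stim = compute_rates(spikes_df([(0, 0, 0.2)]), trials)[0]
        assert not stim.valid[0, stim.bin_centers > 1.15].any()
        mov = compute_rates(spikes_df([(0, 0, 0.2)]), trials, alignment="movement")[0]
        assert not mov.valid[0, mov.bin_centers < -1.15].any()

    def test_bad_parameters_rejected(self, trial_factory):
        trials = [trial_factory(duration=1.0)]
        with pytest.raises(ValueError):
            compute_rates(spikes_df([]), trials, bin_width=0)
        with pytest.raises(ValueError):
            compute_rates(spikes_df([]), trials, smooth_sd=-1)
        with pytest.raises(ValueError):
            compute_rates(spikes_df([]), trials, alignment="go_cue")


class TestClassifyCells:
    def test_silent_unit_inactive(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.2, choice=1, trial_id=i)
                  for i in range(10)]
        cls = classify_cells(spikes_df([]), trials, units=[0])[0]
        assert not cls.active and not cls.selective

    def test_ground_truth_tuned_units_recovered(self, small_dataset):
        cls = classify_cells(small_dataset.spikes, small_dataset.trials)
        for spec in small_dataset.specs:
            c = cls[spec.unit_id]
            if spec.preferred_side == "none":
                continue
            assert c.selective
            assert c.preferred_side == spec.preferred_side

    def test_false_positive_rate_calibrated(self, trial_factory):
        """Untuned Poisson units are flagged at roughly the alpha level."""
        rng = np.random.default_rng(52)
        trials = [trial_factory(duration=1.0, movement=1.2,
                                choice=1 if i % 2 == 0 else -1, trial_id=i)
                  for i in range(60)]
        n_units, flagged = 400, 0
        for u in range(n_units):
            rows = []
            for i in range(60):
                for t in np.sort(rng.uniform(-1.0, 1.2, rng.poisson(8.0 * 2.2))):
                    rows.append((u, i, t))
            c = classify_cells(spikes_df(rows), trials, units=[u])[u]
            flagged += int(c.selective)
        fpr = flagged / n_units
        assert 0.02 <= fpr <= 0.09

    def test_too_few_trials_per_side_not_selective(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.2, choice=1, trial_id=i)
                  for i in range(6)]
        rows = [(0, i, t) for i in range(6)
                for t in np.linspace(0.05, 0.95, 12)]
        cls = classify_cells(spikes_df(rows), trials)[0]
        assert not cls.selective and cls.preferred_side == "none"


class TestAUC:
    def _rate_matrix(self, rates):
        rates = np.asarray(rates, dtype=float)
        n_trials, n_bins = rates.shape
        return RateMatrix(unit_id=0, alignment="stimulus_onset",
                          bin_centers=0.025 * np.arange(n_bins),
                          rates=rates, valid=np.ones_like(rates, dtype=bool),
                          trial_ids=np.arange(n_trials))

    def test_identical_distributions_give_half(self):
        rm = self._rate_matrix(np.ones((8, 3)))
        auc, p, sig, lat = auc_timecourse(rm, np.array([1, 1, 1, 1, -1, -1, -1, -1]),
                                          n_perm=50, rng=0)
        assert np.allclose(auc, 0.5)
        assert np.isnan(lat)

    def test_perfect_separation_gives_one_and_significant(self):
        rates = np.vstack([np.full((6, 10), 5.0), np.full((6, 10), 1.0)])
        rm = self._rate_matrix(rates)
        ch = np.array([1] * 6 + [-1] * 6)
        auc, p, sig, lat = auc_timecourse(rm, ch, n_perm=250, run_len=8, rng=1)
        assert np.allclose(auc, 1.0)
        assert sig.all()
        assert lat == pytest.approx(rm.bin_centers[0])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(53)
        rates = rng.normal(5, 2, size=(6, 4))
        rates[2, 1] = rates[5, 1]  # inject a tie
        ch = np.array([1, 1, 1, -1, -1, -1])
        rm = self._rate_matrix(rates)
        auc, *_ = auc_timecourse(rm, ch, n_perm=10, rng=2)
        for b in range(4):
            wins = 0.0
            for i in range(3):
                for j in range(3, 6):
                    if rates[i, b] > rates[j, b]:
                        wins += 1.0
                    elif rates[i, b] == rates[j, b]:
                        wins += 0.5
            assert auc[b] == pytest.approx(wins / 9.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(54)
        rates = rng.normal(5, 2, size=(10, 6))
        rm = self._rate_matrix(rates)
        ch = np.array([1] * 5 + [-1] * 5)
        a1, *_ = auc_timecourse(rm, ch, n_perm=10, rng=3)
        a2, *_ = auc_timecourse(rm, -ch, n_perm=10, rng=3)
        assert np.allclose(a1, 1.0 - a2)

    def test_null_permutation_pvalues_calibrated(self):
        """Per-bin false-positive rate near alpha on pure-noise units."""
        rng = np.random.default_rng(55)
        sig_frac = []
        for _ in range(60):
            rates = rng.normal(5, 1, size=(40, 8))
            rm = self._rate_matrix(rates)
            ch = np.array([1] * 20 + [-1] * 20)
            _, p, sig, _ = auc_timecourse(rm, ch, n_perm=100, rng=rng)
            sig_frac.append(np.mean(sig))
        fpr = float(np.mean(sig_frac))
        assert 0.01 <= fpr <= 0.10


class TestPopulationPSTH:
    def test_single_cell_single_condition_equals_trial_mean(self, trial_factory):
        trials = [trial_factory(duration=1.0, movement=1.2, choice=1, trial_id=i)
                  for i in range(4)]
        rng = np.random.default_rng(56)
        rows = [(0, i, t) for i in range(4)
                for t in np.sort(rng.uniform(0, 1.0, 20))]
        rms = compute_rates(spikes_df(rows), trials)
        from dynclicks.neural import CellClassification

        cls = {0: CellClassification(unit_id=0, active=True, selective=True,
                                     preferred_side="right", t_stat=3.0,
                                     p_value=0.01, mean_rate=20.0)}
        df = population_psth(rms, trials, cls, duration_bins=(0.0, 2.0))
        pref = df[df["condition"] == "preferred"].iloc[0]
        manual = np.nanmean(rms[0].rates, axis=0)
        assert np.allclose(pref["mean"][np.isfinite(manual)],
                           manual[np.isfinite(manual)], equal_nan=True)

    def test_flipping_preferred_side_swaps_traces(self, small_dataset):
        from dataclasses import replace

        rms = compute_rates(small_dataset.spikes, small_dataset.trials)
        cls = classify_cells(small_dataset.spikes, small_dataset.trials)
        sel = [u for u, c in cls.items() if c.selective][:1]
        u = sel[0]
        flipped = dict(cls)
        other = "left" if cls[u].preferred_side == "right" else "right"
        flipped[u] = replace(cls[u], preferred_side=other)
        a = population_psth({u: rms[u]}, small_dataset.trials, {u: cls[u]})
        b = population_psth({u: rms[u]}, small_dataset.trials, {u: flipped[u]})
        for db in sorted(set(a["duration_bin"])):
            pa = a[(a.duration_bin == db) & (a.condition == "preferred")]
            nb = b[(b.duration_bin == db) & (b.condition == "nonpreferred")]
            if len(pa) and len(nb):
                assert np.allclose(pa.iloc[0]["mean"], nb.iloc[0]["mean"],
                                   equal_nan=True)


class TestChoiceOutcomePSTH:
    def test_traces_split_by_choice_and_outcome(self, trial_factory):
        from dynclicks.neural import choice_outcome_psth

        trials = [trial_factory(duration=1.0, movement=1.2, trial_id=i,
                                choice=1 if i < 4 else -1, hit=i % 2 == 0)
                  for i in range(8)]
        rng = np.random.default_rng(57)
        rows = [(0, i, t) for i in range(8)
                for t in np.sort(rng.uniform(0, 1.0, 15 + 5 * i))]
        rm = compute_rates(spikes_df(rows), trials)[0]
        df = choice_outcome_psth(rm, trials)
        assert set(zip(df.choice, df.outcome)) == {
            ("right", "hit"), ("right", "error"), ("left", "hit"), ("left", "error")}
        # each condition's trace equals the manual average of its trials
        m = (np.array([t.choice for t in trials]) == 1) & \
            np.array([t.hit for t in trials])
        manual = np.nanmean(rm.rates[m], axis=0)
        got = df[(df.choice == "right") & (df.outcome == "hit")].iloc[0]["mean"]
        fin = np.isfinite(manual)
        assert np.allclose(got[fin], manual[fin])
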