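"""Joint distribution, tuning maps, and rank-1 decomposition."""

import numpy as np
import pytest

from dynclicks.neural import RateMatrix
from dynclicks.posterior import PosteriorGrid
from dynclicks.tuning import (Rank1Decomposition, TuningMap, build_joint,
                              default_a_edges, rank1, tuning_map, zscore_rates)


def make_rate_matrix(rates, bin_width=0.025, t0=0.0125):
    rates = np.asarray(rates, dtype=float)
    n_trials, n_bins = rates.shape
    return RateMatrix(unit_id=0, alignment="stimulus_onset",
                      bin_centers=t0 + bin_width * np.arange(n_bins),
                      rates=rates, valid=np.isfinite(rates),
                      trial_ids=np.arange(n_trials))


def make_posterior(times, a_edges, mass, B=0.0):
    return PosteriorGrid(times=np.asarray(times, dtype=float),
                         a_edges=np.asarray(a_edges, dtype=float),
                         mass=np.asarray(mass, dtype=float), choice=1, B=B)


def delta_posterior(duration, a_value, dt=1e-3, a_lim=8.0, da=0.1):
    times = np.arange(0, duration + dt / 2, dt)
    edges = np.arange(-a_lim, a_lim + da / 2, da)
    mass = np.zeros((times.size, edges.size - 1))
    k = np.searchsorted(edges, a_value, side="right") - 1
    mass[:, k] = 1.0
    return make_posterior(times, edges, mass)


class TestBuildJoint:
    def test_delta_posterior_all_mass_in_one_a_bin(self):
        rm = make_rate_matrix(np.full((3, 20), 5.0))
        posts = {i: delta_posterior(0.5, 0.0) for i in range(3)}
        j = build_joint(rm, posts, trials=None)
        a_idx = np.searchsorted(j.a_edges, 0.0, side="right") - 1
        p_a = j.mass.sum(axis=2)
        covered = j.counts > 0
        assert np.allclose(p_a[covered][:, a_idx], 1.0)
        assert np.allclose(p_a[covered].sum(axis=1), 1.0)

    def test_matches_naive_double_loop(self):
        """Cell-by-cell equality with a brute-force implementation."""
        rng = np.random.default_rng(61)
        n_trials, n_bins = 4, 12
        rates = rng.uniform(2, 20, size=(n_trials, n_bins))
        rm = make_rate_matrix(rates)
        a_edges_fine = np.arange(-4, 4.01, 0.1)
        posts = {}
        for i in range(n_trials):
            times = np.arange(0, 0.3 + 5e-4, 1e-3)
            m = rng.random((times.size, a_edges_fine.size - 1))
            m /= m.sum(axis=1, keepdims=True)
            posts[i] = make_posterior(times, a_edges_fine, m)
        j = build_joint(rm, posts, trials=None, n_rate_bins=10)
        # naive reimplementation
        a_edges = default_a_edges()
        sel = rm.bin_centers >= 0
        tc = rm.bin_centers[sel]
        bw = rm.bin_width
        time_edges = np.concatenate([tc - bw / 2, [tc[-1] + bw / 2]])
        r_lo, r_hi = rates.min(), rates.max()
        r_edges = np.linspace(r_lo, r_hi, 11)
        ref = np.zeros_like(j.mass)
        counts = np.zeros(tc.size)
        fine_centers = 0.5 * (a_edges_fine[:-1] + a_edges_fine[1:])
        for i in range(n_trials):
            pg = posts[i]
            for k in range(tc.size):
                if time_edges[k + 1] > pg.times[-1] + 1e-9:
                    continue
                in_slab = (pg.times >= time_edges[k]) & (pg.times < time_edges[k + 1])
                if not in_slab.any():
                    continue
                slab = pg.mass[in_slab].mean(axis=0)
                r_val = rates[i, k]
                r_idx = min(int(np.searchsorted(r_edges, r_val, side="right") - 1), 9)
                counts[k] += 1
                for jj, c in enumerate(fine_centers):
                    a_idx = min(int(np.searchsorted(a_edges, c, side="right") - 1),
                                a_edges.size - 2)
                    ref[k, a_idx, r_idx] += slab[jj]
        ref = np.where(counts[:, None, None] > 0,
                       ref / np.maximum(counts, 1)[:, None, None], 0.0)
        assert np.allclose(j.mass, ref, atol=1e-12)
        assert np.allclose(j.counts, counts)

    def test_mismatched_trial_rejected(self):
        rm = make_rate_matrix(np.full((2, 8), 3.0))
        posts = {5: delta_posterior(0.2, 0.0)}
        with pytest.raises(ValueError):
            build_joint(rm, posts, trials=None)


class TestTuningMap:
    def test_rate_independent_of_a_gives_zero_residual(self):
        rng = np.random.default_rng(62)
        rates = np.tile(rng.uniform(5, 15, size=(1, 16)), (6, 1))
        rm = make_rate_matrix(rates)
        posts = {}
        for i in range(6):
            times = np.arange(0, 0.4 + 5e-4, 1e-3)
            edges = np.arange(-4, 4.01, 0.1)
            m = rng.random((times.size, edges.size - 1))
            m /= m.sum(axis=1, keepdims=True)
            posts[i] = make_posterior(times, edges, m)
        tm = tuning_map(build_joint(rm, posts, trials=None))
        assert np.nanmax(np.abs(tm.residual[tm.valid])) < 1e-9

    def test_residual_property_weighted_slice_mean_is_zero(self, small_dataset):
        from dynclicks import neural
        from dynclicks.posterior import posterior_grid

        ds = small_dataset
        rms = neural.compute_rates(ds.spikes, ds.trials)
        posts = {tr.trial_id: posterior_grid(tr, ds.theta, tr.choice, dt_eval=5e-3)
                 for tr in ds.trials[:40]}
        tm = tuning_map(build_joint(rms[0], posts, ds.trials))
        resid_sum = np.nansum(np.where(tm.valid, tm.p_a_given_t * tm.residual, 0.0),
                              axis=1)
        assert np.nanmax(np.abs(resid_sum)) < 1e-9


class TestRank1:
    def _map_from_matrix(self, M):
        n_t, n_a = M.shape
        return TuningMap(time_centers=0.025 * np.arange(n_t),
                         a_edges=np.linspace(-4, 4, n_a + 1),
                         e_r=M, residual=M,
                         p_a_given_t=np.ones_like(M) / n_a,
                         valid=np.ones_like(M, dtype=bool),
                         time_avg=M.mean(axis=0))

    def test_separable_map_fully_explained(self):
        t = np.linspace(0, 1, 30)
        a = np.linspace(-3, 3, 10)
        M = np.outer(np.minimum(t / 0.5, 1.0) * 8.0, np.tanh(a))
        r1 = rank1(self._map_from_matrix(M))
        assert r1.variance_explained == pytest.approx(1.0, abs=1e-10)
        assert np.abs(r1.reconstruction() - M).max() < 1e-10
        assert (r1.f_a.max() - r1.f_a.min()) == pytest.approx(1.0, abs=1e-12)

    def test_two_component_variance_ratio(self):
        """Adding an orthogonal rank-1 term of relative magnitude eps gives
        variance explained 1 / (1 + eps)."""
        rng = np.random.default_rng(63)
        u1, _ = np.linalg.qr(rng.normal(size=(30, 2)))
        v1, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        for eps in (0.1, 0.5):
            M = np.outer(u1[:, 0], v1[:, 0]) + eps * np.outer(u1[:, 1], v1[:, 1])
            r1 = rank1(self._map_from_matrix(M))
            assert r1.variance_explained == pytest.approx(1 / (1 + eps), abs=1e-10)

    def test_invariance_to_axis_flip_and_scaling(self):
        rng = np.random.default_rng(64)
        M = rng.normal(size=(20, 10))
        ve = rank1(self._map_from_matrix(M)).variance_explained
        assert rank1(self._map_from_matrix(M[:, ::-1])).variance_explained == pytest.approx(ve, abs=1e-12)
        assert rank1(self._map_from_matrix(3.7 * M)).variance_explained == pytest.approx(ve, abs=1e-12)

    def test_sign_convention_follows_preferred_side(self):
        t = np.linspace(0, 1, 20)
        a = np.linspace(-3, 3, 10)
        M = np.outer(t, np.tanh(a))
        right = rank1(self._map_from_matrix(M), preferred_side="right")
        left = rank1(self._map_from_matrix(M), preferred_side="left")
        assert np.polyfit(a, right.f_a, 1)[0] > 0
        assert np.polyfit(a, left.f_a, 1)[0] < 0

    def test_fully_masked_map_rejected(self):
        M = np.full((5, 5), np.nan)
        tm = self._map_from_matrix(M)
        tm.valid[:] = False
        with pytest.raises(ValueError):
            rank1(tm)


class TestPopulationMap:
    def test_identical_cells_average_to_single_map(self, small_dataset):
        from dataclasses import replace

        from dynclicks import neural
        from dynclicks.posterior import posterior_grid
        from dynclicks.tuning import population_map

        ds = small_dataset
        rms = neural.compute_rates(ds.spikes, ds.trials)
        cls = neural.classify_cells(ds.spikes, ds.trials)
        u = [u for u, c in cls.items() if c.selective and c.preferred_side == "right"][0]
        posts = {tr.trial_id: posterior_grid(tr, ds.theta, tr.choice, dt_eval=5e-3)
                 for tr in ds.trials[:40]}
        tm = tuning_map(build_joint(zscore_rates(rms[u]), posts, ds.trials))
        pop, r1 = population_map({u: tm, 99: tm},
                                 {u: cls[u], 99: replace(cls[u], unit_id=99)},
                                 min_trials=5)
        both = np.isfinite(pop.residual) & np.isfinite(tm.residual)
        assert np.allclose(pop.residual[both], tm.residual[both], atol=1e-12)

    def test_mirror_pair_does_not_cancel(self):
        t = np.linspace(0, 1, 20)
        a = np.linspace(-3, 3, 10)
        M = np.outer(t, np.tanh(a))
        tm_r = TestRank1()._map_from_matrix(M)
        tm_l = TestRank1()._map_from_matrix(M[:, ::-1])  # mirrored left-preferring
        from dynclicks.neural import CellClassification
        from dynclicks.tuning import population_map

        cls = {0: CellClassification(0, True, True, "right", 3.0, 0.01, 10.0),
               1: CellClassification(1, True, True, "left", -3.0, 0.01, 10.0)}
        tm_r.counts = np.full(20, 50.0)
        tm_l.counts = np.full(20, 50.0)
        pop, r1 = population_map({0: tm_r, 1: tm_l}, cls, min_trials=1)
        assert np.nanmax(np.abs(pop.residual)) > 0.1 * np.abs(M).max()
        assert np.allclose(pop.residual, M, atol=1e-12)
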