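"""STTC and spike-train statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eisim.exceptions import ParameterError
from eisim.spikes import (
    SpikeTrainPair,
    classify_unit_modulation,
    default_lags,
    filter_pairs,
    mean_pairwise_sttc,
    modulation_index,
    population_trajectories,
    sttc,
    sttc_across_lags,
    sttc_distance_profile,
    sttc_site_adjacency,
)

from helpers import brute_force_sttc

train_strategy = st.lists(
    st.floats(min_value=0.0, max_value=99.99), min_size=1, max_size=30
).map(lambda xs: np.sort(np.array(xs)))


class TestSTTC:
    def test_hand_computed_example(self):
        """Single spikes at 10 s and 50 s in a 100 s epoch, 1 s lag."""
        r = sttc(SpikeTrainPair(np.array([10.0]), np.array([50.0]), 100.0), 1.0)
        assert r.ta == pytest.approx(0.02)
        assert r.tb == pytest.approx(0.02)
        assert r.pa == 0.0 and r.pb == 0.0
        assert r.value == pytest.approx(-0.02)

    def test_identical_trains_give_one(self, rng):
        t = np.sort(rng.uniform(0, 100, 40))
        for lag in (0.0025, 0.1, 1.0):
            assert sttc(SpikeTrainPair(t, t, 100.0), lag).value == pytest.approx(1.0)

    def test_empty_train_flagged_undefined(self):
        r = sttc(SpikeTrainPair(np.array([]), np.array([1.0]), 10.0), 0.1)
        assert not r.defined and np.isnan(r.value)

    def test_fully_tiled_pair_flagged_undefined(self):
        """Dense identical trains tile the whole epoch: denominator is 0."""
        t = np.arange(0.5, 10.0, 0.5)
        r = sttc(SpikeTrainPair(t, t, 10.0), 1.0)
        assert not r.defined

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=train_strategy, b=train_strategy,
           lag=st.floats(min_value=0.01, max_value=5.0))
    def test_symmetry_bounds_and_oracle(self, a, b, lag):
        ra = sttc(SpikeTrainPair(a, b, 100.0), lag)
        rb = sttc(SpikeTrainPair(b, a, 100.0), lag)
        if ra.defined:
            assert ra.value == rb.value
            assert -1.0 <= ra.value <= 1.0
            assert ra.value == pytest.approx(
                brute_force_sttc(a, b, 100.0, lag), abs=1e-12)
        for p in (ra.pa, ra.pb, ra.ta, ra.tb):
            assert 0.0 <= p <= 1.0

    def test_independent_poisson_mean_near_zero(self, rng):
        """Independent homogeneous Poisson pairs are uncorrelated."""
        vals = []
        for _ in range(200):
            a = np.sort(rng.uniform(0, 600.0, rng.poisson(5 * 600)))
            b = np.sort(rng.uniform(0, 600.0, rng.poisson(5 * 600)))
            vals.append(sttc(SpikeTrainPair(a, b, 600.0), 0.1).value)
        assert abs(np.mean(vals)) < 0.01

    def test_rate_robustness_under_thinning(self, rng):
        """Halving both trains of rate-comodulated pairs leaves the
        expected STTC nearly unchanged (rate robustness)."""
        T, lag = 600.0, 1.0
        diffs = []
        for _ in range(40):
            # shared active/silent alternation drives the correlation
            n = rng.poisson(8 * T)
            cand_a, cand_b = rng.uniform(0, T, n), rng.uniform(0, T, n)
            env = lambda t: 0.15 + 0.85 * ((t % 20.0) < 10.0)
            a = np.sort(cand_a[rng.random(n) < env(cand_a)])
            b = np.sort(cand_b[rng.random(n) < env(cand_b)])
            full = sttc(SpikeTrainPair(a, b, T), lag).value
            a2 = a[rng.random(a.size) < 0.5]
            b2 = b[rng.random(b.size) < 0.5]
            thin = sttc(SpikeTrainPair(a2, b2, T), lag).value
            diffs.append(thin - full)
        assert abs(np.mean(diffs)) < 0.02


class TestSTTCAcrossLags:
    def test_default_lag_grid(self):
        lags = default_lags()
        assert lags.size == 13
        assert lags[0] == pytest.approx(0.0025)
        assert lags[-1] == pytest.approx(10.0)
        assert 1.0 in lags
        assert np.all(np.diff(lags) > 0)

    def test_identical_trains_one_at_every_lag(self, rng):
        t = np.sort(rng.uniform(0, 500, 100))
        pair = SpikeTrainPair(t, t, 600.0)
        for r in sttc_across_lags(pair):
            assert r.value == pytest.approx(1.0)

    def test_tiling_nondecreasing_in_lag(self, rng):
        a = np.sort(rng.uniform(0, 100, 25))
        b = np.sort(rng.uniform(0, 100, 30))
        results = sttc_across_lags(SpikeTrainPair(a, b, 100.0))
        ta = [r.ta for r in results]
        tb = [r.tb for r in results]
        assert np.all(np.diff(ta) >= 0) and np.all(np.diff(tb) >= 0)

    def test_jittered_copy_favours_long_lags(self, rng):
        a = np.sort(rng.uniform(0, 600, 300))
        b = np.sort(np.clip(a + rng.uniform(-0.05, 0.05, a.size), 0, 599.999))
        pair = SpikeTrainPair(a, b, 600.0)
        short = sttc(pair, 0.0025).value
        long = sttc(pair, 1.0).value
        assert short < long

    def test_unsorted_lags_rejected(self, rng):
        pair = SpikeTrainPair(np.array([1.0]), np.array([2.0]), 10.0)
        with pytest.raises(ParameterError):
            sttc_across_lags(pair, [0.5, 0.1])


class TestMeanPairwise:
    def test_matches_per_pair_mean(self, rng):
        trains = [np.sort(rng.uniform(0, 120.0, rng.poisson(120 * 3)))
                  for _ in range(8)]
        fast, n = mean_pairwise_sttc(trains, 120.0, lag=1.0, min_spikes=1)
        vals = []
        for i in range(8):
            for j in range(i + 1, 8):
                r = sttc(SpikeTrainPair(trains[i], trains[j], 120.0), 1.0)
                if r.defined:
                    vals.append(r.value)
        assert n == len(vals)
        assert fast == pytest.approx(np.mean(vals), abs=1e-12)

    def test_min_spikes_filter(self, rng):
        trains = [np.sort(rng.uniform(0, 100, k)) for k in (3, 60, 70)]
        _, n = mean_pairwise_sttc(trains, 100.0, lag=0.5, min_spikes=50)
        assert n == 1


class TestSplitHalfStability:
    def test_sttc_consistent_across_recording_halves(self):
        """Per-pair STTC computed on the first and second half of a long
        correlated recording correlates strongly across pairs."""
        from eisim.synth import SyntheticRasterSpec, generate_correlated_raster

        spec = SyntheticRasterSpec(n_units=24, rates=1.0,
                                   correlation_strength=0.8,
                                   distance_decay=150.0,
                                   duration=2400.0, seed=17)
        trains, _, _ = generate_correlated_raster(spec)
        half = spec.duration / 2
        for lag in (0.01, 0.1, 1.0):
            first, second = [], []
            for i in range(24):
                for j in range(i + 1, 24):
                    a1 = trains[i][trains[i] < half]
                    b1 = trains[j][trains[j] < half]
                    a2 = trains[i][trains[i] >= half] - half
                    b2 = trains[j][trains[j] >= half] - half
                    v1 = sttc(SpikeTrainPair(a1, b1, half), lag).value
                    v2 = sttc(SpikeTrainPair(a2, b2, half), lag).value
                    if np.isfinite(v1) and np.isfinite(v2):
                        first.append(v1)
                        second.append(v2)
            r = np.corrcoef(first, second)[0, 1]
            assert r > 0.6


class TestFilterPairs:
    def make(self, na, nb, dur):
        return SpikeTrainPair(
            np.linspace(0, dur * 0.9, na), np.linspace(0, dur * 0.9, nb), dur
        )

    def test_spike_count_rule(self):
        assert filter_pairs([self.make(49, 120, 4000)]) == []

    def test_boundaries_inclusive(self):
        pair = self.make(50, 50, 3600)
        assert filter_pairs([pair]) == [pair]

    def test_enumerated_subset(self):
        pairs = [
            self.make(100, 100, 3600),  # keep
            self.make(49, 100, 3600),   # too few spikes in A
            self.make(100, 10, 3600),   # too few in B
            self.make(100, 100, 3599),  # too short
            self.make(51, 52, 7200),    # keep
        ]
        assert filter_pairs(pairs) == [pairs[0], pairs[4]]


class TestSpatialSummaries:
    def test_single_distance_single_bin(self, rng):
        pairs = [
            SpikeTrainPair(np.sort(rng.uniform(0, 100, 20)),
                           np.sort(rng.uniform(0, 100, 20)), 100.0,
                           distance=150.0)
            for _ in range(5)
        ]
        prof = sttc_distance_profile(pairs, lag=0.5)
        assert (prof["n"] > 0).sum() == 1
        assert prof.loc[prof["n"] > 0, "bin_lo"].iloc[0] == 100.0

    def test_half_open_bins(self, rng):
        t = np.sort(rng.uniform(0, 100, 20))
        pair = SpikeTrainPair(t, np.sort(rng.uniform(0, 100, 20)), 100.0,
                              distance=200.0)
        prof = sttc_distance_profile([pair], lag=0.5,
                                     distance_bins=np.array([100.0, 200.0, 300.0]))
        assert prof.loc[0, "n"] == 0 and prof.loc[1, "n"] == 1

    def test_adjacency_single_pair(self, rng):
        pair = SpikeTrainPair(np.sort(rng.uniform(0, 100, 30)),
                              np.sort(rng.uniform(0, 100, 30)), 100.0,
                              site_a=2, site_b=5)
        adj = sttc_site_adjacency([pair], lag=0.5, n_sites=8)
        observed = np.argwhere(np.isfinite(adj))
        assert {tuple(x) for x in observed} == {(2, 5), (5, 2)}
        assert adj[2, 5] == adj[5, 2]

    def test_adjacency_permutation_equivariance(self, rng):
        pairs = []
        for i, j in [(0, 1), (1, 2), (0, 3)]:
            pairs.append(
                SpikeTrainPair(np.sort(rng.uniform(0, 100, 25)),
                               np.sort(rng.uniform(0, 100, 25)), 100.0,
                               site_a=i, site_b=j)
            )
        adj = sttc_site_adjacency(pairs, lag=0.5, n_sites=4)
        perm = np.array([3, 2, 1, 0])
        permuted_pairs = [
            SpikeTrainPair(p.train_a, p.train_b, 100.0,
                           site_a=int(perm[p.site_a]), site_b=int(perm[p.site_b]))
            for p in pairs
        ]
        adj_p = sttc_site_adjacency(permuted_pairs, lag=0.5, n_sites=4)
        np.testing.assert_array_equal(adj_p[np.ix_(perm, perm)], adj)


class TestModulation:
    @pytest.mark.parametrize("pre,stim,expected",
                             [(3.0, 1.0, 0.5), (2.0, 2.0, 0.0), (5.0, 0.0, 1.0),
                              (0.0, 4.0, -1.0)])
    def test_modulation_index(self, pre, stim, expected):
        assert modulation_index(pre, stim) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(modulation_index(0.0, 0.0))

    def test_known_inhibition_detected(self, rng):
        """Strong rate drop over 30 trials is classified as inhibited."""
        trials = []
        for _ in range(30):
            pre = rng.uniform(-1.5, 0.0, rng.poisson(5 * 1.5))
            stim = rng.uniform(1.5, 3.0, rng.poisson(0.5 * 1.5))
            trials.append(np.sort(np.concatenate([pre, stim])))
        res = classify_unit_modulation(trials)
        assert res.label == "inhibited"
        assert res.mi > 0

    def test_identical_windows_unmodulated(self):
        trials = [np.array([-1.0, 2.0]) for _ in range(10)]
        res = classify_unit_modulation(trials)
        assert res.label == "unmodulated"
        assert res.mi == pytest.approx(0.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ParameterError):
            classify_unit_modulation([np.array([0.5])])


class TestTrajectories:
    def test_two_groups_recovered(self, rng):
        """Opposed ramp-down / ramp-up unit groups appear as monotone
        leading components."""
        t = np.linspace(0, 1, 200)
        down = 1.0 - t
        up = 1.0 / (1.0 + np.exp(-(t - 0.7) / 0.08))
        mat = np.vstack(
            [down + rng.normal(0, 0.05, t.size) for _ in range(12)]
            + [up + rng.normal(0, 0.05, t.size) for _ in range(8)]
        )
        traj = population_trajectories(mat, bin_width=0.01)
        rho1 = stats.spearmanr(traj.components[0], t).statistic
        assert traj.explained_variance_ratio[0] > 0.8
        assert rho1 < -0.9  # leading trajectory tracks the ramp-down group
        # opposed groups load with opposite signs on the leading component
        assert traj.loadings[0][:12].mean() > 0
        assert traj.loadings[0][12:].mean() < 0

    def test_single_template_one_component(self, rng):
        t = np.linspace(0, 1, 100)
        template = np.sin(2 * np.pi * t)
        mat = np.vstack([template + rng.normal(0, 0.01, t.size)
                         for _ in range(10)])
        traj = population_trajectories(mat, bin_width=0.01)
        assert traj.explained_variance_ratio[0] > 0.97

    def test_constant_units_dropped_with_warning(self, rng):
        t = np.linspace(0, 1, 100)
        mat = np.vstack([t, 1 - t, np.zeros_like(t)])
        with pytest.warns(UserWarning, match="constant"):
            traj = population_trajectories(mat, bin_width=0.01)
        assert traj.retained_units.tolist() == [0, 1]

    def test_too_few_units_rejected(self):
        with pytest.raises(ParameterError):
            population_trajectories(np.ones((1, 50)))

    def test_zscore_normalisation(self):
        from eisim.spikes import _smooth_and_zscore

        rng = np.random.default_rng(0)
        mat = rng.normal(5, 2, size=(4, 300))
        z, retained = _smooth_and_zscore(mat, bin_width=0.01,
                                         window=0.5, window_sd=0.05)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1), 1, atol=1e-12)
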