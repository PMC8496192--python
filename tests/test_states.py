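"""AR-HMM state segmentation, occupancy histograms, K-medoids clustering."""

import collections

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gaitmod import (KMedoids, cluster_histograms, fit_state_model,
                     ks_uniformity, occupancy_histograms)
from gaitmod.gaitphase import PhaseSeries
from gaitmod.states import OccupancyHistogram

FS = 256


def _ar2_coeffs(f_hz, r):
    a1 = 2 * r * np.cos(2 * np.pi * f_hz / FS)
    return a1, -r * r


def simulate_switching_ar(duration_s=60.0, dwell_s=0.5, seed=0,
                          regimes=((8.0, 0.97), (35.0, 0.97)), n_ch=2):
    """Two-regime AR(2) switching process with Markov dwell times."""
    rng = np.random.default_rng(seed)
    T = int(duration_s * FS)
    p_switch = 1.0 / (dwell_s * FS)
    states = np.zeros(T, dtype=int)
    s = 0
    for t in range(1, T):
        if rng.random() < p_switch:
            s = 1 - s
        states[t] = s
    coeffs = [_ar2_coeffs(f, r) for f, r in regimes]
    x = np.zeros((T, n_ch))
    for t in range(2, T):
        a1, a2 = coeffs[states[t]]
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + rng.standard_normal(n_ch)
    return x, states


def mapped_accuracy(decoded, truth):
    """Accuracy after mapping each decoded state to its best truth label."""
    ok = decoded >= 0
    decoded, truth = decoded[ok], truth[ok]
    hits = 0
    for k in np.unique(decoded):
        hits += collections.Counter(truth[decoded == k]).most_common(1)[0][1]
    return hits / len(decoded)


class TestARHMM:
    def test_two_regime_recovery(self):
        x, truth = simulate_switching_ar(seed=0)
        sm = fit_state_model(x, n_states_max=4, ar_order=3, seed=1, n_iter=30)
        acc = mapped_accuracy(sm.state_sequence, truth)
        assert acc > 0.85

    def test_em_loglik_monotone(self):
        x, _ = simulate_switching_ar(duration_s=30.0, seed=2)
        sm = fit_state_model(x, n_states_max=3, ar_order=3, seed=2, n_iter=25)
        assert np.all(np.diff(sm.log_likelihoods) >= -1e-6)

    def test_occupancies_sum_to_one(self):
        x, _ = simulate_switching_ar(duration_s=30.0, seed=3)
        sm = fit_state_model(x, n_states_max=4, ar_order=3, seed=3, n_iter=20)
        assert sm.fractional_occupancy.sum() == pytest.approx(1.0)
        assert np.all(sm.fractional_occupancy > 0)

    def test_single_regime_concentrates(self):
        rng = np.random.default_rng(1)
        T = int(60 * FS)
        a1, a2 = _ar2_coeffs(10.0, 0.97)
        x = np.zeros((T, 2))
        for t in range(2, T):
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + rng.standard_normal(2)
        sm = fit_state_model(x, n_states_max=4, ar_order=3, seed=0, n_iter=30)
        assert sm.fractional_occupancy.max() > 0.9

    def test_deterministic_given_seed(self):
        x, _ = simulate_switching_ar(duration_s=20.0, seed=4)
        a = fit_state_model(x, n_states_max=3, seed=9, n_iter=10)
        b = fit_state_model(x, n_states_max=3, seed=9, n_iter=10)
        np.testing.assert_array_equal(a.state_sequence, b.state_sequence)


class TestOccupancyHistograms:
    def _phase(self, n, rng):
        return PhaseSeries(rng.uniform(-np.pi, np.pi, n), np.ones(n, bool),
                           FS)

    def test_uniform_state_near_one_percent(self, rng):
        n = 50000
        seq = np.zeros(n, dtype=int)
        hists = occupancy_histograms(seq, self._phase(n, rng))
        assert len(hists) == 1
        np.testing.assert_allclose(hists[0].probs, 0.01, atol=0.004)
        assert hists[0].probs.sum() == pytest.approx(1.0)

    def test_outer_phase_state_mass_in_outer_bins(self, rng):
        n = 20000
        phase = self._phase(n, rng)
        seq = np.where(np.abs(phase.phase) > 3 * np.pi / 4, 0, 1)
        hists = occupancy_histograms(seq, phase)
        h0 = hists[0]
        outer = np.abs((h0.bin_edges[:-1] + h0.bin_edges[1:]) / 2) > 3 * np.pi / 4
        assert h0.probs[outer].sum() > 0.95

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            occupancy_histograms(np.zeros(10, int), self._phase(20, rng))


class TestKSUniformity:
    def test_uniform_null_rarely_rejects(self):
        reject = 0
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            ph = rng.uniform(-np.pi, np.pi, 10000)
            h = OccupancyHistogram(np.full(100, 0.01),
                                   np.linspace(-np.pi, np.pi, 101), 0,
                                   len(ph), phases=ph)
            reject += ks_uniformity(h) <= 0.05
        assert reject <= 10

    def test_degenerate_phase_rejects_hard(self):
        ph = np.zeros(1000)
        h = OccupancyHistogram(np.full(100, 0.01),
                               np.linspace(-np.pi, np.pi, 101), 0, 1000,
                               phases=ph)
        assert ks_uniformity(h) < 1e-6

    def test_small_sample_warns(self):
        ph = np.zeros(5)
        h = OccupancyHistogram(np.full(100, 0.01),
                               np.linspace(-np.pi, np.pi, 101), 0, 5,
                               phases=ph)
        with pytest.warns(RuntimeWarning, match="unreliable"):
            ks_uniformity(h)


def planted_histograms(rng, n_per=6, noise=0.02):
    grid = np.linspace(-np.pi, np.pi, 100)
    X, labels = [], []
    for i, mu in enumerate((0.0, np.pi / 2, -np.pi / 2)):
        for _ in range(n_per):
            h = np.exp(-((grid - mu) ** 2) / 0.5) + noise * rng.random(100)
            X.append(h / h.sum())
            labels.append(i)
    return np.array(X), np.array(labels)


class TestKMedoids:
    def test_recovers_planted_partition(self, rng):
        X, labels = planted_histograms(rng)
        cl = cluster_histograms(X, k=3, seed=0)
        assert adjusted_rand_score(labels, cl.labels) == 1.0
        assert len(np.unique(cl.labels)) == 3

    def test_medoids_are_members(self, rng):
        X, _ = planted_histograms(rng)
        km = KMedoids(n_clusters=3, random_state=0).fit(X)
        for m, c in zip(km.medoid_indices_, range(3)):
            assert np.any(np.all(X == km.cluster_centers_[c], axis=1))

    def test_k_equals_n_each_own_cluster(self, rng):
        X = rng.random((4, 10))
        km = KMedoids(n_clusters=4, random_state=0).fit(X)
        assert sorted(km.labels_) == [0, 1, 2, 3]

    def test_duplicates_co_clustered(self, rng):
        X, labels = planted_histograms(rng, n_per=3, noise=0.0)
        cl = cluster_histograms(np.vstack([X, X]), k=3, seed=1)
        assert np.array_equal(cl.labels[: len(X)], cl.labels[len(X):])

    def test_deterministic_given_seed(self, rng):
        X, _ = planted_histograms(rng)
        a = KMedoids(n_clusters=3, random_state=7).fit(X)
        b = KMedoids(n_clusters=3, random_state=7).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            cluster_histograms(rng.random((2, 10)), k=3)
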