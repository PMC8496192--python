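"""Permutation schemes, cluster correction, exact small-sample tests."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from gaitmod import (cluster_perm_conditions, cluster_perm_modulogram,
                     modulation_index, modulogram, morlet_tfr,
                     phase_from_force, shuffle_phase_within_cycles,
                     spearman_exact, wilcoxon_exact)
from gaitmod.gaitphase import GaitCycleTable, PhaseSeries


# ---------------------------------------------------------------------------
# independent enumeration oracles

def wilcoxon_oracle(d):
    """Two-sided exact p by explicit enumeration of every sign vector."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    total = ranks.sum()
    w_small = min(w_pos, total - w_pos)
    count = 0
    for signs in itertools.product((1, -1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        if min(w, total - w) <= w_small + 1e-9:
            count += 1
    # each assignment with min rank sum <= observed contributes; two tails
    # are counted jointly by the min() statistic
    return count / 2 ** len(d)


class TestWilcoxonExact:
    def test_all_one_sign_n8(self):
        W, p = wilcoxon_exact(np.arange(1, 9.0), np.zeros(8))
        assert p == pytest.approx(2 / 256)
        assert W == 36.0

    def test_rank3_flipped_n8(self):
        d = np.array([1, 2, -3, 4, 5, 6, 7, 8.0])
        W, p = wilcoxon_exact(d, np.zeros(8))
        assert W == 33.0
        assert p == pytest.approx(10 / 256)

    def test_n2_both_positive(self):
        _, p = wilcoxon_exact(np.array([1.0, 2.0]), np.zeros(2))
        assert p == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = rng.standard_normal(n).round(2)
        d = d[d != 0]
        if len(d) < 2:
            pytest.skip("degenerate draw")
        _, p = wilcoxon_exact(d, np.zeros(len(d)))
        assert p == pytest.approx(min(1.0, wilcoxon_oracle(d)), abs=1e-12)

    def test_matches_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(3)
        d = rng.standard_normal(10)
        _, p = wilcoxon_exact(d, np.zeros(10))
        ref = scipy_wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_exact(np.ones(5), np.ones(5))


class TestSpearmanExact:
    def test_perfect_reversal_n8(self):
        x = np.arange(8.0)
        rho, p = spearman_exact(x, x[::-1])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 40320)

    def test_paper_effect_size_sum_d2_156(self):
        """Sum d^2 = 156 at n = 8 gives rho = -6/7 and exact p = 0.0107."""
        x = np.arange(1, 9.0)
        y = np.array([5, 8, 7, 6, 4, 3, 2, 1.0])
        d = rankdata(x) - rankdata(y)
        assert (d**2).sum() == 156
        rho, p = spearman_exact(x, y)
        assert rho == pytest.approx(-6 / 7)
        assert p == pytest.approx(0.0107, abs=5e-5)

    def test_identity_n5(self):
        x = np.arange(5.0)
        rho, p = spearman_exact(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)

    def test_matches_scipy_exact_permutation(self):
        """Independent route: scipy's exact pairings permutation test."""
        from scipy.stats import permutation_test, spearmanr

        rng = np.random.default_rng(0)
        x = rng.standard_normal(7)
        y = rng.standard_normal(7)
        rho, p = spearman_exact(x, y)
        ref = permutation_test(
            (y,), lambda b: spearmanr(x, b).statistic,
            permutation_type="pairings", n_resamples=np.inf,
            alternative="two-sided")
        assert rho == pytest.approx(spearmanr(x, y).statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError, match="3 <= n <= 9"):
            spearman_exact(np.arange(12.0), np.arange(12.0))


# ---------------------------------------------------------------------------
# within-cycle shuffling

def _toy_phase(n=60, fs=10.0, n_cycles=3):
    per = n // n_cycles
    phase = np.tile(np.linspace(-np.pi, np.pi, per, endpoint=False), n_cycles)
    table = GaitCycleTable(
        lift_sample=np.arange(n_cycles) * per,
        strike_sample=np.arange(n_cycles) * per + per // 2,
        next_lift_sample=(np.arange(n_cycles) + 1) * per,
        duration_s=np.full(n_cycles, per / fs),
        lift_duration_s=np.full(n_cycles, per / 2 / fs),
        fs=fs,
    )
    return PhaseSeries(phase, np.ones(n, bool), fs), table


class TestShuffle:
    def test_split_and_swap_is_circular_rotation(self):
        """A cycle [a,b,c,d,e,f] cut after 2 becomes [c,d,e,f,a,b]."""

        class FixedRng:
            def integers(self, lo, hi):
                return 2

        phase, table = _toy_phase(n=6, fs=10.0, n_cycles=1)
        out = shuffle_phase_within_cycles(phase, table, FixedRng())
        np.testing.assert_array_equal(out.phase, np.roll(phase.phase, -2))

    def test_multiset_preserved_per_cycle(self, rng):
        phase, table = _toy_phase(n=60, n_cycles=3)
        out = shuffle_phase_within_cycles(phase, table, rng)
        for lo, hi in zip(table.lift_sample.astype(int),
                          table.next_lift_sample.astype(int)):
            np.testing.assert_allclose(np.sort(out.phase[lo:hi]),
                                       np.sort(phase.phase[lo:hi]))

    def test_shuffling_destroys_phase_locking(self, beta_session_pre, rng):
        """Average MI at the planted frequency over shuffles is a small
        fraction of the unshuffled MI."""
        rec = beta_session_pre
        ph, table = phase_from_force(rec.get("force_left"), rec.fs)
        tfr = morlet_tfr(rec.pick(labels=["lfp_0"]), decim=8)
        band = (tfr.freqs >= 20) & (tfr.freqs <= 25)
        mi0 = modulation_index(modulogram(tfr, ph, channel=0)).mi[band].mean()
        dec = ph.decimate(8)
        dec = PhaseSeries(dec.phase[:tfr.n_times], dec.valid[:tfr.n_times],
                          dec.fs, dec.strike_anchored)
        table_dec = GaitCycleTable(
            table.lift_sample / 8, table.strike_sample / 8,
            table.next_lift_sample / 8, table.duration_s,
            table.lift_duration_s, fs=rec.fs / 8)
        vals = []
        for _ in range(50):
            sh = shuffle_phase_within_cycles(dec, table_dec, rng)
            vals.append(modulation_index(
                modulogram(tfr, sh, channel=0)).mi[band].mean())
        assert np.mean(vals) < 0.2 * mi0


# ---------------------------------------------------------------------------
# cluster permutation

class TestClusterPermModulogram:
    def test_deterministic_given_seed(self, beta_session_pre):
        rec = beta_session_pre
        ph, table = phase_from_force(rec.get("force_left"), rec.fs)
        tfr = morlet_tfr(rec.pick(labels=["lfp_0"]), decim=16)
        a = cluster_perm_modulogram(tfr, ph, table, n_perm=100, seed=42)
        b = cluster_perm_modulogram(tfr, ph, table, n_perm=100, seed=42)
        np.testing.assert_array_equal(a.z_map, b.z_map)
        assert [c.mass for c in a.clusters] == [c.mass for c in b.clusters]
        np.testing.assert_array_equal(a.null_masses, b.null_masses)

    def test_planted_modulation_detected(self, beta_session_pre):
        rec = beta_session_pre
        ph, table = phase_from_force(rec.get("force_left"), rec.fs)
        tfr = morlet_tfr(rec.pick(labels=["lfp_0"]), decim=16)
        res = cluster_perm_modulogram(tfr, ph, table, n_perm=200, seed=0)
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert sig
        freqs_hit = np.concatenate(
            [tfr.freqs[np.unique(c.cells[:, 0])] for c in sig])
        assert ((freqs_hit >= 20) & (freqs_hit <= 25)).any()

    def test_small_nperm_rejected(self, beta_session_pre):
        rec = beta_session_pre
        ph, table = phase_from_force(rec.get("force_left"), rec.fs)
        tfr = morlet_tfr(rec.pick(labels=["lfp_0"]), decim=16)
        with pytest.raises(ValueError, match="n_perm"):
            cluster_perm_modulogram(tfr, ph, table, n_perm=10)


class TestClusterPermConditions:
    def test_identical_conditions_no_clusters(self, rng):
        a = rng.standard_normal((8, 40))
        res = cluster_perm_conditions(a, a.copy(), n_perm=200, seed=1)
        assert res.clusters == []

    def test_flipping_labels_negates_z(self, rng):
        a = rng.standard_normal((8, 40))
        b = rng.standard_normal((8, 40))
        r1 = cluster_perm_conditions(a, b, n_perm=200, seed=5)
        r2 = cluster_perm_conditions(b, a, n_perm=200, seed=5)
        np.testing.assert_allclose(r1.z_map, -r2.z_map, atol=1e-8)

    def test_planted_band_offset_detected(self, rng):
        freqs = np.arange(1.0, 41.0)
        a = rng.standard_normal((8, 40))
        b = rng.standard_normal((8, 40))
        band = (freqs >= 12) & (freqs <= 24)
        a[:, band] += 3.0
        res = cluster_perm_conditions(a, b, n_perm=500, seed=2, freqs=freqs)
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert sig
        covered = np.concatenate([freqs[c.cells[:, 1]] for c in sig])
        # significant clusters sit inside the planted band and cover most of it
        assert covered.min() >= 11 and covered.max() <= 25
        assert ((covered >= 12) & (covered <= 24)).sum() >= 0.6 * band.sum()

    def test_unpaired_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="unpaired"):
            cluster_perm_conditions(rng.standard_normal((8, 40)),
                                    rng.standard_normal((7, 40)))

    def test_paired_t_statistic_mode(self, rng):
        a = rng.standard_normal((8, 20)) + 1.0
        b = rng.standard_normal((8, 20))
        res = cluster_perm_conditions(a, b, n_perm=200, seed=3, statistic="t")
        assert res.extras["statistic"] == "t"
        assert any(c.p_value < 0.05 for c in res.clusters)
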