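"""Diversity statistics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from soysweep.diversity import (
    ScanConfig,
    WindowedStatTrack,
    hudson_fst_site,
    make_windows,
    pi_ratio,
    site_pi,
    windowed_fst,
    windowed_pi,
)

from conftest import make_matrix, random_matrix


def brute_force_pi_per_bp(matrix, rows, span_bp):
    """Mean pairwise difference per bp over all chromosome pairs."""
    sub = matrix.alleles[rows]
    n = sub.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((sub[i] != sub[j]).sum())
            pairs += 1
    return total / pairs / span_bp


class TestSitePi:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (0, 10, 0.0),  # monomorphic
            (1, 2, 1.0),  # the single pair differs
            (2, 4, 4 / 6),  # brute force: 4 of 6 pairs differ
            (5, 10, 2 * 5 * 5 / 90),
        ],
    )
    def test_matches_pairwise_definition(self, k, n, expected):
        assert site_pi(k, n) == pytest.approx(expected, abs=1e-12)

    def test_rejects_single_chromosome(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


class TestWindowedPi:
    def test_identical_haplotypes_give_zero(self):
        m = make_matrix(np.zeros((4, 5)), positions=[2, 4, 6, 8, 10])
        cfg = ScanConfig(window_bp=10, step_bp=10, min_sites_per_window=0)
        track = windowed_pi(m, np.arange(4), cfg, chrom_length_bp=10)
        assert np.all(track.values == 0)

    def test_single_difference_in_10bp_window(self):
        m = make_matrix([[0], [1]], positions=[5])
        cfg = ScanConfig(window_bp=10, step_bp=10, min_sites_per_window=0)
        track = windowed_pi(m, np.arange(2), cfg, chrom_length_bp=10)
        assert track.values[0] == pytest.approx(0.1)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_chrom = int(rng.integers(2, 11)) * 2
            n_sites = int(rng.integers(2, 51))
            m = random_matrix(rng, n_chrom=n_chrom, n_sites=n_sites)
            span = int(m.positions[-1])
            cfg = ScanConfig(window_bp=span, step_bp=span, min_sites_per_window=0)
            track = windowed_pi(m, np.arange(n_chrom), cfg, chrom_length_bp=span)
            oracle = brute_force_pi_per_bp(m, np.arange(n_chrom), span)
            assert track.values[0] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_allele_label_swap(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, n_chrom=6, n_sites=20)
        cfg = ScanConfig(window_bp=2000, step_bp=2000, min_sites_per_window=0)
        t1 = windowed_pi(m, np.arange(6), cfg, 2000)
        flipped = make_matrix(1 - m.alleles, positions=m.positions)
        t2 = windowed_pi(flipped, np.arange(6), cfg, 2000)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-15)

    def test_sparse_window_is_nan(self):
        m = make_matrix([[0, 1], [1, 0]], positions=[5, 15])
        cfg = ScanConfig(window_bp=10, step_bp=10, min_sites_per_window=3)
        track = windowed_pi(m, np.arange(2), cfg, chrom_length_bp=20)
        assert np.all(np.isnan(track.values))


class TestPiRatio:
    def _track(self, values):
        n = len(values)
        return WindowedStatTrack(
            "chr1", np.arange(n) * 10, np.arange(1, n + 1) * 10, "pi", np.array(values)
        )

    def test_equal_diversity_gives_one(self):
        t = self._track([0.02, 0.01])
        assert np.allclose(pi_ratio(t, t).values, 1.0)

    def test_zero_denominator_is_nan(self):
        r = pi_ratio(self._track([0.02]), self._track([0.0]))
        assert np.isnan(r.values[0])

    def test_direct_division(self):
        r = pi_ratio(self._track([0.02]), self._track([0.005]))
        assert r.values[0] == pytest.approx(4.0)

    def test_window_mismatch_rejected(self):
        a = self._track([1.0, 2.0])
        b = WindowedStatTrack("chr1", [0], [10], "pi", [1.0])
        with pytest.raises(ValueError):
            pi_ratio(a, b)


class TestHudsonFst:
    def test_fixed_difference_gives_unit_ratio(self):
        num, den = hudson_fst_site(1.0, 10, 0.0, 10)
        assert num == pytest.approx(1.0)
        assert den == pytest.approx(1.0)

    def test_no_differentiation_limit(self):
        num, _ = hudson_fst_site(0.5, 10**9, 0.5, 10**9)
        assert num == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_formula_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p1, p2 = rng.random(2)
            n1, n2 = rng.integers(2, 200, size=2)
            num, den = hudson_fst_site(p1, int(n1), p2, int(n2))
            # independently coded copy of the estimator
            exp_num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            exp_den = p1 * (1 - p2) + p2 * (1 - p1)
            assert num == pytest.approx(exp_num, abs=1e-12)
            assert den == pytest.approx(exp_den, abs=1e-12)

    def test_rejects_degenerate_sample_size(self):
        with pytest.raises(ValueError):
            hudson_fst_site(0.5, 1, 0.5, 10)


class TestWindowedFst:
    def test_complete_fixation_gives_one(self):
        top = np.zeros((4, 6), dtype=np.int8)
        bottom = np.ones((4, 6), dtype=np.int8)
        m = make_matrix(np.vstack([top, bottom]))
        cfg = ScanConfig(window_bp=100, step_bp=100)
        track = windowed_fst(m, np.arange(4), np.arange(4, 8), cfg, 100)
        assert track.values[0] == pytest.approx(1.0)

    def test_permuted_labels_centre_near_zero(self):
        rng = np.random.default_rng(11)
        medians = []
        m = random_matrix(rng, n_chrom=40, n_sites=500, spacing=20)
        span = int(m.positions[-1])
        cfg = ScanConfig(window_bp=span // 50, step_bp=span // 50, min_sites_per_window=1)
        perm = rng.permutation(40)
        track = windowed_fst(m, perm[:20], perm[20:], cfg, span)
        raw = track.extra["raw"]
        assert abs(np.nanmedian(raw)) < 0.05

    def test_single_site_window_reduces_to_site_ratio(self):
        m = make_matrix([[0], [1], [1], [1]], positions=[5])
        cfg = ScanConfig(window_bp=10, step_bp=10)
        track = windowed_fst(m, np.array([0, 1]), np.array([2, 3]), cfg, 10)
        num, den = hudson_fst_site(0.5, 2, 1.0, 2)
        assert track.extra["raw"][0] == pytest.approx(num / den)

    def test_invariant_under_site_reordering_within_window(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_chrom=12, n_sites=30)
        span = int(m.positions[-1])
        cfg = ScanConfig(window_bp=span, step_bp=span)
        t1 = windowed_fst(m, np.arange(6), np.arange(6, 12), cfg, span)
        order = rng.permutation(30)
        shuffled = make_matrix(m.alleles[:, order], positions=m.positions)
        t2 = windowed_fst(shuffled, np.arange(6), np.arange(6, 12), cfg, span)
        assert t1.values[0] == pytest.approx(t2.values[0], abs=1e-12)


class TestMakeWindows:
    def test_spans_and_terminal_window(self):
        cfg = ScanConfig(window_bp=20, step_bp=10)
        starts, ends = make_windows(55, cfg)
        assert starts[0] == 0 and ends[0] == 20
        assert ends[-1] == 55
        assert np.all(ends - starts <= 20)

    def test_rejects_bad_step(self):
        with pytest.raises(ValueError):
            ScanConfig(window_bp=10, step_bp=20)


class TestSitePiProperties:
    """Property tests: bounds and symmetry of the per-site estimator."""

    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=200)
    @given(
        n=st.integers(min_value=2, max_value=500),
        k_frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_bounds_and_complement_symmetry(self, n, k_frac):
        k = int(round(k_frac * n))
        value = site_pi(k, n)
        assert 0.0 <= value <= n / (2 * (n - 1)) + 1e-12  # max at k = n/2
        assert value == pytest.approx(site_pi(n - k, n), abs=1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(n=st.integers(min_value=2, max_value=300))
    def test_monomorphic_and_singleton(self, n):
        assert site_pi(0, n) == 0.0
        assert site_pi(n, n) == 0.0
        assert site_pi(1, n) == pytest.approx(2.0 / n)
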