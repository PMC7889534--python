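"""Distance statistics: KS test, Rosin split, tail quantiles, bootstrap."""

import numpy as np
import pytest

from fishdist.stats import (DistanceDataset, bootstrap_min_cells,
                            ks_compare, rosin_threshold, split_at,
                            tail_quantile_flag)


def _brute_force_ks(a, b):
    """Oracle: scan every observation point for the largest ECDF gap."""
    gaps = []
    for x in np.concatenate([a, b]):
        fa = np.mean(np.asarray(a) <= x)
        fb = np.mean(np.asarray(b) <= x)
        gaps.append(abs(fa - fb))
    return max(gaps)


def _kolmogorov_sf(x, terms=101):
    """Oracle: the Kolmogorov survival function by its alternating series
    Q(x) = 2 sum_{k>=1} (-1)^{k-1} exp(-2 k^2 x^2)."""
    if x <= 0:
        return 1.0
    ks = np.arange(1, terms)
    return float(np.clip(
        2.0 * np.sum((-1.0) ** (ks - 1) * np.exp(-2.0 * ks ** 2 * x ** 2)),
        0.0, 1.0))


class TestKS:
    def test_identical_samples(self):
        d, p = ks_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_fully_separated_samples(self):
        d, _ = ks_compare([0.1, 0.2], [5.0, 6.0])
        assert d == 1.0

    def test_hand_enumerated_example(self):
        a, b = [0.1, 0.4, 0.7], [0.2, 0.5]
        d, _ = ks_compare(a, b)
        assert d == pytest.approx(_brute_force_ks(a, b))

    def test_matches_bruteforce_and_asymptotic_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 31))
            b = rng.normal(0.4, 1.2, size=rng.integers(2, 31))
            d, p = ks_compare(a, b)
            assert d == pytest.approx(_brute_force_ks(a, b), abs=1e-12)
            en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
            assert p == pytest.approx(_kolmogorov_sf(en * d), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestSplitAt:
    def test_worked_example(self):
        sp = split_at([0.2, 0.5, 1.5, 2.0], 0.9)
        assert sp.interacting_fraction == 0.5

    def test_all_below(self):
        assert split_at([0.1, 0.2], 5.0).interacting_fraction == 1.0

    def test_tie_counts_as_interacting(self):
        assert split_at([0.9], 0.9).interacting_fraction == 1.0

    def test_fractions_sum_to_one_and_monotone(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(0.5, size=200)
        prev = 0.0
        for thr in np.linspace(0.05, 3.0, 25):
            sp = split_at(d, thr)
            assert sp.interacting_fraction + sp.noninteracting_fraction \
                == pytest.approx(1.0)
            assert sp.interacting_fraction >= prev
            prev = sp.interacting_fraction


class TestRosin:
    @staticmethod
    def _oracle_threshold(d, bin_width):
        """Independent chord scan on the same fixed-width histogram."""
        n_bins = int(np.ceil((max(d) + 1e-9) / bin_width))
        counts, edges = np.histogram(d, bins=n_bins,
                                     range=(0, n_bins * bin_width))
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = int(np.argmax(counts))
        last = int(np.nonzero(counts)[0][-1])
        p0 = np.array([centers[peak], counts[peak]], float)
        p1 = np.array([centers[last], counts[last]], float)
        chord = p1 - p0
        chord /= np.linalg.norm(chord)
        best_k, best_d = peak, -1.0
        for k in range(peak, last + 1):
            v = np.array([centers[k], counts[k]], float) - p0
            perp = abs(v[0] * chord[1] - v[1] * chord[0])
            if perp > best_d:
                best_k, best_d = k, perp
        return centers[best_k]

    def test_triangle_histogram_matches_chord_scan(self):
        # linear decay from the peak: counts 20, 18, ..., 2 per bin
        d = np.concatenate([
            np.full(20 - 2 * k, 0.05 + 0.1 * k) for k in range(10)])
        sp = rosin_threshold(d, bin_width_um=0.1)
        assert sp.threshold_um == pytest.approx(
            self._oracle_threshold(d, 0.1))

    def test_random_histograms_match_chord_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            d = np.concatenate([
                np.abs(rng.normal(0, 0.2, 400)),
                rng.uniform(0.5, 3.0, rng.integers(20, 120)),
            ])
            sp = rosin_threshold(d, bin_width_um=0.1)
            assert sp.threshold_um == pytest.approx(
                self._oracle_threshold(d, 0.1))

    def test_mixture_recovery(self):
        """90/10 half-normal + uniform mixture: threshold lands between
        the regimes and the tail fraction is recovered to a few points."""
        rng = np.random.default_rng(2)
        n = 2000
        tail = rng.random(n) < 0.1
        d = np.where(tail, rng.uniform(0.5, 3.0, n),
                     np.abs(rng.normal(0.0, 0.15, n)))
        sp = rosin_threshold(d)
        assert 0.4 < sp.threshold_um < 1.4
        assert abs(sp.noninteracting_fraction - 0.1) <= 0.04

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError):
            rosin_threshold(np.full(50, 0.42))


class TestTailQuantile:
    def test_self_comparison_leaves_one_minus_q(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(1.0, size=2000)
        frac = tail_quantile_flag(d, d, q=0.99)
        assert frac == pytest.approx(0.01, abs=0.005)

    def test_all_below_reference(self):
        assert tail_quantile_flag([1.0, 2.0, 3.0], [0.1, 0.2]) == 0.0

    def test_planted_tail_mass_recovered(self):
        rng = np.random.default_rng(4)
        ref = np.abs(rng.normal(0, 0.2, 3000))
        cut = np.quantile(ref, 0.99)
        test = np.concatenate([np.abs(rng.normal(0, 0.2, 500)),
                               rng.uniform(cut + 0.5, cut + 2.0, 500)])
        frac = tail_quantile_flag(ref, test, q=0.99)
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 1000) + 0.01


def _mixture_dataset(label, n_cells, p_int, seed):
    rng = np.random.default_rng(seed)
    n = 2 * n_cells
    d = np.where(rng.random(n) < p_int,
                 np.abs(rng.normal(0.0, 0.12, n)),
                 rng.uniform(0.5, 3.0, n))
    return DistanceDataset(label, d, np.repeat(np.arange(n_cells), 2))


class TestBootstrap:
    def test_null_calibration(self):
        """Identical groups: the significant fraction stays at the test
        level and the criterion is never reached."""
        a = _mixture_dataset("x", 300, 0.9, 1)
        res = bootstrap_min_cells(a, a, [25, 100], n_boot=200,
                                  alpha=1e-3, seed=2)
        assert res.min_cells is None
        se = np.sqrt(1e-3 * (1 - 1e-3) / 200)
        assert np.all(res.fraction_significant <= 1e-3 + 3 * se)

    def test_separated_groups_reach_at_smallest_size(self):
        a = DistanceDataset.from_distances("lo", np.linspace(0.0, 0.2, 100))
        b = DistanceDataset.from_distances("hi", np.linspace(5.0, 6.0, 100))
        res = bootstrap_min_cells(a, b, [20, 50], n_boot=100, seed=3)
        assert res.min_cells == 20
        assert res.fraction_significant[0] == 1.0

    def test_bitwise_reproducible_under_seed(self):
        a = _mixture_dataset("a", 200, 0.95, 5)
        b = _mixture_dataset("b", 200, 0.55, 6)
        r1 = bootstrap_min_cells(a, b, [25, 75], n_boot=100, seed=9)
        r2 = bootstrap_min_cells(a, b, [25, 75], n_boot=100, seed=9)
        np.testing.assert_array_equal(r1.fraction_significant,
                                      r2.fraction_significant)
        assert r1.min_cells == r2.min_cells

    def test_resamples_cells_not_distances(self):
        """Each resampled cell contributes all of its distances."""
        d = np.array([0.1, 0.2, 5.0, 5.1])
        ds = DistanceDataset("x", d, np.array([0, 0, 1, 1]))
        groups = ds.cell_groups()
        assert sorted(map(len, groups)) == [2, 2]
        assert ds.n_cells == 2
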