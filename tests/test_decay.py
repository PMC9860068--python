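"""Contact decay curves, SCC reproducibility, MDS and clustering."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hicdyn import (
    BinsTable,
    ContactDataError,
    ContactMatrix,
    classical_mds,
    compare_at_distances,
    contact_probability,
    dissimilarity_matrix,
    fit_decay_exponent,
    hierarchical_cluster,
    long_range_fraction,
    scc,
)
from hicdyn.decay import DecayCurve, _mean_smooth

from conftest import random_contact_matrix


def _matrix(counts, binsize=10):
    counts = np.asarray(counts, dtype=float)
    bins = BinsTable.from_chrom_length("c", counts.shape[0] * binsize, binsize)
    return ContactMatrix(bins, counts)


class TestContactProbability:
    def test_single_stratum_gets_all_mass(self):
        m = _matrix([[0, 3, 0], [3, 0, 2], [0, 2, 0]])
        curve = contact_probability(m, max_s=20)
        assert curve.P[0] == pytest.approx(1.0)
        assert curve.P[1] == 0.0

    def test_uniform_offdiagonal_mass_proportional_to_pixels(self):
        counts = np.ones((4, 4)) - np.eye(4)
        curve = contact_probability(_matrix(counts), max_s=30)
        # strata |i-j| = 1, 2, 3 have 3, 2, 1 upper-triangle pixels
        assert np.allclose(curve.P, np.array([3, 2, 1]) / 6)

    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(0)
        curve = contact_probability(random_contact_matrix(rng, 40), max_s=3_000_000)
        assert curve.P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_decay_exponent_recovered(self):
        rng = np.random.default_rng(1)
        n = 300
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = 2e4 * (d + 1.0) ** -1.0
        iu = np.triu_indices(n)
        counts = np.zeros((n, n))
        counts[iu] = rng.poisson(expected[iu])
        counts += np.triu(counts, 1).T
        curve = contact_probability(_matrix(counts, binsize=100), max_s=n * 100)
        slope = fit_decay_exponent(curve, s_min=1_000, s_max=29_000)
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ContactDataError):
            contact_probability(_matrix(np.zeros((3, 3))), max_s=20)


class TestLongRangeFraction:
    def _uniform_curve(self, k=10):
        return DecayCurve(
            s=np.arange(1, k + 1) * 10,
            P=np.full(k, 1.0 / k),
            counts=np.ones(k),
            n_pixels=np.ones(k, dtype=int),
        )

    def test_fraction_after_threshold(self):
        assert long_range_fraction(self._uniform_curve(), 60) == pytest.approx(0.4)

    def test_threshold_beyond_range_is_zero(self):
        assert long_range_fraction(self._uniform_curve(), 100) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        curve = contact_probability(random_contact_matrix(rng, 30), max_s=2_500_000)
        fracs = [long_range_fraction(curve, t) for t in range(0, 3_000_000, 100_000)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestCompareAtDistances:
    def _curve(self, values):
        values = np.asarray(values, dtype=float)
        return DecayCurve(
            s=np.arange(1, len(values) + 1) * 10,
            P=values,
            counts=values,
            n_pixels=np.ones(len(values), dtype=int),
        )

    def test_identical_replicates_give_t0_p1(self):
        c = self._curve([0.5, 0.3, 0.2])
        table = compare_at_distances({"a": [c, c], "b": [c, c]}, [10])
        assert table.t.iloc[0] == 0.0 and table.p.iloc[0] == 1.0

    def test_matches_closed_form_welch_t(self):
        a = [self._curve([0.10]), self._curve([0.12])]
        b = [self._curve([0.20]), self._curve([0.22])]
        table = compare_at_distances({"a": a, "b": b}, [10])
        t_oracle, p_oracle = stats.ttest_ind([0.10, 0.12], [0.20, 0.22], equal_var=False)
        assert table.t.iloc[0] == pytest.approx(t_oracle)
        assert table.p.iloc[0] == pytest.approx(p_oracle)

    def test_bh_adjustment_matches_step_up_formula(self):
        # p = (.01, .02, .03, .04) with m = 4 all adjust to 0.04
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(padj, 0.04)

    def test_single_replicate_rejected(self):
        c = self._curve([0.5, 0.5])
        with pytest.raises(ContactDataError):
            compare_at_distances({"a": [c], "b": [c, c]}, [10])


def _scc_oracle(a, b, h, max_s):
    """Brute-force SCC: explicit smoothing and per-stratum correlation."""
    n = a.n_bins
    binsize = a.bins.binsize
    xs, ys = [], []
    for x in (a.counts, b.counts):
        sm = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                block = x[max(0, i - h) : i + h + 1, max(0, j - h) : j + h + 1]
                sm[i, j] = block.mean()
        xs.append(sm)
    num = den = 0.0
    for d in range(1, int(max_s // binsize) + 1):
        x = np.diagonal(xs[0], offset=d)
        y = np.diagonal(xs[1], offset=d)
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        w = len(x) * np.sqrt(rx.var() * ry.var())
        num += w * r
        den += w
    return num / den


class TestSCC:
    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(3)
        m = random_contact_matrix(rng, 30)
        res = scc(m, m, h=1)
        assert res.scc == pytest.approx(1.0)
        assert np.allclose(res.per_stratum_rho, 1.0)

    def test_scc_is_weighted_mean_of_strata(self):
        rng = np.random.default_rng(4)
        a = random_contact_matrix(rng, 30)
        b = random_contact_matrix(rng, 30)
        res = scc(a, b, h=1)
        assert res.scc == pytest.approx(
            np.average(res.per_stratum_rho, weights=res.per_stratum_weight)
        )

    def test_unrelated_structures_have_small_scc(self):
        rng = np.random.default_rng(1)
        n = 60
        bins = BinsTable.from_chrom_length("c", n * 10, 10)
        mats = []
        for _ in range(2):
            pattern = rng.choice([-1.0, 1.0], size=n)
            base = 20 * (1 + 0.5 * np.outer(pattern, pattern))
            counts = rng.poisson(np.triu(base))
            counts = counts + np.triu(counts, 1).T
            mats.append(ContactMatrix(bins, counts.astype(float)))
        res = scc(mats[0], mats[1], h=0)
        assert abs(res.scc) < 0.1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        a = random_contact_matrix(rng, 50)
        b = random_contact_matrix(rng, 50)
        got = scc(a, b, h=1, max_s=2_000_000).scc
        want = _scc_oracle(a, b, h=1, max_s=2_000_000)
        assert got == pytest.approx(want, abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(6)
        a = random_contact_matrix(rng, 25)
        b = random_contact_matrix(rng, 25)
        assert scc(a, b).scc == pytest.approx(scc(b, a).scc, abs=1e-12)


class TestDissimilarityAndMDS:
    def test_duplicate_samples_have_zero_dissimilarity(self):
        rng = np.random.default_rng(7)
        m = random_contact_matrix(rng, 25)
        d = dissimilarity_matrix([m, m])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_dissimilarity_within_bounds(self):
        rng = np.random.default_rng(8)
        mats = [random_contact_matrix(rng, 25) for _ in range(3)]
        d = dissimilarity_matrix(mats)
        assert np.all(d >= 0) and np.all(d <= 2)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_mds_reconstructs_collinear_points(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(np.subtract.outer(pts, pts))
        coords = classical_mds(d, k=2)
        rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.allclose(rec, d, atol=1e-6)

    def test_mds_zero_dissimilarity_gives_coincident_points(self):
        coords = classical_mds(np.zeros((4, 4)), k=2)
        assert np.allclose(coords, coords[0])

    def test_mds_invariant_to_labeling_up_to_isometry(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        perm = rng.permutation(6)
        c1 = classical_mds(d, k=2)
        c2 = classical_mds(d[np.ix_(perm, perm)], k=2)
        d1 = np.linalg.norm(c1[:, None] - c1[None, :], axis=-1)
        d2 = np.linalg.norm(c2[:, None] - c2[None, :], axis=-1)
        assert np.allclose(d1[np.ix_(perm, perm)], d2, atol=1e-8)

    def test_mds_warns_when_k_exceeds_rank(self):
        pts = np.array([0.0, 1.0, 2.0])  # collinear: rank 1
        d = np.abs(np.subtract.outer(pts, pts))
        with pytest.warns(RuntimeWarning):
            coords = classical_mds(d, k=3)
        assert coords.shape[1] < 3


class TestHierarchicalCluster:
    def test_two_tight_pairs_merge_first(self):
        # points at 0, 0.1, 10, 10.1
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        d = np.abs(np.subtract.outer(pts, pts))
        z = hierarchical_cluster(d)
        first_two = {frozenset(map(int, row[:2])) for row in z[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        assert np.all(np.diff(z[:, 2]) >= 0)

    def test_single_sample_gives_empty_merge_list(self):
        assert hierarchical_cluster(np.zeros((1, 1))).shape == (0, 4)


class TestSmoothing:
    def test_mean_filter_matches_naive_window_average(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 12))
        sm = _mean_smooth(x, 2)
        i, j = 5, 7
        assert sm[i, j] == pytest.approx(x[3:8, 5:10].mean())
        # edges average only in-bounds cells
        assert sm[0, 0] == pytest.approx(x[0:3, 0:3].mean())
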