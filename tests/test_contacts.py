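"""Contact-matrix I/O, pooling, ICE balancing and normalization."""

import numpy as np
import pytest

from hicdyn import (
    BinsTable,
    ContactDataError,
    ContactMatrix,
    correlation_transform,
    ice_balance,
    matrix_log_ratio,
    observed_over_expected,
    pool_replicates,
    read_contacts,
    write_contacts,
)
from hicdyn.contacts import read_bins, read_cooler_dump, write_bins

from conftest import random_contact_matrix


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def two_bins(tmp_path):
    return _write(
        tmp_path, "bins.tsv", "chr1\t0\t100000\t0\nchr1\t100000\t200000\t1\n"
    )


class TestReadContacts:
    def test_upper_triangle_is_mirrored(self, tmp_path, two_bins):
        coo = _write(tmp_path, "m.coo", "0\t0\t4\n0\t1\t2\n")
        m = read_contacts(coo, two_bins)
        assert np.array_equal(m.counts, [[4, 2], [2, 0]])

    def test_empty_coo_gives_zero_matrix(self, tmp_path):
        bins = _write(
            tmp_path,
            "b3.tsv",
            "chr1\t0\t100000\t0\nchr1\t100000\t200000\t1\nchr1\t200000\t300000\t2\n",
        )
        coo = _write(tmp_path, "empty.coo", "")
        m = read_contacts(coo, bins)
        assert m.counts.shape == (3, 3) and m.counts.sum() == 0

    def test_out_of_range_bin_id_rejected(self, tmp_path, two_bins):
        coo = _write(tmp_path, "bad.coo", "0\t5\t1\n")
        with pytest.raises(ContactDataError):
            read_contacts(coo, two_bins)

    def test_negative_count_rejected(self, tmp_path, two_bins):
        coo = _write(tmp_path, "neg.coo", "0\t1\t-3\n")
        with pytest.raises(ContactDataError):
            read_contacts(coo, two_bins)

    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        m = random_contact_matrix(rng, 30)
        write_contacts(m, tmp_path / "rt.coo", tmp_path / "rt.bins")
        back = read_contacts(tmp_path / "rt.coo", tmp_path / "rt.bins")
        assert np.array_equal(back.counts, m.counts)
        assert back.bins.equals(m.bins)

    def test_cooler_dump_import(self, tmp_path):
        text = (
            "chr1\t0\t100000\tchr1\t100000\t200000\t5\n"
            "chr1\t0\t100000\tchr1\t0\t100000\t3\n"
        )
        m = read_cooler_dump(_write(tmp_path, "dump.tsv", text))
        assert m.counts[0, 1] == 5 and m.counts[1, 0] == 5 and m.counts[0, 0] == 3


class TestBins:
    def test_offset_bins_table_round_trip(self, tmp_path):
        bins = BinsTable("chr2", np.arange(4) * 10 + 100, np.arange(1, 5) * 10 + 100, 10)
        write_bins(bins, tmp_path / "b.tsv")
        assert read_bins(tmp_path / "b.tsv").equals(bins)
        assert bins.bin_of(125) == 2

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ContactDataError):
            BinsTable("chr1", np.array([0, 5]), np.array([10, 15]), 10)


class TestPoolReplicates:
    def test_zero_matrix_is_identity(self):
        rng = np.random.default_rng(1)
        m = random_contact_matrix(rng, 10)
        zero = ContactMatrix(m.bins, np.zeros_like(m.counts))
        assert np.array_equal(pool_replicates(m, zero).counts, m.counts)

    def test_elementwise_sum(self):
        bins = BinsTable.from_chrom_length("c", 20, 10)
        a = ContactMatrix(bins, [[1, 0], [0, 1]])
        b = ContactMatrix(bins, [[1, 2], [2, 1]])
        assert np.array_equal(pool_replicates(a, b).counts, [[2, 2], [2, 2]])

    def test_total_is_sum_of_totals(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = random_contact_matrix(rng, 15)
            b = random_contact_matrix(rng, 15)
            assert pool_replicates(a, b).counts.sum() == pytest.approx(
                a.counts.sum() + b.counts.sum()
            )

    def test_mismatched_bins_rejected(self):
        a = ContactMatrix(BinsTable.from_chrom_length("c", 20, 10), np.zeros((2, 2)) + 1)
        b = ContactMatrix(BinsTable.from_chrom_length("d", 20, 10), np.ones((2, 2)))
        with pytest.raises(ContactDataError):
            pool_replicates(a, b)


def _ipf_oracle(counts, valid, n_iter=5000):
    """Sinkhorn-Knopp alternating row/column proportional fitting.

    For a symmetric input the doubly stochastic limit is the same diagonal
    rescaling D W D that iterative correction targets.
    """
    w = counts[np.ix_(valid, valid)].astype(float)
    for _ in range(n_iter):
        w = w / w.sum(axis=1)[:, None]
        w = w / w.sum(axis=0)[None, :]
    return w / w.sum() * valid.sum()


class TestIceBalance:
    def test_already_balanced_matrix_unchanged_up_to_scale(self):
        bins = BinsTable.from_chrom_length("c", 20, 10)
        m = ContactMatrix(bins, [[0, 2], [2, 0]])
        bal = ice_balance(m)
        v = bal.balanced()
        ratio = v[0, 1] / m.counts[0, 1]
        assert np.allclose(v / ratio, m.counts)
        marg = np.nansum(v, axis=1)
        assert marg[0] == pytest.approx(marg[1])

    def test_zero_coverage_bin_masked(self):
        bins = BinsTable.from_chrom_length("c", 30, 10)
        counts = np.array([[0.0, 5, 0], [5, 2, 0], [0, 0, 0]])
        bal = ice_balance(ContactMatrix(bins, counts))
        assert not bal.mask[2] and bal.mask[0] and bal.mask[1]

    def test_marginals_match_ipf_oracle(self):
        rng = np.random.default_rng(3)
        m = random_contact_matrix(rng, 50)
        bal = ice_balance(m, tol=1e-8)
        v = bal.balanced()[np.ix_(bal.mask, bal.mask)]
        marg = v.sum(axis=1)
        assert np.max(np.abs(marg / marg.mean() - 1)) < 1e-6
        # independent IPF oracle converges to the same balanced matrix shape
        oracle = _ipf_oracle(m.counts, bal.mask)
        assert np.allclose(v / v.sum(), oracle / oracle.sum(), atol=1e-6)

    def test_all_zero_matrix_rejected(self):
        bins = BinsTable.from_chrom_length("c", 30, 10)
        with pytest.raises(ContactDataError):
            ice_balance(ContactMatrix(bins, np.zeros((3, 3))))

    def test_non_convergence_sets_flag(self):
        rng = np.random.default_rng(4)
        m = random_contact_matrix(rng, 40)
        with pytest.warns(RuntimeWarning):
            bal = ice_balance(m, max_iter=1, tol=1e-12)
        assert not bal.converged


class TestObservedOverExpected:
    def test_constant_diagonals_give_ones(self):
        bins = BinsTable.from_chrom_length("c", 40, 10)
        d = np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
        m = ContactMatrix(bins, 10.0 / (d + 1))
        oe = observed_over_expected(m)
        assert np.allclose(oe.counts, 1.0)

    def test_entry_twice_diagonal_mean_is_two(self):
        bins = BinsTable.from_chrom_length("c", 40, 10)
        counts = np.ones((4, 4))
        counts[0, 2] = counts[2, 0] = 2.0  # other |i-j|=2 entry stays 1
        oe = observed_over_expected(ContactMatrix(bins, counts))
        assert oe.counts[0, 2] == pytest.approx(2.0 / 1.5)
        counts2 = np.ones((4, 4))
        counts2[0, 3] = counts2[3, 0] = 2.0  # lone entry on its diagonal
        oe2 = observed_over_expected(ContactMatrix(bins, counts2))
        assert oe2.counts[0, 3] == pytest.approx(1.0)

    def test_per_diagonal_mean_is_one(self):
        rng = np.random.default_rng(5)
        m = random_contact_matrix(rng, 60)
        bal = ice_balance(m)
        oe = observed_over_expected(bal)
        v = oe.counts.astype(float).copy()
        v[~oe.mask, :] = np.nan
        v[:, ~oe.mask] = np.nan
        for d in range(1, 60):
            diag = np.diagonal(v, offset=d)
            finite = np.isfinite(diag)
            vals = diag[finite]
            if len(vals) and vals.sum() > 0:
                assert vals.mean() == pytest.approx(1.0, abs=1e-12)


class TestCorrelationTransform:
    def test_flat_oe_is_fully_masked(self):
        bins = BinsTable.from_chrom_length("c", 50, 10)
        oe = ContactMatrix(bins, np.ones((5, 5)), kind="oe")
        corr = correlation_transform(oe)
        assert not corr.mask.any()

    def test_two_block_plaid_correlations(self):
        bins = BinsTable.from_chrom_length("c", 60, 10)
        pattern = np.array([1, 1, 1, -1, -1, -1])
        oe = 1.0 + 0.5 * np.outer(pattern, pattern)
        corr = correlation_transform(ContactMatrix(bins, oe, kind="oe"))
        same = np.outer(pattern, pattern) > 0
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(corr.counts[same & off], 1.0)
        assert np.allclose(corr.counts[~same], -1.0)

    def test_output_symmetric(self):
        rng = np.random.default_rng(6)
        m = random_contact_matrix(rng, 40)
        corr = correlation_transform(observed_over_expected(ice_balance(m)))
        assert np.allclose(corr.counts, corr.counts.T)


class TestMatrixLogRatio:
    def test_identical_matrices_give_zero(self):
        rng = np.random.default_rng(7)
        m = random_contact_matrix(rng, 20)
        assert np.allclose(matrix_log_ratio(m, m).counts, 0.0)

    def test_doubling_limit(self):
        bins = BinsTable.from_chrom_length("c", 30, 10)
        b = ContactMatrix(bins, np.full((3, 3), 4.0))
        a = ContactMatrix(bins, np.full((3, 3), 8.0))
        lr = matrix_log_ratio(a, b, pseudocount=1e-12)
        assert np.allclose(lr.counts, 1.0, atol=1e-10)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a = random_contact_matrix(rng, 15)
        b = random_contact_matrix(rng, 15)
        ab = matrix_log_ratio(a, b).counts
        ba = matrix_log_ratio(b, a).counts
        assert np.allclose(ab, -ba)

    def test_nonpositive_pseudocount_rejected(self):
        rng = np.random.default_rng(9)
        m = random_contact_matrix(rng, 10)
        with pytest.raises(ContactDataError):
            matrix_log_ratio(m, m, pseudocount=0.0)
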