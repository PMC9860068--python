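"""FPKM, PCA with Horn's parallel analysis, DEG calling, enrichment stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hicdyn import (
    BinsTable,
    ContactDataError,
    ExpressionMatrix,
    call_degs,
    chisq_yates,
    fpkm,
    gene_set_enrichment,
    genes_to_bins,
    log2_enrichment,
    pca_with_horn,
    proximal_genes,
    reciprocal_anchor_enrichment,
    top_loadings,
)


def _expr(counts, lengths=None, times=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(len(counts))]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    n = len(counts)
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 2_000,
            "strand": "+",
            "length": lengths if lengths is not None else np.full(n, 1_000),
        },
        index=counts.index,
    )
    samples = pd.DataFrame(
        {
            "time": times if times is not None else np.zeros(counts.shape[1], int),
            "replicate": np.arange(counts.shape[1]),
        },
        index=counts.columns,
    )
    return ExpressionMatrix(genes=genes, counts=counts, samples=samples)


class TestFpkm:
    def test_formula(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 10
        counts[1, 0] = 10**6 - 10
        expr = _expr(counts, lengths=[1_000, 50_000])
        out = fpkm(expr)
        assert out.iloc[0, 0] == pytest.approx(10 * 1e9 / (1_000 * 1e6))

    def test_zero_count_gives_zero(self):
        expr = _expr([[0, 5], [10, 5]])
        assert fpkm(expr).iloc[0, 0] == 0.0

    def test_invariant_to_global_count_scaling(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(20, 3))
        a = fpkm(_expr(counts))
        b = fpkm(_expr(counts * 2))
        assert np.allclose(a, b)


class TestHornPCA:
    def test_pure_noise_retains_nothing(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 500))
        res = pca_with_horn(x, n_perm=100, seed=3)
        assert res["retained"] == 0

    def test_planted_components_retained(self):
        rng = np.random.default_rng(3)
        n, m = 8, 500
        u1 = np.repeat([1.0, -1.0], 4)
        u2 = np.tile([1.0, -1.0], 4)
        v1, v2 = rng.normal(size=m), rng.normal(size=m)
        x = 10 * (np.outer(u1, v1) + np.outer(u2, v2)) / np.sqrt(m)
        x += rng.normal(size=(n, m))
        res = pca_with_horn(x, n_perm=100, seed=0)
        assert res["retained"] == 2

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        res = pca_with_horn(rng.normal(size=(6, 50)), n_perm=20, seed=0)
        assert res["variance_fractions"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ContactDataError):
            pca_with_horn(rng.normal(size=(6, 50)), n_perm=5)


class TestTopLoadings:
    def test_axis_aligned_component(self):
        loadings = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, -0.2]])
        top = top_loadings(loadings, axis=0, k=1, feature_names=["a", "b", "c"])
        assert top == ["a"]

    def test_positive_and_negative_lists_disjoint(self):
        rng = np.random.default_rng(6)
        loadings = rng.normal(size=(30, 3))
        pos = top_loadings(loadings, axis=1, k=10, sign="positive")
        neg = top_loadings(loadings, axis=1, k=10, sign="negative")
        assert not set(pos) & set(neg)

    def test_k_too_large_rejected(self):
        with pytest.raises(ContactDataError):
            top_loadings(np.zeros((3, 2)), axis=0, k=5)


class TestCallDegs:
    def test_identical_counts_are_ns(self):
        counts = np.tile([[10], [100], [5]], (1, 4))
        expr = _expr(counts)
        degs = call_degs(expr, ["s0", "s1"], ["s2", "s3"])
        assert (degs.direction == "ns").all()

    def test_direction_flips_when_groups_swap(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=(50, 6)).astype(float)
        counts[:5, 3:] *= 16
        expr = _expr(counts)
        fwd = call_degs(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        rev = call_degs(expr, ["s3", "s4", "s5"], ["s0", "s1", "s2"])
        assert np.allclose(fwd.log2fc, -rev.log2fc)
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert all(swap[a] == b for a, b in zip(fwd.direction, rev.direction))

    def test_planted_effects_recovered_with_fdr_control(self):
        rng = np.random.default_rng(8)
        n_genes, n_per_group = 500, 3
        mu = np.exp(rng.normal(5, 1, size=n_genes))
        fold = np.ones(n_genes)
        fold[:50] = 8.0  # planted 8x up-shift in group b
        size = 1 / 0.05
        counts = np.empty((n_genes, 2 * n_per_group))
        for k in range(n_per_group):
            counts[:, k] = rng.negative_binomial(size, size / (size + mu))
            counts[:, n_per_group + k] = rng.negative_binomial(
                size, size / (size + mu * fold)
            )
        expr = _expr(counts)
        degs = call_degs(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        up = degs.direction == "up"
        recall = up[:50].mean()
        false = up[50:].sum()
        assert recall >= 0.9
        assert false / max(1, up.sum()) <= 0.1

    def test_overlapping_groups_rejected(self):
        expr = _expr(np.ones((5, 4)))
        with pytest.raises(ContactDataError):
            call_degs(expr, ["s0", "s1"], ["s1", "s2"])


class TestGenesToBins:
    def _genes(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [250_000, 500_000, 10_000],
                "end": [260_000, 520_000, 20_000],
                "strand": ["+", "+", "+"],
                "length": [1_000, 1_000, 1_000],
            },
            index=["a", "b", "c"],
        )

    def test_tss_bin_assignment_and_edge_convention(self):
        bins = BinsTable.from_chrom_length("chr1", 2_000_000, 500_000)
        with pytest.warns(RuntimeWarning):
            gb = genes_to_bins(self._genes(), bins)
        assert gb["a"] == 0
        assert gb["b"] == 1  # half-open: position 500,000 belongs to bin 1
        assert "c" not in gb.index  # other chromosome skipped

    def test_negative_strand_uses_gene_end(self):
        genes = self._genes().loc[["a"]]
        genes["strand"] = "-"
        bins = BinsTable.from_chrom_length("chr1", 2_000_000, 100_000)
        gb = genes_to_bins(genes, bins)
        assert gb["a"] == 2  # TSS at end-1 = 259,999

    def test_every_mapped_gene_has_one_bin(self):
        bins = BinsTable.from_chrom_length("chr1", 2_000_000, 500_000)
        with pytest.warns(RuntimeWarning):
            gb = genes_to_bins(self._genes(), bins)
        assert gb.index.is_unique and len(gb) == 2


class TestProximalGenes:
    def _genes(self, positions):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": positions,
                "end": np.asarray(positions) + 1_000,
                "strand": "+",
                "length": 1_000,
            },
            index=[f"g{i}" for i in range(len(positions))],
        )

    def test_gene_within_window_included(self):
        genes = self._genes([150_000])
        hit = proximal_genes(genes, np.array([200_000]), window=80_000)
        assert list(hit) == ["g0"]

    def test_zero_window_requires_exact_position(self):
        genes = self._genes([150_000, 200_000])
        hit = proximal_genes(genes, np.array([200_000]), window=0)
        assert list(hit) == ["g1"]

    def test_monotone_in_window(self):
        rng = np.random.default_rng(9)
        genes = self._genes(sorted(rng.integers(0, 10**6, size=50)))
        feats = rng.integers(0, 10**6, size=5)
        sizes = [len(proximal_genes(genes, feats, w)) for w in (0, 10_000, 100_000, 10**6)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestChisqYates:
    def test_worked_example(self):
        res = chisq_yates([[20, 10], [10, 20]])
        assert res["statistic"] == pytest.approx(5.4)
        assert res["p"] == pytest.approx(stats.chi2.sf(5.4, 1))

    def test_balanced_table_is_null(self):
        res = chisq_yates([[10, 10], [10, 10]])
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_invariant_under_transposition(self):
        t = np.array([[7, 21], [13, 5]])
        assert chisq_yates(t)["statistic"] == pytest.approx(
            chisq_yates(t.T)["statistic"]
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ContactDataError):
            chisq_yates([[0, 0], [5, 5]])

    def test_continuity_correction_floors_at_zero(self):
        # |ad - bc| < N/2: the corrected statistic must be 0, not negative
        res = chisq_yates([[5, 5], [5, 6]])
        assert res["statistic"] == 0.0


class TestLog2Enrichment:
    def test_observed_equals_expected_gives_zero(self):
        background = [f"g{i}" for i in range(40)]
        categories = {g: ("x" if i < 20 else "y") for i, g in enumerate(background)}
        hits = {"g0", "g1", "g20", "g21"}  # 2 per category, expected 2
        enr = log2_enrichment(hits, categories, background)
        assert np.allclose(enr["log2_ratio"], 0.0)

    def test_twofold_enrichment(self):
        background = [f"g{i}" for i in range(40)]
        categories = {g: ("x" if i < 20 else "y") for i, g in enumerate(background)}
        hits = {f"g{i}" for i in range(8)}  # 8 observed in x, expected 4
        enr = log2_enrichment(hits, categories, background)
        assert enr.loc["x", "log2_ratio"] == pytest.approx(1.0)

    def test_observed_counts_partition_hits(self):
        rng = np.random.default_rng(10)
        background = [f"g{i}" for i in range(100)]
        categories = {g: rng.choice(["a", "b", "c"]) for g in background}
        hits = set(rng.choice(background, size=30, replace=False))
        enr = log2_enrichment(hits, categories, background)
        assert enr["observed"].sum() == len(hits)


class TestReciprocalAnchors:
    def _genes(self, n=100):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 50_000,
                "end": np.arange(n) * 50_000 + 2_000,
                "strand": "+",
                "length": 1_000,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def _degs(self, genes, up):
        return pd.DataFrame(
            {"direction": ["up" if g in up else "ns" for g in genes.index]},
            index=genes.index,
        )

    def test_uniform_anchors_have_no_enrichment(self):
        genes = self._genes()
        up = {f"g{i}" for i in range(0, 100, 5)}  # every 5th gene
        degs = self._degs(genes, up)
        anchors = genes["start"].to_numpy()  # one anchor per gene
        res = reciprocal_anchor_enrichment(degs, anchors, genes, window=10_000)
        assert abs(res["log2_ratio"]) < 0.1

    def test_anchors_planted_at_degs_are_enriched(self):
        genes = self._genes()
        up = {f"g{i}" for i in range(20)}
        degs = self._degs(genes, up)
        anchors = genes.loc[sorted(up), "start"].to_numpy()
        res = reciprocal_anchor_enrichment(degs, anchors, genes, window=10_000)
        assert res["log2_ratio"] > 1.0
        assert res["p"] < 0.01


class TestGeneSetEnrichment:
    def test_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(50)]
        gene_set = set(universe[:10])
        hits = set(universe[:8])  # 8 of 8-hit set inside a 10-gene set
        res = gene_set_enrichment(hits, {"s": gene_set}, universe)
        want = stats.hypergeom.sf(7, 50, 10, 8)
        assert res.loc["s", "p"] == pytest.approx(want)
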