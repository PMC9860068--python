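"""Expression-side statistics and the observed/expected enrichment framework.

Gene-level RNA-seq counts are the input: FPKM, PCA with Horn's parallel
analysis for component retention, loading extraction, a minimal differential
expression caller (library-size-normalized Welch t on log counts; externally
computed DEG tables are accepted verbatim), gene-to-bin / gene-to-feature
proximity mapping, log2 observed/expected enrichment of gene sets over
genomic categories with Yates-corrected chi-square tests, the reciprocal
anchors-at-DEGs analysis, and generic hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contacts import BinsTable, ContactDataError

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "pca_with_horn",
    "top_loadings",
    "call_degs",
    "genes_to_bins",
    "proximal_genes",
    "log2_enrichment",
    "chisq_yates",
    "reciprocal_anchor_enrichment",
    "gene_set_enrichment",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand", "length"]


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with gene coordinates and sample metadata.

    ``genes`` is indexed by gene id with columns chrom/start/end/strand/length
    (length = exonic bp, > 0); ``counts`` shares the gene index, one column
    per sample; ``samples`` is indexed by sample id with at least a
    ``time`` and ``replicate`` column.
    """

    genes: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ContactDataError(f"gene table lacks columns: {missing}")
        if not self.genes.index.equals(self.counts.index):
            raise ContactDataError("genes and counts must share an index")
        if (self.genes["length"] <= 0).any():
            raise ContactDataError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ContactDataError("counts must be non-negative")
        if not set(self.counts.columns) <= set(self.samples.index):
            raise ContactDataError("every counts column needs sample metadata")

    @classmethod
    def from_tsv(cls, counts_path, genes_path, samples_path) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        genes = pd.read_csv(genes_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(genes=genes.loc[counts.index], counts=counts, samples=samples)


def fpkm(expr: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * total)."""
    totals = expr.counts.sum(axis=0)
    if (totals <= 0).any():
        raise ContactDataError("every sample needs a positive count total")
    lengths = expr.genes["length"].to_numpy()[:, None].astype(float)
    return expr.counts * 1e9 / (lengths * totals.to_numpy()[None, :])


def pca_with_horn(
    x, n_perm: int = 100, quantile: float = 0.95, seed: Optional[int] = None
) -> dict:
    """PCA by SVD with Horn's parallel analysis for component retention.

    Columns of the sample x feature matrix are mean-centered; ``retained``
    counts the leading components whose eigenvalue exceeds the given quantile
    of same-rank eigenvalues from ``n_perm`` independent column-wise
    permutations of the data (the permutation null keeps marginal
    distributions but destroys inter-feature correlation).
    """
    if n_perm < 10:
        raise ContactDataError("n_perm must be >= 10")
    xv = np.asarray(x, dtype=float)
    if xv.ndim != 2 or xv.shape[0] < 3:
        raise ContactDataError("need a 2-D matrix with >= 3 samples")
    n = xv.shape[0]
    xc = xv - xv.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    rng = np.random.default_rng(seed)
    k = len(eig)
    null = np.empty((n_perm, k))
    for b in range(n_perm):
        xp = rng.permuted(xc, axis=0)
        xp -= xp.mean(axis=0, keepdims=True)
        sv = np.linalg.svd(xp, compute_uv=False)
        null[b] = sv**2 / (n - 1)
    thresholds = np.quantile(null, quantile, axis=0)
    retained = 0
    for j in range(k):
        if eig[j] > thresholds[j]:
            retained += 1
        else:
            break
    total = eig.sum()
    return {
        "scores": u * s,
        "loadings": vt.T,
        "eigenvalues": eig,
        "variance_fractions": eig / total if total > 0 else eig,
        "null_quantiles": thresholds,
        "retained": retained,
    }


def top_loadings(
    loadings: np.ndarray,
    axis: int,
    k: int,
    sign: str = "positive",
    feature_names: Optional[Sequence] = None,
) -> list:
    """The k features with largest positive (or most negative) loading."""
    load = np.asarray(loadings)[:, axis]
    if k > len(load):
        raise ContactDataError("k exceeds the number of features")
    order = np.argsort(load)
    idx = order[::-1][:k] if sign == "positive" else order[:k]
    if feature_names is not None:
        return [feature_names[i] for i in idx]
    return list(idx)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (scaled to mean 1).

    Robust to composition bias from a minority of strongly shifted genes,
    unlike plain total-count scaling; falls back to totals when no gene is
    expressed in every sample.
    """
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 10:
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        sf = counts.sum(axis=0)
    return sf / sf.mean()


def call_degs(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Minimal differential-expression caller (b vs a).

    Counts are library-size normalized (scaled to the mean total), log2FC is
    computed with pseudocount 1 on group means, significance by per-gene t
    tests on log2(normalized + 1) with BH adjustment. Per-gene variances are
    moderated toward the gene-wide median with ``prior_df`` pseudo-degrees of
    freedom (the moderated-t idea), which restores power at the 2-3 replicate
    designs this caller targets; set ``prior_df=0`` for the plain Welch test.
    Direction is "up" iff adjusted p < alpha and log2FC > lfc_min, "down"
    symmetrically, else "ns". This does not claim DESeq2 parity; externally
    supplied DEG tables can be used wherever a DEG table is consumed.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ContactDataError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ContactDataError("need >= 2 samples per group")
    counts = expr.counts[group_a + group_b].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ContactDataError("zero-total sample")
    norm = counts / _size_factors(counts)
    na, nb = len(group_a), len(group_b)
    a, b = norm[:, :na], norm[:, na:]
    la, lb = np.log2(a + 1), np.log2(b + 1)
    lfc = np.log2(b.mean(axis=1) + 1) - np.log2(a.mean(axis=1) + 1)
    if prior_df > 0:
        var_a = la.var(axis=1, ddof=1)
        var_b = lb.var(axis=1, ddof=1)
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        s0 = np.median(pooled)
        var_mod = (prior_df * s0 + (na + nb - 2) * pooled) / (prior_df + na + nb - 2)
        se = np.sqrt(var_mod * (1.0 / na + 1.0 / nb))
        diff = lb.mean(axis=1) - la.mean(axis=1)
        df = prior_df + na + nb - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, diff / se, 0.0)
        p = 2 * stats.t.sf(np.abs(t), df)
        p = np.where((se == 0) & (diff == 0), 1.0, p)
        p = np.where((se == 0) & (diff != 0), 0.0, p)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        same = np.isnan(p)
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (padj < alpha) & (lfc > lfc_min),
        "up",
        np.where((padj < alpha) & (lfc < -lfc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": expr.counts.index,
            "log2fc": lfc,
            "p": p,
            "padj": padj,
            "direction": direction,
        }
    ).set_index("gene")


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware transcription start position per gene."""
    tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    return pd.Series(tss, index=genes.index)


def genes_to_bins(genes: pd.DataFrame, bins: BinsTable) -> pd.Series:
    """Map each gene to the bin containing its transcription start.

    Genes on other chromosomes or outside the binned range are skipped (a
    warning reports how many).
    """
    on_chrom = genes[genes["chrom"].astype(str) == bins.chrom]
    tss = tss_positions(on_chrom)
    inside = (tss >= int(bins.starts[0])) & (tss < int(bins.ends[-1]))
    skipped = (len(genes) - len(on_chrom)) + int((~inside).sum())
    if skipped:
        warnings.warn(f"{skipped} genes not mappable to bins", RuntimeWarning)
    tss = tss[inside]
    return ((tss - int(bins.starts[0])) // bins.binsize).astype(int)


def proximal_genes(
    genes: pd.DataFrame, feature_positions: np.ndarray, window: int
) -> pd.Index:
    """Genes whose TSS lies within ±window of any feature position (bp)."""
    if window < 0:
        raise ContactDataError("window must be >= 0")
    pos = np.sort(np.asarray(feature_positions, dtype=np.int64))
    if len(pos) == 0:
        return pd.Index([])
    tss = tss_positions(genes)
    k = np.searchsorted(pos, tss.to_numpy())
    near = np.zeros(len(tss), dtype=bool)
    left = np.clip(k - 1, 0, len(pos) - 1)
    right = np.clip(k, 0, len(pos) - 1)
    near |= np.abs(tss.to_numpy() - pos[left]) <= window
    near |= np.abs(tss.to_numpy() - pos[right]) <= window
    return genes.index[near]


def chisq_yates(table) -> dict:
    """Yates continuity-corrected chi-square for a 2x2 table.

    statistic = N * (max(|ad - bc| - N/2, 0))^2 / (product of marginals);
    p from chi-square with 1 df. Any zero marginal is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ContactDataError("need a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ContactDataError("all marginals must be positive")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    statistic = n * num**2 / (r1 * r2 * c1 * c2)
    return {"statistic": float(statistic), "p": float(stats.chi2.sf(statistic, df=1))}


def log2_enrichment(
    hits: Iterable,
    categories: Mapping,
    background: Iterable,
) -> pd.DataFrame:
    """log2 observed/expected enrichment of a hit set across categories.

    ``categories`` maps item -> category label for every item of the
    background universe; the expected count in a category is
    |hits| * (background items in category / total background), i.e. the
    "observed / density" convention. Each category gets a Yates chi-square of
    hit membership in-category vs out, BH-adjusted across categories.
    Categories where observed > 0 but expected == 0 are flagged and carry no
    log2 value.
    """
    background = list(background)
    if not background:
        raise ContactDataError("empty background")
    hits = set(hits)
    n_bg = len(background)
    n_hits = len(hits)
    labels = {}
    for item in background:
        if item not in categories:
            raise ContactDataError(f"item {item!r} lacks a category")
        labels[item] = categories[item]
    cats = sorted(set(labels.values()), key=str)
    rows = []
    for cat in cats:
        in_cat = [it for it in background if labels[it] == cat]
        obs = sum(1 for it in in_cat if it in hits)
        expected = n_hits * len(in_cat) / n_bg
        flagged = expected == 0 and obs > 0
        if expected > 0 and obs > 0:
            log2r = float(np.log2(obs / expected))
        elif expected > 0:
            log2r = -np.inf
        else:
            log2r = np.nan
        nonhit_in = len(in_cat) - obs
        tbl = np.array(
            [[obs, n_hits - obs], [nonhit_in, (n_bg - n_hits) - nonhit_in]]
        )
        try:
            test = chisq_yates(tbl)
        except ContactDataError:
            test = {"statistic": np.nan, "p": np.nan}
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "expected": expected,
                "log2_ratio": log2r,
                "statistic": test["statistic"],
                "p": test["p"],
                "flagged": flagged,
            }
        )
    df = pd.DataFrame(rows).set_index("category")
    finite = df["p"].notna()
    df["padj"] = np.nan
    if finite.any():
        df.loc[finite, "padj"] = multipletests(df.loc[finite, "p"], method="fdr_bh")[1]
    return df


def reciprocal_anchor_enrichment(
    degs: pd.DataFrame,
    anchor_positions: np.ndarray,
    genes: pd.DataFrame,
    window: int = 10_000,
    direction: str = "up",
) -> dict:
    """Enrichment of loop anchors at DEG loci (features and hits swapped).

    Each anchor is classified by whether a DEG (of the requested direction)
    or any gene has a TSS within ±window; expected = anchors-near-genes x
    (|DEG| / |genes|). Reported with the same log2 observed/expected and
    Yates chi-square statistics as the forward analysis.
    """
    deg_ids = set(degs.index[degs["direction"] == direction])
    if not deg_ids:
        raise ContactDataError("no DEGs of the requested direction")
    pos = np.asarray(anchor_positions, dtype=np.int64)
    tss_all = np.sort(tss_positions(genes).to_numpy())
    tss_deg = np.sort(tss_positions(genes.loc[sorted(deg_ids)]).to_numpy())

    def _near(sorted_pos, query):
        if len(sorted_pos) == 0:
            return np.zeros(len(query), dtype=bool)
        k = np.searchsorted(sorted_pos, query)
        left = np.clip(k - 1, 0, len(sorted_pos) - 1)
        right = np.clip(k, 0, len(sorted_pos) - 1)
        return (np.abs(query - sorted_pos[left]) <= window) | (
            np.abs(query - sorted_pos[right]) <= window
        )

    near_gene = _near(tss_all, pos)
    near_deg = _near(tss_deg, pos)
    n_near = int(near_gene.sum())
    obs = int(near_deg.sum())
    if n_near == 0:
        raise ContactDataError("no anchor is near any gene")
    expected = n_near * len(deg_ids) / len(genes)
    log2r = float(np.log2(obs / expected)) if obs > 0 and expected > 0 else (
        -np.inf if expected > 0 else np.nan
    )
    tbl = np.array(
        [[obs, n_near - obs], [len(deg_ids), len(genes) - len(deg_ids)]]
    )
    try:
        test = chisq_yates(tbl)
    except ContactDataError:
        test = {"statistic": np.nan, "p": np.nan}
    return {
        "observed": obs,
        "expected": expected,
        "log2_ratio": log2r,
        "statistic": test["statistic"],
        "p": test["p"],
        "n_anchors_near_genes": n_near,
    }


def gene_set_enrichment(
    hits: Iterable, gene_sets: Mapping[str, Iterable], universe: Iterable
) -> pd.DataFrame:
    """Hypergeometric over-representation of hits in named gene sets.

    Bonferroni-corrected across sets; this replaces ontology lookups with
    user-supplied sets.
    """
    universe = set(universe)
    hits = set(hits) & universe
    rows = []
    m = len(gene_sets)
    for name, members in gene_sets.items():
        members = set(members) & universe
        obs = len(hits & members)
        p = float(stats.hypergeom.sf(obs - 1, len(universe), len(members), len(hits)))
        rows.append(
            {
                "set": name,
                "observed": obs,
                "set_size": len(members),
                "p": p,
                "p_bonferroni": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows).set_index("set")
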