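"""Contact decay with distance, and between-sample reproducibility.

Covers the P(s) contact-probability curve and its condition-wise comparison
(two-sample Welch t tests with Benjamini-Hochberg adjustment at selected
distances), the HiCRep-style stratum-adjusted correlation coefficient (SCC),
1 − SCC dissimilarity matrices, classical (Torgerson) multidimensional
scaling, and agglomerative clustering of samples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .contacts import ContactDataError, ContactMatrix

__all__ = [
    "DecayCurve",
    "SCCResult",
    "contact_probability",
    "fit_decay_exponent",
    "long_range_fraction",
    "compare_at_distances",
    "scc",
    "dissimilarity_matrix",
    "classical_mds",
    "hierarchical_cluster",
]


@dataclass
class DecayCurve:
    """Contact probability stratified by genomic distance.

    ``s`` is the distance of each stratum in bp (bin-quantized, distance 0
    excluded), ``P`` the probability mass per stratum (sums to 1 over the
    analyzed range), ``counts`` the raw per-stratum totals, ``n_pixels`` the
    number of matrix pixels contributing to each stratum.
    """

    s: np.ndarray
    P: np.ndarray
    counts: np.ndarray
    n_pixels: np.ndarray

    @property
    def counts_total(self) -> float:
        return float(self.counts.sum())

    def per_pixel(self) -> np.ndarray:
        """Mean contact signal per pixel at each stratum."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_pixels > 0, self.counts / self.n_pixels, np.nan)


def _as_list(ms) -> list:
    return list(ms) if isinstance(ms, (list, tuple)) else [ms]


def contact_probability(
    m: "ContactMatrix | Sequence[ContactMatrix]",
    max_s: int,
    use_balanced: bool = False,
) -> DecayCurve:
    """P(s): per-stratum contact totals normalized to sum 1 for s <= max_s.

    Strata are single-bin diagonals; distance 0 is excluded. A list of
    per-chromosome matrices is pooled into one curve. Raw counts are used by
    default (``use_balanced=True`` switches to balanced values).
    """
    mats = _as_list(m)
    if not mats:
        raise ContactDataError("no matrices given")
    binsize = mats[0].bins.binsize
    if max_s < binsize:
        raise ContactDataError("max_s must be at least one binsize")
    n_strata = int(max_s // binsize)
    totals = np.zeros(n_strata)
    npix = np.zeros(n_strata, dtype=np.int64)
    any_signal = False
    for cm in mats:
        if cm.bins.binsize != binsize:
            raise ContactDataError("mixed resolutions in contact_probability")
        if use_balanced:
            v = cm.balanced()
        else:
            v = cm.counts.astype(float).copy()
            v[~cm.mask, :] = np.nan
            v[:, ~cm.mask] = np.nan
        for d in range(1, min(n_strata, cm.n_bins - 1) + 1):
            diag = np.diagonal(v, offset=d)
            finite = np.isfinite(diag)
            totals[d - 1] += np.nansum(diag)
            npix[d - 1] += int(finite.sum())
        any_signal = any_signal or cm.counts.sum() > 0
    if not any_signal or totals.sum() <= 0:
        raise ContactDataError("empty matrix: no contacts in analyzed range")
    s = (np.arange(1, n_strata + 1) * binsize).astype(np.int64)
    return DecayCurve(s=s, P=totals / totals.sum(), counts=totals, n_pixels=npix)


def fit_decay_exponent(
    curve: DecayCurve, s_min: Optional[int] = None, s_max: Optional[int] = None
) -> float:
    """Log-log OLS slope of per-pixel mean contact vs distance."""
    y = curve.per_pixel()
    sel = np.isfinite(y) & (y > 0)
    if s_min is not None:
        sel &= curve.s >= s_min
    if s_max is not None:
        sel &= curve.s <= s_max
    if sel.sum() < 3:
        raise ContactDataError("too few strata for a decay fit")
    return float(np.polyfit(np.log10(curve.s[sel]), np.log10(y[sel]), 1)[0])


def long_range_fraction(curve: DecayCurve, threshold_s: int) -> float:
    """Fraction of contact probability at distances strictly above threshold."""
    return float(curve.P[curve.s > threshold_s].sum())


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_at_distances(
    samples: Mapping[str, Sequence[DecayCurve]], s_list: Sequence[int]
) -> pd.DataFrame:
    """Pairwise two-sided Welch t tests of P(s) between conditions.

    ``samples`` maps condition name to its replicate decay curves (>= 2 each).
    BH adjustment is applied across all condition pairs at each distance.
    """
    for cond, curves in samples.items():
        if len(curves) < 2:
            raise ContactDataError(f"condition {cond!r} has fewer than 2 replicates")
    conds = list(samples)
    rows = []
    for s in s_list:
        vals = {}
        for cond in conds:
            v = []
            for c in samples[cond]:
                k = int(np.argmin(np.abs(c.s - s)))
                v.append(c.P[k])
            vals[cond] = np.array(v)
        pvals, meta = [], []
        for a, b in itertools.combinations(conds, 2):
            t, p = _welch(vals[a], vals[b])
            pvals.append(p)
            meta.append((a, b, t))
        padj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
        for (a, b, t), p, q in zip(meta, pvals, padj):
            rows.append(
                {"s": int(s), "cond_a": a, "cond_b": b, "t": t, "p": p, "p_adj": q}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stratum-adjusted correlation (HiCRep-style)
# ---------------------------------------------------------------------------

@dataclass
class SCCResult:
    """Stratum-adjusted correlation: weighted mean of per-diagonal Pearson r.

    Weights follow the HiCRep recipe: N_k times the geometric mean of the
    rank (variance-stabilized) standard deviations of the two stratum vectors.
    """

    scc: float
    s: np.ndarray
    per_stratum_rho: np.ndarray
    per_stratum_weight: np.ndarray


def _mean_smooth(x: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)^2 mean filter averaging only in-bounds cells.

    Uses an integral image so window sums of integer counts are exact and
    tied values stay tied (the rank-based stratum weights depend on ties).
    """
    if h == 0:
        return x.astype(float)
    n, m = x.shape
    c = np.zeros((n + 1, m + 1))
    c[1:, 1:] = np.cumsum(np.cumsum(x, axis=0), axis=1)
    idx_i = np.arange(n)
    idx_j = np.arange(m)
    lo_i, hi_i = np.maximum(idx_i - h, 0), np.minimum(idx_i + h + 1, n)
    lo_j, hi_j = np.maximum(idx_j - h, 0), np.minimum(idx_j + h + 1, m)
    sums = (
        c[np.ix_(hi_i, hi_j)]
        - c[np.ix_(lo_i, hi_j)]
        - c[np.ix_(hi_i, lo_j)]
        + c[np.ix_(lo_i, lo_j)]
    )
    counts = np.outer(hi_i - lo_i, hi_j - lo_j)
    return sums / counts


def scc(
    a: ContactMatrix,
    b: ContactMatrix,
    h: int = 1,
    max_s: Optional[int] = None,
) -> SCCResult:
    """Stratum-adjusted correlation coefficient between two samples.

    Both matrices are smoothed with a (2h+1)^2 mean filter; per distance
    stratum up to ``max_s`` the Pearson correlation over jointly unmasked
    pixels is combined with HiCRep weights. Strata with < 2 pixels or zero
    variance are skipped.
    """
    if not a.bins.equals(b.bins):
        raise ContactDataError("SCC requires identical bins")
    if h < 0:
        raise ContactDataError("h must be >= 0")
    binsize = a.bins.binsize
    n = a.n_bins
    dmax = n - 1 if max_s is None else min(n - 1, int(max_s // binsize))
    xa = _mean_smooth(a.counts, h)
    xb = _mean_smooth(b.counts, h)
    ok = a.mask & b.mask
    rhos, weights, svals = [], [], []
    for d in range(1, dmax + 1):
        pair_ok = ok[: n - d] & ok[d:]
        if pair_ok.sum() < 2:
            continue
        x = np.diagonal(xa, offset=d)[pair_ok]
        y = np.diagonal(xb, offset=d)[pair_ok]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        w = len(x) * np.sqrt(rx.var() * ry.var())
        rhos.append(r)
        weights.append(w)
        svals.append(d * binsize)
    if not rhos:
        raise ContactDataError("no valid distance strata for SCC")
    rhos = np.array(rhos)
    weights = np.array(weights)
    val = float(np.average(rhos, weights=weights))
    return SCCResult(scc=val, s=np.array(svals), per_stratum_rho=rhos, per_stratum_weight=weights)


def dissimilarity_matrix(
    samples: Sequence[ContactMatrix], h: int = 1, max_s: Optional[int] = None
) -> np.ndarray:
    """D[i, j] = 1 - SCC(sample i, sample j); symmetric with zero diagonal."""
    if len(samples) < 2:
        raise ContactDataError("need at least two samples")
    k = len(samples)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = 1.0 - scc(samples[i], samples[j], h=h, max_s=max_s).scc
    return d


def classical_mds(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center -squared dissimilarities, top-k eigenvectors.

    Returns n x k coordinates (fewer columns, with a warning, if the
    double-centered matrix has fewer positive eigenvalues than k).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ContactDataError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ContactDataError("dissimilarity matrix must be symmetric with zero diagonal")
    if k < 1:
        raise ContactDataError("k must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(bmat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0])) if vals[0] > 0 else np.zeros_like(vals, bool)
    npos = int(pos.sum())
    use = min(k, npos)
    if use < k:
        warnings.warn(
            f"only {npos} positive eigenvalues; returning {use} MDS dimensions",
            RuntimeWarning,
        )
    if use == 0:
        return np.zeros((n, k))
    return vecs[:, :use] * np.sqrt(vals[:use])


def hierarchical_cluster(d: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a dissimilarity matrix.

    Returns the scipy linkage merge list (empty for a single sample).
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] <= 1:
        return np.empty((0, 4))
    return _scipy_linkage(squareform(d, checks=False), method=method)
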