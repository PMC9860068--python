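"""Contact-matrix data model, text I/O, and normalization.

Binned intra-chromosomal Hi-C data are held as dense symmetric per-chromosome
matrices together with their bins table. The module provides replicate
pooling (raw-count summation), ICE matrix balancing (iterative correction to
equal marginals), distance-expected (observed/expected) normalization, the
Pearson correlation transform used upstream of compartment calling, and
elementwise log2 ratio maps for comparing two conditions.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BinsTable",
    "ContactMatrix",
    "ContactDataError",
    "read_bins",
    "write_bins",
    "read_contacts",
    "write_contacts",
    "read_cooler_dump",
    "pool_replicates",
    "ice_balance",
    "observed_over_expected",
    "correlation_transform",
    "matrix_log_ratio",
]


class ContactDataError(ValueError):
    """Raised on malformed or inconsistent contact-matrix input."""


def _opener(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True, eq=False)
class BinsTable:
    """Uniformly binned segmentation of a single chromosome.

    ``start`` is 0-based inclusive, ``end`` half-open; the terminal bin may be
    shorter than ``binsize``. Bin ids are the contiguous 0..n-1 row indices.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    binsize: int

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.shape != ends.shape or starts.ndim != 1 or len(starts) == 0:
            raise ContactDataError("bins table must be a non-empty 1-D segmentation")
        if np.any(ends <= starts):
            raise ContactDataError("bin end must exceed bin start")
        if len(starts) > 1:
            if np.any(np.diff(starts) <= 0):
                raise ContactDataError("bin starts must be strictly increasing")
            if np.any(starts[1:] < ends[:-1]):
                raise ContactDataError("bins must not overlap")
            if np.any((ends[:-1] - starts[:-1]) != self.binsize):
                raise ContactDataError("non-terminal bins must all span binsize bp")
        if ends[-1] - starts[-1] > self.binsize:
            raise ContactDataError("terminal bin exceeds binsize")

    @classmethod
    def from_chrom_length(cls, chrom: str, length: int, binsize: int) -> "BinsTable":
        if length <= 0 or binsize <= 0:
            raise ContactDataError("chromosome length and binsize must be positive")
        starts = np.arange(0, length, binsize, dtype=np.int64)
        ends = np.minimum(starts + binsize, length)
        return cls(chrom, starts, ends, binsize)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def bin_of(self, pos: int) -> int:
        """Bin id containing bp position ``pos`` (half-open intervals)."""
        if pos < self.starts[0] or pos >= self.ends[-1]:
            raise ContactDataError(f"position {pos} outside binned range")
        return int((pos - self.starts[0]) // self.binsize)

    def equals(self, other: "BinsTable") -> bool:
        return (
            self.chrom == other.chrom
            and self.binsize == other.binsize
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "index": np.arange(self.n_bins),
            }
        )


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix with bin metadata.

    ``counts`` holds the current values: raw counts for freshly read matrices,
    or transformed values (O/E, correlation, log-ratio) with ``kind`` saying
    which. ``weights`` are multiplicative ICE balancing weights such that the
    balanced value of pixel (i, j) is ``weights[i] * weights[j] * counts[i, j]``.
    ``mask`` flags usable bins; masked bins contribute nothing to statistics.
    """

    bins: BinsTable
    counts: np.ndarray
    weights: Optional[np.ndarray] = None
    mask: np.ndarray = None
    converged: bool = True
    kind: str = "raw"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise ContactDataError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ContactDataError("contact matrix must be symmetric")
        if self.kind == "raw" and np.nanmin(self.counts) < 0:
            raise ContactDataError("raw counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ContactDataError("mask length must equal bin count")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (n,):
                raise ContactDataError("weights length must equal bin count")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def balanced(self) -> np.ndarray:
        """Balanced (or current) values with masked bins set to NaN."""
        if self.weights is not None:
            out = self.counts * np.outer(self.weights, self.weights)
        else:
            out = self.counts.astype(np.float64).copy()
        out[~self.mask, :] = np.nan
        out[:, ~self.mask] = np.nan
        return out


# ---------------------------------------------------------------------------
# I/O: bins TSV, COO contact text, cooler-style dump. All gzip-transparent.
# ---------------------------------------------------------------------------

def read_bins(path) -> BinsTable:
    """Read a chrom/start/end/index TSV (header optional) for one chromosome."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ContactDataError("bins table needs chrom, start, end, index columns")
    # tolerate a header row
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    chroms = df.iloc[:, 0].astype(str)
    if chroms.nunique() != 1:
        raise ContactDataError("a bins table must describe a single chromosome")
    starts = df.iloc[:, 1].astype(np.int64).to_numpy()
    ends = df.iloc[:, 2].astype(np.int64).to_numpy()
    idx = df.iloc[:, 3].astype(np.int64).to_numpy()
    order = np.argsort(idx)
    if not np.array_equal(idx[order], np.arange(len(idx))):
        raise ContactDataError("bin indices must be contiguous from 0")
    starts, ends = starts[order], ends[order]
    binsize = int(ends[0] - starts[0]) if len(starts) == 1 else int(starts[1] - starts[0])
    return BinsTable(chroms.iloc[0], starts, ends, binsize)


def write_bins(bins: BinsTable, path) -> None:
    with _opener(path, "wt") as fh:
        bins.to_frame().to_csv(fh, sep="\t", header=False, index=False)


def read_contacts(coo_path, bins_path) -> ContactMatrix:
    """Materialize a symmetric matrix from "bin1<TAB>bin2<TAB>count" text.

    The upper triangle is mirrored; duplicate pixels accumulate. Unknown bin
    ids and negative counts are rejected.
    """
    bins = read_bins(bins_path)
    n = bins.n_bins
    m = np.zeros((n, n), dtype=np.float64)
    try:
        coo = pd.read_csv(coo_path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        coo = pd.DataFrame(columns=[0, 1, 2])
    if len(coo):
        if coo.shape[1] < 3:
            raise ContactDataError("COO rows must be bin1<TAB>bin2<TAB>count")
        i = coo.iloc[:, 0].astype(np.int64).to_numpy()
        j = coo.iloc[:, 1].astype(np.int64).to_numpy()
        c = coo.iloc[:, 2].astype(np.float64).to_numpy()
        if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
            raise ContactDataError("bin id outside bins table")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ContactDataError("contact counts must be finite and non-negative")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        np.add.at(m, (lo, hi), c)
        upper = np.triu(m, 1)
        m = m + upper.T
    return ContactMatrix(bins, m)


def write_contacts(m: ContactMatrix, coo_path, bins_path=None) -> None:
    """Write the non-zero upper triangle (incl. diagonal) as COO text."""
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.counts[iu, ju]
    keep = vals != 0
    with _opener(coo_path, "wt") as fh:
        for a, b, v in zip(iu[keep], ju[keep], vals[keep]):
            if float(v).is_integer():
                fh.write(f"{a}\t{b}\t{int(v)}\n")
            else:
                fh.write(f"{a}\t{b}\t{v!r}\n")
    if bins_path is not None:
        write_bins(m.bins, bins_path)


def read_cooler_dump(path, chrom: Optional[str] = None) -> ContactMatrix:
    """Import a cooler-style text dump.

    Expected columns: chrom1 start1 end1 chrom2 start2 end2 count. Only
    intra-chromosomal rows of a single chromosome are accepted (pass ``chrom``
    to select one from a mixed dump).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "count"],
    )
    df = df[df.chrom1 == df.chrom2]
    if chrom is not None:
        df = df[df.chrom1.astype(str) == str(chrom)]
    if df.empty:
        raise ContactDataError("no usable intra-chromosomal rows in dump")
    if df.chrom1.nunique() != 1:
        raise ContactDataError("dump spans several chromosomes; pass chrom=")
    binsize = int((df.end1 - df.start1).min())
    length = int(max(df.end1.max(), df.end2.max()))
    bins = BinsTable.from_chrom_length(str(df.chrom1.iloc[0]), length, binsize)
    n = bins.n_bins
    i = (df.start1.to_numpy() // binsize).astype(np.int64)
    j = (df.start2.to_numpy() // binsize).astype(np.int64)
    c = df["count"].astype(np.float64).to_numpy()
    if np.any(c < 0):
        raise ContactDataError("contact counts must be non-negative")
    m = np.zeros((n, n))
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    np.add.at(m, (lo, hi), c)
    m = m + np.triu(m, 1).T
    return ContactMatrix(bins, m)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pool_replicates(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Sum raw counts of two replicates; balancing weights are cleared."""
    if not a.bins.equals(b.bins):
        raise ContactDataError("cannot pool matrices with different bins")
    return ContactMatrix(a.bins, a.counts + b.counts)


def ice_balance(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_filter: float = 3.0,
) -> ContactMatrix:
    """Iterative correction (ICE) to equal marginals.

    Bins with zero coverage, or whose raw marginal falls more than
    ``mad_filter`` median absolute deviations below the median marginal, are
    masked before correction. Weights are scaled so balanced marginals of
    unmasked bins average 1. Non-convergence within ``max_iter`` sets
    ``converged=False`` on the result (with a warning) rather than raising.
    """
    if tol <= 0:
        raise ContactDataError("tol must be positive")
    counts = m.counts
    if counts.sum() == 0:
        raise ContactDataError("cannot balance an all-zero matrix")
    marg = counts.sum(axis=1)
    valid = marg > 0
    nz = marg[valid]
    med = np.median(nz)
    mad = np.median(np.abs(nz - med))
    if mad > 0 and mad_filter is not None:
        valid &= marg >= med - mad_filter * mad
    valid &= m.mask
    if valid.sum() < 2:
        raise ContactDataError("fewer than two usable bins after coverage filtering")

    sub = counts[np.ix_(valid, valid)]
    b = np.ones(valid.sum())
    converged = False
    for _ in range(max_iter):
        s = (sub / np.outer(b, b)).sum(axis=1)
        if np.any(s == 0):  # bin became disconnected within the valid set
            raise ContactDataError("zero marginal inside valid set during ICE")
        rel = s / s.mean()
        if np.max(np.abs(rel - 1)) < tol:
            converged = True
            break
        b *= rel
    s = (sub / np.outer(b, b)).sum(axis=1)
    scale = np.sqrt(s.mean())
    w = np.full(m.n_bins, np.nan)
    w[valid] = 1.0 / (b * scale)
    if not converged:
        warnings.warn("ICE did not converge within max_iter", RuntimeWarning)
    return ContactMatrix(m.bins, counts.copy(), weights=w, mask=valid, converged=converged)


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each diagonal by its mean over unmasked entries.

    Operates on balanced values when weights are present, otherwise on the
    stored values directly (useful for noise-free expected matrices).
    Diagonals with zero mean are left as zero. Masked bins hold 0 and stay
    masked.
    """
    v = m.balanced()
    n = m.n_bins
    oe = np.zeros_like(v)
    for d in range(n):
        diag = np.diagonal(v, offset=d)
        finite = np.isfinite(diag)
        if not finite.any():
            continue
        mu = diag[finite].mean()
        if mu > 0:
            vals = np.where(finite, diag / mu, 0.0)
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    oe[~m.mask, :] = 0.0
    oe[:, ~m.mask] = 0.0
    return ContactMatrix(m.bins, oe, mask=m.mask.copy(), kind="oe")


def correlation_transform(oe: ContactMatrix) -> ContactMatrix:
    """Pearson correlation of O/E rows over unmasked columns.

    Zero-variance rows are masked. The diagonal is set to 1 on unmasked bins.
    """
    valid = oe.mask.copy()
    if valid.sum() < 3:
        raise ContactDataError("need at least 3 unmasked bins for correlation")
    sub = oe.counts[np.ix_(valid, valid)]
    sd = sub.std(axis=1)
    keep = sd > 0
    valid_idx = np.flatnonzero(valid)
    valid2 = np.zeros(oe.n_bins, dtype=bool)
    valid2[valid_idx[keep]] = True
    if valid2.sum() < 3:
        # all (or nearly all) rows constant: everything masked
        out = np.zeros_like(oe.counts)
        return ContactMatrix(oe.bins, out, mask=np.zeros(oe.n_bins, bool), kind="corr")
    sub2 = oe.counts[np.ix_(valid2, valid2)]
    corr = np.corrcoef(sub2)
    np.fill_diagonal(corr, 1.0)
    out = np.zeros_like(oe.counts)
    out[np.ix_(valid2, valid2)] = corr
    return ContactMatrix(oe.bins, out, mask=valid2, kind="corr")


def matrix_log_ratio(
    a: ContactMatrix,
    b: ContactMatrix,
    pseudocount: float = 1e-6,
    normalize: bool = False,
) -> ContactMatrix:
    """log2((a + pc) / (b + pc)) elementwise over jointly unmasked bins.

    Inputs are expected balanced and scaled to equal totals; pass
    ``normalize=True`` to rescale both to unit total over shared unmasked
    pixels first.
    """
    if pseudocount <= 0:
        raise ContactDataError("pseudocount must be positive")
    if not a.bins.equals(b.bins):
        raise ContactDataError("bins tables differ")
    mask = a.mask & b.mask
    va, vb = a.balanced(), b.balanced()
    va = np.where(np.isfinite(va), va, 0.0)
    vb = np.where(np.isfinite(vb), vb, 0.0)
    if normalize:
        sel = np.ix_(mask, mask)
        ta, tb = va[sel].sum(), vb[sel].sum()
        if ta <= 0 or tb <= 0:
            raise ContactDataError("cannot normalize a zero-total matrix")
        va, vb = va / ta, vb / tb
    ratio = np.log2((va + pseudocount) / (vb + pseudocount))
    ratio[~mask, :] = 0.0
    ratio[:, ~mask] = 0.0
    return ContactMatrix(a.bins, _symmetrize(ratio), mask=mask, kind="ratio")


def _symmetrize(x: np.ndarray) -> np.ndarray:
    return (x + x.T) / 2.0
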