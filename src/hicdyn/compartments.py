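"""A/B compartment calling and time-course compartment dynamics.

Compartments are the two alternating megabase-scale chromatin states visible
as a plaid pattern in Hi-C maps. Per chromosome, the leading eigenvector
(PC1) of the Pearson correlation-transformed contact matrix separates the two
states; its sign is oriented so that positive PC1 correlates with a per-bin
covariate (gene density by default), making A the gene-dense, active state.

The module also classifies per-bin switch trajectories across time points
(stable A/B vs dynamic patterns like "B-to-A"), computes saddle matrices
(mean O/E between PC1-decile pairs) quantifying compartment strength, PC1
scatter statistics between samples, per-bin PC1 difference tracks, and a
rank-sum comparison of gene expression in a region set against background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BinsTable, ContactDataError, ContactMatrix

__all__ = [
    "CompartmentTrack",
    "SaddleMatrix",
    "compartment_pc1",
    "classify_switches",
    "switch_proportions",
    "dynamic_fraction",
    "pc1_scatter_stats",
    "pc1_delta_track",
    "saddle",
    "saddle_log_ratio",
    "expression_vs_background",
]

STABLE_A = "stable A"
STABLE_B = "stable B"
MASKED = "masked"


@dataclass
class CompartmentTrack:
    """Per-bin PC1 score and A/B state for one chromosome.

    State is "A" wherever pc1 > 0, "B" wherever pc1 <= 0, and "masked" on
    invalid bins (pc1 is NaN there).
    """

    bins: BinsTable
    pc1: np.ndarray
    state: np.ndarray

    def __post_init__(self):
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.state = np.asarray(self.state, dtype=object)
        if len(self.pc1) != self.bins.n_bins or len(self.state) != self.bins.n_bins:
            raise ContactDataError("track length must match bins")

    @property
    def mask(self) -> np.ndarray:
        return self.state != MASKED


def compartment_pc1(
    corr: ContactMatrix, orientation: np.ndarray
) -> CompartmentTrack:
    """PC1 of the correlation matrix, sign-fixed against a covariate track.

    The leading eigenvector of the correlation matrix restricted to unmasked
    bins is scaled to unit norm times sqrt(eigenvalue), then flipped so its
    Pearson correlation with ``orientation`` (e.g. gene density per bin) is
    positive. A = pc1 > 0.
    """
    orientation = np.asarray(orientation, dtype=float)
    if len(orientation) != corr.n_bins:
        raise ContactDataError("orientation track length must match bins")
    valid = corr.mask
    if valid.sum() < 3:
        raise ContactDataError("too few unmasked bins for PC1")
    sub = corr.counts[np.ix_(valid, valid)]
    sub = (sub + sub.T) / 2.0
    try:
        vals, vecs = np.linalg.eigh(sub)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ContactDataError(f"eigendecomposition failed: {exc}")
    v = vecs[:, -1]
    lam = max(vals[-1], 0.0)
    v = v / np.linalg.norm(v) * np.sqrt(lam)
    ori = orientation[valid]
    if np.std(ori) > 0 and np.std(v) > 0:
        r = np.corrcoef(v, ori)[0, 1]
    else:
        r = 0.0
    if r < 0:
        v = -v
    elif r == 0 or np.isnan(r):
        # deterministic tie-break: first non-zero loading positive
        nz = np.flatnonzero(v)
        if len(nz) and v[nz[0]] < 0:
            v = -v
    pc1 = np.full(corr.n_bins, np.nan)
    pc1[valid] = v
    state = np.array([MASKED] * corr.n_bins, dtype=object)
    state[valid] = np.where(pc1[valid] > 0, "A", "B")
    return CompartmentTrack(bins=corr.bins, pc1=pc1, state=state)


def classify_switches(tracks: Sequence[CompartmentTrack]) -> np.ndarray:
    """Per-bin switch label from the A/B state sequence across time points.

    Consecutive repeats collapse ("B,B,A,A" -> "B-to-A"); a masked state at
    any time point invalidates the bin ("masked").
    """
    if len(tracks) < 2:
        raise ContactDataError("need at least two time points")
    bins = tracks[0].bins
    for t in tracks[1:]:
        if not t.bins.equals(bins):
            raise ContactDataError("tracks must share a bins table")
    n = bins.n_bins
    labels = np.empty(n, dtype=object)
    states = np.vstack([t.state for t in tracks])
    for i in range(n):
        seq = states[:, i]
        if np.any(seq == MASKED):
            labels[i] = MASKED
            continue
        collapsed = [seq[0]]
        for s in seq[1:]:
            if s != collapsed[-1]:
                collapsed.append(s)
        if len(collapsed) == 1:
            labels[i] = f"stable {collapsed[0]}"
        else:
            labels[i] = "-to-".join(collapsed)
    return labels


def switch_proportions(labels: np.ndarray) -> pd.Series:
    """Proportion of each switch label over unmasked bins (sums to 1)."""
    keep = labels[labels != MASKED]
    if len(keep) == 0:
        raise ContactDataError("all bins masked")
    return pd.Series(keep).value_counts(normalize=True)


def dynamic_fraction(labels: np.ndarray) -> float:
    """Fraction of unmasked bins whose state changes at least once."""
    keep = labels[labels != MASKED]
    if len(keep) == 0:
        raise ContactDataError("all bins masked")
    return float(np.mean([not str(l).startswith("stable") for l in keep]))


def pc1_scatter_stats(x: CompartmentTrack, y: CompartmentTrack) -> dict:
    """Spearman rho and OLS slope of y.pc1 on x.pc1 over shared unmasked bins."""
    sel = x.mask & y.mask & np.isfinite(x.pc1) & np.isfinite(y.pc1)
    if sel.sum() < 3:
        raise ContactDataError("need >= 3 shared unmasked bins")
    xv, yv = x.pc1[sel], y.pc1[sel]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ContactDataError("constant PC1 input")
    rho = float(stats.spearmanr(xv, yv).statistic)
    slope = float(np.polyfit(xv, yv, 1)[0])
    return {"rho": rho, "slope": slope, "n": int(sel.sum())}


def pc1_delta_track(a: CompartmentTrack, b: CompartmentTrack) -> np.ndarray:
    """Per-bin PC1 difference b - a (NaN wherever either bin is masked)."""
    if not a.bins.equals(b.bins):
        raise ContactDataError("tracks must share a bins table")
    return b.pc1 - a.pc1


@dataclass
class SaddleMatrix:
    """Mean O/E between PC1-quantile pairs, quantiles ascending in PC1.

    Cell (0, 0) is therefore the strongest-B corner and (k-1, k-1) the
    strongest-A corner.
    """

    values: np.ndarray
    counts: np.ndarray
    edges: np.ndarray


def saddle(
    oe: "ContactMatrix | Sequence[ContactMatrix]",
    track: "CompartmentTrack | Sequence[CompartmentTrack]",
    n_bins: int = 10,
) -> SaddleMatrix:
    """Saddle matrix of mean O/E over PC1-decile pairs.

    Bins are ranked by PC1 (ascending, ties broken by bin index) into
    ``n_bins`` quantile groups per chromosome; the cell (p, q) averages O/E
    over all off-diagonal pixel pairs with one bin in group p and one in q,
    pooled across chromosomes.
    """
    oes = oe if isinstance(oe, (list, tuple)) else [oe]
    tracks = track if isinstance(track, (list, tuple)) else [track]
    if len(oes) != len(tracks):
        raise ContactDataError("one track per O/E matrix required")
    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins))
    edges_all = []
    for m, t in zip(oes, tracks):
        if not m.bins.equals(t.bins):
            raise ContactDataError("O/E and track bins differ")
        valid = m.mask & t.mask & np.isfinite(t.pc1)
        idx = np.flatnonzero(valid)
        if len(idx) < n_bins:
            raise ContactDataError("fewer unmasked bins than saddle quantiles")
        order = idx[np.lexsort((idx, t.pc1[idx]))]
        groups = np.array_split(order, n_bins)
        g = np.full(m.n_bins, -1)
        for q, members in enumerate(groups):
            g[members] = q
        sub = m.counts
        gi = g[idx]
        pairs = sub[np.ix_(idx, idx)]
        gg_i = np.repeat(gi, len(idx))
        gg_j = np.tile(gi, len(idx))
        vals = pairs.ravel()
        offdiag = ~np.eye(len(idx), dtype=bool).ravel()
        np.add.at(sums, (gg_i[offdiag], gg_j[offdiag]), vals[offdiag])
        np.add.at(counts, (gg_i[offdiag], gg_j[offdiag]), 1)
        edges_all.append([t.pc1[gr[0]] for gr in groups] + [t.pc1[groups[-1][-1]]])
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / counts, np.nan)
    values = (values + values.T) / 2.0
    return SaddleMatrix(values=values, counts=counts, edges=np.asarray(edges_all[0]))


def saddle_log_ratio(a: SaddleMatrix, b: SaddleMatrix) -> np.ndarray:
    """Elementwise log2(a / b) of two saddle matrices."""
    if a.values.shape != b.values.shape:
        raise ContactDataError("saddle shapes differ")
    if np.any(~(a.values > 0)) or np.any(~(b.values > 0)):
        raise ContactDataError("saddle log ratio requires strictly positive cells")
    return np.log2(a.values / b.values)


def expression_vs_background(
    values: pd.Series,
    gene_bins: pd.Series,
    region_bins: set,
    background: str = "rest",
) -> dict:
    """Rank-sum test of per-gene expression inside a bin set vs background.

    ``values`` maps gene id to an expression summary (e.g. log FPKM);
    ``gene_bins`` maps gene id to its bin. ``background`` is "rest" (genes
    outside the region set) or "all" (every gene).
    """
    common = values.index.intersection(gene_bins.index)
    vals = values.loc[common]
    inside = gene_bins.loc[common].isin(region_bins)
    region_vals = vals[inside]
    bg_vals = vals if background == "all" else vals[~inside]
    if len(region_vals) == 0 or len(bg_vals) == 0:
        raise ContactDataError("empty region or background gene set")
    stat, p = stats.mannwhitneyu(region_vals, bg_vals, alternative="two-sided")
    return {
        "statistic": float(stat),
        "p": float(p),
        "median_region": float(np.median(region_vals)),
        "median_background": float(np.median(bg_vals)),
        "n_region": int(len(region_vals)),
        "n_background": int(len(bg_vals)),
    }
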