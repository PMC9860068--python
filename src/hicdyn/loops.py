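"""Donut-filter pairwise point interaction (loop) calling and summaries.

A simplified single-resolution HiCCUPS-style caller: each candidate pixel is
compared against four local-neighborhood expected values (donut, lower-left,
horizontal, vertical), each rescaled by the pixel's distance-decay expected.
Significance is a Poisson upper tail on the raw count against the most
conservative (largest) of the four expecteds, with Benjamini-Hochberg
correction within distance bands instead of HiCCUPS's lambda-chunking.
Significant pixels passing an enrichment floor on every filter are merged
into loops by proximity; the centroid pixel (strongest balanced signal) is
reported with its two anchor bin intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .compartments import CompartmentTrack
from .contacts import ContactDataError, ContactMatrix

__all__ = [
    "LoopSet",
    "local_expected",
    "call_loops",
    "anchor_distances",
    "intersect_anchor_sets",
    "stratify_loops_by_compartment",
]

FILTERS = ("donut", "lower_left", "horizontal", "vertical")


@dataclass
class LoopSet:
    """Called loops with anchor intervals, observed counts and q-values."""

    loops: pd.DataFrame  # chrom, start1, end1, start2, end2, observed, q, ...
    resolution: int
    params: dict

    def __len__(self) -> int:
        return len(self.loops)

    def anchor_midpoints(self) -> tuple[np.ndarray, np.ndarray]:
        m1 = ((self.loops.start1 + self.loops.end1) // 2).to_numpy()
        m2 = ((self.loops.start2 + self.loops.end2) // 2).to_numpy()
        return m1, m2

    def to_bedpe(self, path) -> None:
        df = self.loops.copy()
        df["name"] = [f"loop_{k}" for k in range(len(df))]
        out = df[["chrom", "start1", "end1", "start2", "end2", "name", "q"]]
        out.insert(3, "chrom2", df["chrom"])
        out.to_csv(path, sep="\t", header=False, index=False)


def _footprints(p: int, w: int) -> dict[str, np.ndarray]:
    """Boolean (2w+1)^2 kernels for the four HiCCUPS neighborhoods."""
    if not (w > p >= 1):
        raise ContactDataError("need w > p >= 1")
    da, db = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    cheb = np.maximum(np.abs(da), np.abs(db))
    donut = (cheb > p) & (cheb <= w) & (da != 0) & (db != 0)
    lower_left = (da >= 1) & (da <= w) & (db <= -1) & (db >= -w) & ~((da <= p) & (db >= -p))
    horizontal = (np.abs(da) <= 1) & (np.abs(db) > p) & (np.abs(db) <= w)
    vertical = (np.abs(db) <= 1) & (np.abs(da) > p) & (np.abs(da) <= w)
    return {
        "donut": donut,
        "lower_left": lower_left,
        "horizontal": horizontal,
        "vertical": vertical,
    }


def _decay_expected(v: np.ndarray) -> np.ndarray:
    """Per-diagonal mean of finite entries; full expected matrix by |i-j|."""
    n = v.shape[0]
    e = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(v, offset=d)
        finite = np.isfinite(diag)
        e[d] = diag[finite].mean() if finite.any() else 0.0
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return e[idx]


def local_expected(
    m: ContactMatrix, pixel: tuple[int, int], p: int = 2, w: int = 5
) -> dict[str, float]:
    """Expected balanced counts at one pixel under the four local filters.

    Each filter expected is E(d_pixel) * sum(observed over footprint) /
    sum(decay-expected over footprint), i.e. the neighborhood's O/E applied
    to the pixel's own distance expectation.
    """
    i, j = pixel
    if i > j:
        i, j = j, i
    n = m.n_bins
    if j - i <= w or i - w < 0 or j + w >= n:
        raise ContactDataError("pixel too close to the diagonal or matrix edge")
    v = m.balanced() if m.weights is not None else np.where(
        np.outer(m.mask, m.mask), m.counts.astype(float), np.nan
    )
    emat = _decay_expected(v)
    kernels = _footprints(p, w)
    out = {}
    sub_v = v[i - w : i + w + 1, j - w : j + w + 1]
    sub_e = emat[i - w : i + w + 1, j - w : j + w + 1]
    for name, k in kernels.items():
        sel = k & np.isfinite(sub_v)
        so, se = sub_v[sel].sum(), sub_e[sel].sum()
        out[name] = float(emat[i, j] * so / se) if se > 0 else np.nan
    return out


def call_loops(
    m: ContactMatrix,
    p: int = 2,
    w: int = 5,
    fdr: float = 0.1,
    enrichment_min: float = 1.75,
    merge_radius: int = 20_000,
    max_s: Optional[int] = None,
    band_width: int = 20,
    singleton_q_factor: float = 0.1,
    singleton_enrichment: float = 2.0,
) -> LoopSet:
    """Call focal point interactions on a balanced matrix.

    Per-pixel Poisson upper-tail p-values are computed on raw counts against
    the maximum of the four filter expecteds (converted to the raw scale via
    the balancing weights), BH-adjusted within distance bands of
    ``band_width`` diagonals. Pixels with q <= fdr and observed/expected >=
    ``enrichment_min`` for every filter are merged into loops when within
    ``merge_radius``; the merged loop reports its strongest pixel. A genuine
    focal peak spans several significant pixels, so single-pixel clusters are
    kept only under stricter evidence (q <= fdr * singleton_q_factor and
    enrichment >= singleton_enrichment on every filter).
    """
    n = m.n_bins
    if n < 2 * w + 3:
        raise ContactDataError("matrix too small for the filter geometry")
    binsize = m.bins.binsize
    weights = m.weights if m.weights is not None else np.where(m.mask, 1.0, np.nan)
    v = m.counts * np.outer(weights, weights)
    v[~m.mask, :] = np.nan
    v[:, ~m.mask] = np.nan
    emat = _decay_expected(v)
    finite = np.isfinite(v)
    v0 = np.where(finite, v, 0.0)
    e0 = np.where(finite, emat, 0.0)

    kernels = _footprints(p, w)
    exp_f = {}
    for name, k in kernels.items():
        kf = k.astype(float)
        so = ndimage.correlate(v0, kf, mode="constant", cval=0.0)
        se = ndimage.correlate(e0, kf, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_f[name] = np.where(se > 0, emat * so / se, np.nan)

    dmax = n - 1 if max_s is None else min(n - 1, int(max_s // binsize))
    iu, ju = np.triu_indices(n, k=w + 1)
    d = ju - iu
    keep = (d <= dmax) & (iu - w >= 0) & (ju + w < n) & finite[iu, ju]
    iu, ju, d = iu[keep], ju[keep], d[keep]

    exp_stack = np.stack([exp_f[name][iu, ju] for name in FILTERS])
    ok = np.all(np.isfinite(exp_stack), axis=0) & np.all(exp_stack > 0, axis=0)
    iu, ju, d, exp_stack = iu[ok], ju[ok], d[ok], exp_stack[:, ok]

    lam_bal = exp_stack.max(axis=0)
    wij = weights[iu] * weights[ju]
    lam_raw = lam_bal / wij
    obs_raw = m.counts[iu, ju]
    pvals = stats.poisson.sf(obs_raw - 1, lam_raw)

    qvals = np.ones_like(pvals)
    bands = (d - (w + 1)) // band_width
    for band in np.unique(bands):
        sel = bands == band
        qvals[sel] = multipletests(pvals[sel], method="fdr_bh")[1]

    enrich = v[iu, ju][None, :] / exp_stack
    sig = (qvals <= fdr) & np.all(enrich >= enrichment_min, axis=0)

    si, sj, sq = iu[sig], ju[sig], qvals[sig]
    sval = v[si, sj]
    smin_enrich = enrich[:, sig].min(axis=0)
    r = max(1, int(merge_radius // binsize))
    loops = _merge_pixels(si, sj, sval, sq, r, smin_enrich)

    rows = []
    for (ci, cj, q, size, min_enr) in loops:
        if size == 1 and not (
            q <= fdr * singleton_q_factor and min_enr >= singleton_enrichment
        ):
            continue
        rows.append(
            {
                "chrom": m.bins.chrom,
                "start1": int(m.bins.starts[ci]),
                "end1": int(m.bins.ends[ci]),
                "start2": int(m.bins.starts[cj]),
                "end2": int(m.bins.ends[cj]),
                "bin1": int(ci),
                "bin2": int(cj),
                "observed": float(m.counts[ci, cj]),
                "q": float(q),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start1", "end1", "start2", "end2", "bin1", "bin2", "observed", "q"],
    )
    params = {
        "p": p, "w": w, "fdr": fdr, "enrichment_min": enrichment_min,
        "merge_radius": merge_radius, "n_pixels_tested": int(len(pvals)),
    }
    return LoopSet(loops=df, resolution=binsize, params=params)


def _merge_pixels(si, sj, sval, sq, radius, senr=None):
    """Union-find merge of significant pixels within Chebyshev ``radius``."""
    k = len(si)
    if senr is None:
        senr = np.full(k, np.inf)
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = np.argsort(si)
    for a_pos in range(k):
        a = order[a_pos]
        for b_pos in range(a_pos + 1, k):
            b = order[b_pos]
            if si[b] - si[a] > radius:
                break
            if abs(int(sj[a]) - int(sj[b])) <= radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for x in range(k):
        groups.setdefault(find(x), []).append(x)
    out = []
    for members in groups.values():
        best = max(members, key=lambda x: (sval[x], -si[x], -sj[x]))
        out.append(
            (int(si[best]), int(sj[best]), float(sq[best]), len(members),
             float(senr[best]))
        )
    out.sort()
    return out


def anchor_distances(loops: LoopSet) -> np.ndarray:
    """Per-loop distance between anchor midpoints, in bp."""
    if len(loops) == 0:
        raise ContactDataError("empty loop set")
    m1, m2 = loops.anchor_midpoints()
    return np.abs(m2 - m1)


def intersect_anchor_sets(
    samples: Mapping[str, LoopSet], window: int = 10_000
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Unify loop anchors across samples and tabulate UpSet-style membership.

    Anchor positions (midpoints of both anchors of every loop) are clustered
    by single-linkage along the chromosome with gap <= ``window``; each
    cluster records which samples contributed. Returns the per-cluster
    membership table and counts per non-empty sample combination.
    """
    if len(samples) < 2:
        raise ContactDataError("need at least two samples")
    entries = []
    for name, ls in samples.items():
        if len(ls) == 0:
            continue
        m1, m2 = ls.anchor_midpoints()
        for pos in np.concatenate([m1, m2]):
            entries.append((int(pos), name))
    if not entries:
        return pd.DataFrame(columns=["position", *samples]), {}
    entries.sort()
    clusters = []
    cur_pos, cur_members = entries[0][0], {entries[0][1]}
    last = entries[0][0]
    positions = [entries[0][0]]
    for pos, name in entries[1:]:
        if pos - last <= window:
            cur_members.add(name)
            positions.append(pos)
        else:
            clusters.append((int(np.mean(positions)), frozenset(cur_members)))
            cur_members = {name}
            positions = [pos]
        last = pos
    clusters.append((int(np.mean(positions)), frozenset(cur_members)))
    rows = []
    combo_counts: dict[frozenset, int] = {}
    for pos, members in clusters:
        rows.append({"position": pos, **{s: (s in members) for s in samples}})
        combo_counts[members] = combo_counts.get(members, 0) + 1
    return pd.DataFrame(rows), combo_counts


def stratify_loops_by_compartment(
    loops: LoopSet, states: CompartmentTrack
) -> tuple[np.ndarray, pd.Series]:
    """Label each loop A-A / A-B / B-B by its anchors' compartment states.

    Each anchor takes the state of the compartment-track bin containing its
    midpoint; anchors in masked bins yield the label "unassigned", which is
    excluded from the returned proportions.
    """
    if len(loops) == 0:
        raise ContactDataError("empty loop set")
    m1, m2 = loops.anchor_midpoints()
    binsize = states.bins.binsize
    labels = []
    for a, b in zip(m1, m2):
        try:
            s1 = states.state[states.bins.bin_of(int(a))]
            s2 = states.state[states.bins.bin_of(int(b))]
        except ContactDataError:
            labels.append("unassigned")
            continue
        if s1 == "masked" or s2 == "masked":
            labels.append("unassigned")
        else:
            labels.append("-".join(sorted([s1, s2])))
    labels = np.array(labels, dtype=object)
    assigned = labels[labels != "unassigned"]
    props = (
        pd.Series(assigned).value_counts(normalize=True)
        if len(assigned)
        else pd.Series(dtype=float)
    )
    return labels, props
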