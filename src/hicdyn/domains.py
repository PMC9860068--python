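"""Insulation scores, TAD boundary calling, and domain-level summaries.

The insulation score slides a square window along the matrix diagonal (mean
contact signal between the upstream and downstream flanks of each bin) and
log2-normalizes it by the chromosome-wide geometric mean of the window means,
so valid scores average zero per chromosome. Local minima of the track are
TAD boundary candidates; boundary strength is the difference between the
flanking insulation maxima and the minimum.

Also provided: windowed intersections between boundary sets (with fractions
relative to each set), lost/gained/shared categorization between an early and
a late sample, aggregate rescaled O/E pileups over TADs, and TAD-size
distributions stratified by compartment state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import CompartmentTrack
from .contacts import BinsTable, ContactDataError, ContactMatrix

__all__ = [
    "InsulationTrack",
    "BoundarySet",
    "insulation_score",
    "call_boundaries",
    "intersect_boundaries",
    "boundary_category",
    "tads_from_boundaries",
    "aggregate_tads",
    "tad_sizes_by_compartment",
]


@dataclass
class InsulationTrack:
    """Per-bin insulation score; ``valid`` flags bins with a complete window."""

    bins: BinsTable
    score: np.ndarray
    valid: np.ndarray
    window: int


@dataclass
class BoundarySet:
    """TAD boundaries as (bin-aligned bp midpoint, strength >= 0)."""

    chrom: str
    positions: np.ndarray
    strengths: np.ndarray
    binsize: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if np.any(self.strengths < 0):
            raise ContactDataError("boundary strengths must be >= 0")

    def __len__(self) -> int:
        return len(self.positions)


def insulation_score(
    m: ContactMatrix, window: int = 200_000, min_coverage: float = 0.5
) -> InsulationTrack:
    """Sliding-square insulation score on a balanced matrix.

    For each bin i with a complete window, the mean contact over the
    (window/binsize)^2 square spanning the upstream x downstream flanks is
    computed (masked pixels are ignored; the window must retain at least
    ``min_coverage`` of its pixels); scores are log2 of that mean over the
    chromosome geometric mean of valid window means, so valid scores are
    mean-zero. Edge bins and zero-mean windows are invalid (NaN).
    """
    binsize = m.bins.binsize
    if window < binsize:
        raise ContactDataError("window must be at least one binsize")
    if window % binsize != 0:
        raise ContactDataError("window must be a multiple of binsize")
    w = window // binsize
    n = m.n_bins
    v = m.balanced()
    means = np.full(n, np.nan)
    for i in range(w, n - w):
        sq = v[i - w : i, i + 1 : i + 1 + w]
        finite = np.isfinite(sq)
        if finite.sum() >= min_coverage * sq.size:
            means[i] = sq[finite].mean()
    valid = np.isfinite(means) & (means > 0) & m.mask
    if valid.sum() == 0:
        raise ContactDataError("no bin has a complete positive insulation window")
    log2m = np.full(n, np.nan)
    log2m[valid] = np.log2(means[valid])
    score = log2m - np.nanmean(log2m[valid])
    return InsulationTrack(bins=m.bins, score=score, valid=valid, window=window)


def call_boundaries(
    track: InsulationTrack,
    delta_window: int = 120_000,
    min_strength: float = 0.1,
) -> BoundarySet:
    """Boundaries at local insulation minima, filtered by strength.

    Strength is the mean of the maximal score within ``delta_window`` to the
    left and to the right, minus the score at the minimum. Candidates without
    valid bins on both flanks are dropped, and of several candidate minima
    within ``delta_window`` of each other only the deepest is kept (the
    sliding window smears each dip over several bins, so secondary wiggles on
    the dip walls are not separate boundaries). Boundary position is the
    midpoint of the minimum bin.
    """
    s = track.score
    valid = track.valid
    binsize = track.bins.binsize
    dw = max(1, int(delta_window // binsize))
    n = len(s)
    cand = []
    for i in range(1, n - 1):
        if not (valid[i] and valid[i - 1] and valid[i + 1]):
            continue
        if not (s[i] < s[i - 1] and s[i] <= s[i + 1]):
            continue
        cand.append(i)
    # non-minimum suppression within the delta window
    kept = []
    for i in cand:
        if kept and i - kept[-1][0] <= dw:
            if s[i] < s[kept[-1][0]]:
                kept[-1] = (i,)
            continue
        kept.append((i,))
    positions, strengths = [], []
    for (i,) in kept:
        left = s[max(0, i - dw) : i]
        right = s[i + 1 : i + 1 + dw]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        if len(left) == 0 or len(right) == 0:
            continue
        strength = 0.5 * (left.max() + right.max()) - s[i]
        if strength >= min_strength:
            positions.append(int(track.bins.midpoints[i]))
            strengths.append(float(strength))
    return BoundarySet(
        chrom=track.bins.chrom,
        positions=np.array(positions, dtype=np.int64),
        strengths=np.array(strengths, dtype=float),
        binsize=binsize,
        params={"delta_window": delta_window, "min_strength": min_strength,
                "window": track.window},
    )


def _match_nearest(a: np.ndarray, b: np.ndarray, window: int):
    """Greedy one-to-one nearest matching of two sorted position sets."""
    pairs = []
    if len(a) and len(b):
        cand = []
        for ia, pa in enumerate(a):
            for ib, pb in enumerate(b):
                dist = abs(int(pa) - int(pb))
                if dist <= window:
                    cand.append((dist, ia, ib))
        cand.sort()
        used_a, used_b = set(), set()
        for dist, ia, ib in cand:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            pairs.append((ia, ib))
    return pairs


def intersect_boundaries(a: BoundarySet, b: BoundarySet, window: int = 40_000) -> dict:
    """Windowed intersection of two boundary sets.

    A boundary is shared iff a boundary of the other set lies within
    ±window; matching is one-to-one (nearest first), so each boundary counts
    once. Fractions are relative to each set's own size, hence asymmetric.
    """
    if window < 0:
        raise ContactDataError("window must be >= 0")
    pairs = _match_nearest(a.positions, b.positions, window)
    ia = {p[0] for p in pairs}
    ib = {p[1] for p in pairs}
    return {
        "shared": [(int(a.positions[x]), int(b.positions[y])) for x, y in pairs],
        "a_only": [int(p) for k, p in enumerate(a.positions) if k not in ia],
        "b_only": [int(p) for k, p in enumerate(b.positions) if k not in ib],
        "shared_a_fraction": len(pairs) / len(a) if len(a) else np.nan,
        "shared_b_fraction": len(pairs) / len(b) if len(b) else np.nan,
    }


def boundary_category(
    early: BoundarySet, late: BoundarySet, window: int = 40_000
) -> pd.DataFrame:
    """Label the union of two boundary sets as lost / gained / shared.

    "lost" boundaries are present only in the early sample, "gained" only in
    the late sample, "shared" within ±window in both.
    """
    res = intersect_boundaries(early, late, window)
    rows = []
    for pa, pb in res["shared"]:
        rows.append({"position": (pa + pb) // 2, "label": "shared"})
    for p in res["a_only"]:
        rows.append({"position": p, "label": "lost"})
    for p in res["b_only"]:
        rows.append({"position": p, "label": "gained"})
    df = pd.DataFrame(rows, columns=["position", "label"])
    return df.sort_values("position").reset_index(drop=True)


def tads_from_boundaries(boundaries: BoundarySet) -> list[tuple[int, int]]:
    """TADs as bp intervals between consecutive boundaries."""
    pos = np.sort(boundaries.positions)
    return [(int(pos[k]), int(pos[k + 1])) for k in range(len(pos) - 1)]


def _overlap_matrix(n_src: int, n_tgt: int) -> np.ndarray:
    """Row-stochastic area-overlap matrix mapping n_src cells onto n_tgt."""
    edges_src = np.linspace(0.0, 1.0, n_src + 1)
    edges_tgt = np.linspace(0.0, 1.0, n_tgt + 1)
    r = np.zeros((n_tgt, n_src))
    for t in range(n_tgt):
        lo, hi = edges_tgt[t], edges_tgt[t + 1]
        for s in range(n_src):
            ov = min(hi, edges_src[s + 1]) - max(lo, edges_src[s])
            if ov > 0:
                r[t, s] = ov
    r /= r.sum(axis=1, keepdims=True)
    return r


def aggregate_tads(
    oe: ContactMatrix,
    tads: Sequence[tuple[int, int]],
    flank_fraction: float = 0.5,
    target_size: int = 33,
) -> dict:
    """Average O/E pileup over TADs rescaled to a common grid.

    Each TAD window (with flanks of ``flank_fraction`` x TAD size on each
    side) is rescaled to target_size x target_size by area-weighted
    interpolation; the pileup is the NaN-aware mean across TADs. TADs shorter
    than 3 bins, or whose flanked window leaves the chromosome, are skipped
    and counted.
    """
    if len(tads) == 0:
        raise ContactDataError("empty TAD list")
    if target_size % 2 == 0:
        raise ContactDataError("target_size must be odd")
    binsize = oe.bins.binsize
    v = oe.balanced() if oe.weights is not None else np.where(
        np.outer(oe.mask, oe.mask), oe.counts, np.nan
    )
    n = oe.n_bins
    acc = np.zeros((target_size, target_size))
    wacc = np.zeros((target_size, target_size))
    used = skipped = 0
    for start, end in tads:
        b0, b1 = start // binsize, max(start // binsize + 1, -(-end // binsize))
        size = b1 - b0
        if size < 3:
            skipped += 1
            continue
        flank = max(1, int(round(size * flank_fraction)))
        lo, hi = b0 - flank, b1 + flank
        if lo < 0 or hi > n:
            skipped += 1
            continue
        sub = v[lo:hi, lo:hi]
        r = _overlap_matrix(hi - lo, target_size)
        finite = np.isfinite(sub)
        x0 = np.where(finite, sub, 0.0)
        num = r @ x0 @ r.T
        den = r @ finite.astype(float) @ r.T
        with np.errstate(invalid="ignore"):
            tile = np.where(den > 0, num / den, np.nan)
        ok = np.isfinite(tile)
        acc[ok] += tile[ok]
        wacc[ok] += 1
        used += 1
    if used == 0:
        raise ContactDataError("no usable TADs for pileup")
    with np.errstate(invalid="ignore"):
        pileup = np.where(wacc > 0, acc / wacc, np.nan)
    return {"pileup": pileup, "n_used": used, "n_skipped": skipped}


def tad_sizes_by_compartment(
    tads: Sequence[tuple[int, int]], states: CompartmentTrack
) -> dict:
    """TAD size distributions per compartment state, with a rank-sum test.

    Each TAD is assigned to the state (A or B) covering the majority of its
    bp; TADs overlapping only masked bins are skipped.
    """
    sizes = {"A": [], "B": []}
    skipped = 0
    starts, ends = states.bins.starts, states.bins.ends
    for t_start, t_end in tads:
        ov = np.minimum(ends, t_end) - np.maximum(starts, t_start)
        ov = np.clip(ov, 0, None).astype(float)
        cover = {"A": ov[states.state == "A"].sum(), "B": ov[states.state == "B"].sum()}
        if cover["A"] == 0 and cover["B"] == 0:
            skipped += 1
            continue
        label = "A" if cover["A"] >= cover["B"] else "B"
        sizes[label].append(t_end - t_start)
    out = {k: np.array(vals, dtype=float) for k, vals in sizes.items()}
    if len(out["A"]) and len(out["B"]):
        stat, p = stats.mannwhitneyu(out["A"], out["B"], alternative="two-sided")
    else:
        stat, p = np.nan, np.nan
    out.update({"statistic": float(stat), "p": float(p), "n_skipped": skipped})
    return out
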