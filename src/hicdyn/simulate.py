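"""Seeded synthetic time course with planted chromatin structure.

Emulates a 4-time-point, 2-replicate differentiation study on one synthetic
chromosome: power-law distance decay, a two-state compartment plaid whose
B-compartment strength increases (and A weakens) with time, nested TAD blocks
with partially turned-over boundaries, focal loop peaks that accumulate and
lengthen over time, Poisson-sampled contact counts per replicate, and matched
negative-binomial expression counts whose differential genes sit in bins with
planted compartment transitions (up in B-to-A, down in A-to-B). All planted
structure is returned as a serializable truth object so every pipeline stage
can be scored against ground truth.

Randomness is fully determined by a master seed; every sample/layer gets its
own derived substream, so adding samples does not shift existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .contacts import BinsTable, ContactDataError, ContactMatrix
from .expression import ExpressionMatrix

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_timecourse", "generate_expression"]


@dataclass
class SimulationConfig:
    """Study design and planted-effect sizes for the synthetic time course.

    Defaults describe one 100-Mb chromosome observed at 4 time points with 2
    replicates each: compartments at 500 kb (200 bins), TADs at 40 kb, loops
    at 10 kb inside a 20-Mb window, a distance-decay exponent of -1, ~25%
    dynamic compartment bins, 20% boundary turnover, and loop counts growing
    across time points.
    """

    n_timepoints: int = 4
    n_replicates: int = 2
    chrom: str = "chrS"
    chrom_length: int = 100_000_000

    binsize_compartment: int = 500_000
    binsize_strat: int = 100_000
    binsize_tad: int = 40_000
    binsize_loop: int = 10_000
    # deep-sequenced focal window for loop calling; None places a window of
    # loop_window_size over the region with the most balanced A/B composition
    loop_window: Optional[tuple] = None
    loop_window_size: int = 20_000_000

    # expected total counts per matrix (upper triangle incl. diagonal)
    depth_compartment: float = 5e6
    depth_strat: float = 8e6
    depth_tad: float = 2e7
    depth_loop: float = 1.2e7

    decay_exponent: float = -1.0
    # contact decay shallows over the time course (long-range contacts gain
    # share as cells differentiate); None uses decay_exponent at every tp
    decay_exponent_per_tp: Optional[tuple] = (-1.05, -1.02, -0.98, -0.95)
    # per-bin visibility bias (lognormal sigma); what ICE is meant to remove
    bias_sigma: float = 0.25
    plaid_strength_a: tuple = (1.6, 1.55, 1.5, 1.45)
    plaid_strength_b: tuple = (1.5, 1.6, 1.7, 1.8)
    dynamic_fraction: float = 0.25
    segment_mean_bp: int = 3_000_000
    double_switch_fraction: float = 0.2

    tad_mean_bp: int = 1_000_000
    tad_boost: float = 2.0
    boundary_turnover: float = 0.2

    loop_counts: tuple = (25, 35, 45, 55)
    loop_enrichment: float = 8.0
    loop_sigma_bins: float = 0.75
    loop_deg_anchor_frac: float = 0.5
    loop_min_dist_bins: int = 30
    loop_max_dist_bins_t0: int = 60
    loop_dist_growth_bins: int = 40

    genes_per_bin_a: float = 4.0
    genes_per_bin_b: float = 1.5
    expr_log_mean: float = 4.5
    expr_log_sigma: float = 1.0
    deg_effect_log2: float = 3.0
    n_background_degs: int = 40
    dispersion: float = 0.05

    master_seed: int = 0

    def __post_init__(self):
        for frac in (self.dynamic_fraction, self.boundary_turnover,
                     self.loop_deg_anchor_frac, self.double_switch_fraction):
            if not 0 <= frac <= 1:
                raise ContactDataError("fractions must lie in [0, 1]")
        for depth in (self.depth_compartment, self.depth_strat, self.depth_tad, self.depth_loop):
            if depth <= 0:
                raise ContactDataError("depth must be positive")
        if len(self.plaid_strength_a) < self.n_timepoints or len(self.plaid_strength_b) < self.n_timepoints:
            raise ContactDataError("plaid strengths needed for every time point")
        if len(self.loop_counts) < self.n_timepoints:
            raise ContactDataError("loop counts needed for every time point")
        if (
            self.decay_exponent_per_tp is not None
            and len(self.decay_exponent_per_tp) < self.n_timepoints
        ):
            raise ContactDataError("decay exponent needed for every time point")
        if self.tad_mean_bp < 3 * self.binsize_tad:
            raise ContactDataError("boundary spacing below 3 bins is infeasible")

    @property
    def binsizes(self) -> dict:
        return {
            "compartment": self.binsize_compartment,
            "strat": self.binsize_strat,
            "tad": self.binsize_tad,
            "loop": self.binsize_loop,
        }


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.master_seed), *map(int, key)]))


# stream codes for derived substreams
_STRUCTURE, _GENES, _MATRIX, _EXPRESSION, _LOOPS, _BIAS = 1, 2, 3, 4, 5, 6


@dataclass
class SyntheticTruth:
    """Planted structure: sufficient to re-generate and to score recovery."""

    config: SimulationConfig
    # compartment segments: (start_bp, end_bp, states per tp as +1/-1 tuple)
    segments: list
    # boundary bp positions (bin midpoints at the TAD layer) per time point
    boundaries: list
    # union of boundary positions with per-tp presence flags
    boundary_presence: pd.DataFrame
    # planted loops per tp: list of (bin_i, bin_j) at the loop layer
    loops: list
    genes: pd.DataFrame  # id-indexed: chrom/start/end/strand/length/base_mean/
    #                      deg_direction/switch_time/transition_class
    dynamic_fraction_planted: float

    def states_at(self, binsize: int, tp: int) -> np.ndarray:
        """Planted compartment state (+1 A / -1 B) per bin at a resolution."""
        n = -(-self.config.chrom_length // binsize)
        out = np.zeros(n, dtype=np.int8)
        mids = (np.arange(n) * binsize) + binsize // 2
        mids = np.minimum(mids, self.config.chrom_length - 1)
        for start, end, states in self.segments:
            sel = (mids >= start) & (mids < end)
            out[sel] = states[tp]
        return out

    def segment_label(self, states: tuple) -> str:
        names = ["A" if s > 0 else "B" for s in states]
        collapsed = [names[0]]
        for s in names[1:]:
            if s != collapsed[-1]:
                collapsed.append(s)
        return f"stable {collapsed[0]}" if len(collapsed) == 1 else "-to-".join(collapsed)

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "segments": [(int(s), int(e), list(map(int, st))) for s, e, st in self.segments],
            "boundaries": [[int(p) for p in b] for b in self.boundaries],
            "boundary_presence": self.boundary_presence.to_dict(orient="list"),
            "loops": [[(int(i), int(j)) for i, j in lp] for lp in self.loops],
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "dynamic_fraction_planted": float(self.dynamic_fraction_planted),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_d = payload["config"]
        for key in ("plaid_strength_a", "plaid_strength_b", "loop_counts",
                    "loop_window", "decay_exponent_per_tp"):
            if cfg_d.get(key) is not None:
                cfg_d[key] = tuple(cfg_d[key])
        cfg = SimulationConfig(**cfg_d)
        genes = pd.DataFrame(payload["genes"]).set_index("gene")
        return cls(
            config=cfg,
            segments=[(s, e, tuple(st)) for s, e, st in payload["segments"]],
            boundaries=[list(b) for b in payload["boundaries"]],
            boundary_presence=pd.DataFrame(payload["boundary_presence"]),
            loops=[[tuple(x) for x in lp] for lp in payload["loops"]],
            genes=genes,
            dynamic_fraction_planted=payload["dynamic_fraction_planted"],
        )


# ---------------------------------------------------------------------------
# Planted structure
# ---------------------------------------------------------------------------

def _plant_segments(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[list, float]:
    bs = cfg.binsize_compartment
    length = cfg.chrom_length
    segs = []
    pos = 0
    state = int(rng.integers(0, 2)) * 2 - 1
    while pos < length:
        span = int(rng.exponential(cfg.segment_mean_bp))
        span = max(2 * bs, (span // bs) * bs)
        end = min(pos + span, length)
        segs.append([pos, end, state])
        state = -state
        pos = end
    # mark segments dynamic until the planted bp fraction is reached,
    # alternating between A-based and B-based segments so the switch
    # directions stay bp-balanced and the A/B composition is stable in time
    # (otherwise composition drift confounds compartment-strength contrasts)
    # dynamic segments come in A/B pairs matched by size rank and sharing
    # their switch times, so both switch directions carry similar bp and the
    # A/B composition stays stable at every time point (composition drift
    # would confound compartment-strength contrasts)
    bp = lambda k: segs[k][1] - segs[k][0]
    pool_a = sorted((k for k, s in enumerate(segs) if s[2] > 0), key=bp)
    pool_b = sorted((k for k, s in enumerate(segs) if s[2] < 0), key=bp)
    ranks = list(range(min(len(pool_a), len(pool_b))))
    rng.shuffle(ranks)
    target = cfg.dynamic_fraction * length
    dynamic_bp = 0.0
    t = cfg.n_timepoints
    patterns: dict[int, tuple] = {}
    for rank in ranks:
        ka, kb = pool_a[rank], pool_b[rank]
        pair_bp = bp(ka) + bp(kb)
        if abs(dynamic_bp + pair_bp - target) > abs(dynamic_bp - target):
            continue
        if rng.random() < cfg.double_switch_fraction and t >= 3:
            t1 = int(rng.integers(1, t - 1))
            t2 = int(rng.integers(t1 + 1, t + 1))
            flips = tuple(t1 <= tt < t2 for tt in range(t))
        else:
            tswitch = int(rng.integers(1, t))
            flips = tuple(tt >= tswitch for tt in range(t))
        patterns[int(ka)] = flips
        patterns[int(kb)] = flips
        dynamic_bp += pair_bp
    out = []
    for k, (s, e, base) in enumerate(segs):
        flips = patterns.get(k)
        if flips is not None:
            states = tuple(-base if f else base for f in flips)
        else:
            states = tuple(base for _ in range(t))
        out.append((s, e, states))
    # realized dynamic fraction at the compartment layer, bin-weighted
    n = -(-length // bs)
    mids = np.minimum(np.arange(n) * bs + bs // 2, length - 1)
    dyn = np.zeros(n, dtype=bool)
    for s, e, states in out:
        if len(set(states)) > 1:
            dyn |= (mids >= s) & (mids < e)
    return out, float(dyn.mean())


def _plant_boundaries(cfg: SimulationConfig, segments: list, rng: np.random.Generator):
    bs = cfg.binsize_tad
    n = cfg.chrom_length // bs
    t = cfg.n_timepoints
    margin = 10  # keep boundaries away from chromosome edges

    # compartment segment edges insulate whenever the flanking states differ;
    # they are genuine boundaries of the generated contact structure
    edge_bins, edge_presence = [], []
    for k in range(1, len(segments)):
        left_states, right_states = segments[k - 1][2], segments[k][2]
        b = segments[k][0] // bs
        if margin <= b < n - margin:
            edge_bins.append(int(b))
            edge_presence.append(
                [left_states[tt] != right_states[tt] for tt in range(t)]
            )

    base_bins = []
    pos = margin
    while True:
        step = rng.normal(cfg.tad_mean_bp / bs, 0.15 * cfg.tad_mean_bp / bs)
        pos += int(max(5, round(step)))
        if pos >= n - margin:
            break
        if any(abs(pos - e) < 5 for e in edge_bins):
            continue  # keep planted boundaries clear of segment edges
        base_bins.append(pos)
    presence = np.ones((len(base_bins), t), dtype=bool)
    for k in range(len(base_bins)):
        if rng.random() < cfg.boundary_turnover:
            tswitch = int(rng.integers(1, t))
            if rng.random() < 0.5:  # lost in differentiation
                presence[k, tswitch:] = False
            else:  # gained
                presence[k, :tswitch] = False
    base_bins = base_bins + edge_bins
    presence = np.vstack([presence, np.array(edge_presence, dtype=bool).reshape(len(edge_bins), t)])
    order = np.argsort(base_bins)
    base_bins = [base_bins[k] for k in order]
    presence = presence[order]
    positions_bp = [int(b * bs + bs // 2) for b in base_bins]
    per_tp = [
        [positions_bp[k] for k in range(len(base_bins)) if presence[k, tt]]
        for tt in range(t)
    ]
    df = pd.DataFrame(
        {"position": positions_bp, **{f"t{tt}": presence[:, tt] for tt in range(t)}}
    )
    return per_tp, df


def _plant_genes(cfg: SimulationConfig, segments: list, rng: np.random.Generator) -> pd.DataFrame:
    bs = cfg.binsize_compartment
    n = cfg.chrom_length // bs
    mids = np.arange(n) * bs + bs // 2
    mean_state = np.zeros(n)
    label = np.array(["stable A"] * n, dtype=object)
    for s, e, states in segments:
        sel = (mids >= s) & (mids < e)
        mean_state[sel] = np.mean(states)
        names = ["A" if x > 0 else "B" for x in states]
        collapsed = [names[0]]
        for x in names[1:]:
            if x != collapsed[-1]:
                collapsed.append(x)
        lab = f"stable {collapsed[0]}" if len(collapsed) == 1 else "-to-".join(collapsed)
        label[sel] = lab
    rows = []
    gid = 0
    for b in range(n):
        lam = cfg.genes_per_bin_a if mean_state[b] > 0 else cfg.genes_per_bin_b
        for _ in range(rng.poisson(lam)):
            start = int(b * bs + rng.integers(0, bs - 10_000))
            glen = int(np.clip(rng.lognormal(7.6, 0.6), 300, 20_000))  # exonic bp
            rows.append(
                {
                    "gene": f"g{gid:05d}",
                    "chrom": cfg.chrom,
                    "start": start,
                    "end": start + glen * 3,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "length": glen,
                    "bin": b,
                    "transition_class": label[b],
                }
            )
            gid += 1
    genes = pd.DataFrame(rows).set_index("gene")
    # expression baselines and planted differential genes
    genes["base_mean"] = np.exp(
        rng.normal(cfg.expr_log_mean, cfg.expr_log_sigma, size=len(genes))
    )
    direction = np.array(["none"] * len(genes), dtype=object)
    switch_time = np.zeros(len(genes), dtype=int)
    t = cfg.n_timepoints
    for k, (_, row) in enumerate(genes.iterrows()):
        lab = row["transition_class"]
        seg_states = None
        for s, e, states in segments:
            if s <= row["start"] < e:
                seg_states = states
                break
        if lab == "B-to-A":
            direction[k] = "up"
            switch_time[k] = next(tt for tt in range(1, t) if seg_states[tt] > 0)
        elif lab == "A-to-B":
            direction[k] = "down"
            switch_time[k] = next(tt for tt in range(1, t) if seg_states[tt] < 0)
    # compartment-independent DEGs in stable bins (realistic background DE)
    stable_pool = np.flatnonzero(
        (direction == "none")
        & genes["transition_class"].str.startswith("stable").to_numpy()
    )
    n_bg = min(cfg.n_background_degs, len(stable_pool))
    for k in rng.choice(stable_pool, size=n_bg, replace=False):
        direction[k] = "up" if rng.random() < 0.5 else "down"
        switch_time[k] = int(rng.integers(1, t))
    genes["deg_direction"] = direction
    genes["switch_time"] = switch_time
    return genes


def _plant_loops(cfg: SimulationConfig, truth: "SyntheticTruth", rng: np.random.Generator) -> list:
    bs = cfg.binsize_loop
    w0, w1 = cfg.loop_window
    lo_bin, hi_bin = w0 // bs, w1 // bs
    n_window = hi_bin - lo_bin
    genes = truth.genes
    last = cfg.n_timepoints - 1
    states_last = truth.states_at(bs, last)[lo_bin:hi_bin]
    # candidate anchors at upregulated genes inside the window
    up = genes[(genes["deg_direction"] == "up")]
    up_tss = np.where(up["strand"] == "-", up["end"] - 1, up["start"])
    up_bins = np.unique((up_tss[(up_tss >= w0) & (up_tss < w1)] // bs).astype(int))
    margin = 8  # > w + merge radius, keeps filters inside the matrix
    taken: list[tuple[int, int]] = []

    def far_enough(i, j):
        return all(max(abs(i - a), abs(j - b)) > 14 for a, b in taken)

    per_tp = []
    current: list[tuple[int, int]] = []
    for tt in range(cfg.n_timepoints):
        target = cfg.loop_counts[tt]
        dmax = cfg.loop_max_dist_bins_t0 + cfg.loop_dist_growth_bins * tt
        n_new = max(0, target - len(current))
        n_reg = int(round(cfg.loop_deg_anchor_frac * n_new)) if len(up_bins) else 0
        placed_reg = attempts = 0
        # regulatory loops first: anchored at an up-gene, partner anchor in
        # chromatin of the same (late-time-point A) state
        while placed_reg < n_reg and attempts < 20_000:
            attempts += 1
            dist = int(rng.integers(cfg.loop_min_dist_bins, dmax + 1))
            i = int(rng.choice(up_bins)) - lo_bin
            j = i + dist if rng.random() < 0.5 else i - dist
            if i > j:
                i, j = j, i
            if not (margin <= i and j < n_window - margin):
                continue
            if states_last[i] <= 0 or states_last[j] <= 0:
                continue
            if not far_enough(i, j):
                continue
            taken.append((i, j))
            current.append((i, j))
            placed_reg += 1
        attempts = 0
        while len(current) < target and attempts < 20_000:
            attempts += 1
            dist = int(rng.integers(cfg.loop_min_dist_bins, dmax + 1))
            i = int(rng.integers(margin, n_window - margin))
            j = i + dist
            if j >= n_window - margin:
                continue
            if not far_enough(i, j):
                continue
            taken.append((i, j))
            current.append((i, j))
        per_tp.append(sorted(current))
    return per_tp


# ---------------------------------------------------------------------------
# Expected matrices and count sampling
# ---------------------------------------------------------------------------

def _expected_matrix(cfg: SimulationConfig, truth: SyntheticTruth, layer: str, tp: int) -> tuple[np.ndarray, BinsTable]:
    bs = cfg.binsizes[layer]
    if layer == "loop":
        w0, w1 = cfg.loop_window
        n = (w1 - w0) // bs
        offset_bp = w0
        bins = BinsTable(
            cfg.chrom,
            np.arange(n) * bs + w0,
            np.arange(1, n + 1) * bs + w0,
            bs,
        )
    else:
        n = -(-cfg.chrom_length // bs)
        offset_bp = 0
        bins = BinsTable.from_chrom_length(cfg.chrom, cfg.chrom_length, bs)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    if cfg.decay_exponent_per_tp is not None:
        exponent = cfg.decay_exponent_per_tp[tp]
    else:
        exponent = cfg.decay_exponent
    expected = (d + 1.0) ** exponent

    # compartment plaid
    if layer == "loop":
        full_states = truth.states_at(bs, tp)
        states = full_states[w0 // bs : w0 // bs + n]
    else:
        states = truth.states_at(bs, tp)
    sa = cfg.plaid_strength_a[tp]
    sb = cfg.plaid_strength_b[tp]
    a_bin = states > 0
    pair_aa = np.outer(a_bin, a_bin)
    pair_bb = np.outer(~a_bin, ~a_bin)
    plaid = np.where(pair_aa, sa, np.where(pair_bb, sb, 1.0 / np.sqrt(sa * sb)))
    expected *= plaid

    # TAD blocks at the fine layers
    if layer in ("tad", "loop"):
        bounds_bp = np.asarray(truth.boundaries[tp])
        bounds = ((bounds_bp - offset_bp) // bs).astype(int)
        bounds = bounds[(bounds > 0) & (bounds < n)]
        domain = np.zeros(n, dtype=int)
        domain[np.sort(bounds)] = 1
        domain = np.cumsum(domain)
        same = np.equal.outer(domain, domain)
        expected *= np.where(same, cfg.tad_boost, 1.0)

    # focal loop peaks
    if layer == "loop":
        sig2 = 2 * cfg.loop_sigma_bins**2
        peak = cfg.loop_enrichment - 1.0
        for (i, j) in truth.loops[tp]:
            for di in range(-3, 4):
                for dj in range(-3, 4):
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < n:
                        g = peak * np.exp(-(di * di + dj * dj) / sig2)
                        expected[a, b] *= 1.0 + g
                        expected[b, a] = expected[a, b]

    # multiplicative per-bin visibility biases (mappability/GC analogue),
    # identical across time points and replicates; mean-one lognormal
    if cfg.bias_sigma > 0:
        rng_bias = _rng(cfg, _BIAS, _LAYER_CODE[layer])
        bias = np.exp(
            rng_bias.normal(-cfg.bias_sigma**2 / 2, cfg.bias_sigma, size=n)
        )
        expected *= np.outer(bias, bias)

    depth = {
        "compartment": cfg.depth_compartment,
        "strat": cfg.depth_strat,
        "tad": cfg.depth_tad,
        "loop": cfg.depth_loop,
    }[layer]
    iu = np.triu_indices(n)
    expected *= depth / expected[iu].sum()
    return expected, bins


_LAYER_CODE = {"compartment": 0, "strat": 1, "tad": 2, "loop": 3}


def _sample_counts(cfg: SimulationConfig, expected: np.ndarray, layer: str, tp: int, rep: int) -> np.ndarray:
    rng = _rng(cfg, _MATRIX, _LAYER_CODE[layer], tp, rep)
    n = expected.shape[0]
    iu = np.triu_indices(n)
    draws = rng.poisson(expected[iu])
    m = np.zeros((n, n))
    m[iu] = draws
    m = m + np.triu(m, 1).T
    return m


def _resolve_loop_window(cfg: SimulationConfig, segments: list) -> tuple:
    """Pick the focal window with the most balanced A/B composition over time."""
    if cfg.loop_window is not None:
        return tuple(cfg.loop_window)
    size = cfg.loop_window_size
    bs = cfg.binsize_compartment
    step = max(bs, size // 10)
    n = cfg.chrom_length // bs
    mids = np.minimum(np.arange(n) * bs + bs // 2, cfg.chrom_length - 1)
    states = np.zeros((cfg.n_timepoints, n), dtype=np.int8)
    for s, e, st in segments:
        sel = (mids >= s) & (mids < e)
        for tp in range(cfg.n_timepoints):
            states[tp, sel] = st[tp]
    # B-to-A bins host the planted upregulated genes; the focal window must
    # hold both compartment types and some repressive-to-active transitions
    b2a = (states[0] < 0) & (states[-1] > 0)
    best, best_score = 0, -1.0
    for start in range(0, cfg.chrom_length - size + 1, step):
        lo, hi = start // bs, (start + size) // bs
        window = states[:, lo:hi]
        a_frac = (window > 0).mean(axis=1)
        balance = float(np.min(np.minimum(a_frac, 1 - a_frac)))
        score = min(balance, 2.0 * float(b2a[lo:hi].mean()))
        if score > best_score:
            best, best_score = start, score
    return (best, best + size)


def generate_timecourse(config: Optional[SimulationConfig] = None):
    """Generate the synthetic study: contact matrices plus planted truth.

    Returns ``(matrices, truth)`` where matrices maps
    ``(timepoint, replicate, layer)`` — layer in {"compartment", "strat",
    "tad", "loop"} — to a raw-count ContactMatrix. The same config and master
    seed always regenerate bit-identical output. The truth carries the
    resolved configuration (e.g. the placed loop window).
    """
    cfg = config or SimulationConfig()
    rng_struct = _rng(cfg, _STRUCTURE)
    segments, dyn_frac = _plant_segments(cfg, rng_struct)
    cfg = dataclasses.replace(cfg, loop_window=_resolve_loop_window(cfg, segments))
    boundaries, presence = _plant_boundaries(cfg, segments, rng_struct)
    genes = _plant_genes(cfg, segments, _rng(cfg, _GENES))
    truth = SyntheticTruth(
        config=cfg,
        segments=segments,
        boundaries=boundaries,
        boundary_presence=presence,
        loops=[],
        genes=genes,
        dynamic_fraction_planted=dyn_frac,
    )
    truth.loops = _plant_loops(cfg, truth, _rng(cfg, _LOOPS))

    matrices = {}
    for layer in ("compartment", "strat", "tad", "loop"):
        for tp in range(cfg.n_timepoints):
            expected, bins = _expected_matrix(cfg, truth, layer, tp)
            for rep in range(cfg.n_replicates):
                counts = _sample_counts(cfg, expected, layer, tp, rep)
                matrices[(tp, rep, layer)] = ContactMatrix(bins, counts)
    return matrices, truth


def generate_expression(truth: SyntheticTruth, config: Optional[SimulationConfig] = None):
    """Negative-binomial expression counts matched to the planted truth.

    Genes in B-to-A bins are up-shifted by 2**deg_effect_log2 from their
    segment's switch time onward; A-to-B genes are down-shifted symmetrically;
    background DEGs shift at their own planted time. Returns the
    ExpressionMatrix and the DEG truth table (gene, direction).
    """
    cfg = config or truth.config
    genes = truth.genes
    t, r = cfg.n_timepoints, cfg.n_replicates
    sample_ids, time_lab, rep_lab = [], [], []
    cols = {}
    shift = np.where(
        genes["deg_direction"] == "up",
        cfg.deg_effect_log2,
        np.where(genes["deg_direction"] == "down", -cfg.deg_effect_log2, 0.0),
    )
    disp = cfg.dispersion
    size = 1.0 / disp
    for tp in range(t):
        active = (genes["switch_time"].to_numpy() <= tp) & (
            genes["deg_direction"].to_numpy() != "none"
        )
        mu = genes["base_mean"].to_numpy() * np.where(active, 2.0 ** shift, 1.0)
        for rep in range(r):
            rng = _rng(cfg, _EXPRESSION, tp, rep)
            prob = size / (size + mu)
            counts = rng.negative_binomial(size, prob)
            sid = f"T{tp}R{rep}"
            cols[sid] = counts
            sample_ids.append(sid)
            time_lab.append(tp)
            rep_lab.append(rep)
    counts_df = pd.DataFrame(cols, index=genes.index)
    samples = pd.DataFrame({"time": time_lab, "replicate": rep_lab}, index=sample_ids)
    expr = ExpressionMatrix(
        genes=genes[["chrom", "start", "end", "strand", "length"]].copy(),
        counts=counts_df,
        samples=samples,
    )
    deg_truth = genes[["deg_direction", "transition_class", "switch_time"]].copy()
    return expr, deg_truth
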