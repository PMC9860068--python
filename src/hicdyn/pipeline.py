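"""Figure-level orchestration of the analysis stages on a run directory.

``stage_simulate`` writes a complete synthetic study (COO contact text, bins
tables, expression counts, gene annotation, planted truth, and a YAML
manifest) into a run directory; the downstream stages read the manifest,
chain the library operations into the standard time-course analyses, and
write TSV/bedGraph/BED/BEDPE outputs into per-stage subdirectories. Outputs
are deterministic given the configuration and master seed; a failed stage
removes its partial output directory.

``stage_compare`` runs the cross-course comparisons (SCC, PC1 scatter,
insulation correlation) between two completed run directories, emulating the
comparison of two differentiation time courses.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import shutil
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import compartments as cmp
from . import contacts as ct
from . import decay as dc
from . import domains as dm
from . import expression as ex
from . import loops as lp
from .simulate import SimulationConfig, generate_expression, generate_timecourse

log = logging.getLogger("hicdyn")

STAGES = (
    "simulate",
    "decay",
    "scc",
    "compartments",
    "domains",
    "loops",
    "expression",
    "enrich",
)

DEFAULT_PARAMS = {
    "max_s": 100_000_000,
    "long_range_threshold": 30_000_000,
    "t_test_distances": [30_000_000, 75_000_000],
    "scc_h": 1,
    "insulation_window": 200_000,
    "delta_window": 120_000,
    "min_strength": 0.1,
    "boundary_window": 40_000,
    "loop_p": 2,
    "loop_w": 5,
    "loop_fdr": 0.1,
    "loop_enrichment_min": 1.75,
    "merge_radius": 20_000,
    "deg_alpha": 0.05,
    "deg_lfc_min": 1.0,
    "proximal_window": 80_000,
    "horn_n_perm": 100,
}


def load_config(run_dir, overrides: Optional[dict] = None) -> dict:
    """Analysis parameters: defaults <- run config file <- explicit overrides."""
    params = dict(DEFAULT_PARAMS)
    cfg_path = Path(run_dir) / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            params.update((yaml.safe_load(fh) or {}).get("params", {}))
    if overrides:
        params.update(overrides)
    return params


def _write_bedgraph(path, bins: ct.BinsTable, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(bins.starts, bins.ends, values):
            if np.isfinite(v):
                fh.write(f"{bins.chrom}\t{s}\t{e}\t{v:.6g}\n")


def _write_bed(path, chrom, starts, ends, names, scores=None) -> None:
    with open(path, "w") as fh:
        for k, (s, e, nm) in enumerate(zip(starts, ends, names)):
            score = 0 if scores is None else scores[k]
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{nm}\t{score}\n")


def _sample_name(tp: int, rep: int) -> str:
    return f"T{tp}R{rep}"


def _manifest(run_dir) -> dict:
    path = Path(run_dir) / "manifest.yaml"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the 'simulate' stage first (or provide a manifest)"
        )
    with open(path) as fh:
        return yaml.safe_load(fh)


def _load_matrix(run_dir, entry) -> ct.ContactMatrix:
    run_dir = Path(run_dir)
    return ct.read_contacts(run_dir / entry["coo"], run_dir / entry["bins"])


def _matrices_for_layer(run_dir, manifest, layer: str) -> dict:
    out = {}
    for s in manifest["samples"]:
        out[(s["time"], s["replicate"])] = _load_matrix(run_dir, s["matrices"][layer])
    return out


def _pooled_by_timepoint(run_dir, manifest, layer: str) -> dict:
    """Raw replicate-pooled matrix per time point."""
    mats = _matrices_for_layer(run_dir, manifest, layer)
    pooled = {}
    for (tp, rep), m in sorted(mats.items()):
        pooled[tp] = m if tp not in pooled else ct.pool_replicates(pooled[tp], m)
    return pooled


def _stage_dir(run_dir, stage: str) -> Path:
    d = Path(run_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_stage(stage: str, run_dir, seed: Optional[int] = None, params: Optional[dict] = None,
              sim_config: Optional[SimulationConfig] = None) -> list:
    """Run one pipeline stage; returns the list of files written.

    Partial outputs of a failing stage are removed before the error is
    re-raised.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    func = globals()[f"stage_{stage}"]
    out_dir = _stage_dir(run_dir, stage) if stage != "simulate" else None
    try:
        if stage == "simulate":
            return func(run_dir, seed=seed, config=sim_config, params=params)
        return func(run_dir, params=params)
    except Exception:
        if out_dir is not None and out_dir.exists():
            shutil.rmtree(out_dir)
        raise


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(run_dir, seed: Optional[int] = None,
                   config: Optional[SimulationConfig] = None,
                   params: Optional[dict] = None) -> list:
    """Generate the synthetic study and write every input the pipeline reads."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, master_seed=int(seed))
    log.info("simulating time course (seed=%s)", cfg.master_seed)
    matrices, truth = generate_timecourse(cfg)
    expr, deg_truth = generate_expression(truth, cfg)
    data = run_dir / "data"
    data.mkdir(exist_ok=True)
    written = []
    bins_written = {}
    samples_meta = []
    for tp in range(cfg.n_timepoints):
        for rep in range(cfg.n_replicates):
            entry = {"id": _sample_name(tp, rep), "time": tp, "replicate": rep, "matrices": {}}
            for layer in ("compartment", "strat", "tad", "loop"):
                m = matrices[(tp, rep, layer)]
                bins_rel = f"data/bins.{layer}.tsv"
                if layer not in bins_written:
                    ct.write_bins(m.bins, run_dir / bins_rel)
                    bins_written[layer] = bins_rel
                    written.append(bins_rel)
                coo_rel = f"data/{entry['id']}.{layer}.coo.tsv"
                ct.write_contacts(m, run_dir / coo_rel)
                written.append(coo_rel)
                entry["matrices"][layer] = {"coo": coo_rel, "bins": bins_rel}
            samples_meta.append(entry)
    expr.counts.to_csv(data / "counts.tsv", sep="\t")
    expr.genes.to_csv(data / "genes.tsv", sep="\t", index_label="gene")
    expr.samples.to_csv(data / "samples.tsv", sep="\t", index_label="sample")
    truth.to_json(data / "truth.json")
    deg_truth.to_csv(data / "deg_truth.tsv", sep="\t", index_label="gene")
    manifest = {
        "chrom": cfg.chrom,
        "n_timepoints": cfg.n_timepoints,
        "n_replicates": cfg.n_replicates,
        "samples": samples_meta,
        "expression": {
            "counts": "data/counts.tsv",
            "genes": "data/genes.tsv",
            "samples": "data/samples.tsv",
        },
        "truth": "data/truth.json",
        "seed": cfg.master_seed,
    }
    with open(run_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(run_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"sim": dataclasses.asdict(cfg), "params": params or {}}, fh, sort_keys=False
        )
    written += ["data/counts.tsv", "data/genes.tsv", "data/samples.tsv",
                "data/truth.json", "data/deg_truth.tsv", "manifest.yaml", "config.yaml"]
    return written


def stage_decay(run_dir, params: Optional[dict] = None) -> list:
    """P(s) per sample, long-range fractions, and pairwise t tests."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    out = _stage_dir(run_dir, "decay")
    mats = _matrices_for_layer(run_dir, manifest, "compartment")
    curves = {}
    rows = []
    for (tp, rep), m in sorted(mats.items()):
        curve = dc.contact_probability(m, max_s=pr["max_s"])
        curves[(tp, rep)] = curve
        name = _sample_name(tp, rep)
        pd.DataFrame({"s": curve.s, "P": curve.P, "counts": curve.counts}).to_csv(
            out / f"ps.{name}.tsv", sep="\t", index=False
        )
        rows.append(
            {
                "sample": name,
                "time": tp,
                "replicate": rep,
                "long_range_fraction": dc.long_range_fraction(curve, pr["long_range_threshold"]),
                "decay_exponent": dc.fit_decay_exponent(curve),
            }
        )
    pd.DataFrame(rows).to_csv(out / "long_range.tsv", sep="\t", index=False)
    by_cond = {}
    for (tp, rep), c in curves.items():
        by_cond.setdefault(f"t{tp}", []).append(c)
    tests = dc.compare_at_distances(by_cond, pr["t_test_distances"])
    tests.to_csv(out / "ps_tests.tsv", sep="\t", index=False)
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def stage_scc(run_dir, params: Optional[dict] = None) -> list:
    """SCC matrix across samples, 1-SCC MDS embedding, and clustering."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    out = _stage_dir(run_dir, "scc")
    mats = _matrices_for_layer(run_dir, manifest, "compartment")
    keys = sorted(mats)
    names = [_sample_name(*k) for k in keys]
    samples = [mats[k] for k in keys]
    d = dc.dissimilarity_matrix(samples, h=pr["scc_h"], max_s=pr["max_s"])
    sccm = 1.0 - d
    pd.DataFrame(sccm, index=names, columns=names).to_csv(out / "scc.tsv", sep="\t")
    coords = dc.classical_mds(d, k=2)
    pd.DataFrame(coords, index=names, columns=["mds1", "mds2"]).to_csv(
        out / "mds.tsv", sep="\t", index_label="sample"
    )
    z = dc.hierarchical_cluster(d)
    pd.DataFrame(z, columns=["a", "b", "height", "size"]).to_csv(
        out / "linkage.tsv", sep="\t", index=False
    )
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def _gene_density(run_dir, manifest, bins: ct.BinsTable) -> np.ndarray:
    genes = pd.read_csv(Path(run_dir) / manifest["expression"]["genes"], sep="\t", index_col=0)
    gb = ex.genes_to_bins(genes, bins)
    density = np.zeros(bins.n_bins)
    vc = gb.value_counts()
    density[vc.index.to_numpy()] = vc.to_numpy()
    return density


def _compartment_tracks(run_dir, manifest, layer: str, params: dict) -> dict:
    """ICE -> O/E -> correlation -> oriented PC1, per time point."""
    pooled = _pooled_by_timepoint(run_dir, manifest, layer)
    tracks, oes = {}, {}
    density = None
    for tp, m in pooled.items():
        bal = ct.ice_balance(m)
        oe = ct.observed_over_expected(bal)
        corr = ct.correlation_transform(oe)
        if density is None:
            density = _gene_density(run_dir, manifest, m.bins)
        tracks[tp] = cmp.compartment_pc1(corr, density)
        oes[tp] = oe
    return tracks, oes


def stage_compartments(run_dir, params: Optional[dict] = None) -> list:
    """PC1 tracks, switch taxonomy, scatter stats, saddles, delta track."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    out = _stage_dir(run_dir, "compartments")
    tracks, oes = _compartment_tracks(run_dir, manifest, "compartment", pr)
    tps = sorted(tracks)
    for tp in tps:
        tr = tracks[tp]
        _write_bedgraph(out / f"pc1.t{tp}.bedgraph", tr.bins, tr.pc1)
        keep = tr.mask
        _write_bed(
            out / f"state.t{tp}.bed",
            tr.bins.chrom,
            tr.bins.starts[keep],
            tr.bins.ends[keep],
            tr.state[keep],
        )
    labels = cmp.classify_switches([tracks[tp] for tp in tps])
    props = cmp.switch_proportions(labels)
    props.rename_axis("label").to_frame("proportion").to_csv(
        out / "switch_proportions.tsv", sep="\t"
    )
    bins0 = tracks[tps[0]].bins
    keep = labels != cmp.MASKED
    _write_bed(out / "switches.bed", bins0.chrom, bins0.starts[keep], bins0.ends[keep], labels[keep])
    first, last = tracks[tps[0]], tracks[tps[-1]]
    scatter = cmp.pc1_scatter_stats(first, last)
    scatter["dynamic_fraction"] = cmp.dynamic_fraction(labels)
    with open(out / "scatter_stats.json", "w") as fh:
        json.dump(scatter, fh, indent=1)
    _write_bedgraph(out / "pc1_delta.bedgraph", bins0, cmp.pc1_delta_track(first, last))
    saddles = {}
    for tp in tps:
        sad = cmp.saddle(oes[tp], tracks[tp])
        saddles[tp] = sad
        pd.DataFrame(sad.values).to_csv(out / f"saddle.t{tp}.tsv", sep="\t",
                                        header=False, index=False)
    ratio = cmp.saddle_log_ratio(saddles[tps[-1]], saddles[tps[0]])
    pd.DataFrame(ratio).to_csv(out / "saddle_log_ratio.tsv", sep="\t", header=False, index=False)
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def stage_domains(run_dir, params: Optional[dict] = None) -> list:
    """Insulation tracks, boundaries, intersections, pileups, TAD sizes."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    out = _stage_dir(run_dir, "domains")
    pooled = _pooled_by_timepoint(run_dir, manifest, "tad")
    tps = sorted(pooled)
    boundary_sets = {}
    oe_by_tp = {}
    for tp in tps:
        bal = ct.ice_balance(pooled[tp])
        track = dm.insulation_score(bal, window=pr["insulation_window"])
        _write_bedgraph(out / f"insulation.t{tp}.bedgraph", track.bins, track.score)
        bset = dm.call_boundaries(track, delta_window=pr["delta_window"],
                                  min_strength=pr["min_strength"])
        boundary_sets[tp] = bset
        _write_bed(
            out / f"boundaries.t{tp}.bed",
            bset.chrom,
            bset.positions - bset.binsize // 2,
            bset.positions + bset.binsize // 2,
            [f"b{k}" for k in range(len(bset))],
            scores=[f"{s:.4f}" for s in bset.strengths],
        )
        oe_by_tp[tp] = ct.observed_over_expected(bal)
    rows = []
    for ta, tb in itertools.combinations(tps, 2):
        res = dm.intersect_boundaries(boundary_sets[ta], boundary_sets[tb],
                                      window=pr["boundary_window"])
        rows.append({"a": f"t{ta}", "b": f"t{tb}",
                     "shared_a_fraction": res["shared_a_fraction"],
                     "shared_b_fraction": res["shared_b_fraction"],
                     "n_shared": len(res["shared"])})
    pd.DataFrame(rows).to_csv(out / "boundary_intersections.tsv", sep="\t", index=False)
    cats = dm.boundary_category(boundary_sets[tps[0]], boundary_sets[tps[-1]],
                                window=pr["boundary_window"])
    cats.to_csv(out / "boundary_categories.tsv", sep="\t", index=False)
    for tp in (tps[0], tps[-1]):
        tads = dm.tads_from_boundaries(boundary_sets[tp])
        agg = dm.aggregate_tads(oe_by_tp[tp], tads)
        pd.DataFrame(agg["pileup"]).to_csv(out / f"pileup.t{tp}.tsv", sep="\t",
                                           header=False, index=False)
    # TAD sizes by compartment need the compartment stage
    comp_dir = Path(run_dir) / "compartments"
    state_bed = comp_dir / f"state.t{tps[-1]}.bed"
    if state_bed.exists():
        states = _read_state_bed(state_bed, pooled[tps[-1]].bins.chrom)
        tads = dm.tads_from_boundaries(boundary_sets[tps[-1]])
        sizes = dm.tad_sizes_by_compartment(tads, states)
        pd.DataFrame(
            {
                "compartment": ["A"] * len(sizes["A"]) + ["B"] * len(sizes["B"]),
                "size": np.concatenate([sizes["A"], sizes["B"]]),
            }
        ).to_csv(out / "tad_sizes_by_compartment.tsv", sep="\t", index=False)
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def _read_state_bed(path, chrom) -> cmp.CompartmentTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "state", "score"])
    df = df[df.chrom == chrom]
    binsize = int((df.end - df.start).max())
    length = int(df.end.max())
    bins = ct.BinsTable.from_chrom_length(chrom, length, binsize)
    state = np.array([cmp.MASKED] * bins.n_bins, dtype=object)
    pc1 = np.full(bins.n_bins, np.nan)
    idx = (df.start.to_numpy() // binsize).astype(int)
    state[idx] = df.state.to_numpy()
    pc1[idx] = np.where(df.state.to_numpy() == "A", 1.0, -1.0)
    return cmp.CompartmentTrack(bins=bins, pc1=pc1, state=state)


def stage_loops(run_dir, params: Optional[dict] = None) -> list:
    """Loop calls per time point, anchor UpSet, distances, stratification."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    out = _stage_dir(run_dir, "loops")
    pooled = _pooled_by_timepoint(run_dir, manifest, "loop")
    tps = sorted(pooled)
    loop_sets = {}
    for tp in tps:
        bal = ct.ice_balance(pooled[tp])
        ls = lp.call_loops(
            bal,
            p=pr["loop_p"],
            w=pr["loop_w"],
            fdr=pr["loop_fdr"],
            enrichment_min=pr["loop_enrichment_min"],
            merge_radius=pr["merge_radius"],
        )
        loop_sets[f"t{tp}"] = ls
        ls.to_bedpe(out / f"loops.t{tp}.bedpe")
        if len(ls):
            pd.DataFrame({"distance": lp.anchor_distances(ls)}).to_csv(
                out / f"anchor_distances.t{tp}.tsv", sep="\t", index=False
            )
    membership, combos = lp.intersect_anchor_sets(loop_sets, window=pr["merge_radius"])
    membership.to_csv(out / "anchor_membership.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"combination": "+".join(sorted(c)), "count": n} for c, n in sorted(
            combos.items(), key=lambda kv: -kv[1])]
    ).to_csv(out / "anchor_upset.tsv", sep="\t", index=False)
    # stratify by compartment state recomputed at the stratification layer
    strat_tracks, _ = _compartment_tracks(run_dir, manifest, "strat", pr)
    rows = []
    for tp in tps:
        ls = loop_sets[f"t{tp}"]
        if not len(ls):
            continue
        _, props = lp.stratify_loops_by_compartment(ls, strat_tracks[tp])
        for lab, frac in props.items():
            rows.append({"time": tp, "pair": lab, "proportion": frac})
    pd.DataFrame(rows).to_csv(out / "loops_by_compartment.tsv", sep="\t", index=False)
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def _expression_matrix(run_dir, manifest) -> ex.ExpressionMatrix:
    paths = manifest["expression"]
    run_dir = Path(run_dir)
    return ex.ExpressionMatrix.from_tsv(
        run_dir / paths["counts"], run_dir / paths["genes"], run_dir / paths["samples"]
    )


def stage_expression(run_dir, params: Optional[dict] = None) -> list:
    """FPKM, PCA with Horn's parallel analysis, and DEG calling."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    out = _stage_dir(run_dir, "expression")
    expr = _expression_matrix(run_dir, manifest)
    fk = ex.fpkm(expr)
    fk.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene")
    logf = np.log2(fk + 1.0)
    pca = ex.pca_with_horn(
        logf.T.to_numpy(), n_perm=pr["horn_n_perm"], seed=manifest.get("seed", 0)
    )
    pd.DataFrame(
        pca["scores"][:, :4],
        index=logf.columns,
        columns=[f"pc{k+1}" for k in range(min(4, pca["scores"].shape[1]))],
    ).to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
    with open(out / "pca_summary.json", "w") as fh:
        json.dump(
            {
                "retained": int(pca["retained"]),
                "variance_fractions": [float(x) for x in pca["variance_fractions"][:8]],
            },
            fh,
            indent=1,
        )
    tps = sorted(expr.samples["time"].unique())
    group_a = list(expr.samples.index[expr.samples["time"] == tps[0]])
    group_b = list(expr.samples.index[expr.samples["time"] == tps[-1]])
    degs = ex.call_degs(expr, group_a, group_b, alpha=pr["deg_alpha"], lfc_min=pr["deg_lfc_min"])
    degs.to_csv(out / "degs.tsv", sep="\t", index_label="gene")
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def stage_enrich(run_dir, params: Optional[dict] = None) -> list:
    """Enrichment statistics linking compartments, TADs and loops to DEGs."""
    pr = load_config(run_dir, params)
    manifest = _manifest(run_dir)
    run_path = Path(run_dir)
    for prereq in ("compartments", "expression", "domains", "loops"):
        if not (run_path / prereq).exists():
            raise FileNotFoundError(
                f"stage 'enrich' needs '{prereq}' outputs ({run_path / prereq} missing)"
            )
    out = _stage_dir(run_dir, "enrich")
    genes = pd.read_csv(run_path / manifest["expression"]["genes"], sep="\t", index_col=0)
    degs = pd.read_csv(run_path / "expression" / "degs.tsv", sep="\t", index_col=0)
    switches = pd.read_csv(
        run_path / "compartments" / "switches.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "label", "score"],
    )
    binsize = int((switches.end - switches.start).max())
    bins = ct.BinsTable.from_chrom_length(manifest["chrom"], int(switches.end.max()), binsize)
    gene_bins = ex.genes_to_bins(genes, bins)
    bin_label = {}
    for _, row in switches.iterrows():
        bin_label[int(row.start // binsize)] = row.label
    categories = {
        g: bin_label.get(int(b), "masked") for g, b in gene_bins.items()
    }
    background = [g for g, lab in categories.items() if lab != "masked"]
    frames = []
    for direction in ("up", "down"):
        hits = set(degs.index[degs.direction == direction]) & set(background)
        enr = ex.log2_enrichment(hits, categories, background)
        enr["direction"] = direction
        frames.append(enr.reset_index())
    pd.concat(frames).to_csv(out / "deg_compartment_enrichment.tsv", sep="\t", index=False)

    cats = pd.read_csv(run_path / "domains" / "boundary_categories.tsv", sep="\t")
    rows = []
    for direction in ("up", "down"):
        deg_set = set(degs.index[degs.direction == direction])
        for label in ("lost", "gained", "shared"):
            pos = cats.position[cats.label == label].to_numpy()
            if len(pos) == 0:
                continue
            prox = set(ex.proximal_genes(genes, pos, pr["proximal_window"]))
            obs = len(prox & deg_set)
            expected = len(prox) * len(deg_set) / len(genes)
            log2r = float(np.log2(obs / expected)) if obs and expected else np.nan
            tbl = [[obs, len(deg_set) - obs],
                   [len(prox) - obs, (len(genes) - len(deg_set)) - (len(prox) - obs)]]
            try:
                test = ex.chisq_yates(tbl)
            except ct.ContactDataError:
                test = {"statistic": np.nan, "p": np.nan}
            rows.append({"direction": direction, "boundary": label, "observed": obs,
                         "expected": expected, "log2_ratio": log2r, **test})
    pd.DataFrame(rows).to_csv(out / "deg_boundary_enrichment.tsv", sep="\t", index=False)

    # DEGs at loop anchors and the reciprocal analysis, last time point
    tps = sorted({s["time"] for s in manifest["samples"]})
    bedpe = run_path / "loops" / f"loops.t{tps[-1]}.bedpe"
    loop_rows = []
    if bedpe.exists():
        ldf = pd.read_csv(bedpe, sep="\t", header=None,
                          names=["c1", "s1", "e1", "c2", "s2", "e2", "name", "q"])
        anchors = np.concatenate([(ldf.s1 + ldf.e1) // 2, (ldf.s2 + ldf.e2) // 2])
        prox = set(ex.proximal_genes(genes, anchors, pr["proximal_window"]))
        for direction in ("up", "down"):
            deg_set = set(degs.index[degs.direction == direction])
            obs = len(prox & deg_set)
            expected = len(prox) * len(deg_set) / len(genes)
            log2r = float(np.log2(obs / expected)) if obs and expected else np.nan
            loop_rows.append({"analysis": "degs_at_anchors", "direction": direction,
                              "observed": obs, "expected": expected, "log2_ratio": log2r})
            try:
                rec = ex.reciprocal_anchor_enrichment(
                    degs, anchors, genes, window=pr["proximal_window"], direction=direction
                )
                loop_rows.append({"analysis": "anchors_at_degs", "direction": direction,
                                  "observed": rec["observed"], "expected": rec["expected"],
                                  "log2_ratio": rec["log2_ratio"]})
            except ct.ContactDataError:
                pass
    pd.DataFrame(loop_rows).to_csv(out / "deg_anchor_enrichment.tsv", sep="\t", index=False)
    return [str(p.relative_to(run_dir)) for p in out.iterdir()]


def stage_compare(run_a, run_b, out_dir, params: Optional[dict] = None) -> list:
    """Cross-course comparison of two completed runs (SCC, PC1, insulation)."""
    pr = load_config(run_a, params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man_a, man_b = _manifest(run_a), _manifest(run_b)
    mats_a = _pooled_by_timepoint(run_a, man_a, "compartment")
    mats_b = _pooled_by_timepoint(run_b, man_b, "compartment")
    rows = []
    for ta, ma in sorted(mats_a.items()):
        for tb, mb in sorted(mats_b.items()):
            if not ma.bins.equals(mb.bins):
                continue
            rows.append({"a": f"A.t{ta}", "b": f"B.t{tb}",
                         "scc": dc.scc(ma, mb, h=pr["scc_h"], max_s=pr["max_s"]).scc})
    pd.DataFrame(rows).to_csv(out / "cross_scc.tsv", sep="\t", index=False)

    tracks_a, _ = _compartment_tracks(run_a, man_a, "compartment", pr)
    tracks_b, _ = _compartment_tracks(run_b, man_b, "compartment", pr)
    rows = []
    for ta, tra in sorted(tracks_a.items()):
        for tb, trb in sorted(tracks_b.items()):
            if not tra.bins.equals(trb.bins):
                continue
            st = cmp.pc1_scatter_stats(tra, trb)
            rows.append({"a": f"A.t{ta}", "b": f"B.t{tb}", **st})
    pd.DataFrame(rows).to_csv(out / "cross_pc1.tsv", sep="\t", index=False)

    ins_a = {tp: dm.insulation_score(ct.ice_balance(m), window=pr["insulation_window"])
             for tp, m in _pooled_by_timepoint(run_a, man_a, "tad").items()}
    ins_b = {tp: dm.insulation_score(ct.ice_balance(m), window=pr["insulation_window"])
             for tp, m in _pooled_by_timepoint(run_b, man_b, "tad").items()}
    rows = []
    for ta, ia in sorted(ins_a.items()):
        for tb, ib in sorted(ins_b.items()):
            sel = ia.valid & ib.valid
            if sel.sum() < 3:
                continue
            rho = stats.spearmanr(ia.score[sel], ib.score[sel]).statistic
            rows.append({"a": f"A.t{ta}", "b": f"B.t{tb}", "spearman_rho": float(rho)})
    pd.DataFrame(rows).to_csv(out / "cross_insulation.tsv", sep="\t", index=False)
    return [str(p) for p in out.iterdir()]
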