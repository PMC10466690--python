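"""Configuration, logging and orchestration of the full analysis chain.

The pipeline runs simulate (or ingest) -> callpeaks -> classify -> motifs
-> cluster -> report. Every stage reads its inputs from the serialized
intermediates in the output directory and writes its own outputs there, so
re-running any single stage reproduces the full-run result for that stage,
and the whole run is a deterministic function of (config, inputs, seed).

A run manifest (resolved configuration with every defaulted value echoed,
input checksums, per-stage record counts, wall-clock, software version) is
written on success and on handled failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core_io import (
    DepthTrack, FpkmTable, SampleGroup,
    read_depth_bedgraph, read_fasta, read_fpkm_table, read_genes,
    write_depth_bedgraph, write_fasta, write_fpkm_table, write_genes_bed,
)
from .simulate import (
    ExpressionSpec, SimulationConfig, SyntheticDataset, simulate_dataset,
)
from .peaks import PeakParams, call_peaks, read_peaks_bed, write_peaks_bed
from .differential import (
    classify_peaks, partition_counts, read_differential_tsv,
    write_differential_tsv, write_label_beds,
)
from .motifs import (
    MotifParams, build_frequency_vectors, consolidate_motifs, discover_motifs,
    peak_sequence, read_catalog_tsv, read_vectors_tsv, shuffle_background,
    write_catalog_meme, write_catalog_tsv, write_vectors_tsv,
)
from .differential import PEAKS_0_5, PEAKS_2_0
from .clustering import (
    cluster_composition, embed_2d, fit_kmeans, plot_embedding,
    select_group_specific_clusters, write_assignments_tsv,
    write_centroids_tsv, write_composition_tsv,
)
from .expression import (
    build_cluster_gene_report, compute_fold_changes, link_peaks_to_genes,
    write_changes_tsv, write_report_tsv,
)

log = logging.getLogger("peakshift")

STAGES = ("simulate", "callpeaks", "classify", "motifs", "cluster", "report")


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateBlock(_Strict):
    genome_length: int = 500_000
    chrom: str = "chr1"
    bin_size: int = 10
    n_peaks: Dict[str, int] = Field(
        default_factory=lambda: {"MUT_ENRICHED": 20, "CTRL_ENRICHED": 20, "SHARED": 10}
    )
    peak_height_range: Tuple[float, float] = (30.0, 50.0)
    peak_width_range: Tuple[int, int] = (300, 800)
    background_lambda: float = 5.0
    n_control_samples: int = 2
    n_mutant_samples: int = 3
    enrichment_ratio: Dict[str, float] = Field(
        default_factory=lambda: {"MUT_ENRICHED": 4.0, "CTRL_ENRICHED": 0.25, "SHARED": 1.0}
    )
    motif_plants: List[Tuple[str, str, int]] = Field(
        default_factory=lambda: [
            ("CCCCACCCC", "MUT_ENRICHED", 3),
            ("TAGAAATA", "CTRL_ENRICHED", 3),
        ]
    )
    n_genes: int = 200
    fraction_down: float = 0.15
    fraction_up: float = 0.15

    def to_simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            seed=seed,
            genome_length=self.genome_length,
            chrom=self.chrom,
            bin_size=self.bin_size,
            n_peaks=dict(self.n_peaks),
            peak_height_range=self.peak_height_range,
            peak_width_range=self.peak_width_range,
            background_lambda=self.background_lambda,
            n_control_samples=self.n_control_samples,
            n_mutant_samples=self.n_mutant_samples,
            enrichment_ratio=dict(self.enrichment_ratio),
            motif_plants=[tuple(m) for m in self.motif_plants],
            expression=ExpressionSpec(
                n_genes=self.n_genes,
                fraction_down=self.fraction_down,
                fraction_up=self.fraction_up,
            ),
        )


class InputsBlock(_Strict):
    control_bedgraphs: List[str]
    mutant_bedgraphs: List[str]
    genome_fasta: str
    genes: str
    fpkm: str
    fpkm_group_map: Dict[str, str]
    #: optional per-sample depth scale factors (library-size normalization);
    #: depth is used raw when omitted
    scale_factors: Dict[str, float] = Field(default_factory=dict)


class PeaksBlock(_Strict):
    bin_size: int = 10
    window_bins: int = 21
    slope_factor: float = 2.0
    max_excess_min: float = 2.5
    area_min: float = 5.0
    baseline_relative: bool = True
    max_span_bp: Optional[int] = 3000
    boundary_tolerance: float = 1.0
    suppress_overlaps: bool = True
    trim_fraction: float = 0.1
    detection: Literal["pooled", "per-group-union"] = "pooled"

    def to_params(self) -> PeakParams:
        return PeakParams(
            window_bins=self.window_bins, slope_factor=self.slope_factor,
            max_excess_min=self.max_excess_min, area_min=self.area_min,
            baseline_relative=self.baseline_relative,
            max_span_bp=self.max_span_bp,
            boundary_tolerance=self.boundary_tolerance,
            suppress_overlaps=self.suppress_overlaps,
            trim_fraction=self.trim_fraction, detection=self.detection,
        )


class ClassifyBlock(_Strict):
    all_lines: bool = False


class MotifsBlock(_Strict):
    k_min: int = 6
    k_max: int = 10
    alpha: float = 0.05
    min_fraction: float = 0.25
    max_motifs_per_class: int = 20
    similarity_threshold: float = 0.8
    engine: Literal["builtin", "streme"] = "builtin"
    per_kb: bool = True

    def to_params(self, shuffle_seed: int) -> MotifParams:
        return MotifParams(
            k_min=self.k_min, k_max=self.k_max, alpha=self.alpha,
            min_fraction=self.min_fraction, max_motifs=self.max_motifs_per_class,
            similarity_threshold=self.similarity_threshold,
            engine=self.engine, shuffle_seed=shuffle_seed,
        )


class ClusterBlock(_Strict):
    k: int = 8
    n_restarts: int = 4
    purity_min: float = 0.9
    n_top_motifs: int = 5
    standardize: bool = False
    embed: bool = False


class ReportBlock(_Strict):
    direction: Literal["DOWN", "UP"] = "DOWN"
    max_distance: int = 10_000
    pseudocount: float = 0.1
    down_ratio_max: float = 0.5
    up_ratio_min: float = 2.0
    control_fpkm_min: float = 10.0


class RunConfig(_Strict):
    """Schema-validated run configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "peakshift_run"
    simulate: Optional[SimulateBlock] = Field(default_factory=SimulateBlock)
    inputs: Optional[InputsBlock] = None
    peaks: PeaksBlock = Field(default_factory=PeaksBlock)
    classify: ClassifyBlock = Field(default_factory=ClassifyBlock)
    motifs: MotifsBlock = Field(default_factory=MotifsBlock)
    cluster: ClusterBlock = Field(default_factory=ClusterBlock)
    report: ReportBlock = Field(default_factory=ReportBlock)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "version": __version__,
            "config": json.loads(config.model_dump_json()),
            "input_checksums": {},
            "stages": {},  # stage -> {"counts": ..., "seconds": ...}
            "status": "pending",
            "failed_stage": None,
            "error": None,
        }

    def record(self, stage: str, counts: Dict[str, int], seconds: float) -> None:
        self.data["stages"][stage] = {"counts": counts, "seconds": round(seconds, 3)}

    def write(self, out_dir: Path) -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Stage implementations (each reads serialized intermediates from out_dir)
# ---------------------------------------------------------------------------

def _bin_size(config: RunConfig) -> int:
    if config.simulate is not None:
        return config.simulate.bin_size
    return config.peaks.bin_size


def _input_paths(config: RunConfig, out: Path) -> Dict:
    """Resolved input file locations: simulated under out/inputs, else user paths."""
    if config.simulate is not None:
        d = out / "inputs"
        sim = config.simulate
        return {
            "control": {f"control_{i+1}": d / f"control_{i+1}.bedgraph"
                        for i in range(sim.n_control_samples)},
            "mutant": {f"mutant_{i+1}": d / f"mutant_{i+1}.bedgraph"
                       for i in range(sim.n_mutant_samples)},
            "genome": d / "genome.fa",
            "genes": d / "genes.bed",
            "fpkm": d / "fpkm.tsv",
            "group_map": None,
        }
    inp = config.inputs
    return {
        "control": {Path(p).stem: Path(p) for p in inp.control_bedgraphs},
        "mutant": {Path(p).stem: Path(p) for p in inp.mutant_bedgraphs},
        "genome": Path(inp.genome_fasta),
        "genes": Path(inp.genes),
        "fpkm": Path(inp.fpkm),
        "group_map": inp.fpkm_group_map,
    }


def _load_groups(config: RunConfig, out: Path) -> Tuple[SampleGroup, SampleGroup]:
    paths = _input_paths(config, out)
    bin_size = _bin_size(config)
    scale = config.inputs.scale_factors if config.inputs else {}
    groups = []
    for label in ("control", "mutant"):
        samples = {}
        for sid, p in paths[label].items():
            tracks = read_depth_bedgraph(p, bin_size)
            factor = scale.get(sid)
            if factor:
                tracks = {
                    c: DepthTrack(c, t.bin_size, t.values * factor, t.origin_bp)
                    for c, t in tracks.items()
                }
            samples[sid] = tracks
        groups.append(SampleGroup(label, samples))
    return groups[0], groups[1]


def stage_simulate(config: RunConfig, out: Path) -> Dict[str, int]:
    if config.simulate is None:
        paths = _input_paths(config, out)
        for key in ("genome", "genes", "fpkm"):
            if not Path(paths[key]).exists():
                raise FileNotFoundError(f"input file missing: {paths[key]}")
        log.info("ingest: using user-supplied inputs")
        return {"simulated": 0}
    sim_config = config.simulate.to_simulation_config(config.seed)
    ds = simulate_dataset(sim_config)
    d = out / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    for group in (ds.control, ds.mutant):
        for sid, tracks in group.samples.items():
            write_depth_bedgraph(tracks, d / f"{sid}.bedgraph")
    write_fasta(ds.genome, d / "genome.fa")
    write_genes_bed(ds.genes, d / "genes.bed")
    write_fpkm_table(ds.fpkm, d / "fpkm.tsv")
    # ground-truth tables, for evaluation against planted objects
    with open(d / "truth_peaks.bed", "w") as fh:
        for p in ds.truth.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                     f"{p.peak_class}\t{p.apex}\t{p.height:.6g}\n")
    with open(d / "truth_motifs.tsv", "w") as fh:
        fh.write("consensus\tpeak_class\tpeak_id\tstart\tinstance\n")
        for m in ds.truth.motifs:
            fh.write(f"{m.consensus}\t{m.peak_class}\t{m.peak_id}\t{m.start}\t{m.instance}\n")
    with open(d / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\tdirection\tchrom\tstart\tend\tanchor_peak_id\n")
        for g in ds.truth.genes:
            fh.write(f"{g.gene_id}\t{g.direction}\t{g.chrom}\t{g.start}\t{g.end}\t"
                     f"{g.anchor_peak_id or ''}\n")
    counts = {
        "peaks_planted": len(ds.truth.peaks),
        "motifs_planted": len(ds.truth.motifs),
        "genes": len(ds.truth.genes),
    }
    log.info("simulate: %s", counts)
    return counts


def stage_callpeaks(config: RunConfig, out: Path) -> Dict[str, int]:
    control, mutant = _load_groups(config, out)
    peaks = call_peaks([control, mutant], config.peaks.to_params())
    write_peaks_bed(peaks, out / "peaks.tsv")
    log.info("callpeaks: %d peaks", len(peaks))
    return {"peaks": len(peaks)}


def stage_classify(config: RunConfig, out: Path) -> Dict[str, int]:
    control, mutant = _load_groups(config, out)
    peaks = read_peaks_bed(out / "peaks.tsv", _bin_size(config))
    diff = classify_peaks(peaks, control, mutant, all_lines=config.classify.all_lines)
    write_differential_tsv(diff, out / "differential.tsv")
    write_label_beds(diff, out)
    counts = partition_counts(diff)
    log.info("classify: %s", counts)
    return counts


def stage_motifs(config: RunConfig, out: Path) -> Dict[str, int]:
    genome = read_fasta(_input_paths(config, out)["genome"])
    diff = read_differential_tsv(out / "differential.tsv", _bin_size(config))
    params = config.motifs.to_params(shuffle_seed=config.seed)
    discovered = []
    for cls in (PEAKS_2_0, PEAKS_0_5):
        seqs = [peak_sequence(genome, dp.peak) for dp in diff if dp.label == cls]
        if len(seqs) < 10:
            raise ValueError(f"motif discovery needs >= 10 {cls} peaks, got {len(seqs)}")
        discovered.extend(discover_motifs(seqs, params=params, source_class=cls))
    if not discovered:
        raise ValueError("no motifs discovered; relax motif parameters")
    catalog = consolidate_motifs(discovered, config.motifs.similarity_threshold)
    write_catalog_tsv(catalog, out / "motifs.tsv")
    write_catalog_meme(catalog, out / "motifs.meme")
    vectors = build_frequency_vectors(diff, genome, catalog, per_kb=config.motifs.per_kb)
    write_vectors_tsv(vectors, catalog, out / "vectors.tsv")
    counts = {"motifs_discovered": len(discovered), "motifs_consolidated": len(catalog),
              "vectors": len(vectors)}
    log.info("motifs: %s", counts)
    return counts


def stage_cluster(config: RunConfig, out: Path) -> Dict[str, int]:
    vectors = read_vectors_tsv(out / "vectors.tsv")
    catalog = read_catalog_tsv(out / "motifs.tsv")
    import numpy as np

    X = [v for v in vectors]
    if config.cluster.standardize:
        mat = np.vstack([v.values for v in vectors])
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd[sd == 0] = 1.0
        for v in X:
            v.values = (v.values - mu) / sd
    model = fit_kmeans(X, k=config.cluster.k, seed=config.seed,
                       n_restarts=config.cluster.n_restarts)
    comp = cluster_composition(model, vectors)
    selected = select_group_specific_clusters(
        comp, model, config.cluster.purity_min, config.cluster.n_top_motifs
    )
    write_assignments_tsv(model, vectors, out / "assignments.tsv")
    write_centroids_tsv(model, catalog, out / "centroids.tsv")
    write_composition_tsv(comp, out / "composition.tsv")
    with open(out / "selected_clusters.json", "w") as fh:
        json.dump(
            [
                {"cluster": gs.cluster, "dominant_origin": gs.dominant_origin,
                 "purity": gs.purity, "top_motifs": gs.top_motifs}
                for gs in selected
            ],
            fh, indent=2,
        )
        fh.write("\n")
    if config.cluster.embed:
        coords = embed_2d(vectors, seed=config.seed)
        with open(out / "embedding.tsv", "w") as fh:
            fh.write("peak_id\tx\ty\n")
            for v, (x, y) in zip(vectors, coords):
                fh.write(f"{v.peak_id}\t{x:.6g}\t{y:.6g}\n")
        plot_embedding(coords, vectors, model, out / "embedding.png")
    counts = {"clusters": model.k, "selected_clusters": len(selected),
              "wcss": round(model.wcss, 6)}
    log.info("cluster: %s", counts)
    return counts


def stage_report(config: RunConfig, out: Path) -> Dict[str, int]:
    paths = _input_paths(config, out)
    genes = read_genes(paths["genes"])
    group_map = paths["group_map"]
    if group_map is None:
        import pandas as pd

        header = pd.read_csv(paths["fpkm"], sep="\t", nrows=0, index_col=0)
        group_map = {c: ("control" if c.startswith("control") else "mutant")
                     for c in header.columns}
    fpkm = read_fpkm_table(paths["fpkm"], group_map)
    diff = read_differential_tsv(out / "differential.tsv", _bin_size(config))
    vectors = read_vectors_tsv(out / "vectors.tsv")
    catalog = read_catalog_tsv(out / "motifs.tsv")

    # rebuild the fitted model from serialized assignments + centroids
    from .clustering import ClusterModel
    import numpy as np

    assignments = {}
    with open(out / "assignments.tsv") as fh:
        next(fh)
        for line in fh:
            pid, _, c = line.rstrip("\n").split("\t")
            assignments[pid] = int(c)
    centroids = []
    with open(out / "centroids.tsv") as fh:
        next(fh)
        for line in fh:
            centroids.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    model = ClusterModel(
        k=len(centroids), seed=config.seed, peak_ids=list(assignments),
        assignments=assignments, centroids=np.array(centroids), wcss=float("nan"),
    )
    with open(out / "selected_clusters.json") as fh:
        from .clustering import GroupSpecificCluster

        selected = [
            GroupSpecificCluster(d["cluster"], d["dominant_origin"],
                                 d["purity"], d["top_motifs"])
            for d in json.load(fh)
        ]
    rep = config.report
    changes = compute_fold_changes(
        fpkm, pseudocount=rep.pseudocount, down_ratio_max=rep.down_ratio_max,
        up_ratio_min=rep.up_ratio_min, control_fpkm_min=rep.control_fpkm_min,
    )
    write_changes_tsv(changes, out / "expression_changes.tsv")
    vectorized = {v.peak_id for v in vectors}
    linked_peaks = [dp for dp in diff if dp.peak_id in vectorized]
    links = link_peaks_to_genes(linked_peaks, genes, rep.max_distance)
    rows = build_cluster_gene_report(
        selected, diff, model, links, changes, direction_filter=rep.direction
    )
    write_report_tsv(rows, out / "report.tsv")
    counts = {"links": len(links), "report_rows": len(rows),
              "genes_reported": len({r.gene_id for r in rows})}
    log.info("report: %s", counts)
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "callpeaks": stage_callpeaks,
    "classify": stage_classify,
    "motifs": stage_motifs,
    "cluster": stage_cluster,
    "report": stage_report,
}


def run_stage(config: RunConfig, stage: str, out_dir=None) -> Dict[str, int]:
    """Run one stage against the serialized intermediates in the run directory."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[stage](config, out)


def run_pipeline(config: RunConfig, out_dir=None) -> RunManifest:
    """Execute all stages in order; identical config + inputs + seed give
    byte-identical outputs (manifest timing fields aside).

    On a stage failure the partial outputs are retained, the manifest
    records the failing stage and the error, and the exception propagates.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            counts = _STAGE_FUNCS[stage](config, out)
            manifest.record(stage, counts, time.perf_counter() - t0)
            if stage == "simulate":
                paths = _input_paths(config, out)
                checks = {}
                for key in ("genome", "genes", "fpkm"):
                    p = Path(paths[key])
                    checks[p.name] = _sha256(p)
                for label in ("control", "mutant"):
                    for sid, p in paths[label].items():
                        checks[Path(p).name] = _sha256(Path(p))
                manifest.data["input_checksums"] = checks
        manifest.data["status"] = "ok"
    except Exception as exc:
        manifest.data["status"] = "failed"
        done = set(manifest.data["stages"])
        manifest.data["failed_stage"] = next(s for s in STAGES if s not in done)
        manifest.data["error"] = f"{type(exc).__name__}: {exc}"
        manifest.write(out)
        raise
    manifest.write(out)
    return manifest
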