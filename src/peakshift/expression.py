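"""FPKM fold-change filtering, peak-to-gene linking and the final report.

Expression direction rules (per gene, ratios taken against the mean of the
control samples, with a small pseudocount guarding zero division):

* DOWN — control FPKM > 10 and FPKM ratio <= 0.5 in *all* mutant lines;
* UP   — FPKM ratio >= 2.0 in all mutant lines;
* NONE — otherwise.

The control FPKM > 10 gate applies to the downregulated list only; the two
differential rules cannot both hold, so directions are mutually exclusive
by construction.

Peaks are linked to genes on the same chromosome whose edge-to-edge gap is
at most 10 kb (inclusive; overlap counts as distance 0, gene body, not
TSS). The final report lists genes of the requested direction linked to
peaks whose frequency vectors fall in a selected group-specific cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core_io import FpkmTable, GeneModel
from .differential import DifferentialPeak
from .clustering import ClusterModel, GroupSpecificCluster

DOWN = "DOWN"
UP = "UP"
NONE = "NONE"


@dataclass
class ExpressionChange:
    gene_id: str
    control_fpkm: float
    ratios: Dict[str, float]  # mutant line -> FPKM ratio vs control
    direction: str


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance: int  # bp; 0 when the intervals overlap


@dataclass
class ReportRow:
    cluster: int
    dominant_origin: str
    purity: float
    peak_id: str
    chrom: str
    peak_start: int
    peak_end: int
    gene_id: str
    direction: str
    distance: int


def compute_fold_changes(
    fpkm: FpkmTable,
    pseudocount: float = 0.1,
    down_ratio_max: float = 0.5,
    up_ratio_min: float = 2.0,
    control_fpkm_min: float = 10.0,
) -> List[ExpressionChange]:
    """Per-gene mutant/control FPKM ratios and direction labels.

    ``ratio = (mutant + pseudocount) / (control + pseudocount)`` where
    control is the mean over control samples. The default pseudocount of
    0.1 FPKM leaves ratios of genes above the FPKM > 10 gate essentially
    unchanged while keeping ratios finite at zero control expression.
    """
    df = fpkm.values
    control = df[fpkm.control_samples].mean(axis=1)
    changes = []
    for gene_id in df.index:
        c = float(control.loc[gene_id])
        ratios = {
            line: float((df.at[gene_id, line] + pseudocount) / (c + pseudocount))
            for line in fpkm.mutant_samples
        }
        vals = list(ratios.values())
        if c > control_fpkm_min and all(r <= down_ratio_max for r in vals):
            direction = DOWN
        elif all(r >= up_ratio_min for r in vals):
            direction = UP
        else:
            direction = NONE
        changes.append(ExpressionChange(gene_id, c, ratios, direction))
    return changes


def peak_gene_distance(
    peak_start: int, peak_end: int, gene_start: int, gene_end: int
) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 on overlap."""
    return max(gene_start - peak_end, peak_start - gene_end, 0)


def link_peaks_to_genes(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> List[PeakGeneLink]:
    """All same-chromosome (peak, gene) pairs within ``max_distance`` bp.

    ``peaks`` may hold PeakCandidate or DifferentialPeak objects. The bound
    is inclusive: a gap of exactly ``max_distance`` links, one more does not.
    """
    links: List[PeakGeneLink] = []
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for item in peaks:
        peak = item.peak if isinstance(item, DifferentialPeak) else item
        cands = by_chrom.get(peak.chrom, ())
        if not cands:
            continue
        starts = np.array([g.start for g in cands])
        ends = np.array([g.end for g in cands])
        gaps = np.maximum.reduce(
            [starts - peak.end_bp, peak.start_bp - ends, np.zeros(len(cands), dtype=int)]
        )
        for g, gap in zip(cands, gaps):
            if gap <= max_distance:
                links.append(PeakGeneLink(peak.peak_id, g.gene_id, int(gap)))
    return links


def build_cluster_gene_report(
    selected_clusters: Sequence[GroupSpecificCluster],
    diff_peaks: Sequence[DifferentialPeak],
    model: ClusterModel,
    links: Sequence[PeakGeneLink],
    changes: Sequence[ExpressionChange],
    direction_filter: str = DOWN,
) -> List[ReportRow]:
    """Genes of the requested direction linked to selected-cluster peaks.

    One row per (peak, gene) link — a gene reached through several peaks
    appears once per peak. Rows are sorted by (cluster, chrom, peak start).
    An empty selected-cluster list yields an empty report.
    """
    import warnings

    if not selected_clusters:
        warnings.warn("no selected clusters: the report is empty")
        return []
    cluster_of = {gs.cluster: gs for gs in selected_clusters}
    peak_by_id = {dp.peak_id: dp for dp in diff_peaks}
    direction_of = {ch.gene_id: ch.direction for ch in changes}
    rows = []
    for link in links:
        dp = peak_by_id.get(link.peak_id)
        if dp is None or link.peak_id not in model.assignments:
            continue
        c = model.assignments[link.peak_id]
        gs = cluster_of.get(c)
        if gs is None:
            continue
        if direction_of.get(link.gene_id) != direction_filter:
            continue
        p = dp.peak
        rows.append(
            ReportRow(
                c, gs.dominant_origin, gs.purity, link.peak_id, p.chrom,
                p.start_bp, p.end_bp, link.gene_id, direction_filter, link.distance,
            )
        )
    rows.sort(key=lambda r: (r.cluster, r.chrom, r.peak_start, r.gene_id))
    return rows


def write_report_tsv(rows: Sequence[ReportRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster\tdominant_origin\tpurity\tpeak_id\tchrom\tpeak_start\t"
            "peak_end\tgene_id\tdirection\tdistance\n"
        )
        for r in rows:
            fh.write(
                f"{r.cluster}\t{r.dominant_origin}\t{r.purity:.6g}\t{r.peak_id}\t"
                f"{r.chrom}\t{r.peak_start}\t{r.peak_end}\t{r.gene_id}\t"
                f"{r.direction}\t{r.distance}\n"
            )


def write_changes_tsv(changes: Sequence[ExpressionChange], path) -> None:
    if not changes:
        raise ValueError("no expression changes to write")
    lines = sorted(changes[0].ratios)
    with open(path, "w") as fh:
        fh.write("gene_id\tcontrol_fpkm\t" + "\t".join(f"ratio_{l}" for l in lines)
                 + "\tdirection\n")
        for ch in changes:
            ratios = "\t".join(f"{ch.ratios[l]:.6g}" for l in lines)
            fh.write(f"{ch.gene_id}\t{ch.control_fpkm:.6g}\t{ratios}\t{ch.direction}\n")
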