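"""Synthetic two-condition ChIP-seq / RNA-seq data with known ground truth.

The generator emulates the statistical structure of a differential H3K27me3
experiment: Poisson-noise coverage with localized Gaussian-shaped enrichment
peaks whose mutant:control depth ratios span three classes (mutant-enriched
> 2, control-enriched < 0.5, shared ~ 1), peak-underlying sequences with
planted short motifs per class, gene models placed near peaks, and an FPKM
table with genes down/up at least two-fold in every mutant line.

Every output is a deterministic function of the single configured seed;
sub-streams per component are derived with :class:`numpy.random.SeedSequence`
so partial re-runs reproduce byte-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import (
    ConfigError,
    DepthTrack,
    FpkmTable,
    GeneModel,
    GenomeSequence,
    IUPAC_CODES,
    SampleGroup,
)
import pandas as pd

MUT_ENRICHED = "MUT_ENRICHED"
CTRL_ENRICHED = "CTRL_ENRICHED"
SHARED = "SHARED"
PEAK_CLASSES = (MUT_ENRICHED, CTRL_ENRICHED, SHARED)

DOWN = "DOWN"
UP = "UP"
NONE = "NONE"


@dataclass
class ExpressionSpec:
    """Ground-truth expression structure for the simulated FPKM table."""

    n_genes: int = 200
    fraction_down: float = 0.15
    fraction_up: float = 0.15
    fold_range: Tuple[float, float] = (2.5, 8.0)
    control_fpkm_range: Tuple[float, float] = (1.0, 1000.0)
    #: control FPKM floor for DOWN genes so they clear the FPKM > 10 gate
    down_control_fpkm_min: float = 20.0
    noise_sigma: float = 0.05
    n_control_samples: int = 2
    n_mutant_lines: int = 3
    gene_length_range: Tuple[int, int] = (1000, 3000)
    #: gap between a planted regulated gene and its anchor peak edge
    gene_gap_range: Tuple[int, int] = (500, 4000)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe one 500-kb chromosome with 50 well-separated peaks
    (20 mutant-enriched at 4:1, 20 control-enriched at 1:4, 10 shared),
    Poisson background depth 5, peak excess depth 30-50 (>= 5x the
    background noise SD of sqrt(5)), two control and three mutant samples,
    and one planted short motif per differential class.
    """

    seed: int = 0
    genome_length: int = 500_000
    chrom: str = "chr1"
    bin_size: int = 10
    n_peaks: Dict[str, int] = field(
        default_factory=lambda: {MUT_ENRICHED: 20, CTRL_ENRICHED: 20, SHARED: 10}
    )
    peak_height_range: Tuple[float, float] = (30.0, 50.0)
    peak_width_range: Tuple[int, int] = (300, 800)
    background_lambda: float = 5.0
    n_control_samples: int = 2
    n_mutant_samples: int = 3
    enrichment_ratio: Dict[str, float] = field(
        default_factory=lambda: {MUT_ENRICHED: 4.0, CTRL_ENRICHED: 0.25, SHARED: 1.0}
    )
    #: (consensus, target class, insertions per peak)
    motif_plants: List[Tuple[str, str, int]] = field(
        default_factory=lambda: [
            ("CCCCACCCC", MUT_ENRICHED, 3),
            ("TAGAAATA", CTRL_ENRICHED, 3),
        ]
    )
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def validate(self) -> None:
        if self.background_lambda <= 0:
            raise ConfigError("background_lambda must be > 0")
        if self.bin_size < 1 or self.genome_length < self.bin_size:
            raise ConfigError("bad genome_length / bin_size")
        if set(self.n_peaks) - set(PEAK_CLASSES):
            raise ConfigError(f"unknown peak classes: {set(self.n_peaks) - set(PEAK_CLASSES)}")
        if self.enrichment_ratio.get(MUT_ENRICHED, 4.0) <= 2.0:
            raise ConfigError("enrichment_ratio[MUT_ENRICHED] must be > 2")
        if self.enrichment_ratio.get(CTRL_ENRICHED, 0.25) >= 0.5:
            raise ConfigError("enrichment_ratio[CTRL_ENRICHED] must be < 0.5")
        w_lo, w_hi = self.peak_width_range
        if not (0 < w_lo <= w_hi):
            raise ConfigError("bad peak_width_range")
        for consensus, cls, n_ins in self.motif_plants:
            if cls not in PEAK_CLASSES:
                raise ConfigError(f"motif target class {cls!r} unknown")
            if set(consensus.upper()) - set(IUPAC_CODES):
                raise ConfigError(f"motif {consensus!r} is not valid IUPAC")
            if n_ins * len(consensus) > w_lo:
                raise ConfigError(f"motif {consensus!r} x{n_ins} does not fit the narrowest peak")
        ex = self.expression
        if ex.fraction_down + ex.fraction_up > 1:
            raise ConfigError("fraction_down + fraction_up must be <= 1")
        total = sum(self.n_peaks.values())
        slot = self.genome_length // max(total, 1)
        if total and slot < 3 * w_hi:
            raise ConfigError(
                "genome too short to separate peaks by >= 2x the maximum width"
            )


@dataclass
class TruePeak:
    peak_id: str
    chrom: str
    start: int          # bp, half-open
    end: int
    apex: int           # bp
    peak_class: str
    height: float       # excess depth of the taller group at the apex


@dataclass
class TrueMotif:
    consensus: str
    peak_class: str
    peak_id: str
    start: int          # bp position of the planted instance
    instance: str


@dataclass
class TrueGene:
    gene_id: str
    direction: str      # DOWN / UP / NONE
    chrom: str
    start: int
    end: int
    anchor_peak_id: Optional[str] = None


@dataclass
class GroundTruth:
    """Planted objects with recoverable unique ids."""

    peaks: List[TruePeak] = field(default_factory=list)
    motifs: List[TrueMotif] = field(default_factory=list)
    genes: List[TrueGene] = field(default_factory=list)

    def peaks_of_class(self, peak_class: str) -> List[TruePeak]:
        return [p for p in self.peaks if p.peak_class == peak_class]

    def genes_of_direction(self, direction: str) -> List[TrueGene]:
        return [g for g in self.genes if g.direction == direction]


def _streams(config: SimulationConfig) -> Dict[str, np.random.Generator]:
    """One deterministic child RNG per simulation component."""
    root = np.random.SeedSequence(config.seed)
    names = ("layout", "genome", "depth", "fpkm")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _plan_peaks(config: SimulationConfig, rng: np.random.Generator) -> List[TruePeak]:
    """Lay out non-overlapping peaks separated by >= 2x the maximum width.

    The chromosome is divided into equal slots, one peak per slot with a
    small jitter, which guarantees the separation constraint by construction.
    """
    classes: List[str] = []
    for cls in PEAK_CLASSES:
        classes.extend([cls] * config.n_peaks.get(cls, 0))
    if not classes:
        return []
    rng.shuffle(classes)
    total = len(classes)
    slot = config.genome_length // total
    w_lo, w_hi = config.peak_width_range
    jitter_max = max((slot - 3 * w_hi) // 2, 0)
    peaks: List[TruePeak] = []
    for i, cls in enumerate(classes):
        width = int(rng.integers(w_lo, w_hi + 1))
        height = float(rng.uniform(*config.peak_height_range))
        center = slot * i + slot // 2
        if jitter_max > 0:
            center += int(rng.integers(-jitter_max, jitter_max + 1))
        start = center - width // 2
        peaks.append(
            TruePeak(f"true_{i:04d}", config.chrom, start, start + width, center, cls, height)
        )
    return peaks


def simulate_genome(config: SimulationConfig) -> Tuple[GenomeSequence, GroundTruth]:
    """Uniform-random genome with motif instances planted inside target peaks.

    Degenerate IUPAC letters in a planted consensus are instantiated
    uniformly over their allowed bases, independently per insertion.
    """
    config.validate()
    streams = _streams(config)
    truth = GroundTruth(peaks=_plan_peaks(config, streams["layout"]))
    rng = streams["genome"]
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=config.genome_length)

    for consensus, cls, n_ins in config.motif_plants:
        consensus = consensus.upper()
        k = len(consensus)
        for peak in truth.peaks_of_class(cls):
            if n_ins * k > peak.end - peak.start:
                raise ConfigError(f"motif {consensus!r} does not fit peak {peak.peak_id}")
            # evenly spaced non-overlapping insertion anchors within the peak
            span = (peak.end - peak.start) // n_ins
            for j in range(n_ins):
                lo = peak.start + j * span
                pos = int(rng.integers(lo, lo + span - k + 1))
                instance = "".join(
                    rng.choice(sorted(IUPAC_CODES[c])) for c in consensus
                )
                seq[pos:pos + k] = list(instance)
                truth.motifs.append(TrueMotif(consensus, cls, peak.peak_id, pos, instance))
    genome = GenomeSequence({config.chrom: "".join(seq)})
    return genome, truth


def expected_excess(config: SimulationConfig, truth: GroundTruth, group: str) -> np.ndarray:
    """Expected per-bin excess depth (above background) for one group.

    Each peak contributes a Gaussian bump centered on its apex with
    SD = width / 4; the taller group's apex amplitude equals the peak's
    planted height and the two groups' amplitudes obey the class's
    mutant:control enrichment ratio.
    """
    n_bins = config.genome_length // config.bin_size
    centers = (np.arange(n_bins) + 0.5) * config.bin_size
    excess = np.zeros(n_bins)
    for peak in truth.peaks:
        ratio = config.enrichment_ratio[peak.peak_class]
        amp_mut = peak.height * min(ratio, 1.0) if ratio < 1 else peak.height
        amp_ctrl = amp_mut / ratio
        amp = amp_mut if group == "mutant" else amp_ctrl
        sd = (peak.end - peak.start) / 4.0
        lo = np.searchsorted(centers, peak.apex - 5 * sd)
        hi = np.searchsorted(centers, peak.apex + 5 * sd)
        z = (centers[lo:hi] - peak.apex) / sd
        excess[lo:hi] += amp * np.exp(-0.5 * z * z)
    return excess


def simulate_depth(
    config: SimulationConfig, truth: GroundTruth
) -> Tuple[SampleGroup, SampleGroup]:
    """Per-sample Poisson depth tracks for the control and mutant groups.

    Per bin, depth ~ Poisson(background_lambda + group excess); noise is
    independent per sample and deterministic given the seed.
    """
    config.validate()
    streams = _streams(config)
    rng = streams["depth"]
    lam = {
        g: config.background_lambda + expected_excess(config, truth, g)
        for g in ("control", "mutant")
    }
    groups = {}
    for label, n in (("control", config.n_control_samples),
                     ("mutant", config.n_mutant_samples)):
        samples = {}
        for i in range(n):
            values = rng.poisson(lam[label]).astype(float)
            samples[f"{label}_{i + 1}"] = {
                config.chrom: DepthTrack(config.chrom, config.bin_size, values)
            }
        groups[label] = SampleGroup(label, samples)
    return groups["control"], groups["mutant"]


def _plan_genes(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> List[TrueGene]:
    """Place DOWN genes next to mutant-enriched peaks, UP genes next to
    control-enriched peaks, and NONE genes in the remaining background."""
    ex = config.expression
    n_down = round(ex.n_genes * ex.fraction_down)
    n_up = round(ex.n_genes * ex.fraction_up)
    genes: List[TrueGene] = []

    def place_near(peak: TruePeak, gene_id: str, direction: str) -> TrueGene:
        gap = int(rng.integers(*ex.gene_gap_range))
        length = int(rng.integers(*ex.gene_length_range))
        side = rng.integers(0, 2)
        if side == 0:
            start = peak.end + gap
        else:
            start = peak.start - gap - length
        start = max(0, min(start, config.genome_length - length))
        return TrueGene(gene_id, direction, peak.chrom, start, start + length, peak.peak_id)

    mut_peaks = truth.peaks_of_class(MUT_ENRICHED)
    ctrl_peaks = truth.peaks_of_class(CTRL_ENRICHED)
    idx = 0
    for j in range(n_down):
        if not mut_peaks:
            raise ConfigError("DOWN genes require at least one MUT_ENRICHED peak")
        genes.append(place_near(mut_peaks[j % len(mut_peaks)], f"G{idx:04d}", DOWN))
        idx += 1
    for j in range(n_up):
        if not ctrl_peaks:
            raise ConfigError("UP genes require at least one CTRL_ENRICHED peak")
        genes.append(place_near(ctrl_peaks[j % len(ctrl_peaks)], f"G{idx:04d}", UP))
        idx += 1
    length_hi = ex.gene_length_range[1]
    for _ in range(ex.n_genes - n_down - n_up):
        length = int(rng.integers(*ex.gene_length_range))
        start = int(rng.integers(0, max(config.genome_length - length_hi, 1)))
        genes.append(TrueGene(f"G{idx:04d}", NONE, config.chrom, start, start + length))
        idx += 1
    return genes


def simulate_fpkm(
    config: SimulationConfig, truth: Optional[GroundTruth] = None
) -> Tuple[FpkmTable, GroundTruth]:
    """FPKM table with planted DOWN / UP / NONE genes.

    Control FPKM is log-uniform over the configured range (DOWN genes drawn
    above ``down_control_fpkm_min`` so they clear the control FPKM > 10
    detection gate). Per mutant line, the FPKM ratio to the realized control
    mean is sampled log-uniformly inside the class interval (DOWN <= 0.45,
    UP >= 2.2, NONE in [0.85, 1.18]), jittered by multiplicative log-normal
    noise and clipped back into the class interval so the planted direction
    is recoverable by construction.

    When ``truth`` (with planted peaks) is given, gene bodies are also
    placed on the chromosome: DOWN genes adjacent to mutant-enriched peaks,
    UP genes adjacent to control-enriched peaks, NONE genes anywhere; the
    placements are recorded in the returned ground truth.
    """
    config.validate()
    ex = config.expression
    streams = _streams(config)
    rng = streams["fpkm"]
    if truth is None:
        truth = GroundTruth()
    if truth.peaks:
        truth.genes = _plan_genes(config, truth, rng)
    else:
        truth.genes = [
            TrueGene(f"G{i:04d}", NONE, config.chrom, 0, 1000)
            for i in range(ex.n_genes)
        ]
        n_down = round(ex.n_genes * ex.fraction_down)
        n_up = round(ex.n_genes * ex.fraction_up)
        for g in truth.genes[:n_down]:
            g.direction = DOWN
        for g in truth.genes[n_down:n_down + n_up]:
            g.direction = UP

    fold_lo = max(ex.fold_range[0], 2.2)
    fold_hi = max(ex.fold_range[1], fold_lo)
    c_lo, c_hi = ex.control_fpkm_range
    rows = []
    index = []
    for gene in truth.genes:
        if gene.direction == DOWN:
            control = float(np.exp(rng.uniform(
                np.log(max(c_lo, ex.down_control_fpkm_min)), np.log(c_hi))))
        else:
            control = float(np.exp(rng.uniform(np.log(c_lo), np.log(c_hi))))
        ctrl_vals = control * np.exp(rng.normal(0, ex.noise_sigma, ex.n_control_samples))
        ctrl_mean = ctrl_vals.mean()
        ratios = []
        for _ in range(ex.n_mutant_lines):
            if gene.direction == DOWN:
                r = np.exp(rng.uniform(np.log(1 / fold_hi), np.log(1 / fold_lo)))
                r = min(r * np.exp(rng.normal(0, ex.noise_sigma)), 0.45)
            elif gene.direction == UP:
                r = np.exp(rng.uniform(np.log(fold_lo), np.log(fold_hi)))
                r = max(r * np.exp(rng.normal(0, ex.noise_sigma)), 2.2)
            else:
                r = np.exp(rng.uniform(np.log(0.85), np.log(1.18)))
                r = float(np.clip(r * np.exp(rng.normal(0, ex.noise_sigma)), 0.8, 1.25))
            ratios.append(float(r))
        rows.append(list(ctrl_vals) + [ctrl_mean * r for r in ratios])
        index.append(gene.gene_id)

    columns = [f"control_{i + 1}" for i in range(ex.n_control_samples)] + [
        f"mutant_line_{j + 1}" for j in range(ex.n_mutant_lines)
    ]
    df = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=columns)
    roles = {c: ("control" if c.startswith("control") else "mutant") for c in columns}
    return FpkmTable(df, roles), truth


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeSequence
    control: SampleGroup
    mutant: SampleGroup
    fpkm: FpkmTable
    genes: List[GeneModel]
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generators off one seed and bundle the results."""
    genome, truth = simulate_genome(config)
    control, mutant = simulate_depth(config, truth)
    fpkm, truth = simulate_fpkm(config, truth)
    genes = [
        GeneModel(g.gene_id, g.chrom, g.start, g.end, "+") for g in truth.genes
    ]
    return SyntheticDataset(config, genome, control, mutant, fpkm, genes, truth)
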