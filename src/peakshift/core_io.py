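"""Shared genomic data model and readers/writers for the standard formats.

Conventions used throughout the package:

* all genomic coordinates are 0-based half-open (bedGraph native);
* read depth is stored binned, not per-base; every track in one analysis
  shares the same ``bin_size`` and bin origin;
* depth and peaks are unstranded (ChIP coverage carries no strand); gene
  strand is retained for reporting only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """An input file violates its format contract."""


class ConfigError(ValueError):
    """A configuration value or mapping is invalid."""


# IUPAC nucleotide codes -> the set of plain bases each one stands for.
IUPAC_CODES: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate IUPAC) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Genome as chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-{{A,C,G,T,N}} characters: {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence on [start, end) with bounds checking."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class DepthTrack:
    """Binned, non-negative read-depth signal for one sample on one chromosome.

    ``values[i]`` is the mean depth over base pairs
    ``[origin_bp + i*bin_size, origin_bp + (i+1)*bin_size)``.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    origin_bp: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1 bp")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth values must be finite")
        if np.any(self.values < 0):
            raise ValueError("depth values must be >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def compatible_with(self, other: "DepthTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.origin_bp == other.origin_bp
        )


@dataclass
class SampleGroup:
    """A named group ('control' or 'mutant') of per-sample depth-track sets.

    ``samples`` maps sample id -> {chrom -> DepthTrack}.
    """

    group_label: str
    samples: Dict[str, Dict[str, DepthTrack]]

    def __post_init__(self) -> None:
        if self.group_label not in ("control", "mutant"):
            raise ConfigError("group_label must be 'control' or 'mutant'")
        if not self.samples:
            raise ConfigError("a sample group needs at least one sample")
        chrom_sets = {sid: frozenset(tr) for sid, tr in self.samples.items()}
        if len(set(chrom_sets.values())) != 1:
            raise ConfigError("all samples in a group must cover the same chromosomes")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.samples)

    @property
    def chromosomes(self) -> List[str]:
        first = next(iter(self.samples.values()))
        return list(first)

    def tracks_for(self, chrom: str) -> List[DepthTrack]:
        return [self.samples[sid][chrom] for sid in self.samples]

    def mean_track(self, chrom: str) -> DepthTrack:
        """Per-bin mean depth across the group's samples."""
        tracks = self.tracks_for(chrom)
        ref = tracks[0]
        for t in tracks[1:]:
            if not t.compatible_with(ref) or t.n_bins != ref.n_bins:
                raise ValueError(f"inconsistent binning across samples on {chrom}")
        stacked = np.vstack([t.values for t in tracks])
        return DepthTrack(chrom, ref.bin_size, stacked.mean(axis=0), ref.origin_bp)


@dataclass(frozen=True)
class GeneModel:
    """One gene body on 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class FpkmTable:
    """Gene x sample FPKM matrix plus the sample -> role mapping.

    ``roles`` assigns every sample column either the role ``'control'`` or
    ``'mutant'``; each mutant column is treated as one mutant cell line.
    """

    values: pd.DataFrame
    roles: Dict[str, str]

    def __post_init__(self) -> None:
        df = self.values
        if df.isna().to_numpy().any():
            raise FormatError("FPKM table has missing cells")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("FPKM table has non-numeric cells")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise FormatError("FPKM values must be finite and >= 0")
        missing = set(df.columns) - set(self.roles)
        if missing:
            raise ConfigError(f"samples absent from group map: {sorted(missing)}")
        labels = [self.roles[s] for s in df.columns]
        if any(r not in ("control", "mutant") for r in labels):
            raise ConfigError("sample roles must be 'control' or 'mutant'")
        if "control" not in labels:
            raise ConfigError("group map must name at least one control sample")
        if "mutant" not in labels:
            raise ConfigError("group map must name at least one mutant sample")

    @property
    def control_samples(self) -> List[str]:
        return [s for s in self.values.columns if self.roles[s] == "control"]

    @property
    def mutant_samples(self) -> List[str]:
        return [s for s in self.values.columns if self.roles[s] == "mutant"]


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_depth_bedgraph(path: str | Path, bin_size: int) -> Dict[str, DepthTrack]:
    """Read a 4-column bedGraph and rebin it to ``bin_size``.

    Intervals must be non-overlapping per chromosome and carry values >= 0.
    Each output bin holds the coverage-weighted mean depth over the bin,
    counting uncovered base pairs as depth 0, so total mass
    ``sum(value * bp)`` is conserved by rebinning.
    """
    if bin_size < 1:
        raise ConfigError("bin_size must be >= 1")
    records: Dict[str, List[tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable record") from exc
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if not math.isfinite(value) or value < 0:
                raise FormatError(f"{path}:{lineno}: negative or non-finite value {v}")
            records.setdefault(chrom, []).append((start, end, value))
    if not records:
        raise FormatError(f"{path}: empty bedGraph")

    tracks: Dict[str, DepthTrack] = {}
    for chrom, ivals in records.items():
        ivals.sort()
        prev_end = -1
        for start, end, _ in ivals:
            if start < prev_end:
                raise FormatError(f"{path}: overlapping intervals on {chrom} at {start}")
            prev_end = end
        n_bins = math.ceil(ivals[-1][1] / bin_size)
        mass = np.zeros(n_bins)  # depth * bp per bin
        for start, end, value in ivals:
            b0, b1 = start // bin_size, (end - 1) // bin_size
            if b0 == b1:
                mass[b0] += value * (end - start)
                continue
            mass[b0] += value * ((b0 + 1) * bin_size - start)
            mass[b1] += value * (end - b1 * bin_size)
            if b1 > b0 + 1:
                mass[b0 + 1:b1] += value * bin_size
        tracks[chrom] = DepthTrack(chrom, bin_size, mass / bin_size)
    return tracks


def write_depth_bedgraph(tracks: Mapping[str, DepthTrack], path: str | Path) -> None:
    """Write binned tracks as bedGraph, merging runs of equal-valued bins.

    Zero runs are written too, so the track length (bin count) survives a
    round trip exactly.
    """
    with open(path, "w") as fh:
        for chrom in tracks:
            t = tracks[chrom]
            vals = t.values
            i = 0
            while i < t.n_bins:
                j = i
                while j + 1 < t.n_bins and vals[j + 1] == vals[i]:
                    j += 1
                start = t.origin_bp + i * t.bin_size
                end = t.origin_bp + (j + 1) * t.bin_size
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[i]:.10g}\n")
                i = j + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased, U is mapped to T and degenerate IUPAC codes to
    N; any non-IUPAC character is rejected. Duplicate headers and empty
    sequences are format errors.
    """
    sequences: Dict[str, str] = {}
    degenerate = str.maketrans({c: "N" for c in "RYSWKMBDHV"})
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - set(IUPAC_CODES)
        if bad:
            raise FormatError(f"{path}: illegal characters in {rec.id!r}: {sorted(bad)}")
        sequences[rec.id] = seq.translate(degenerate)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (BED6 / GFF3)
# ---------------------------------------------------------------------------

_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


def read_genes(path: str | Path, feature_type: str = "gene") -> List[GeneModel]:
    """Read gene models from BED6 (or BED4+) or GFF3, autodetected by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path, feature_type)
    return _read_genes_bed(path)


def _read_genes_bed(path: Path) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
            strand = parts[5] if len(parts) >= 6 else "."
            genes.append(GeneModel(parts[3], parts[0], int(parts[1]), int(parts[2]), strand))
    if not genes:
        raise FormatError(f"{path}: no gene records")
    return genes


def _read_genes_gff3(path: Path, feature_type: str) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if parts[2] != feature_type:
                continue
            m = _GFF_ID_RE.search(parts[8])
            gene_id = m.group(1) if m else f"{parts[0]}:{parts[3]}-{parts[4]}"
            # GFF3 is 1-based inclusive; convert to 0-based half-open.
            genes.append(GeneModel(gene_id, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    if not genes:
        raise FormatError(f"{path}: no {feature_type!r} records")
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# FPKM table
# ---------------------------------------------------------------------------

def read_fpkm_table(path: str | Path, group_map: Mapping[str, str]) -> FpkmTable:
    """Read a TSV (header = sample ids, first column = gene ids) of FPKM values.

    ``group_map`` maps sample id -> 'control' | 'mutant' and must cover every
    sample column in the file.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: empty FPKM table")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise FormatError(f"{path}: non-numeric cell in column {col!r}")
        df[col] = coerced
    return FpkmTable(df, dict(group_map))


def write_fpkm_table(table: FpkmTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")
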