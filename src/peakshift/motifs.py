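"""Motif discovery, consolidation and per-peak frequency vectors.

The built-in discoverer is a k-mer enrichment screen: for each k in a
configured range, every k-mer present in the foreground sequences is tested
for presence/absence enrichment against background sequences (one-sided
Fisher exact, Bonferroni-corrected over all tested k-mers), and significant
k-mers that overlap in at least k-1 positions are collapsed into a single
consensus with IUPAC degeneracy at disagreeing positions. An adapter for an
external motif-discovery program (STREME) is provided for fidelity runs;
the built-in path keeps the pipeline hermetic.

Occurrence counting is IUPAC-aware, overlapping, and double-stranded: a
motif's occurrences in a sequence are the positions matched by the
consensus plus the positions matched by its reverse complement. An N in the
*sequence* matches nothing. Frequencies are occurrences per kb of peak
sequence.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact

from .core_io import IUPAC_CODES, GenomeSequence, reverse_complement
from .differential import DifferentialPeak, PEAKS_0_5, PEAKS_2_0

# base-set -> IUPAC letter, inverse of IUPAC_CODES
_SET_TO_CODE = {v: k for k, v in IUPAC_CODES.items()}


@dataclass
class MotifParams:
    k_min: int = 6
    k_max: int = 10
    alpha: float = 0.05
    #: k-mers present in fewer than this fraction of foreground sequences
    #: are not tested (they cannot reach Bonferroni significance anyway)
    min_fraction: float = 0.25
    max_motifs: int = 20
    similarity_threshold: float = 0.8
    engine: str = "builtin"  # 'builtin' | 'streme'
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if not (4 <= self.k_min <= self.k_max <= 30):
            raise ValueError("need 4 <= k_min <= k_max <= 30")
        if self.engine not in ("builtin", "streme"):
            raise ValueError("engine must be 'builtin' or 'streme'")


@dataclass
class Motif:
    motif_id: int
    consensus: str
    source_class: str
    #: enrichment p-value of the seeding k-mer (builtin engine)
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not (4 <= len(self.consensus) <= 30):
            raise ValueError(f"motif length must be in [4, 30]: {self.consensus!r}")
        if set(self.consensus) - set(IUPAC_CODES):
            raise ValueError(f"invalid IUPAC consensus {self.consensus!r}")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class MotifCatalog:
    motifs: List[Motif]
    similarity_threshold: float = 0.8

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if ids != list(range(len(ids))):
            raise ValueError("motif ids must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


@dataclass
class FrequencyVector:
    peak_id: str
    origin: str  # PEAKS_2_0 | PEAKS_0_5
    values: np.ndarray  # occurrences per kb, one entry per catalog motif


# ---------------------------------------------------------------------------
# Occurrence counting
# ---------------------------------------------------------------------------

def _regex(consensus: str) -> re.Pattern:
    # character classes contain plain bases only, so N in the sequence
    # (never in a class) matches nothing
    return re.compile(
        "(?=" + "".join("[" + "".join(sorted(IUPAC_CODES[c])) + "]" for c in consensus) + ")"
    )


def count_occurrences(sequence: str, motif: Motif | str) -> int:
    """Overlapping occurrences of the motif on both strands of ``sequence``.

    Counts positions where the consensus matches the forward sequence plus
    positions where its reverse complement does; a self-reverse-complement
    consensus is therefore counted once per strand (twice per site).
    """
    consensus = motif.consensus if isinstance(motif, Motif) else motif.upper()
    seq = sequence.upper()
    n = len(re.findall(_regex(consensus), seq))
    n += len(re.findall(_regex(reverse_complement(consensus)), seq))
    return n


# ---------------------------------------------------------------------------
# Built-in discovery
# ---------------------------------------------------------------------------

def shuffle_background(sequences: Sequence[str], seed: int = 0) -> List[str]:
    """Per-sequence base shuffle: same composition, no positional signal."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sequences:
        arr = np.array(list(s.upper()))
        rng.shuffle(arr)
        out.append("".join(arr))
    return out


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def _presence_counter(sequences: Sequence[str], k: int) -> Counter:
    """Number of sequences containing each canonical k-mer on either strand."""
    counter: Counter = Counter()
    for s in sequences:
        s = s.upper()
        seen = set()
        for strand_seq in (s, reverse_complement(s)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i:i + k]
                if "N" not in kmer:
                    seen.add(_canonical(kmer))
        counter.update(seen)
    return counter


def _align_score(a: str, b: str) -> Tuple[int, int, str]:
    """Best (#matching aligned positions, offset of b relative to a, strand)
    over all ungapped offsets and both strands; exact base matching."""
    best = (-1, 0, "+")
    for strand, bb in (("+", b), ("-", reverse_complement(b))):
        for off in range(-len(bb) + 1, len(a)):
            m = sum(
                1
                for i in range(max(0, off), min(len(a), off + len(bb)))
                if a[i] == bb[i - off]
            )
            if m > best[0]:
                best = (m, off, strand)
    return best


def _consensus_from_members(members: List[Tuple[str, int]], seed_len: int) -> str:
    """IUPAC consensus of k-mers aligned at (kmer, offset) pairs.

    Columns are restricted to the seeding k-mer's span [0, seed_len):
    flanking bases seen in only some members would otherwise make the
    consensus more specific than the signal supports.
    """
    cols: List[set] = [set() for _ in range(seed_len)]
    for km, off in members:
        for i, base in enumerate(km):
            if 0 <= off + i < seed_len:
                cols[off + i].add(base)
    return "".join(_SET_TO_CODE[frozenset(c)] for c in cols)


def discover_motifs(
    sequences: Sequence[str],
    background_sequences: Optional[Sequence[str]] = None,
    params: Optional[MotifParams] = None,
    source_class: str = PEAKS_2_0,
) -> List[Motif]:
    """Enriched short motifs in ``sequences`` relative to a background.

    Background defaults to a seeded per-sequence shuffle of the inputs.
    Returns at most ``params.max_motifs`` motifs ordered by enrichment
    p-value of their seeding k-mer.
    """
    params = params or MotifParams()
    if len(sequences) < 10:
        raise ValueError("motif discovery needs at least 10 sequences")
    if params.engine == "streme":
        return discover_motifs_external(sequences, background_sequences, params, source_class)
    if background_sequences is None:
        background_sequences = shuffle_background(sequences, params.shuffle_seed)

    n_fg, n_bg = len(sequences), len(background_sequences)
    candidates: List[Tuple[float, str]] = []  # (p, canonical kmer)
    total_tested = 0
    for k in range(params.k_min, params.k_max + 1):
        fg = _presence_counter(sequences, k)
        bg = _presence_counter(background_sequences, k)
        total_tested += len(fg)
        for kmer, a in fg.items():
            if a / n_fg < params.min_fraction:
                continue
            b = bg.get(kmer, 0)
            if a / n_fg <= b / n_bg:
                continue
            _, p = fisher_exact([[a, n_fg - a], [b, n_bg - b]], alternative="greater")
            candidates.append((float(p), kmer))
    if not candidates or total_tested == 0:
        return []
    threshold = params.alpha / total_tested
    significant = sorted(
        ((p, km) for p, km in candidates if p < threshold),
        key=lambda t: (t[0], -len(t[1]), t[1]),  # ties: longest k-mer seeds
    )
    if not significant:
        return []

    # Greedy collapse: walk k-mers from most significant; attach a k-mer to
    # the first cluster whose seed it overlaps in >= min(len)-1 positions.
    clusters: List[Dict] = []
    for p, kmer in significant:
        placed = False
        for cl in clusters:
            seed = cl["seed"]
            m, off, strand = _align_score(seed, kmer)
            if m >= min(len(seed), len(kmer)) - 1:
                oriented = kmer if strand == "+" else reverse_complement(kmer)
                cl["members"].append((oriented, off))
                placed = True
                break
        if not placed:
            clusters.append({"seed": kmer, "p": p, "members": [(kmer, 0)]})

    clusters.sort(key=lambda cl: cl["p"])
    motifs = []
    for i, cl in enumerate(clusters[:params.max_motifs]):
        motifs.append(
            Motif(i, _consensus_from_members(cl["members"], len(cl["seed"])),
                  source_class, cl["p"])
        )
    return motifs


# ---------------------------------------------------------------------------
# External adapter
# ---------------------------------------------------------------------------

def discover_motifs_external(
    sequences: Sequence[str],
    background_sequences: Optional[Sequence[str]],
    params: MotifParams,
    source_class: str = PEAKS_2_0,
) -> List[Motif]:
    """Delegate discovery to the STREME program and parse its motifs.

    Raises :class:`EnvironmentError` when the program is not on PATH; the
    built-in engine (``engine='builtin'``) is the hermetic fallback.
    """
    exe = shutil.which("streme")
    if exe is None:
        raise EnvironmentError(
            "the 'streme' program is not available; use engine='builtin' instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fg = tmp / "fg.fa"
        fg.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(sequences)))
        cmd = [exe, "--p", str(fg), "--dna", "--text",
               "--minw", str(params.k_min), "--maxw", str(params.k_max),
               "--nmotifs", str(params.max_motifs)]
        if background_sequences is not None:
            bg = tmp / "bg.fa"
            bg.write_text(
                "".join(f">b{i}\n{s}\n" for i, s in enumerate(background_sequences))
            )
            cmd += ["--n", str(bg)]
        result = subprocess.run(cmd, capture_output=True, text=True, check=True)
    motifs = []
    for i, m in enumerate(re.finditer(r"^MOTIF\s+\d+-(\S+)", result.stdout, re.M)):
        if i >= params.max_motifs:
            break
        motifs.append(Motif(i, m.group(1), source_class))
    return motifs


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def motif_similarity(a: str, b: str) -> float:
    """Max over ungapped offsets and both strands of
    (IUPAC-aware matching positions) / (length of the shorter motif).

    Two aligned positions match when their IUPAC base sets intersect.
    """
    a, b = a.upper(), b.upper()
    best = 0
    for bb in (b, reverse_complement(b)):
        for off in range(-len(bb) + 1, len(a)):
            m = sum(
                1
                for i in range(max(0, off), min(len(a), off + len(bb)))
                if IUPAC_CODES[a[i]] & IUPAC_CODES[bb[i - off]]
            )
            best = max(best, m)
    return best / min(len(a), len(b))


def consolidate_motifs(
    motifs: Sequence[Motif], similarity_threshold: float = 0.8
) -> MotifCatalog:
    """Merge homologous motifs into one catalog entry each.

    Single-linkage grouping under :func:`motif_similarity` >= threshold;
    each group's representative is its longest member (ties: first by input
    order); ids are reassigned contiguously in input order of the groups.
    """
    if not motifs:
        raise ValueError("need at least one motif to consolidate")
    n = len(motifs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if motif_similarity(motifs[i].consensus, motifs[j].consensus) >= similarity_threshold:
                parent[find(j)] = find(i)

    groups: Dict[int, List[Motif]] = {}
    order: List[int] = []
    for i, m in enumerate(motifs):
        root = find(i)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(m)

    consolidated = []
    for new_id, root in enumerate(order):
        rep = max(groups[root], key=lambda m: m.length)  # max is stable: first longest
        consolidated.append(Motif(new_id, rep.consensus, rep.source_class, rep.p_value))
    return MotifCatalog(consolidated, similarity_threshold)


# ---------------------------------------------------------------------------
# Frequency vectors
# ---------------------------------------------------------------------------

def peak_sequence(genome: GenomeSequence, peak) -> str:
    return genome.fetch(peak.chrom, peak.start_bp, peak.end_bp)


def build_frequency_vectors(
    diff_peaks: Sequence[DifferentialPeak],
    genome: GenomeSequence,
    catalog: MotifCatalog,
    per_kb: bool = True,
) -> List[FrequencyVector]:
    """Convert each differential peak into a motif-occurrence frequency vector.

    Only PEAKS_2_0 / PEAKS_0_5 peaks are vectorized (UNCHANGED peaks carry
    no differential signal and are excluded downstream). Values are
    occurrences x 1000 / peak length bp, or raw counts with
    ``per_kb=False``.
    """
    if len(catalog) == 0:
        raise ValueError("cannot vectorize against an empty motif catalog")
    vectors = []
    for dp in diff_peaks:
        if dp.label not in (PEAKS_2_0, PEAKS_0_5):
            continue
        seq = peak_sequence(genome, dp.peak)
        counts = np.array([count_occurrences(seq, m) for m in catalog], dtype=float)
        values = counts * 1000.0 / len(seq) if per_kb else counts
        vectors.append(FrequencyVector(dp.peak_id, dp.label, values))
    return vectors


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_catalog_tsv(catalog: MotifCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tconsensus\tlength\tsource_class\tp_value\n")
        for m in catalog:
            fh.write(f"{m.motif_id}\t{m.consensus}\t{m.length}\t{m.source_class}\t{m.p_value:.6g}\n")


def read_catalog_tsv(path) -> MotifCatalog:
    motifs = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            mid, consensus, _, cls, p = line.rstrip("\n").split("\t")
            motifs.append(Motif(int(mid), consensus, cls, float(p)))
    return MotifCatalog(motifs)


def write_catalog_meme(catalog: MotifCatalog, path) -> None:
    """Minimal MEME motif format; per-position uniform over the IUPAC set."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in catalog:
            fh.write(f"MOTIF m{m.motif_id} {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length}\n")
            for c in m.consensus:
                allowed = IUPAC_CODES[c]
                probs = [1.0 / len(allowed) if b in allowed else 0.0 for b in "ACGT"]
                fh.write(" " + " ".join(f"{p:.6f}" for p in probs) + "\n")
            fh.write("\n")


def write_vectors_tsv(vectors: Sequence[FrequencyVector], catalog: MotifCatalog, path) -> None:
    with open(path, "w") as fh:
        header = "peak_id\torigin\t" + "\t".join(f"m{m.motif_id}" for m in catalog)
        fh.write(header + "\n")
        for v in vectors:
            vals = "\t".join(f"{x:.10g}" for x in v.values)
            fh.write(f"{v.peak_id}\t{v.origin}\t{vals}\n")


def read_vectors_tsv(path) -> List[FrequencyVector]:
    vectors = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vectors.append(
                FrequencyVector(parts[0], parts[1], np.array([float(x) for x in parts[2:]]))
            )
    return vectors
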