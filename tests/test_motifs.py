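import numpy as np
import pytest
from hypothesis import given, strategies as st

from peakshift import (
    Motif, MotifParams, build_frequency_vectors, consolidate_motifs,
    count_occurrences, discover_motifs, motif_similarity, reverse_complement,
    shuffle_background,
)
from peakshift.core_io import GenomeSequence, IUPAC_CODES
from peakshift.differential import DifferentialPeak, PEAKS_0_5, PEAKS_2_0
from peakshift.motifs import discover_motifs_external
from peakshift.peaks import PeakCandidate


def brute_count(sequence, consensus):
    """Position-by-position IUPAC scanner, both strands."""
    def matches(seq, pat, i):
        return all(
            seq[i + j] in IUPAC_CODES[p] and seq[i + j] != "N"
            for j, p in enumerate(pat)
        )

    total = 0
    for pat in (consensus, reverse_complement(consensus)):
        for i in range(len(sequence) - len(pat) + 1):
            total += matches(sequence, pat, i)
    return total


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), n))


def plant(rng, seq, motif, times):
    arr = list(seq)
    for _ in range(times):
        i = int(rng.integers(0, len(seq) - len(motif)))
        arr[i:i + len(motif)] = list(motif)
    return "".join(arr)


class TestCountOccurrences:
    def test_single_forward_occurrence(self):
        assert count_occurrences("CCCCACCCCA", "CCCCACCCC") == 1

    def test_iupac_wildcard_matches(self):
        assert count_occurrences("ACA", "ANA") == 1

    def test_overlapping_and_both_strands(self):
        # forward AAAAA twice; its reverse complement TTTTT never occurs
        assert count_occurrences("AAAAAA", "AAAAA") == 2
        # reverse-strand hit: GGGG's reverse complement CCCC appears once
        assert count_occurrences("ACCCCA", "GGGG") == 1

    def test_sequence_n_matches_nothing(self):
        assert count_occurrences("AANAA", "AAAAA") == 0
        assert count_occurrences("AANAA", "ANA") == 0

    def test_equals_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(99)
        motifs = ["CCCCACCCC", "TAGAAATA", "ANA", "AAAAA", "RYSW", "TTTT"]
        for _ in range(100):
            seq = random_seq(rng, int(rng.integers(20, 1001)), "ACGTN")
            m = motifs[int(rng.integers(len(motifs)))]
            assert count_occurrences(seq, m) == brute_count(seq, m)

    @given(st.text(alphabet="ACGTN", min_size=8, max_size=60))
    def test_strand_symmetry(self, seq):
        for m in ("TAGAAATA", "ANA"):
            assert count_occurrences(seq, m) == count_occurrences(
                reverse_complement(seq), m
            )


class TestSimilarityAndConsolidation:
    def motif(self, i, consensus, cls=PEAKS_2_0):
        return Motif(i, consensus, cls)

    def test_identical_motifs_merge(self):
        catalog = consolidate_motifs(
            [self.motif(0, "AAAAA"), self.motif(1, "AAAAA")], 0.8
        )
        assert len(catalog) == 1

    def test_offset_homologs_merge(self):
        # CCCACCCC aligns inside CCCCACCCC with 8/8 matching positions
        assert motif_similarity("CCCCACCCC", "CCCACCCC") == 1.0
        catalog = consolidate_motifs(
            [self.motif(0, "CCCCACCCC"), self.motif(1, "CCCACCCC")], 0.8
        )
        assert len(catalog) == 1
        assert catalog.motifs[0].consensus == "CCCCACCCC"  # longest member wins

    def test_dissimilar_motifs_stay_separate(self):
        assert motif_similarity("AAAAA", "CCCCC") == 0.0
        catalog = consolidate_motifs(
            [self.motif(0, "AAAAA"), self.motif(1, "CCCCC")], 0.8
        )
        assert len(catalog) == 2
        assert [m.motif_id for m in catalog] == [0, 1]

    def test_reverse_complement_homologs_merge(self):
        catalog = consolidate_motifs(
            [self.motif(0, "TAGAAATA"), self.motif(1, "TATTTCTA")], 0.8
        )
        assert len(catalog) == 1

    def test_consolidation_idempotent(self):
        rng = np.random.default_rng(4)
        motifs = [self.motif(i, random_seq(rng, int(rng.integers(5, 12))))
                  for i in range(12)]
        once = consolidate_motifs(motifs, 0.8)
        twice = consolidate_motifs(list(once.motifs), 0.8)
        assert [m.consensus for m in twice] == [m.consensus for m in once]


class TestDiscovery:
    def sequences_with_plant(self, motif, n=50, length=400, seed=0):
        rng = np.random.default_rng(seed)
        return [plant(rng, random_seq(rng, length), motif, 2) for _ in range(n)]

    @staticmethod
    def best_identity(found, target):
        """Best per-position agreement of any found consensus with the target,
        over both strands and all ungapped offsets."""
        best = 0
        for m in found:
            for cons in (m.consensus, reverse_complement(m.consensus)):
                for off in range(-len(cons) + 1, len(target)):
                    hits = sum(
                        1
                        for i in range(max(0, off), min(len(target), off + len(cons)))
                        if target[i] in IUPAC_CODES[cons[i - off]]
                    )
                    best = max(best, hits)
        return best

    def test_recovers_planted_nonamer(self):
        seqs = self.sequences_with_plant("CCCCACCCC", seed=1)
        found = discover_motifs(seqs, params=MotifParams(shuffle_seed=1))
        assert found and self.best_identity(found, "CCCCACCCC") >= 8

    def test_recovers_planted_octamer(self):
        seqs = self.sequences_with_plant("TAGAAATA", seed=2)
        found = discover_motifs(seqs, params=MotifParams(shuffle_seed=2))
        assert found and self.best_identity(found, "TAGAAATA") >= 7

    def test_no_enrichment_no_motifs(self):
        rng = np.random.default_rng(3)
        seqs = [random_seq(rng, 300) for _ in range(30)]
        assert discover_motifs(seqs, background_sequences=seqs) == []

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["ACGTACGT"] * 5)

    def test_shuffle_background_preserves_composition(self):
        seqs = ["ACGTACGTAA", "GGGGCCCCTT"]
        bg = shuffle_background(seqs, seed=0)
        assert [sorted(b) for b in bg] == [sorted(s) for s in seqs]
        assert bg == shuffle_background(seqs, seed=0)

    def test_external_engine_unavailable_raises_environment_error(self, monkeypatch):
        monkeypatch.setattr("shutil.which", lambda exe: None)
        with pytest.raises(EnvironmentError, match="builtin"):
            discover_motifs_external(["ACGT" * 20] * 10, None, MotifParams())


class TestFrequencyVectors:
    def setup_method(self):
        seq = "A" * 400 + "CCCCACCCC" + "A" * 591  # one occurrence in 1 kb
        self.genome = GenomeSequence({"chrT": seq + "G" * 1000})
        self.catalog = consolidate_motifs(
            [Motif(0, "CCCCACCCC", PEAKS_2_0), Motif(1, "TAGAAATA", PEAKS_0_5)], 0.8
        )

    def peak(self, start_bp, end_bp, label, pid="p1"):
        c = PeakCandidate("chrT", start_bp, (start_bp + end_bp) // 2, end_bp - 1,
                          0, 10, 100, bin_size=1, peak_id=pid)
        return DifferentialPeak(c, 1.0, 4.0, label)

    def test_per_kb_normalization(self):
        [v] = build_frequency_vectors([self.peak(0, 1000, PEAKS_2_0)],
                                      self.genome, self.catalog)
        assert v.origin == PEAKS_2_0
        assert np.allclose(v.values, [1.0, 0.0])

    def test_doubling_length_halves_values(self):
        [v1] = build_frequency_vectors([self.peak(0, 1000, PEAKS_2_0)],
                                       self.genome, self.catalog)
        [v2] = build_frequency_vectors([self.peak(0, 2000, PEAKS_2_0)],
                                       self.genome, self.catalog)
        assert np.allclose(v2.values, v1.values / 2)

    def test_unchanged_peaks_excluded(self):
        vs = build_frequency_vectors([self.peak(0, 1000, "UNCHANGED")],
                                     self.genome, self.catalog)
        assert vs == []

    def test_empty_catalog_rejected(self):
        from peakshift.motifs import MotifCatalog

        with pytest.raises(ValueError):
            build_frequency_vectors([self.peak(0, 1000, PEAKS_2_0)],
                                    self.genome, MotifCatalog([]))

    def test_peak_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_vectors([self.peak(1500, 2500, PEAKS_2_0)],
                                    self.genome, self.catalog)
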