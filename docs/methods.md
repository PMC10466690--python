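# Methods

## Data model and conventions

All genomic coordinates are 0-based half-open (bedGraph native); GFF3
input is converted on read. Depth is stored binned (default 10 bp bins),
never per base: the method operates on a smoothed genome-wide signal, so
binning bounds memory without losing anything the smoother would keep.
All tracks in one analysis must share bin size and origin. ChIP coverage
is treated as unstranded; gene strand is retained for reporting only.
Depth tracks are used raw by default; an optional per-sample scale factor
(`inputs.scale_factors`) supports library-size normalization when samples
were sequenced to very different depths.

## Peak calling

The detection signal is the per-bin mean over all samples of both groups
("pooled"): one genome-wide peak set is detected once, and group depths
are then compared within it, which treats the two conditions
symmetrically. A per-group-union mode is available.

**Smoothing.** Centered moving average; edge bins average over the
available window. Default `window_bins = 21` (210 bp at 10 bp bins). The
window must be small relative to the peak scale (hundreds of bp here) but
large enough that Poisson noise does not fragment a single enrichment
bump into several local maxima; at background depth λ ≈ 5 averaged over
five samples, a 21-bin window brings the noise SD of the smoothed signal
to ≈ 0.2 depth units, well below the 2.5 depth threshold, while widening
a Gaussian bump of SD σ only to √(σ² + w²/12). Smaller windows (5–11
bins) systematically split wide peaks in half-depth fragments.

**Landmarks.** Local minima and maxima of the smoothed signal (plateau
runs yield one extremum at the run center, left-center on even runs; both
track ends count as minima so edge-truncated peaks stay representable),
plus slope-change points where consecutive nonzero same-sign first
differences differ by more than `slope_factor = 2` in either direction
(strict; zero slopes never qualify, avoiding division by zero on flats).

**Candidates and filters.** Every (start, apex, end) triple with a
maximum as apex, minima/slope-changes as boundaries, and no bin above the
apex depth inside the span is a candidate. Baseline = mean smoothed depth
at the two boundaries; a candidate survives iff max excess > 2.5 **and**
integrated excess > 5.0, both strictly (boundary values are rejected).
The thresholds apply to baseline-subtracted depth by default — the
baselines exist precisely to be subtracted — with a raw-depth mode behind
`baseline_relative=False`. `enumerate_candidates` is exhaustive and is
verified against a brute-force O(n³) triple scan in the tests.

**One peak per summit.** The exhaustive triple set is massively
redundant; three deterministic reductions produce the reported peaks:

1. *Per-apex selection.* Among surviving candidates sharing an apex, the
   kept one must be **grounded**: each boundary's depth lies within
   `boundary_tolerance` (default 1.0 depth units) of the lowest boundary
   depth reachable on its side. This skips single shallow dips on a
   flank (which would truncate the span) without allowing the span to
   wander into background in search of a marginally lower valley. Among
   grounded survivors the minima-bounded narrowest wins; ties go to the
   greater integrated excess, then the leftmost start. The selection is
   implemented lazily per apex inside `call_peaks` and property-tested
   equal to enumerate → filter → deduplicate.
2. *Non-maximum suppression.* Surviving peaks are accepted in order of
   decreasing max excess; a peak overlapping an accepted one is dropped.
   This removes shoulder maxima on the flanks of strong peaks.
3. *Span refinement.* Boundaries are trimmed inward to the outermost
   bins whose smoothed depth reaches baseline + `trim_fraction` (default
   0.1) × max excess, and statistics are recomputed on the trimmed span.
   Valley-to-valley spans carry long near-baseline tails plus the
   moving-average halo; the trimmed span tracks the enrichment footprint,
   which is what overlap-based evaluation and motif extraction want.

`max_span_bp` (default 3000, `None` disables) caps candidate spans in
`call_peaks`; exhaustive enumeration around a tall apex is otherwise
quadratic in the landmark count over multi-kilobase windows.

## Differential classification

[Dp]_ctrl and [Dp]_mut are means of the *unsmoothed* depth over the peak
interval (per-bin mean across the group's samples, then across bins);
smoothing only shapes peak geometry. Labels use strict inequalities
([Dp]_ctrl < 0.5·[Dp]_mut → Peaks_2.0; [Dp]_ctrl > 2·[Dp]_mut →
Peaks_0.5; else unchanged), so no ratio is ever formed and zero depths
are handled naturally (0/0 → unchanged). The default compares against the
mutant group mean — the weakest consistent reading of a per-line
comparison — while `all_lines=True` demands the inequality against every
mutant sample individually. Swapping the groups provably swaps the two
differential labels. Unchanged peaks are excluded from the motif and
clustering stages: only the two differential classes are vectorized.

## Motif discovery, consolidation and vectorization

The built-in discoverer screens k-mers (k = 6…10) for presence/absence
enrichment in the class's peak sequences against a background (default: a
seeded per-sequence base shuffle, preserving composition) with a
one-sided Fisher exact test, Bonferroni-corrected over all distinct
k-mers enumerated from the input; k-mers below 25% foreground presence
are skipped (they cannot reach corrected significance at these sample
sizes). Significant k-mers are walked in order of significance (ties:
longer k-mer first, then lexicographic — sub-words of a longer planted
motif tie on the minimal achievable p-value and must not outrank it) and
greedily collapsed into clusters when they align to a cluster's seed with
at least min(length)−1 matching positions over ungapped offsets on either
strand. The cluster consensus spans exactly the seed's positions, with
IUPAC degeneracy where members disagree; flanking bases seen in only some
members are discarded as unsupported. An adapter for the external STREME
program exists for fidelity runs (`engine='streme'`); it raises an
environment error with a fallback hint when the binary is absent.

Consolidation across classes is single-linkage under the similarity
max over ungapped offsets and strands of (IUPAC-intersecting positions) /
(shorter length), merged at ≥ 0.8 (configurable); the representative is
the longest member (ties: first by input order). Consolidation is
idempotent, and no two retained motifs reach the threshold.

Occurrence counting is overlapping and double-stranded: positions matched
by the consensus plus positions matched by its reverse complement on the
forward sequence (a self-reverse-complement motif is thus counted once
per strand at each site); an N in the sequence matches nothing.
Frequency vectors are occurrences × 1000 / peak length (per-kb), because
peak lengths vary and raw counts would let length dominate the
clustering; a raw-count mode exists.

## Clustering and group-specific clusters

k-means with k = 8 by default. The fit is Lloyd's algorithm from a
seeded greedy farthest-point initialization (first center drawn from the
seeded generator, each next center the point farthest from the chosen
set), best of `n_restarts = 4` by within-cluster sum of squares; empty
clusters are re-seeded with the point farthest from its centroid. The
implementation is in-package because the pipeline asserts WCSS
monotonicity at every iteration and needs bit-identical results for a
given seed; tests cross-check its WCSS against scikit-learn's KMeans.
Vectors are not standardized by default (per-kb frequencies share units);
a z-score mode exists. At convergence each centroid equals the mean of
its members and every vector sits with its nearest centroid (ties to the
lower index).

Cluster composition counts members by differential origin; a cluster with
maximum origin proportion ≥ `purity_min` (default 0.9; 1.0 gives a strict
"only one origin" reading) is group-specific, and its centroid's largest
coordinates (ties to the lower motif id) name its characteristic motifs.
Cluster indices depend on the seed and carry no meaning across runs —
only purity and centroid properties are asserted. The 2-D UMAP embedding
is display-only: deterministic under its seed, but its coordinates carry
no downstream semantics, and it does not collapse duplicate inputs onto
identical points.

## Expression filtering, linking and the report

Per gene, ratio = (mutant FPKM + ε)/(mean control FPKM + ε) with
pseudocount ε = 0.1 FPKM — negligible above the FPKM > 10 gate, but it
keeps ratios finite at zero control expression. DOWN requires control
FPKM > 10 and ratio ≤ 0.5 in all mutant lines; UP requires ratio ≥ 2.0 in
all lines (the stated up-rule carries no control gate). The down-ratio
0.5 mirrors the stated two-fold up rule symmetrically and is
configurable. Peak–gene links connect same-chromosome pairs whose
edge-to-edge gap (gene body, not TSS; overlap = 0) is ≤ 10,000 bp
inclusive. The report lists genes of the requested direction linked to
peaks assigned to a selected cluster, one row per (peak, gene) link,
sorted by (cluster, chromosome, peak start).

## Synthetic data

The generator emulates the study conditions end to end on one 500-kb
chromosome (bin 10 bp):

* **Peaks.** 50 planted (20 mutant-enriched, 20 control-enriched, 10
  shared), laid out one per equal slot with jitter so peaks are separated
  by at least twice the maximum width. Widths are uniform 300–800 bp;
  expected excess depth is Gaussian (apex at the planted center,
  SD = width/4). Peak heights are uniform 30–50 depth units — strong
  peaks, ≥ 5× the background noise SD (√5 ≈ 2.2) with enough headroom
  that a two-fold depth comparison over a whole peak interval (which
  dilutes the apex signal with background) still separates the classes.
  Mutant:control apex ratios are 4.0 / 0.25 / 1.0 per class, the taller
  group at the planted height.
* **Coverage.** Per bin and sample, depth ~ Poisson(5 + group excess),
  independent across samples; two control and three mutant samples
  (three mutant lines, as in the study design).
* **Genome.** I.i.d. uniform A/C/G/T; three instances of CCCCACCCC per
  mutant-enriched peak and of TAGAAATA per control-enriched peak,
  inserted at recorded positions (degenerate IUPAC letters, if any, are
  instantiated uniformly).
* **Expression.** 200 genes, 15% down / 15% up. Control FPKM is
  log-uniform over 1–1000 (DOWN genes over ≥ 20, so planted DOWN genes
  clear the control-FPKM > 10 detection gate). Per mutant line the ratio
  is log-uniform within the class interval, jittered by log-normal noise
  (σ = 0.05) and clipped back to ≤ 0.45 (down), ≥ 2.2 (up) or
  [0.8, 1.25] (null) — the margins keep the planted direction exactly
  recoverable through the pseudocount. DOWN genes are placed 0.5–4 kb
  from mutant-enriched peaks, UP genes beside control-enriched peaks,
  null genes anywhere.

Everything derives from a single seed through per-component
`SeedSequence` children, so partial re-runs are byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mappability and GC biases, fragment-length
structure, chromatin-domain-scale correlation of the mark (real H3K27me3
forms broad domains, not isolated Gaussian bumps), overlapping or nested
peaks, copy-number differences between lines, biological replicate
variance beyond Poisson counting noise, and motif positional preference
within peaks.

## Pipeline, determinism, numerical conventions

The pipeline (simulate/ingest → callpeaks → classify → motifs → cluster →
report) serializes every intermediate as text with fixed float formats;
each stage reads its inputs from the run directory, so re-running one
stage reproduces the full-run file exactly, and a full run is a pure
function of (config, inputs, seed). The YAML config is schema-validated
(unknown keys rejected) and echoed, defaults included, into
`manifest.json` together with input SHA-256 checksums, per-stage counts
and timings. On a stage failure the manifest records the failing stage
and partial outputs are kept.

Tie-breaks are deterministic throughout: plateau extrema at run centers,
dedup preferences ordered (grounded, minima-bounded, narrowest, greatest
area, leftmost), k-means nearest-centroid ties to the lower index,
centroid-ranking ties to the lower motif id, k-mer significance ties to
the longer then lexicographically smaller k-mer. Threshold comparisons
from the published rules (2.5, 5.0, 0.5×, 2×) are strict; the 10-kb link
radius and the ≥ 2-fold expression rules are inclusive. Candidate
statistics are reproducible from the smoothed track to 1e-9; bedGraph
round-trips preserve binned values to 1e-9 and rebinning conserves
total mass (depth × bp) to 1e-6 relative.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run the full study at its
default size (500 kb, 50 peaks, 5 ChIP samples, 200 genes; seconds per
run) and verify the peak caller against the brute-force oracle on ~100
random tracks of 30–500 bins — sizes at which the O(n³) oracle is exact
and fast. These are the package's chosen verification conditions;
genome-scale inputs stream through the same code paths, with runtime
dominated by the per-apex candidate search.

## Known limitations

* The landmark/triple formulation fragments very broad, flat-topped
  enrichment domains; the smoothing window and trim fraction trade
  fragment merging against boundary sharpness.
* The built-in motif finder is a consensus/mismatch method: it recovers
  short, well-conserved motifs but has no PWM scoring, no E-value
  calibration, and limited power for long degenerate motifs; the STREME
  adapter exists for production motif discovery.
* Differential classification is a deterministic ratio rule, not a
  statistical test; it inherits the depth-normalization assumption that
  samples are comparable (or pre-scaled via `scale_factors`).
* Peak–gene linking is distance-only (no TAD or contact information) and
  gene-body anchored; a TSS mode is a natural extension but not built.
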