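# peakshift

Differential H3K27me3 ChIP-seq analysis for two-condition designs: a
custom read-depth peak caller, ratio-based differential classification,
k-mer motif discovery with frequency-vector clustering, and integration
with FPKM expression changes to nominate cluster-associated regulated
genes. A synthetic-data generator with full ground truth makes every stage
verifiable without any external downloads.

The package targets the common epigenomics question "which genomic regions
gained or lost a repressive histone mark between a control cell line and a
panel of mutant lines, what sequence motifs characterize those regions,
and which nearby genes changed expression accordingly?" — for analysts who
have per-sample genome coverage (bedGraph), a genome FASTA, gene models
(BED6/GFF3) and an FPKM table.

## Method

1. **Peak calling.** The per-bin mean depth over all samples is smoothed
   with a centered moving average. Landmarks are marked at local minima,
   local maxima, and points where consecutive slopes change more than
   two-fold. All (start, apex, end) landmark triples are enumerated; with
   baseline *b* = (D(start)+D(end))/2, a candidate is kept when
   max excess D(apex) − *b* > 2.5 and integrated excess
   Σ max(0, D(x) − *b*) > 5.0 (both strict). Overlapping candidates are
   reduced to one peak per summit and trimmed to the enrichment footprint.
2. **Differential classification.** For each peak the mean unsmoothed
   depths [Dp]_ctrl and [Dp]_mut are compared:
   *Peaks_2.0* when [Dp]_ctrl < ½·[Dp]_mut, *Peaks_0.5* when
   [Dp]_ctrl > 2·[Dp]_mut, otherwise unchanged.
3. **Motifs.** Short motifs (k = 6…10) enriched in each class's peak
   sequences versus shuffled backgrounds (one-sided Fisher exact,
   Bonferroni) are consolidated into one catalog; each peak becomes a
   vector of motif frequencies (occurrences/kb, both strands).
4. **Clustering.** k-means (k = 8, deterministic seeded Lloyd with
   restarts) groups the vectors; clusters with origin purity ≥ 0.9 are the
   group-specific clusters and their centroid's top coordinates name the
   characteristic motifs. An optional UMAP scatter displays the vectors.
5. **Expression report.** Genes with control FPKM > 10 and FPKM ratio
   ≤ 0.5 in **all** mutant lines (downregulated; ≥ 2.0 for upregulated)
   that lie within 10 kb of a peak in a selected cluster form the final
   report.

## Worked example

The default configuration simulates one 500-kb chromosome with 50 planted
peaks (20 mutant-enriched at 4:1, 20 control-enriched at 1:4, 10 shared),
Poisson background depth 5, two control and three mutant ChIP samples,
planted motifs CCCCACCCC (mutant-enriched peaks) and TAGAAATA
(control-enriched peaks), and a 200-gene FPKM table with 30 down- and 30
upregulated genes placed near the corresponding peak classes:

```bash
$ peakshift run --seed 4 --out demo_run
run complete: demo_run/manifest.json
  simulate: {'peaks_planted': 50, 'motifs_planted': 120, 'genes': 200}
  callpeaks: {'peaks': 50}
  classify: {'PEAKS_2_0': 20, 'PEAKS_0_5': 20, 'UNCHANGED': 10}
  motifs: {'motifs_discovered': 2, 'motifs_consolidated': 2, 'vectors': 40}
  cluster: {'clusters': 8, 'selected_clusters': 8, 'wcss': 3.0798}
  report: {'links': 368, 'report_rows': 66, 'genes_reported': 30}
```

Reading the counts: all 50 planted peaks were called and every one
received its planted differential label; the two planted motifs were
recovered and consolidated (`demo_run/motifs.tsv` lists their consensus
strings); all eight k-means clusters were origin-pure at the 0.9 purity
threshold; and the final report (`demo_run/report.tsv`) contains exactly
the 30 planted downregulated genes, each within 10 kb of a
mutant-enriched peak (66 rows because a gene linked through several peaks
appears once per peak). Every intermediate — bedGraph coverage, peak BED,
classification TSV, motif catalog (TSV + MEME), frequency vectors, cluster
assignments/centroids/composition, expression directions — is serialized
under `demo_run/`, and `manifest.json` records the resolved configuration,
input checksums, per-stage counts and timings. Re-running with the same
seed reproduces every output byte for byte.

The same stages are available as library functions (`simulate_dataset`,
`call_peaks`, `classify_peaks`, `discover_motifs`, `consolidate_motifs`,
`build_frequency_vectors`, `fit_kmeans`, `compute_fold_changes`,
`link_peaks_to_genes`, `build_cluster_gene_report`) and as individual CLI
subcommands (`simulate`, `callpeaks`, `classify`, `motifs`, `cluster`,
`report`) that re-run one stage from the serialized intermediates.

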