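# repeatbind

Analysis toolkit for asking how two paralogous DNA-binding proteins with
identical in-vitro specificity — a ubiquitously expressed chromatin
architecture factor ("protein A", CTCF-like) and its germline-specific
paralog aberrantly activated in cancer ("protein B", BORIS/CTCFL-like) —
partition the repeated fraction of a genome, and what the germline paralog
does to transposable-element transcription.  Because short reads cannot be
placed uniquely in massively repeated DNA, the design mirrors the two-step
field practice: occupancy is first measured on a tiling repeat microarray
(two-channel ChIP vs input per 50-base tile) and then validated by ChIP-seq
against a repeat *sub-genome* (a FASTA of repeat instances used as the
alignment reference).  Everything is exercised end to end on synthetic
genomes with planted ground truth, so every statistic the pipeline produces
can be checked against what was planted.

## What the pipeline computes

1. **Tiling and normalization.**  Tandem repeats are cut into 50-base tiles
   (repeats shorter than a tile are extended in tandem fashion).  Raw
   two-channel intensities are centered against the mean of a random-sequence
   control-feature set, converted to M/A values (M = log2 ch1/ch2,
   A = ½·log2 ch1·ch2), and corrected by lowess: M ← M − lowess(M | A),
   removing the intensity-dependent dye bias.
2. **Differential statistics.**  A moderated two-group statistic
   d_i = (mean_B − mean_A)/(s_i + s0) with permutation-estimated FDR
   (significance-analysis-of-microarrays style), and an SVD principal-
   component analysis in which PC1 (the common trend) is discarded and
   per-tile loadings on PC2 — the component separating the two proteins'
   arrays — are standardised to Z-scores.
3. **Occupancy classes.**  Tiles are called CO_BOUND (linear fold ≥ 4 for
   both proteins in *all* replicates), A_ONLY / B_ONLY (fold ≥ 4 for one
   protein and ≤ 1 for the other in all replicates, plus |Z| ≥ 5 with the
   matching sign), else UNCLASSIFIED; repeats take the class of their
   best-supported tile.
4. **Sequencing validation.**  An ungapped best-stratum aligner (exact-seed
   pigeonhole, 95 % identity ⇔ ≤ 2 mismatches in a 50-mer, deterministic
   tie-breaking) maps reads to the repeat sub-genome; an array-positive
   repeat is validated if any of its tiles is enriched ≥ 2-fold over input
   (tags per ten million) in every sequencing replicate of the implicated
   protein(s).
5. **Element profiles.**  Binned tag-density metaprofiles along composite
   retrotransposon-like elements (hexamer – Alu-like – VNTR – SINE-R-like –
   polyA), and a k-means (k = 4) ranked clustering of per-element profiles
   whose enrichment-ranked clusters yield the occupied-element fraction.
6. **Motifs.**  A one-occurrence-per-sequence (OOPS) EM learns position
   weight matrices on both strands at fixed width; site p-values are exact
   (dynamic-programming convolution of discretised column scores); a
   staggered-duplication detector finds two offset copies of the short
   consensus inside a longer one — the mechanism by which tandem repeats
   assemble cluster binding sites from a single ~20-bp core site.
7. **Element expression.**  Exact-match (0-mismatch) counting of RNA-seq
   reads per element, normalization to tags per ten million, fold
   enrichment over the averaged empty-vector reference, the silent-element
   rule (< 10 normalized counts in the reference, > 2-fold induced by any
   treatment), paired t tests, treatment concordance (Pearson r of log2
   folds) and subfamily breakdowns of co-activated elements.

The synthetic-data generator (`repeatbind.simulate`) plants all of this:
three occupancy classes on tandem repeats, element occupancy concentrated
on GC-rich VNTRs, array trend/dye-bias/noise structure that the
normalization must remove, fragment-based read sampling (300–500 bp
fragments, 50 bp single-end reads), and condition-dependent activation of
silent elements with a shared latent factor giving a target correlation
between treatments.

## Worked example

```python
from repeatbind import pipeline

cfg = pipeline.validate_config(None)          # the default synthetic study
report = pipeline.run_pipeline(cfg, "out/")
print(report["stages"]["chipchip"]["class_tally"])
print(report["stages"]["chipseq"])
print(report["stages"]["expression"]["mean_folds"])
```

prints (seed 1):

```
{'UNCLASSIFIED': 1005, 'CO_BOUND': 41, 'B_ONLY': 15, 'A_ONLY': 15}
{'n_positive_calls': 71, 'n_validated': 68, 'validated_fraction': 0.9577,
 'sva_occupied_fraction': 0.7}
{'boris_kd': 1.0539, 'dznep': 1.3936, 'kd_dznep': 1.5732}
```

Reading this: of 1,076 catalogued repeats, the three planted classes
(40 co-bound, 15 A-only, 15 B-only) are recovered — the one extra CO_BOUND
call is a background repeat crossing the fourfold threshold by chance
(0.1 % of 1,006) — and 68 of the 71 array-positive repeats survive the
twofold/all-replicates sequencing validation.  The k-means clustering of
element profiles estimates that 70 % of the SVA-like elements are occupied
by protein B (70 % was planted).  On the expression side the recovered mean
activation folds of baseline-silent elements under knockdown, drug, and
combined treatment bracket the planted means of 1.03, 1.37 and 1.55, with
the knockdown and drug effects correlated at r ≈ 0.78 across elements
(0.8 planted through the shared latent factor).

The same stages are available as a CLI (`repeatbind pipeline run`,
`repeatbind occupancy call`, `repeatbind seqval align|quantify|profile`,
`repeatbind motif learn|stagger`, `repeatbind teexpr count|fold`).

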