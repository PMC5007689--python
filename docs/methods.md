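# Methods

This note documents the generative model behind the synthetic studies, the
analysis procedures, the defaults that matter and why they were chosen, and
the limits of what a passing synthetic study demonstrates.

## The synthetic genome

One chromosome is assembled from interleaved feature blocks separated by
random-composition spacers (GC 0.41, ~600 kb of background total):

* **Simple tandem repeats** — 1,070 by default.  Planted repeats (40
  co-bound, 15 A-only, 15 B-only) have a 25-bp unit consisting of a GC-rich
  20-mer core binding site plus random padding, repeated 8 times; each site
  copy is independently mutated at 5 % per base.  Background repeats (1,000)
  have random units.  Because consecutive units juxtapose site copies, any
  sufficiently long array is a *staggered cluster* of binding sites.
* **SVA-like composite elements** — 100 by default, with the fixed region
  order hexamer(CCCTCT)×12 – Alu-like(300 bp) – VNTR – SINE-R-like(400 bp) –
  polyA(25 bp).  The VNTR unit is two juxtaposed copies of the core site
  plus a GC-rich pad (49 bp), repeated 6–12 times, so elements are 1.1–1.5 kb
  (always ≥ 1 kb).  Each element diverges from the family canonical at 6 %
  per base — enough that most 50-bp windows are element-unique under exact
  alignment, which is what makes per-element read assignment meaningful (at
  3 % divergence the deterministic best-hit tie-break visibly drains reads
  from later elements).  70 % of elements are planted "occupied".
* **Alphoid-like arrays** — 171-bp units, half the arrays carrying a
  17-bp CENP-B-box-like submotif.  They are carried as sequence features and
  planted unbound by default: their enrichment in the motivating system is
  weak, and keeping single-protein tiles rare is what gives the Z-score
  criterion its meaning (see below).

Ground truth (classes, occupancy flags, motif placements, affinity tracks,
expression folds) is emitted alongside, and a fixed config reproduces
byte-identical output.

## Occupancy and the array model

Per-base affinity is piecewise constant: background 1, enriched 8, depleted
0.7.  Enriched is deliberately twice the 4× calling threshold: sequencing
fragments of 300–500 bp against 200-bp repeats smear roughly half of the
read centers outside the repeat, so an 8× planted affinity is what keeps
the *sequencing* tile ratio comfortably above the 2× validation threshold.
Depleted (0.7) encodes exclusion of the other paralog; if the non-enriched
protein sat exactly at fold 1, the "≤ 1 in all replicates" rule would fail
half its replicates by symmetry and single-protein classes would be
unrecoverable by construction.

Array intensities per tile/protein/replicate:

    ch2 = g2 · c_t · ε            (input channel)
    ch1 = g1 · c_t · a_tp · 2^(b_t + dye(A_t)) · ε'   (ChIP channel)

with c_t a per-tile hybridization copy factor (log2 sd 1.2, base 500),
g1/g2 per-array channel multipliers (log2 sd 0.5) that make control-feature
centering necessary, b_t a per-tile offset shared by every array (log2 sd
0.25) — the first-principal-component "trend" analog — multiplicative
log-normal noise (log2 sd 0.1 per channel), and dye(A) a cubic
(0.25, 0.08, −0.02) in the row's centred expected mean log-intensity.  The
dye bias is a function of the row's own expected A (including the
enrichment term): the analysis removes it as a function of *observed* A,
and a bias injected at a shifted abscissa would leave a systematic residual
on enriched tiles that no analysis could remove.  500 random-sequence
control tiles play the role of the array's control feature set.

### Normalization

Channels are divided by the per-array control means; a pseudocount of 0.5
is added to raw intensities before logs.  The lowess correction is the
exact per-point definition — tricube weights over the span fraction
(default 0.3) of nearest neighbours in A, local *linear* fit, three
bisquare robustifying passes — with no interpolation shortcuts, so the unit
tests can check it against a naive per-point weighted-least-squares
reimplementation at 1e-9.  In the noise-free limit a linear dye bias is
removed to machine precision; the default cubic is removed to the
smoother's bias, about 5e-2 away from the sparse A extremes (a local linear
smoother cannot do better on curvature; the robust passes are what keeps
the 4 % of enriched outlier tiles from dragging the fit).

### Differential statistics and classification

The moderated statistic is d_i = (mean_B − mean_A)/(s_i + s0) with the
pooled two-sample standard error s_i and s0 = median(s_i) — a simplification
of the canonical coefficient-of-variation-minimizing percentile search that
is stable at this scale.  FDR(Δ) is the median over label permutations of
the count of |d*| ≥ Δ divided by the observed count, over a Δ grid
(default 0.1–5, 50 points, 200 permutations).

PCA is computed by SVD of the column-centred tiles × 6-array corrected-M
matrix.  PC1 absorbs the shared trend b_t plus mean enrichment (~80 % of
variance on default data) and is discarded; PC2 is the A-vs-B contrast
(~17 %); remaining components are replicate noise.  Tile loadings on PC2
are standardised to Z-scores and the sign is fixed so protein-A arrays
score positive.  Because Z is standardised over *all* tiles, its scale is
set by the fraction f of single-protein tiles: Z_planted ≈ 1/√f.  The
default mix keeps f ≈ 2.5 % so planted single-protein tiles sit near
Z ≈ ±6, comfortably past the |Z| ≥ 5 cut — this is why the generator is
stingy with single-protein repeats and why alphoid arrays are not planted
as A-only.

Class rules are applied on the linear fold scale (fold = 2^M, "4×" ⇔
M ≥ 2) per tile, with conjunction over all replicates, then aggregated to
repeats by best-supported tile (co-bound beats single-protein; ties by the
largest minimum implicated fold).  Whether the Z criterion applies to tiles
or repeats first is an interpretation; tile-first is implemented.

## The aligner

Ungapped end-to-end alignment of fixed-length reads: an identity threshold
maps to a mismatch budget ⌊L·(1−identity)⌋ (95 % of a 50-mer ⇔ ≤ 2;
47/50 = 0.94 is rejected), candidate positions come from budget+1 disjoint
exact 16-mer seeds (pigeonhole: any hit within budget matches at least one
seed exactly), verification is vectorised mismatch counting, and only
best-stratum hits are kept with the deterministic tie-break (reference id
lexicographic, then position, then forward strand).  A multi-mapping read
therefore goes to one reproducible location rather than a random one —
a documented divergence from randomized best-hit aligners, traded for
reproducibility.  The unit and acceptance suites hold the aligner equal to
an exhaustive all-positions scan on references up to ~20 kb.

Tile densities are tags per ten million mapped reads with a pseudocount of
1 on both densities; validation requires one tile of the repeat at ratio
≥ 2 in **all** sequencing replicates of each implicated protein
("reproducibly" = every provided replicate; two by default).  Metaprofiles
bin read centers (center = position + L/2) at 50 bp from each element's
start, normalize per ten million and per contributing element, and smooth
with a centred 3-bin moving average.  The occupied fraction caps per-element
profiles at the matrix 99th percentile, k-means clusters them (k = 4, 10
restarts, fixed seed), ranks clusters by mean chip/input enrichment and
counts clusters at mean ≥ 2 as occupied.  The family-level VNTR interval
used when checking peak localization is the union of per-element VNTR
intervals in element-relative coordinates (the pre-VNTR region length is
constant by construction).

## Motifs

The OOPS model assumes exactly one site per sequence, uniform over
positions and strands.  EM seeds are the most frequent w-mers (ties
lexicographic), making the fit deterministic without a random state;
pseudocount 0.25 per base; background is the 0-order composition of the
input.  With a pseudocount the quantity EM provably ascends is the
MAP objective (likelihood plus Dirichlet log-prior); that is asserted every
iteration, and the raw likelihood history is recorded (it can dip by ~1e-3).

Site p-values discretise per-column log2-odds at 0.01 bits and convolve the
column distributions under the background; thresholding at the site's own
lattice score makes the DP exactly equal to exhaustive enumeration at small
widths.

Staggered duplication slides the short matrix (both orientations) across
the long one and takes the mean per-column Pearson correlation; duplication
is called when two offsets ≥ d_min apart (default half the short width)
both reach similarity 0.8, and o2 − o1 estimates the tandem unit length.
Geometry constrains the valid regime: two full copies of a ws-wide site fit
in a wl-window only if the unit ≤ wl − ws, so the 20-mer-in-40-window
configuration can only exhibit duplication for units ≤ 20 bp, and the
staggered analyses use a 16-bp-unit / 12-mer-site repeat family.  The
default 25-bp-unit family is used for consensus recovery at w = 20.

## Element expression

The count model: each element has a baseline expectation (silent elements
uniform 2–9 normalized counts — below the silent cutoff of 10; expressed
elements 50–300), four libraries per condition at 1e8 total reads,
normalization denominator 1e7, Poisson counts.  Per-condition log2 fold
effects of silent elements are μ_c + σ(√ρ·z + √(1−ρ)·u) with σ = 0.5,
a latent z shared across the three treatments, ρ = 0.8, and μ_c set so the
linear-scale mean equals the condition's mean fold (defaults 1.03, 1.37,
1.55); expressed elements do not respond.  The depth and library count were
chosen from an error budget: count noise enters measured log-folds with
variance ≈ 2.1/(λ·n_lib), and at λ ≈ 60 raw counts it attenuates the
planted correlation by only ~0.02–0.03, keeping the recovered r near the
planted 0.8 rather than an artefact of shallow counting.

Fold tables use a pseudocount of 1 normalized tag on both sides — silent
elements otherwise produce undefined ratios in sparse data — but the
per-condition *distribution-mean* summary (`activation_summary`) uses
pseudocount-free ratios of condition-mean to reference-mean counts,
dropping zero-reference elements: with reference means < 10, a pseudocount
of 1 shrinks a true mean fold of 1.55 by ~0.07, a bias larger than the
recovery tolerance, while the deep-count regime keeps denominators positive
without it.  Paired t tests run on log2(normalized + 1) per element
(the scale is a documented choice; configurable); a zero-variance
difference vector is reported as a degenerate case, not a p-value.
Concordance reports Pearson r of log2 folds over elements silent in the
reference, the co-activated set (fold ≥ 2 in both conditions), and
subfamily proportions of the co-activated vs the full set.

## What passing tells you, and what it does not

The generator produces exactly the structure the analyses assume:
multiplicative biases removable by centering+lowess, piecewise-constant
affinity, Poisson counts, divergence-separated elements, no copy-number
aberrations, no sequencing error (the identity and zero-mismatch rules are
the objects under test, so the default error rate is 0), haploid genome,
single-end reads.  Recovery of planted truth therefore validates the
*implementation* of the procedures and their thresholds' internal
consistency — not their robustness to real-data pathologies (probe
cross-hybridization, PCR duplicates, copy-number variation between the
ChIP and input channels, un-annotated repeat polymorphism), which are out
of scope here.

Problem sizes (≈1 Mb genome, ~4,900 tiles, 10⁵-read libraries, 2,000
elements) are the package's default desk-scale study; every threshold and
rate above is a config field, and the methods scale linearly in reads and
tiles.
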