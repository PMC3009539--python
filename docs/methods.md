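# Methods

## Coordinates and windows

All internal coordinates are 0-based half-open (BED convention); 1-based
tables are converted at the reader boundary.  Window arithmetic is
strand-aware: "−300/+200 around an anchor" means 300 bp upstream through
200 bp downstream in transcription direction, i.e. `[p−300, p+200)` on
`+` and the mirror `[p−199, p+301)` on `−`.  Windows that cross a
chromosome end are N-padded so the feature vector keeps its fixed length
L = 500; composition denominators stay at L, L−1, L−2 regardless of N
content, while k-mers containing N are skipped from every count.

## Peak calling

The background model is a single genome-wide Poisson rate
λ = library_size · window / effective_genome_size (effective genome size
defaults to the covered genome length).  500 bp windows every 50 bp are
scored with the Poisson survival function, Benjamini–Hochberg converts
p-values to q-values across all windows of the genome, and windows with
q ≤ FDR (default 0.001) are merged when they overlap or touch.  The
summit is the base of maximum coverage (leftmost on ties); the reported
p/q are the best window values in the merged region.  Tightening the FDR
monotonically shrinks the set of significant windows and called bases; the
*number* of merged peaks can occasionally rise when a tighter threshold
splits one region in two, which is why the tests assert monotonicity of
windows and bases rather than peak counts.  Local-λ models and
input-control subtraction are out of scope; peaks from any external caller
can be imported from BED instead.

## Feature normalisations

Three choices are not forced by the feature definitions and are therefore
made explicit here:

* **Physico-chemical features** are the mean property per valid k-mer
  position, Σ n_x·φ_P(x) / #valid-windows.  This makes the feature
  length-independent and maps a constant scale φ≡c to exactly c; an all-N
  window yields 0.
* **Average TPM** is per base: mean of the per-base TPM profile over the
  500 window positions.  Max/avg is defined as 0 when the average is 0.
* **Multi-sample pooling**: each sample is converted to TPM independently
  (removing depth bias) and per-base TPM is then summed across samples of
  the same assay (configurable to mean).  Coverage can be masked to each
  assay's significant regions before feature computation (default in the
  benchmark), so only tags inside enriched regions contribute.

CAGE is used unstranded by default; the window's CAGE feature is the total
TPM falling inside it.

## Property scales

The 22 scales (A-philicity through EIIP) are loaded from packaged TSVs and
can be replaced by user files.  EIIP and the unified nearest-neighbour
duplex free energies carry real literature values; the other twenty are
deterministic synthetic stand-ins (`*.synthetic.tsv`, flagged in their
headers) with realistic shape but not the published measurements.  Every
mechanical property of the pipeline — totality over Δ_k, linearity,
constant-scale identity, feature extraction and classification — is
independent of the actual values; users who need the published tables drop
them into a scales directory and pass `--scales-dir`.

## Dataset construction

"Peak falls within a window" is tested on the peak **summit** by default
(a point, independent of caller-specific peak widths); any-overlap mode is
available.  A non-promoter record must satisfy all of: summit inside a
gene body; summit not within −300/+200 of *any* TSS; host transcript's
own promoter window contains a Pol-II peak; no intersection with exclusion
tracks; and the −300/+200 record window fully inside the host gene.
Exclusion tracks given as anchor points (EST 5′ ends, homolog promoter
TSSs) are expanded with the same −300/+200 window.  After pooling tissues,
any non-promoter window overlapping a promoter window by ≥ 1 bp is
dropped (strictest reading of "overlapping records").  The train/test
split is random stratified with a stored seed; per-class train counts can
be pinned explicitly to replay a given bookkeeping layout.

## Classification and evaluation

Random forest and bagged trees (scikit-learn) with 100 trees and
unlimited depth by default; a gradient-boosting adapter is provided behind
the same interface.  TPC is FP/TP — the unique simple formula consistent
with every published benchmark row (e.g. 332/7603 → 0.04,
1848/2581 → 0.72, 2664/2563 → 1.04).  Metrics with zero denominators are
reported as 0 and flagged rather than NaN.  Variable importance follows
the classic out-of-bag permutation procedure: per tree, accuracy on the
untouched OOB sample minus accuracy after permuting one predictor,
averaged over trees, normalised by the standard error of the per-tree
decreases, and averaged again over independently seeded forests.  It is
implemented over `BaggingClassifier` with `max_features="sqrt"` trees
because scikit-learn's built-in permutation importance is not the OOB/SE
procedure.  Mean decrease in Gini is the average impurity importance of
the trees.

## Annotation

Both-strand scanning scores the −300/+200 window in forward orientation
and its reverse complement on the mirrored window; calls above the
probability threshold (default 0.5) on both strands of one peak merge into
a single promoter (union interval, max score).  Gene assignment tests the
summit against strand-aware [−2000, +500] with **inclusive** boundaries,
resolving multiple candidates to the nearest TSS and ties to the smaller
coordinate.  Promoters from multiple samples are clustered per gene by
single-linkage ≥ 1 bp overlap — the simplest reproducible notion of "the
same promoter seen in several samples".

## Synthetic data

The generator emulates exactly the signal structure the classifier uses:
uniform background sequence with promoter windows resampled from a
CpG-enriched first-order Markov model (enrichment multiplies C→G/G→C
odds; promoter GC 0.6); Pol-II rates of 0.05 background, +0.8 over
promoter windows, a weak linear 5′→3′ body decay (0.03→0), and
punctate 300 bp stalling bumps (+0.5, Poisson-many per gene, ≥ 1.6 kb
apart, clear of TSS windows) that create distinct intragenic peaks;
H3K4me3 +0.6 over −500/+1000 at each TSS; CAGE concentrated in ±25 bp of
the TSS (150 expected tags).  A quarter of genes carry an alternative TSS
2.5–4 kb into the body.  Defaults produce ≈ 530 promoter and ≈ 1,600
non-promoter records on a 10 Mb genome — a deliberately desk-scale
benchmark (the published benchmark of this problem used ~12k/46k records
from five tissues).

What passing on this generator shows — and does not.  The synthetic
classes are separable almost perfectly (MCC ≈ 1) because signal features
are clean and promoters are homogeneous; real data adds unmodelled
mappability/GC bias, antibody variation, CpG-poor promoters and stalled
polymerase at non-promoters, so real-data accuracy will be lower (the
published benchmark reports MCC ≈ 0.89).  The tests demonstrate
correctness of the machinery and recoverability under the stated model,
not field performance.

## Numerical and degenerate-input conventions

Poisson tails use the survival function (stable for large counts); BH
q-values use the monotone step-up adjustment; max/avg = 0 when avg = 0;
all-N windows give zero vectors; empty tracks yield no peaks; ties in
summits and TSS assignment break to the smaller coordinate; all
randomness flows through `numpy.random.default_rng` seeds carried in
configs, results objects and run logs.

## Known limitations

Single global background rate (no local λ, no input subtraction);
promoter/non-promoter decision is window-level, not a core-promoter
localisation; CAGE strand information is ignored by default; the twenty
synthetic property scales carry no biophysical meaning; Rotational
Forest/LogitBoost are approximated by the gradient-boosting adapter rather
than re-implemented.
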