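# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Normalization model

Expression values are assumed log-like intensities. Filtering is
two-pass with strict thresholds: genes whose missing fraction exceeds
`max_missing` (default 0.10) are removed first, then samples are
re-evaluated over the surviving genes. Imputation substitutes the
gene's mean over all observed samples (not group-restricted), and runs
*before* z-scoring so the control mean/sd are computed on complete
rows; the run summary records this ordering. Standardization is
control-referenced: x → (x − mean_ctrl)/sd_ctrl per gene with the n−1
standard deviation (the package-wide convention). After the transform
the control group of every retained gene has mean 0 (|mean| < 1e−9)
and sample variance 1 (|var − 1| < 1e−6) exactly, and the whole
operation is invariant to any per-gene affine rescaling of the input —
which is what makes the raw-scale and z-scale entry points equivalent.
Genes with zero control variance cannot be standardized and are
reported (the pipeline drops them; the low-level function raises).

## Stage-specific genes

The coefficient of variation CV = sd/mean is computed over cancer
samples only. It is a meaningful "fluctuation" measure on the raw
intensity scale, where quiet genes have small sd relative to a large
positive mean. On the control-referenced z-scale the ratio inverts its
meaning (background genes have mean ≈ 0, hence enormous |CV|), so the
pipeline computes CV on the raw matrix when raw input is provided. The
generator does not emulate the low-intensity probe floor that the
filter targets in real arrays, so synthetic end-to-end runs set
`cv_quantile = 1.0` (filter disabled); the filter's mechanics (quantile
cut on |CV|, boundary ties kept, undefined CVs excluded) are tested
directly instead.

Differential expression uses a moderated two-sample t: per-gene pooled
variances s² with d = n₁ + n₀ − 2 degrees of freedom are shrunk toward
a scaled inverse-chi-square prior (d₀, s₀²) fitted by moment matching
on log s² (digamma/trigamma equations, Newton inversion of the
trigamma), giving s̃² = (d₀s₀² + ds²)/(d₀ + d) and a t-statistic with
d + d₀ degrees of freedom. With the prior weight at zero this is
exactly the pooled-variance two-sample t, which is exposed as
`method="ttest"` and used as the cross-check oracle in the tests.
log_fc is the difference of group means, already a log-scale quantity
on z-scored data; the default cutoffs are P < 0.05 and |logFC| ≥ 1,
uncorrected (a Benjamini–Hochberg flag would be a one-liner on the
returned table; raw thresholds are the analysis convention here). Δ2
keeps each shared gene's direction in both phases separately, since
they can disagree.

## Co-expression and networks

Per-phase correlations are computed over that phase's samples only —
phase-specific structure is unobservable otherwise — while the
non-specific (Δ2) network uses all samples. Classification at
±`corr_threshold` (default 0.5) is strict, so |r| exactly at the
threshold is unclassified; stable pairs must hold the same sign in
every supplied phase. Clustering uses 1 − r distance and average
linkage; merge ties resolve by scipy's deterministic index order, so
results are reproducible for a fixed input order.

Topology metrics fix conventions for fragmented graphs, which these
networks typically are: the average shortest path averages over ordered
reachable pairs within components of size ≥ 2 (undefined, NaN, for an
edgeless graph); closeness uses the Wasserman–Faust component scaling
closeness(v) = ((r_v − 1)/Σd) · ((r_v − 1)/(n − 1)) where r_v is v's
reachable-set size — identical to the textbook closeness on connected
graphs; the clustering coefficient is 0 for degree < 2. Degree weights
are w = 1/(1 + e^(−degree)), so an isolated gene weighs 0.5 and weights
increase strictly with connectivity but never reach 1; universe genes
absent from the network inherit the minimum in-network weight rather
than 0, which keeps them scoreable without rewarding absence.

## Pathway deviation score

Enrichment is the one-sided hypergeometric tail (Fisher's exact test,
"greater"), with pathways intersected with the tested-gene universe
first. Gene-level evidence is a three-group one-way ANOVA p-value
mapped through the upper-tail normal quantile, Z = Φ⁻¹(1 − p), and
multiplied by the gene's network weight. P-values are floored at 1e−16
so Z stays finite in double precision; degenerate genes (no variance
anywhere) get p = 1 by convention.

The score A(P) is the maximum over prefix sizes t of the mean of the t
largest weighted Z values scaled by √t. It is order-invariant,
positively homogeneous, and monotone in every Z — all property-tested
against an exhaustive prefix-enumeration oracle. Because A grows with
the number of scored members k, each pathway is standardized against
μ_k, σ_k of A over random size-k gene sets drawn without replacement
from the background pool (all genes with a defined Z). The default is
10,000 permutations; the test suite and acceptance script use 2,000,
which already puts the Monte-Carlo error of A_corrected well below the
effect sizes being detected. Permutation streams derive from the
master seed and the set size k, making results independent of pathway
evaluation order and letting equal-k pathways share one null — two
pathways with identical member Z multisets therefore get exactly equal
A_corrected. Subsets are drawn by random-key argpartition, which
vectorizes the whole batch.

Per-sample profiles substitute the sample's weighted z-scored
expression for the gene-level Z inside the same max-prefix statistic,
yielding one value per (pathway, sample); these are a positively biased
max statistic, so their absolute level is not interpretable — only the
contrast across phases, which the pathway-level one-way ANOVA screens
at `anova_p` (default 0.05). Both the gene-level A_corrected and the
per-sample reading are computed and reported, since each answers a
different question (is the pathway deviated at all vs. in which phase).

## Diagnostic model

RFE ranks features with a linear-kernel SVM (C = 1), whose weights are
well defined, while the accuracy curve and the final model use an
RBF-kernel SVM — the standard split when the deployment kernel has no
native feature weights. The selected set is the accuracy-curve argmax
with ties going to fewer features; because CV accuracy saturates on
well-separated data, the argmax can be far smaller than the planted
panel, so the trace also exposes `top_features(k)`, the k
longest-surviving features, as the ranking readout. A zero-width RBF
kernel is degenerate, so the default kernel width is scikit-learn's
`"scale"` (1/(n_features · var)); the grid searches (C, γ) around it
with ties broken toward smaller C then smaller γ. Evaluation is
stratified k-fold (default 5) with per-fold ROC from decision scores,
trapezoidal AUC, and accuracy/AUROC reported as the mean over folds.
Three labelling schemes are supported: benign (stage I–II) vs malignant
(III–IV), control vs cancer, and early vs late phase. The default
configuration is benign-vs-malignant; note that in the synthetic cohort
the planted effects are referenced to controls and identical within a
phase, so stage II (late-phase) samples labelled benign carry the
late-phase signature by construction and the benign/malignant contrast
is intentionally weak there — synthetic demonstrations use the
control-vs-cancer or early-vs-late scheme instead.

## The synthetic-data generator

The generator produces data directly on the post-normalization scale:
background cells iid N(0, 1) in every sample, so controls match the
normalization model by construction. Planted structure:

- **DE genes** — a ±`shift` mean offset (default 2 z-units, half up,
  half down) in the designated phase(s); "both" genes shift identically
  in early and late.
- **Correlated blocks** — one latent factor per (block, phase):
  x = √ρ·f + √(1−ρ)·ε gives exact pairwise correlation ρ in
  expectation (default ρ = 0.7, 3 blocks of 10); negative ρ alternates
  loading signs. Block genes are disjoint from DE genes so correlation
  and mean effects stay independently testable.
- **Pathways** — `n_deviated` pathways (default 5 of 50, size 20) draw
  at least 80% of members from planted shared-DE genes, the rest from
  background; non-deviated pathways draw from background only, so
  recovery is well-posed without being degenerate.

Group sizes default to 81/28/53 (control/early/late), the cohort shape
of the motivating study; gene counts default to 2,000, a desk-scale
size at which every statistical property the tests assert (null
uniformity, calibration, recovery rates) is already stable. An
optional per-gene affine map (`denormalize`) produces raw-style
intensities for exercising the preprocessing stage, and
`inject_missing` blanks an exact fraction of cells.

What the generator does **not** emulate: probe-level artifacts,
batch/array effects, heavy-tailed or count-based noise, intensity-
dependent variance, realistic pathway overlap, or any gene-gene biology
beyond the planted blocks. Passing tests therefore demonstrate that
the algorithms recover the structures they claim to detect under the
stated noise model — not that those structures are detectable at the
same rates in any particular real cohort.

## Numerical conventions and degenerate inputs

- Sample standard deviations use ddof = 1 everywhere.
- CV is undefined (excluded, warned) when the case mean is exactly 0;
  quantile-boundary ties in the CV filter are all kept.
- Correlation of a constant gene is undefined: flagged NaN, classed
  "none" in pair tables, a hard error in clustering.
- ANOVA with zero between- and within-group variance gives p = 1; zero
  within- with positive between-group variance gives p = 0 (then
  floored by the Z conversion).
- A permutation null with σ_k ≈ 0 (constant background) is an error,
  not a silent infinity.
- Every stochastic component (generator, permutations, fold
  assignment) takes an explicit seed; the pipeline derives per-stage
  streams from one master seed via `SeedSequence`, so stages are
  reproducible independently of each other.

## Problem sizes

Default test and acceptance runs use 500–2,000 genes, 90–162 samples,
2,000 permutations per calibration, 50 pathways, and a 198-gene
candidate panel for RFE — sizes chosen so each statistical check is
comfortably powered while a full run stays in the tens of seconds.
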