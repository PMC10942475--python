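# Methods

This note documents the models and procedures implemented in `motifdiff`, the
defaults chosen where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Coordinates and fragment handling

All intervals are BED-style 0-based half-open. A fragment of length
`end − start` marks two Tn5 insertion events, at `start` and `end − 1`.
Fragment files are assumed pre-shifted (10x convention); for unshifted input,
`tn5_insertions(frags, 4, 5)` applies the usual +4/−5 correction. Duplicate
counts (optional 5th column) are carried as integer weights and honoured by
every counting operation; the semi-simulation expands weighted rows inside
perturbed regions so that the downsampling formula counts fragments, not rows.

Peak resizing anchors each merged interval at its floored midpoint and sets a
fixed width (default 300 bp, a common choice close to typical median peak
size). Out-of-range intervals are truncated at 0 and at the contig end, so a
peak at the very edge of a contig may be narrower than the target width; away
from edges the midpoint moves by at most 1 bp. Fragment-length classes use
the fixed thresholds (0, 120] nucleosome-free, (120, 300] mono-,
(300, 500] di-, (500, ∞) multi-nucleosome; the nucleosome-free *filter* keeps
lengths in [30, 120].

## Deviation scores with matched backgrounds

The expectation model is library-size only: `E_ij = r_i c_j / N` with `r`, `c`
the count marginals. (TMM-style size factors were considered and omitted:
replacing the library-size normalization does not remove the between-sample
distributional shifts that motivate downstream score normalization, which is
cheaper and more direct.)

Background peaks are sampled per foreground peak from its k nearest
neighbours (default k = 50) in standardized (GC fraction, log1p mean count)
space, one uniform draw per iteration. This is a deliberate simplification of
bin-based Mahalanobis sampling: the operative contract is statistical — on
null data the z-scores across motifs should be approximately standard normal
— and the test suite checks exactly that (|mean| < 0.1, sd within
[0.7, 1.3] at 500 iterations). Results stabilize as the number of iterations
grows; the package default is 2000, and the suite verifies that the
seed-to-seed variance of a motif's z-score decreases from 50 to 1000
iterations. With sd = 0 across background draws the z-score is set to 0 and
flagged rather than propagating NaN; motifs with no matched peaks are NaN and
flagged.

Score normalization before testing: `center` subtracts the per-sample median
and `scale` divides by the MAD (robust statistics, because empirical z-score
distributions are heavy-tailed and can shift or stretch between samples for
technical reasons); `quantile` maps every sample onto the mean order-statistic
reference and is the recommended default.

## GC smooth quantile normalization

Input is `log2(CPM + 0.5)`; the transform ahead of normalization is not
dictated by the method, and log-CPM is adequate variance stabilization at the
fixture scale. Peaks enter equal-occupancy GC bins (default 10; bins left
with < 2 peaks by ties merge into a neighbour). Within a bin, for quantile
rank k the normalized value for group g is `w_k q_k + (1 − w_k) q_gk`, where
`q_k` is the across-sample mean order statistic, `q_gk` the group-specific
one, and `w_k = 1 − SSB_k/SST_k` clipped to [0, 1] and smoothed by a running
median over max(3, 5% of ranks). One group (or identical group
distributions) gives w = 1, i.e. exact within-bin quantile normalization;
a pure between-group shift gives w = 0 and survives normalization. Values map
back through average ranks (ties receive the mean of the implicated
reference values).

## Regression activities

The per-sample multivariate model regresses each sample's (column-centered)
normalized accessibility on the column-standardized motif-match matrix plus
an intercept, by OLS through a single QR factorization shared across samples.
The activity score is the per-motif t-value, not the raw coefficient:
standardized quantities feed the moderated test more comparably across
motifs. All-zero, duplicated and collinear columns are dropped with a logged
warning and reported NaN — highly similar motifs are better handled as
archetypes upstream.

Univariate per-motif models regress the peak log-fold-change on the match
indicator, the match score, or indicator plus GC covariate (via residualizing
both sides on [1, gc]). The logFC itself is the difference of group means of
normalized log2 values; when ties exist, uniform jitter of amplitude
0.001 × max|logFC| (fixed seed) makes values strictly orderable for binning.

Binned enrichment sorts peaks into an odd number (default 9) of equal-count
logFC bins; the bin whose range covers zero is the reference. Per motif and
non-zero bin, a one-sided Fisher exact test (hypergeometric tail) compares
motif presence in the bin against the zero bin (`vsZero`) or all other bins
(`vsOthers`); log2 enrichments add 0.5 to all four table cells. Per-motif
p-values aggregate by Simes' rule, which is valid under the positive
dependence expected between overlapping bins. Sequence-composition-corrected
enrichment is out of scope; Fisher's exact test is the replacement.

## Footprint methods

Insertion profiles accumulate events in ±200 bp around fixed-width motif
matches, strand-flipped for minus-strand sites. The insertion model weights
positions by the motif's global (across-sample) profile, smoothed by an
11-bp centered running mean (a free parameter; the profile shape is what
matters) and symmetrized by mirror-averaging, normalized to sum 1; the score
is the weighted sum of a sample's insertion counts.

The BagFoot-like test summarizes each motif/sample as footprint depth
`log2((F20/40 + c)/(M/L + c))` — near-flank vs in-motif per-bp insertion
rate, pseudocount c = 0.5 — and flanking accessibility `log2(F200/400 + c)`.
The windows (20 bp and 200 bp per side) define the statistic; the per-bp
log-ratio arithmetic is this package's choice, made for scale invariance.
Depth and flank matrices are tested separately with the moderated machinery
and combined per motif by Fisher's method (chi-square, 4 df), then
BH-adjusted. Sequence (Tn5 preference) bias correction is omitted: it is
shared across samples and cancels in relative comparisons.

## Moderated testing

Two-group pooled-variance designs only. The prior (d₀, s₀²) is estimated by
matching moments of the log residual variances (digamma/trigamma closed
forms, Newton inversion of the trigamma); `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ +
d_g)`, with t referred to d₀ + d_g degrees of freedom. Forcing d₀ = 0
reproduces the ordinary pooled t exactly (tested to 1e-10); a single testable
motif falls back to it with a warning. BH is the multiplicity control
throughout.

## Semi-simulation

ChIP peak enrichments are quantile-mapped (type-7, linear interpolation
between order statistics) onto the reference scenario's enrichment
distribution; each peak takes the log2FC of the nearest reference peak
(equidistant ties to the lower index). The printed downsampling rule is
applied on the log scale — retention fraction `2^(−p·|log2FC|)` — because
strength 0 must reproduce the original data exactly, which a linear product
would violate. Negative log2FC downsamples group B, positive group A, so the
realized B-vs-A ratio carries the planted sign. Downsampling is independent
per (peak, sample), as the formula indexes both; each fragment is resolved to
one peak (largest overlap, ties to the lower index). Given the same plan,
different seeds change fragment identities but never the retained counts.

Two bundled reference scenarios are synthetic, deterministic curves over a
log-normal-shaped enrichment grid: *activation* (effects grow with occupancy,
up to ~3 log2 units) and *haploinsufficiency* (mild effects, largest at
low-occupancy peaks). They emulate the qualitative shapes of ligand-induced
receptor activation and halved TF dosage; real reference tables can be
supplied as TSVs of (enrichment, log2fc).

Composition biases re-sample fragments with acceptance probability
proportional to target density over empirical density of the attribute (GC in
10 bins over [0, 1], or the four length classes), normalized so the maximum
acceptance is 1; weighted rows are binomially thinned. Target mass on
empirically empty bins is unreachable and warned about.

## Synthetic fixtures

Defaults describe a small but realistic bulk ATAC two-group study: 2000
fixed-width peaks on two synthetic contigs with 0.9–2.2 kb gaps; per-peak GC
~ Beta(10, 10) (mean 0.5, sd ≈ 0.11); per-peak NB means log-normal(3.3, 0.6)
(median ≈ 27 fragments/peak) with NB size 10 and per-sample log-normal depth
factors (sd 0.15); fragment lengths from the class mixture
(0.55, 0.30, 0.10, 0.05) over ranges 30–120 / 121–300 / 301–500 / 501–800 bp;
3 vs 3 samples. Motif matches are Bernoulli with logit linear in
standardized GC (per-motif coefficients ~ N(0, 0.5)) plus a latent peak
factor on which the perturbed motif and its 10 designated "network" motifs
load, inducing the co-occurrence that the network score relies on. A few PPM
near-duplicate pairs (never involving the perturbed motif) give archetype
clustering real structure. The ChIP set covers 70% of the perturbed motif's
matched peaks plus ~10% off-motif peaks, with enrichment correlated to peak
occupancy.

What the generator does **not** emulate: real sequence (GC and matches are
annotations, not scanned from sequence), peak-width heterogeneity, spatial
correlation between neighbouring peaks, batch structure beyond a scalar depth
factor, and single-cell sparsity. Passing tests therefore demonstrate
correctness of the algorithms and calibration under the stated generative
model — not performance on any particular real dataset.

## Benchmark metrics

Results are ranked by ascending p, ties by descending |effect|, then motif id
(NA last) — deterministic ranking matters for permutation-based methods that
produce ties. The true-motif rank is the best rank of any true motif. Member
AUC scores average the top-k member proportion over k = 1..100 (capped at the
number of motifs) and divide by the best attainable curve. Precision at
FDR 0.05 counts as positives all motifs whose archetype cluster contains a
network member (raw members only via a flag); recall counts only true
motifs. The rank transform `2e^(−√r)/(1 + e^(−√r))` maps ranks onto (0,
0.538] so they can be averaged with the bounded scores; missing method ×
dataset cells are imputed with the worse (smaller, after transformation) of
the dataset column's median and mean. Motif similarity is IC-weighted Pearson
over all ungapped alignments (overlap ≥ 5) and both orientations, with column
weight the mean information content (2 + Σ p log2 p) of the two aligned
columns; archetypes are complete-linkage clusters of 1 − similarity cut at
0.45 (human default) or 0.35 (mouse). Rank-sum aggregation across methods
uses the exact convolution of independent uniform ranks when n × methods ≤
10⁴, else seeded Monte-Carlo.

## Problem sizes used in the checks

The calibration and recovery suites run at the default fixture size (2000
peaks × 100 motifs × 6 samples) with 250 background iterations for
pipeline-level checks and 500 for the null-calibration check, 20 seeds per
perturbation strength, and 2000 simulated null motif-sets for the type-I
check; these sizes give stable statistics while keeping the whole suite fast
on a single CPU. `scripts/acceptance.py` defaults to 8 seeds per strength for
the same reason (`--n-runs` raises it).

## Known limitations

* Only two-group pooled-variance designs; no covariates or contrast matrices.
* Background matching is kNN-based; the neighbourhood size trades matching
  fidelity against pool diversity and is fixed, not adaptive.
* The insertion-model weight normalization and the footprint depth/flank
  arithmetic are package definitions; other reasonable definitions exist.
* The bundled binding scenarios are stylized; quantitative conclusions about
  a specific TF require a real reference scenario table.
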