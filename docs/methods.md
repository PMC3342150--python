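# Methods

This note documents the models behind `circmir`, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical conventions that make every result reproducible bit for bit.

## Synthetic cohort

No raw data exist for the serum profiling study this package models, so all
inputs are generated (`circmir.synth`), under a single integer seed per
object.

**Reference.** A class-tagged mini-reference stands in for miRBase plus
genome annotation: by default 60 mature miRNAs (18–25 nt) — always including
hsa-miR-375, hsa-miR-122 and hsa-miR-16 with their canonical mature
sequences — plus tRNA (70–90 nt), rRNA (90–150), scRNA (80–130), snRNA
(90–150), snoRNA (60–120) and an "other" class (40–80). Sequences are drawn
uniformly over {A,C,G,T}; a candidate is rejected if it equals, contains or
is contained in an existing entry, so exact-substring annotation can never
confuse two entries and the truth-vs-assignment round trip is exact.

**Reads.** Reads are exact contiguous substrings of reference entries
(length clipped to the 15–52 nt size-selection window), with classes drawn
multinomially from the serum composition: miRNA 50%, tRNA 28%, scRNA 8.8%,
rRNA 4.4%, snRNA 0.6%, snoRNA 0.4%. Those six classes cover 92.2% of a
serum library; the remaining 7.8% is assigned to "other". No sequencing
errors, adapters or isomiRs are simulated — annotation downstream is
specified as exact matching, so error models would only obscure the
accounting identities the tests rely on.

**Counts.** For gene g in sample s the count is negative binomial with mean

    mu_gs = L_s * a_g * 2^(sum of planted effects active in s)

and common dispersion phi (variance mu + phi*mu^2), drawn via the
gamma–Poisson mixture. Baseline relative abundances `a_g` are log-normal
(sigma = 1.5, normalised to sum to 1) so a few genes dominate, matching the
wide dynamic range of circulating miRNAs; library sizes `L_s` are log-normal
(sigma = 0.3) around `mean_library_size` so normalisation is non-trivial.
Defaults fix the study conditions: 42 samples, 11/42 relapsing, HER2+ 23/42,
ER+ 21/42, PR+ 14/42, inflammatory 10/42; regimen C is the trastuzumab arm
(the HER2+ patients) and the HER2− patients split A:B = 7:12; pCR occurs in
12/23 of HER2+ and 2/19 of HER2− patients. Covariates are assigned by
independent seeded permutations with exactly those marginal counts; their
mutual correlations in the real cohort are not reproduced. The default
planted effects are the relapse-contrast magnitudes of the two markers —
miR-375 at −1.90 log2 and miR-122 at +1.35 log2 — and miR-16 is never
planted, consistent with its role as the PCR reference. The default common
dispersion is 0.2, a typical bulk small-RNA value; the study reports none.
`mean_library_size` defaults to 500,000 miRNA-assigned reads — the real
samples had 7–12 million aligned reads, which is beyond desk scale, and the
multi-seed recovery suites run at 100,000 as the package's chosen problem
size.

Because counts are generated per gene without per-sample renormalisation,
planting an effect on an abundant gene shifts that sample's total; scaling
to a common depth then induces a small apparent opposite shift in every
other gene (compositional bias, at most a few tenths of a log2 unit here).
This is a real property of total-count normalisation, not an artefact to be
removed; the null-calibration tests therefore use cohorts with no planted
effects.

**qPCR.** Ct values are linear in the normalised log2 count:
`Ct = 36 − 0.95·log2value + N(0, noise_sd)` (noise_sd 0.5 by default), so
−Ct tracks sequencing abundance with realistic assay noise and the ΔCt
transform `2^(Ct_ref − Ct_gene)` recovers a monotone function of abundance.

## Annotation

Reads are size-selected to 15–52 nt, then assigned iff they occur as an
exact contiguous substring of at least one reference entry (U→T and case
normalised; characters outside {A,C,G,T,U,N} make a read unassigned, never
fatal). Multi-class hits resolve by the fixed priority miRNA > tRNA > rRNA >
scRNA > snRNA > snoRNA > other; within the winning class the
lexicographically smallest entry id wins and the read is flagged ambiguous.
Each read contributes exactly one count, keeping matrices integral for the
exact NB test. Mismatch-tolerant genomic alignment is out of scope by
design: the deterministic exact-match rule is what makes the
provenance-vs-count identities testable. Composition fractions are computed
over assigned reads only.

## Filtering and normalisation

The analysis set is built in a fixed order: detectability (count ≥ 1 in ≥ 2
samples), then abundance (count strictly > 50 in ≥ ceil(10% of samples)),
then quantile normalisation, then log2(x+1). Quantile normalisation maps
each column onto the across-column mean of order statistics; tied values
within a column receive the mean of the reference quantiles their tie group
spans. This tie rule must be fixed for exactness on count data; note that
with column-specific ties the transform is only idempotent up to
tie-averaging. Sample clustering uses 1 − Pearson correlation and average
linkage; zero-variance columns get maximal distance (2.0) with a warning,
and samples are processed in lexicographic id order so equal-distance merges
are deterministic. Correlation/average is a choice — the study's figure
names neither a distance nor a linkage.

## Differential abundance

A single common dispersion is used throughout (no tagwise shrinkage): the
study's testing settings are unstated, and the common-dispersion model is
exactly what the generator produces, making parameter recovery well-posed.
phi is estimated by maximising the conditional NB log-likelihood summed over
genes and groups on depth-equalised counts, clamped to [1e-6, 10].

For the exact test, samples are scaled to the geometric-mean library depth
and rounded half-up to integer pseudo-counts (the rounding rule is fixed for
determinism). Group sums are NB with sizes n_g/phi; conditioning on their
total, the two-sided p doubles the smaller tail (observed point included in
both tails), capped at 1 — the doubling convention is fixed so the
enumeration oracle is well-defined. For large totals only the support
carrying non-negligible conditional mass (±25 SD around the conditional
mode, always extended to cover the observation) is enumerated; the windowed
path agrees with full enumeration to 1e-6 relative. Below phi = 1e-10 the
conditional binomial limit is used directly.

The regimen-adjusted test fits the NB log-linear model by IRLS at fixed phi
with log-library-size offsets and compares the group-augmented model to the
covariate-only null by χ²(1). Rank deficiency (group aliased with the
adjustment) and IRLS non-convergence yield NaN, flagged, never a crash.
Group means in the output table are averages of pseudo-counts, and the log2
fold is log2(mean₁/mean₂) with zeros left as flagged infinities rather than
folded with a pseudo-count. FDR is Benjamini–Hochberg step-up. Rows sort by
p then gene id, so tables are order-stable.

## Classifier

"Univariate logistic regression using the two-gene signature" is read as one
logistic model with the two miRNA levels as two covariates; the single-gene
variants use one covariate each, spanning both readings of the phrase.
Features are z-scored internally and coefficients back-transformed, so any
positive affine rescaling of a feature leaves predictions unchanged; this
also makes sequencing-count and PCR-level inputs interchangeable up to
scale. IRLS converges when the largest score component falls below 1e-8
(≤ 50 iterations); complete separation triggers a refit with an L2 ridge of
1e-4 on the slopes, recorded as `converged=False` — the study is silent on
separation, and the tiny ridge preserves the sample ranking (AUC 1 on
separated data) while keeping parameters finite.

The probability cutoff minimises the training misclassification count over
midpoints between consecutive distinct fitted probabilities plus the two
boundary midpoints; ties break toward the largest margin to the nearest
probability, then the smallest cutoff. "Relapsed" requires probability
strictly greater than the cutoff. LOOCV refits both the model and the
cutoff on every fold; a fold whose training labels collapse to one class
predicts the training majority and is flagged. External validation fits one
model and one cutoff on the full training cohort and applies them unchanged.

## Performance statistics

Sensitivity and specificity are exact ratios, displayed as half-up-rounded
integer percents (7/8 → 88%). The odds ratio is the cross-product
(tp·tn)/(fn·fp) — identical to the exponentiated slope of an unconditional
logistic regression on a binary predictor — with a Woolf 95% CI and Wald
p-value; any zero cell triggers the Haldane–Anscombe +0.5 correction,
flagged, and a double-zero margin leaves the OR undefined. Group
comparisons of PCR levels use Welch's unequal-variance t-test on log2
relative levels (the study says only "t-tests"; Welch is the safer default),
reporting group means and SEMs. Platform consistency uses Pearson r between
normalised log2 counts and log2 PCR relative levels with the t-transform
p-value (n − 2 df).

## Problem sizes and determinism

Every stochastic operation takes an explicit seed and reproduces
byte-identical output under it; the pipeline's JSON summary is reproducible
across reruns of the same configuration. The test suite's heavy checks use
deliberately chosen sizes: planted-marker recovery and the Youden-index
comparison run 50 cohorts of 42 samples at 100,000 reads mean depth;
annotation composition uses 100,000 reads; null calibrations use 100–1000
replicates. These sizes are the package's own accuracy/runtime trade-off.

## Limitations

The generator draws clinical covariates independently (no ER/PR/HER2
correlation structure), simulates no sequencing errors or isomiRs, and uses
one common dispersion — so passing tests demonstrate correctness of the
statistical machinery and recoverability of planted effects under the
stated model, not robustness to misspecification on real sera. Normalisation
is total-count/quantile based; size-factor methods (TMM, median-of-ratios)
are noted alternatives, not implemented. Confidence intervals for the OR are
Woolf approximations, not exact conditional intervals; survival analysis is
out of scope.
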