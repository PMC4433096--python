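# Methods

## Scope and model

`mockbias` treats a 16S amplicon pipeline as a sequence of three biased
stages — DNA extraction, PCR amplification, sequencing plus taxonomic
classification — acting on a community of p known strains. Mock
communities with prescribed proportions of cells, extracted DNA, and PCR
product pass through nested subsets of the pipeline, so pairwise
differences of their observed compositions attribute bias to individual
stages. Everything downstream (mixture-effect models, significance tests,
inverse correction) operates on proportions, i.e. compositional data on
the simplex.

Two facts shape the statistics. First, because proportions sum to one, the
per-sample bias vector x̂ − x sums to zero: one taxon's amplification is
necessarily another's suppression, and the bias covariance across taxa is
singular by construction (handled with a pseudo-inverse in the Mahalanobis
test). Second, an intercept is not identifiable on the simplex, so
regression uses the Scheffé parameterization: linear terms give the
expected response at pure blends, and binary/ternary product terms measure
departure from linear blending (synergy if positive, antagonism if
negative).

## Design generation

The candidate set for a special cubic fit is the p pure blends, C(p,2)
binary midpoints, and C(p,3) ternary centroids — exactly as many points as
the model has coefficients. D-optimal subsets are found by Fedorov point
exchange on log det(XᵀX) with 10 seeded random restarts; exchange ties
break by candidate index, making selection deterministic per seed. When
the requested support equals the candidate count (the default), selection
is the identity and the support is the full simplex-centroid-style set.

Lack-of-fit runs must lie off the support: the first is the overall
centroid (all components at 1/p), later ones equal blends of a random
subset of min(4, p) components, rejected until distinct from every
existing row. Replicates are drawn uniformly without replacement from the
unique runs, and the final run order is shuffled; all three uses of
randomness come from one seed. The default seven-taxon layout — 63
support + 2 lack-of-fit + 15 replicates = 80 runs, 65 unique
treatments — is the sizing used throughout the analysis scripts.

Proportions are serialized with 17 significant digits so that a written
design reads back bit-exactly, preserving both the simplex sum to within
1e-12 and exact equality between a replicate and its source run.

## The generative model

The simulator is the smallest mechanism able to produce both per-taxon
main effects and the pairwise blending effects the Scheffé models are
designed to detect. Template weights for a sample with prescribed
proportions x are

- cells: wᵢ = xᵢ · cᵢ · eᵢ · (1 + Σⱼ γᵢⱼxⱼ) · aᵢ · (1 + Σⱼ δᵢⱼxⱼ) · sᵢ
- dna:   wᵢ = xᵢ · (cᵢ/Gᵢ) · aᵢ · (1 + Σⱼ δᵢⱼxⱼ) · sᵢ
- pcr:   wᵢ = xᵢ · sᵢ

with cᵢ the 16S copy number, Gᵢ the genome size in Mb (a fixed share of
taxon mass in a DNA mixture carries fewer 16S templates when the genome is
larger), e/a/s strictly positive extraction, PCR, and
sequencing/classification efficiencies, and γ/δ zero-diagonal interaction
matrices. Counts are Multinomial(depth, w/Σw) after mean-one lognormal
jitter on w (independent per sample and taxon), so replicate runs differ
by technical noise only. Bias from non-viable cells cannot be separated
from extraction bias by this experimental contrast and is folded into eᵢ.

Defaults, chosen as the study conditions the package emulates:

- depth = 16,000 reads/sample (≈3.9 M reads over 240 samples);
- noise_cv = 0.03, sized so replicate median absolute error stays below
  the 5% technical-variation ceiling;
- `default` scenario: lognormal(0, 0.5) extraction and PCR efficiencies,
  sequencing factors lognormal(0, 0.025) (near identity, reflecting the
  small sequencing/classification stage), interactions 20% dense with
  magnitudes capped at min(0.5, 0.9/(p−1)) so 1 + Σγx stays positive on
  the whole simplex;
- `neutral`, `extraction_only`, `pcr_only` scenarios zero out the
  complementary parameters for stage-isolation tests.

What the generator does *not* emulate: read-level artifacts (quality,
chimeras, primer mismatch), misclassification between panel taxa, taxa
outside the panel, and any higher-than-pairwise interaction. Passing tests
therefore demonstrate that the estimators recover a multiplicative
first-order bias mechanism — not that real pipelines obey one. The
interaction magnitudes are stand-ins, not estimates of any particular
laboratory's system.

## Bias quantification

Counts are adjusted before normalization (cells: /cᵢ; dna: ·Gᵢ/cᵢ; pcr:
none); adjustment then normalization is invariant to rescaling a sample's
counts. Stage decomposition averages replicate runs within each experiment
before differencing, because experiments share treatment combinations, not
physical samples. Summaries (median, IQR, median absolute error) include a
taxon only for samples where its prescribed proportion is positive;
presence is defined by prescription, not observation, so a fully
suppressed taxon still contributes its (large) bias.

Technical variation is the median over replicate-group deviations from the
group mean — mean rather than median as the reference point, since most
groups are pairs where the two coincide.

Significance per stage uses the Mahalanobis distance of the mean
difference vector under the sample covariance (pseudo-inverse when
ill-conditioned, which is always the case for full-composition
differences), with a seeded percentile bootstrap over samples (default
10,000 resamples, 95% interval); bias is flagged significant when zero
falls outside the interval. Known limitation: a percentile interval on a
nonnegative statistic is anti-conservative near the null — with exactly
zero differences the interval collapses to [0, 0] and is correctly
non-significant, but small non-systematic noise can still exclude zero.
The test is best read as a yardstick for clearly non-zero stage bias, and
the per-taxon medians/IQRs remain the primary description.

## Mixture-effect models

Per-taxon fits are ordinary least squares without intercept on the special
cubic model matrix; coefficient t-tests come from the standard OLS
machinery. R² is reported about the response mean (1 − SSE/SST centered),
with the uncentered variant carried alongside, since no-intercept software
conventions differ and the two can diverge. Blending-term screening
applies Bonferroni within a model over its C(p,2) + C(p,3) blending terms
only — linear terms are main effects, not part of the screened family —
and orders significant terms by adjusted p-value.

Blending surfaces for a pair (i, j) average model predictions over a
uniform simplex lattice (default step 0.05) of the remaining p − 2
components scaled to 1 − xᵢ − xⱼ. Along the hypotenuse the average
collapses to the exact two-component value βᵢxᵢ + βⱼxⱼ + β_ij xᵢxⱼ. The
lattice average is a design choice; a Dirichlet-weighted average would
emphasize interior compositions differently.

## Inverse correction

The scaling factor x̂ᵢ/xᵢ is defined only where xᵢ > 0. One
RandomForestRegressor per taxon (500 trees, max_features = 2, seeded)
regresses the factor on the sample's full observed proportion vector.
Using *observed* proportions as predictors is a deliberate resolution of
an ambiguity: the factors are defined against actual proportions, but
actual proportions are unknowable for a clinical sample, so the model must
be usable from observations alone. Both correction orientations are
implemented — the default divides the observed proportion by the predicted
observed/actual factor (internally consistent with the response
definition); `actual_over_obs` multiplies instead, the literal
multiply-by-factor reading. Predicted factors are clipped to a 1e-6 floor
before division; taxa with zero counts stay zero; results re-normalize to
sum to one. Taxa observed in a sample but absent from the trained panel
are an error rather than silently dropped.

Cross-validation partitions samples (never individual observations, which
would leak a sample's other taxa into training) into k seeded folds and
reports per-taxon mean absolute error of corrected vs actual proportions
on the held-out samples.

## Problem sizes and numerical choices

The analysis scripts and test suite run the full 80-run, seven-taxon,
16,000-reads layout; asymptotic checks (stage isolation, parameter
recovery) use depth 1e5, and brute-force oracles for D-optimality and
surface averaging use p = 3–4 where exhaustive enumeration is exact. Unit
tests shrink forests to 10–100 trees where only behavior, not the default
accuracy, is under test; the defaults (500 trees, 10,000 bootstrap
resamples) are used where accuracy claims are asserted. Simplex membership
is validated at 1e-6 for model matrices (measured data) and 1e-12 for
designs (constructed data). Rank deficiency in fits is an error naming the
collinear columns rather than a silent pseudo-inverse, because a
rank-deficient mixture design is a design bug, not a numerical nuisance.
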