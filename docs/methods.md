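# Methods

## The analysis model

The package treats fish invasibility as a variance-explanation problem.
For a non-native species at *n* river sites, two response variables are
modelled: occurrence (presence/absence, binomial GLM with logit link) and
abundance (four-class ordinal recoding of density, Poisson GLM with log
link). The count treatment of the density classes is statistically unusual
but deliberate: raw densities are continuous, heavily zero-inflated and
long-tailed, and standardising each species to its own maximum and binning
into 0 / (0–10%] / (10–50%] / >50% gives a small-count response that a
Poisson family handles well. The Pearson dispersion (χ²/df) is checked on
every fit; above 1 the quasi families (identical point estimates, dispersion-
scaled inference, QAIC computed with the dispersion of the largest candidate
model) are used for reporting.

Explained deviance D = 1 − residual/null is decomposed over three predictor
sets — environmental (E), human pressure (P), spatial (S) — by fitting the
seven models on E, P, S, E∪P, E∪S, P∪S, E∪P∪S and applying
inclusion–exclusion (formulas in the README). The decomposition is exact:
the eight components sum to one algebraically, which the code asserts to
1e-10 on every fitted partition. Shared components can be negative when
predictors in different sets suppress each other; they are flagged and
reported as computed, because clamping at zero would silently break the
sum-to-one identity.

The spatial set is the cubic trend surface in site coordinates: x and y are
centred to zero mean (which reduces — not eliminates — collinearity between
successive polynomial terms) and expanded into x, y, xy, x², y², x²y, xy²,
x³, y³. Any planar projection works, since only relative positions enter.

**Selection before partitioning.** Within each of E, P and S a "minimal
adequate" subset is chosen by forward selection: starting from the
intercept-only model, the candidate with the lowest AIC is added provided
every VIF in the augmented design stays ≤ 3.0, stopping when no admissible
addition lowers the AIC; ties are broken by the larger single-step deviance
reduction, then lexicographically. Whether partitioning should operate on
selected subsets or full sets is genuinely open; selected subsets are the
default (matching the minimal-adequate modelling style) and `select=False`
switches to full-set partitioning. Candidates should first pass the
Spearman screen (|ρ| > 0.75, p < 0.05, drop the lower-priority member of
each offending pair) and the standard transforms — natural log(x+1) for
linear measurements, arcsin√x for proportions (percentages divided by 100
first). The log base is a convention choice; the natural log is used
throughout.

One important caveat: AIC forward selection admits a no-effect candidate
whenever its deviance drop exceeds 2, which for a χ²₁ variable happens with
probability ≈ 0.157. With ten independent noise candidates the probability
of stopping at the intercept-only model is therefore only ≈ 0.84¹⁰ ≈ 0.18.
Forward-AIC selection is anticonservative on wide candidate lists by
construction; the VIF cap controls redundancy, not false inclusion.

## Pressure scoring

Ten ordinal criteria are scored 1 (minimal) to 5 (maximal disturbance);
their sum is the total human pressure (10–50). A site is *reference* iff
all scores are ≤ 2 with at most one 3. Chemistry measurements (BOD5, COD,
TSS, SRP, NO2, NO3, NH4, total inorganic N) complement the evaluation as
GLM covariates but never enter the sum. The five quality classes bin the
total; no canonical boundaries exist for this binning, so the default is
equal-width bins over [10, 50] — High [10, 18), Good [18, 26), Moderate
[26, 34), Poor [34, 42), Bad [42, 50] — which is monotone, partitions the
range, and places every possible reference site in High or Good (verified
exhaustively in the tests). The boundaries are a configurable parameter,
not ground truth.

## Nonparametric tests

The rank-transformation ANCOVA fits an ordinary ANCOVA (group + covariate)
after replacing both response and covariate by midranks, testing the group
factor on (g−1, n−g−1) df. Ranking the covariate along with the response
follows the literal rank-transform reading; a constant covariate is dropped
(the test then reduces exactly to one-way ANOVA on ranks with df n−g).
Mann-Whitney uses midranks, a tie-corrected normal approximation without
continuity correction, and an exact mode (full enumeration of the
permutation distribution of U, valid under ties) automatically engaged at
n1+n2 ≤ 12. The two-proportion Z test uses the pooled-variance form. All
tests are two-sided; no multiplicity correction is applied across the
battery. PCA for the environmental-gradient covariable operates on the
correlation scale (z-scored variables), with the sign fixed so the largest-
magnitude loading is positive.

## The synthetic-data generator

The generator reproduces the *design* of the survey the analysis assumes:
380 sites in 12 river types (28, 60, 68, 20, 28, 16, 33, 26, 33, 22, 37, 9
sites per type), each type characterised by published means/SDs of mean
annual temperature, precipitation, altitude and drainage area. Draws are
independent truncated normals per type (only marginal moments are
published); an optional 4×4 correlation matrix induces cross-variable
correlation through a Gaussian copula, default identity. Truncation at
physical bounds (area > 0, altitude ≥ 0, precipitation ≥ 0) means that for
types whose bound sits within ~2 SD of the mean the realised moments are
the truncated-normal moments, not the nominal ones (e.g. altitude 413 ± 242
truncated at 0 gains ≈ 24 m of mean); the tests assert convergence to the
analytic truncated moments, and to the nominal values where the bound is
> 3.5 SD away.

Pressure profiles come from a latent per-site disturbance intensity
u ∈ [0, 1]: a configurable fraction of sites (default 198/380, the
disturbed share of the survey) draws u ~ U(0.2, 1), the rest
u ~ U(0, 0.08), and each of the ten scores is 1 + Binomial(4, u). This
yields the full gradient from all-1 profiles to all-5 profiles and roughly
the survey's reference/disturbed split after classification. Chemistry
covariates are lognormal with log-scale means increasing in u. Coordinates
are uniform on the unit square — real geography is irrelevant to testing
the trend-surface machinery.

Densities follow a zero-inflated log-linear model: log λ is an intercept
(default 0.5, ≈ 1.6 ind./100 m², a realistic per-species site density for
these assemblages) plus user-chosen coefficients applied to *z-scored*
predictors (so effect sizes are comparable across units); realised counts
are Poisson(λ) masked by an independent Bernoulli zero with probability
`zero_inflation_prob`. Zero inflation independent of covariates is the
simplest mechanism producing the zero-richness of real density tables.

What the generator does **not** emulate: inter-variable correlations of
real catchments (altitude–temperature–precipitation covary strongly in
nature), confounding between pressure and environment (real disturbance
concentrates in lowlands; the simulator draws them independently, which
makes recovery experiments cleaner but easier than reality), species
interactions, spatially autocorrelated residuals, and sampled-area
variation (densities are emitted directly rather than as counts over a
recorded area). Passing recovery tests therefore demonstrates correctness
of the machinery, not robustness to confounded field data.

## Numerical choices

- GLM fitting: IRLS (statsmodels), relative tolerance 1e-8, 100 iteration
  cap; non-convergence and separation are flagged and abort the partition
  with the offending sub-model named.
- Listwise deletion over the union of all sets' columns before a partition,
  so all seven deviances refer to the same rows.
- Midranks for all ties; Mann-Whitney exact-mode tail comparisons use a
  1e-12 guard against floating-point fuzz on midrank sums.
- VIF of a single-column design is 1 by convention; R² ≥ 1 − 1e-12 reports
  an infinite VIF.
- Density-class boundaries at exactly 10% and 50% fall to the lower class,
  making the four classes a partition of [0, 1].
- Empty predictor sets are legal: their models are intercept-only (D = 0)
  and the partition degrades exactly to the two-set (or one-set) formulas.

## Problem sizes used in the test and acceptance runs

Recovery experiments use 20 replicates of 504 sites (42 per type) per
effect structure; test-calibration experiments use 2 000 null simulations
per test (n = 60, three groups for the ANCOVA; n = 200 per group,
p = 0.3 for the Z test); selection-behaviour experiments use 100 runs of
n = 500 with 10 candidates. The full default suite plus the acceptance
script runs in well under five minutes on one CPU.

## Known limitations

- The REFCOND-style class boundaries are a package default, not a published
  standard; analyses sensitive to the binning should sweep them.
- Forward-AIC selection is anticonservative on pure noise (see above); a
  stricter entry rule (e.g. BIC or a p-value threshold) is deliberately not
  the default because AIC-minimality defines the intended model search.
- The density-class Poisson treatment discards within-class abundance
  information; it is the analysis contract, not a recommendation for
  contexts where proper zero-inflated or negative-binomial models are
  feasible.
- QAIC uses the dispersion of the model being reported rather than a
  global ĉ unless the caller supplies one; with all observed dispersions
  below 1 in the intended use, the quasi path mostly exists for
  completeness.
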