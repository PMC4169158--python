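# Methods

## The question

Per-site mutability models are routinely validated by binning the
genome on the predicted mutability index (MI), counting de novo
mutations (DNMs) per bin, and correlating `log(d/n)` with MI. Because a
width-10 MI bin contains between ~10⁶ and ~10⁸ sites while DNM studies
contribute only hundreds to thousands of mutations, that validation
averages per-site rates over enormous numbers of sites. `mutvar`
quantifies two consequences: (i) how much per-site rate variance could
remain unexplained without degrading the binned correlation, and
(ii) how much single-nucleotide ("cryptic") rate variation the
two-species coincident-SNP excess demands.

## Binned log-linear regression

Sites are aggregated into half-open MI bins `[lo, lo+w)` (default
`w = 10`) tiling the track's MI range; a bin records the site count
`n`, the DNM count `d`, and the site-count-weighted mean MI (`mi_mid`).
Bins with `d ≤ 5` are dropped before fitting — counts that small make
`log z` too unstable — and so, a fortiori, are bins with `d = 0`, where
the log rate is undefined.

The fit is weighted least squares of `log_b(d/n)` on `mi_mid`
(default base 10; the base is carried in the fit object so all
downstream rate predictions invert consistently). Three weighting
schemes are provided:

- **expected** (default): a two-stage fit. A first pass weighted by
  the observed counts yields expected counts `Z` per bin; the final
  pass weights each bin by the inverse of the known delta-method
  variance of the log rate under Poisson counts,
  `Var[log_b z] = (1/Z + 1/(2Z²)) / ln²(b)`, and the coefficient
  covariance uses that known variance rather than an estimated
  residual scale. Weighting by the *expected* count matters: an
  observed count is positively correlated with its own residual, so
  naive `d`-weighting tilts the fit and, combined with a residual
  scale estimated from ~10 points, makes 2-SE intervals
  anti-conservative. In repeated synthetic studies (650 DNMs, 12
  bins) the expected-weight scheme covers the generating slope within
  2 SE at the nominal ~95% rate, versus ~94% for `d`-weights.
- **dnm**: weight by the observed count `d` (the first-order inverse
  variance of `log z`), residual scale estimated — kept for
  sensitivity analysis.
- **equal**: ordinary least squares.

The Pearson correlation `r` is computed on the same binned
`(MI, log z)` pairs that are plotted and regressed, not per site. A
constant response returns a flagged degenerate fit (slope 0, `r`
reported as 0) rather than an error.

`fit_quadratic` adds an MI² term and reports its two-sided p-value;
`compare_slopes` tests two independent fits with
`z = (b₁−b₂)/√(se₁²+se₂²)`; `bootstrap_fit` resamples *bins* with
replacement (replicates with fewer than three distinct MI values are
redrawn, so every refit is identifiable).

## The hidden-variance engine

Given fitted coefficients and the per-bin site counts, the expected
count at MI `x` is `Z(x) = n·b^(a+b·x)`. One simulated dataset draws,
per bin, a mean-one lognormal factor with variance ϒ/n and then a
Poisson count with that inflated mean. The rationale: if each *site*
carries an unexplained mean-one rate factor with variance ϒ, the mean
of `n` such factors is itself approximately lognormal with variance
ϒ/n, so a single per-bin factor reproduces the bin-level effect of
per-site variance. The law of total variance gives
`Var(count) = Z + Z²·ϒ/n`, which the tests verify directly.

`run_table1` computes the observed correlation, simulates `n_reps`
datasets (default 1000), drops any replicate with a zero-count bin
(reported in `n_dropped`), and returns the proportion of kept
replicates whose correlation *strictly* exceeds the observed one.
By default each replicate first refits the regression on a bootstrap
resample of the bins, propagating the uncertainty in the rate/MI
relationship into the simulation; a flag disables this for variance
decomposition. `upsilon_sweep` runs one row per ϒ on independent
child streams of the master seed, so results are reproducible and
independent of sweep order.

A mean-one variate with variance ϒ has coefficient of variation √ϒ
(`cv_of_lognormal`); ϒ = 10⁵ corresponds to a CV above 300, which is
why the sweep's flat region is scientifically striking.

### Lognormal parameterization

All mean-one lognormal factors with variance V use the unique
parameterization `σ² = ln(1+V)`, log-mean `−σ²/2`. V = 0 short-circuits
to exact ones and consumes no random draws, so the ϒ = 0 path is
bit-identical to pure Poisson sampling under the same seed.

## Coincident-SNP gamma theory

Site rates γ are modelled as mean-one gamma with shape α (scale 1/α,
variance 1/α); v is the divergence per site between the species
(defaults 0.0092 non-CpG, 0.092 CpG, overridable). The per-site
coincidence kernel

    K(γ) = e^(−vγ)·γ² + (1 − e^(−2vγ))

combines the double-hit route (independent SNPs in both species at a
site that has not destroyed itself by substituting — hypermutable sites
self-destruct, hence the e^(−vγ) factor) with a term for sites that
have undergone a substitution. The coincidence probability is
`u_h·u_c·E[K(γ)]`; the SNP-density prefactor cancels from every ratio
used and is carried only in the Monte-Carlo generator.

Quantities:

- **excess ratio** `E[K(γ)]/K(1)` — how much rate variation inflates
  coincidence over a uniform-rate genome. This is the quantity equated
  to the observed excess (the published excesses are already corrected
  for adjacent-nucleotide context, so the uniform-rate baseline is the
  correct denominator). It tends to `E[γ²] = 1 + 1/α` as v → 0 and to
  1 as α → ∞.
- **mean fold-hypermutability Q** — the average γ of coincident-SNP
  sites. The default estimator γ-weights the double-hit term only,
  `Q = E[e^(−vγ)γ³ + 1 − e^(−2vγ)] / E[K(γ)]`; this is the form behind
  the quoted 1.40×/2.71× estimates. A fully size-biased variant
  (`weighting="full"`, `Q = E[γ·K(γ)]/E[K(γ)]`) is provided for
  sensitivity and gives slightly larger folds (1.43/2.72 on the same
  inputs). Both reduce to `E[γ³]/E[γ²] = (α+2)/α` as v → 0 and to 1 as
  α → ∞.

### Numerics

Gamma expectations are evaluated with adaptive quadrature on the
probability scale, `∫₀¹ f(F⁻¹(u)) du` (relative tolerance 1e−10),
which folds the density in analytically and conditions the integral
equally well for a near-point-mass (α ~ 10⁹) and a heavy-tailed
(α ≪ 1) mixing distribution. Closed-form gamma moments
`E[γᵏe^(−cγ)] = Π_{i<k}((α+i)/α)·(1+c/α)^(−(α+k))` serve as an
independent oracle in the tests, never as the computation path.

Shape inversion (`fit_shape`) root-finds on log α. The excess ratio is
not monotone over all of (0, ∞) — it collapses toward 0 as α → 0
because the gamma mass piles up where the kernel vanishes — so the
solver works on the physically relevant decreasing branch (α at or
above the argmax, located by a coarse log-grid scan when needed).
An excess ≤ 1 or above the branch maximum raises a ValueError.
Confidence intervals on the excess map through the monotone
composition excess → α → Q endpoint-by-endpoint, which is exact.

## Synthetic data

The generators produce inputs with exactly the statistical structure
the analyses assume, no more:

- **MI tracks**: a Gaussian mixture discretized to integer MI by CDF
  differences, truncated and renormalized to the requested range, with
  site counts allocated by one multinomial draw (total exact). The
  real genome's MI distribution is not public, so the mixture is
  illustrative; analyses depend on it only through the per-bin site
  counts.
- **DNM datasets**: per-site rates `b^(a+b·MI)`, rescaled so the
  expected total matches the requested study size; optional per-site
  mean-one lognormal factors (variance ϒ_true) before Poisson
  sampling; optional MI-dependent retention thinning to emulate
  under-ascertainment in mutable regions. Chromosome and position are
  opaque labels — nothing downstream uses coordinates.
- **Two-species SNP tables**: γ per site from the mean-one gamma;
  coincidence drawn directly from the kernel probability
  `u_a·u_b·K(γ)`. The kernel *is* the model under test, so sampling it
  is the faithful Monte-Carlo realization of the theory rather than a
  circular shortcut; a full mutation-history simulation is out of
  scope. Single-species SNP flags are filled in by a simplistic,
  mutually exclusive `u·γ` thinning purely so tables look realistic —
  only the coincidence probability carries the model, and marginal SNP
  densities should not be interpreted.

What the generators deliberately do not emulate: real sequence
context, the MI predictor itself, linkage between neighbouring sites,
ancestral polymorphism or selection at coincident sites, and the
true (unknown) genome MI distribution. Passing tests therefore
demonstrate the internal consistency and statistical calibration of
the methods, not the accuracy of any particular published dataset.

## Study conditions used in the tests

The simulation checks run on a synthetic study chosen to mirror the
real analyses' scale: ~650 DNMs (the size of the dataset the MI model
was trained on), 12 width-10 MI bins, generating slope 0.01 per MI
unit in log10, and 10⁷ sites per bin for the hidden-variance
experiments (a width-10 bin of a 3×10⁹-site genome spanning ~160 MI
units holds 10⁶–10⁸ sites). Monte-Carlo checks of the quadrature use
10⁷ gamma draws; simulation sweeps use 1000 replicates, matching the
engine's default.

## Known limitations

- The two-stage expected-count weighting assumes the Poisson count
  model is correct; with strong overdispersion *within* bins the
  standard errors are again optimistic (that is precisely the
  scenario the hidden-variance engine is for).
- The bootstrap resamples bins, not raw DNMs; with ~12 bins the
  bootstrap distribution is coarse.
- `fit_shape` treats the observed excess as exact apart from its CI;
  uncertainty in the divergence v is not propagated.
- The permutation test in `compare_mi_sets` is exact only up to its
  `1/(n_perm+1)` resolution.
- Sample-variance assertions on heavy-tailed lognormal mixtures
  (factor variance ≫ 1) are made as order-of-magnitude checks; the
  variance estimator itself is unstable there, and tests document
  this rather than pretending otherwise.
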