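# Methods

## The model

The package analyses the allometry of maximum growth rate across
vertebrate groups.  For each species the observation is a pair derived
from a fitted sigmoid growth curve:

* **AGR** — maximum absolute growth rate (g/day), the peak of dM/dt,
  attained at the curve's inflection point;
* **BMatMG** — body mass at maximum growth (g), the mass at that
  inflection point.

The regression model, per taxonomic group, is

    log10 AGR_i = b0 + b1 * log10 BMatMG_i + e_i,
    e ~ N(0, sigma^2 * C_lambda)

where `C` is the Brownian-motion covariance of the group's phylogeny
(`C_ij` = shared root-to-MRCA branch length) and `C_lambda` has its
off-diagonal multiplied by Pagel's lambda.  lambda = 0 is an ordinary
regression; lambda = 1 the full Brownian expectation.  Two mean structures
are fitted: a free slope `b1`, and `b1` fixed at 0.75, the value predicted
by metabolic scaling theory.  The fixed-slope intercept back-transforms to
the *normalization constant* `10^b0`, the predicted growth rate (g/day) of
a 1-gram mass at maximum growth, which is the quantity compared across
groups.

## Growth-model standardization

Published growth constants `k` come from three sigmoid families whose
inflection sits at different fractions of asymptotic mass `A`:

| family          | mass curve                      | BMatMG / A | AGR            |
|-----------------|---------------------------------|-----------:|----------------|
| logistic        | `A / (1 + e^{-k(t-t0)})`        | 1/2        | (1/2) k·BMatMG |
| Gompertz        | `A·exp(-b e^{-kt})`             | 1/e        | k·BMatMG       |
| von Bertalanffy | `A (1 - (1/3) e^{-kt})^3`       | 8/27       | (3/2) k·BMatMG |

The von Bertalanffy curve is the *cubed mass* form; the name is attached
to several parameterizations in the literature, and only this one is
consistent with an inflection at (8/27)·A and the 3/2 multiplier.  Note
that with the 1/3 coefficient the inflection sits at t = 0 and the curve
extends back to t = -ln(3)/k; the numerical inflection locator searches
that extended domain.

Conventions (configurable, logged where they matter):

* Yearly and monthly rate constants convert to daily with 365 days/year
  and 365/12 days/month.
* Species with several records are collapsed to arithmetic means of AGR
  and BMatMG on the linear scale; logs are recomputed from the means.
  Dinosaur growth series are exempt — every (mass, rate) point is kept as
  its own observation.
* Directly measured rates (fastest-interval estimates rather than fitted
  constants, as for the classical reptile compilations) pass AGR through
  unchanged but must declare an `assumed_family` (von Bertalanffy for
  those reptile data) to place BMatMG; the package refuses to default
  silently.
* Species names are matched between tables and trees after trimming,
  whitespace/underscore collapsing and case-folding.

## Estimation

Maximum likelihood throughout — not REML — so AIC values are comparable
across mean structures (free vs fixed slope), which is exactly the
comparison the analysis makes.  For fixed lambda, coefficients and sigma^2
have closed forms; lambda is profiled over the positive-definite feasible
interval of `C_lambda` (determined by bisection with a Cholesky probe):
a 201-point grid, then Brent refinement between the grid optimum's
neighbours.  The fit asserts that refinement never falls below the grid.
Flat profiles (within 1e-8, e.g. a star tree) warn and report the
smallest-magnitude lambda.

The feasible interval extends below 0 and above 1 on most trees, and
negative estimates do occur in comparative data; `restrict_lambda=True`
confines the search to [0, 1].  Bounds are clipped to ±10 when the
covariance is diagonal (lambda then drops out entirely).  Trees with
duplicate (identical-twin) tips make `C` singular at lambda = 1 and are
rejected with advice to drop a tip.

Standard errors and 95% CIs are Wald t intervals conditional on the
estimated lambda (no lambda uncertainty is propagated), with
`sigma^2_unbiased = RSS_gls / (n - q)` and `t(n - q)` quantiles, q = number
of mean parameters (2 free, 1 fixed).  AIC counts p = 4 (pgls, free),
3 (pgls, fixed), 3 (ols, free), 2 (ols, fixed) — coefficients + sigma^2 +
lambda where applicable.  p-values are two-sided t tests against zero,
reported but not used for decisions.

Numerical notes: the GLS quadratic form is computed from the residual
itself (`r' V^-1 r`), not the algebraically equal shortcut `r' V^-1 y`,
which loses precision to cancellation on near-perfect fits; a fit whose
sigma^2 falls below 1e-24 of the response's mean square is flagged as a
degenerate perfect fit (infinite likelihood, zero-width intervals).

## Group fits and comparisons

`fit_group` runs all four variants.  OLS uses every record; the
phylogenetic fits use the records whose species match a tree tip (species
missing from the tree are reported and retained for OLS).  Groups that
keep multiple records per taxon (dinosaurs) get a record-level covariance
by expanding each matched tip into per-record leaves on short terminal
branches — 1e-6 of tree height by default, not exactly zero, so the
covariance stays positive definite at lambda = 1; the records of one taxon
then share that taxon's full covariance.  How multi-point growth series
should map onto tree tips has no canonical answer; this expansion is one
documented choice, not a claim of equivalence with any published analysis.

Cross-group comparisons use the fixed-slope fits: CI-inclusion flags in
both directions (is A's intercept inside B's 95% CI? — asymmetric by
construction), fold differences `10^(b0_A - b0_B)`, a ranking by
intercept, and residual variation (residual + intercept per species,
summarized with median/quartiles/1.5×IQR whiskers — the R box-plot
default).  Two "statistically different" rules are implemented: the
default *either* rule (some coefficient outside the other model's CI, in
either direction, intercept and/or slope) and a stricter *both* rule
(each intercept outside the other's CI).

A Boltzmann-factor utility `exp(-E/(k T_a)) / exp(-E/(k T_b))` (defaults
E = 0.63 eV, k = 8.6173324e-5 eV/K, T_a = 314 K, T_b = 309 K) expresses
the metabolic ratio expected from body-temperature difference alone, for
contrast with the observed growth-rate folds.

## The synthetic generator

Real inputs are trait compilations plus published phylogenies; the
generator emulates their statistical structure so the pipeline is testable
end to end:

* **Trees** — pure-birth (Yule) trees via dendropy's birth–death
  simulator.  The simulator stops at the n-th birth event, which leaves
  the two newest tips as zero-length twins; terminal branches are extended
  by the Exp(n·birth_rate) holding time of the n-lineage interval, giving
  a well-conditioned ultrametric tree.
* **Traits** — log10 BMatMG uniform over a per-group mass range (log10 g);
  residuals multivariate normal with covariance `sigma2 * R_lambda`, where
  `R_lambda` is the lambda-transformed Brownian matrix normalized to unit
  diagonal.  sigma2 is therefore the *marginal* per-species residual
  variance on the log10 scale, independent of tree height — the same
  variance × correlation factorization a Pagel correlation structure uses.
  If a group's target lambda falls outside a sampled tree's feasible
  interval (possible for negative targets) it is pulled 10% inside the
  bound and the effective value recorded in the truth file.
* **Raw records** — standardized pairs are inverted algebraically to
  (family, k, adult mass) records; re-standardizing reproduces the inputs
  to floating-point accuracy.

Defaults are the study conditions of published vertebrate growth
allometries: seven groups with sample sizes 343/164/299/21/19/35/30,
fixed-slope intercepts from −0.506 (altricial birds) to −2.512 (fishes),
lambdas from −0.124 to 0.943, slope 0.75, and a dinosaur group of 19
records over 7 taxa to exercise the no-aggregation path.  Default
sigma2 = 0.01 (residual sd 0.1 log10 units) was calibrated so simulated
fixed-slope intercept CI widths match those published for the largest
group; both a CI-width and an AIC back-calculation give ~0.010–0.0125.
Mass ranges are uniform in log10 (true mass distributions are unreported;
a log-normal option would be a one-line change in the sampler).

What the generator does **not** emulate: real taxonomies and names,
non-Yule tree shapes, measurement error in k, non-uniform mass sampling,
and group-specific residual variances.  Passing tests therefore show the
estimator and pipeline are correct and calibrated under the assumed model,
not that any particular biological dataset satisfies those assumptions.

A consequence of phylogenetic signal worth knowing when interpreting
recovery tests: under lambda near 1 the intercept behaves like a root
state whose uncertainty does *not* vanish as tips are added (empirical sd
~0.04–0.06 log10 units at these settings).  Recovery of the intercept is
therefore checked as unbiasedness plus near-nominal CI coverage rather
than as a fixed absolute error.

## Problem sizes in tests

The test suite runs the full seven-group fixture once end to end, a
200-replicate slope-recovery study at n = 100 tips, likelihood-grid
cross-checks on trees of ≤ 6 tips, and 50 000-replicate Brownian
simulations on small trees; together they complete in a few minutes on a
single CPU.  All randomness is seeded; reruns are byte-identical.

## Known limitations

* Only the Pagel-lambda correlation structure is supported (no OU,
  Blomberg's kappa or ACDC), and no measurement-error model.
* CIs condition on the estimated lambda; lambda uncertainty is not
  propagated (gls-style intervals).
* In fixed-slope fits the profile likelihood can have a pole at the lower
  lambda-feasibility boundary: the vanishing eigenvector of `C_lambda`
  there is nearly constant, so the intercept absorbs it, the quadratic
  form stays finite while `log det` diverges, and the estimated intercept
  variance collapses.  Groups whose lambda is driven to that boundary
  (small groups with weak or negative signal) then print near-zero-width
  intercept CIs.  Published tables of this analysis show exactly this
  artifact in their marsupial row; it is a property of boundary ML, not a
  bug, and `restrict_lambda=True` (lambda in [0, 1]) avoids it.
* The pipeline does not fit growth curves to longitudinal data; it
  consumes published constants (the inverse generator exists only in the
  synthetic module).
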