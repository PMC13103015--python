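# Methods

## The bivariate trajectory-association model

Each (protein, echo) pair is modeled jointly.  Writing $P$ for the
log-transformed protein and $E$ for the echocardiographic variable, the
stacked response of patient $i$ is multivariate normal,

$$\mathbf{y}_i \sim N\!\big(X_i\boldsymbol\beta,\; Z_i D Z_i^\top + R_i\big),$$

with outcome-specific fixed effects (intercept, age in years, a female
indicator, and a 2-df natural-spline basis of months since the index
event), outcome-specific random-effect designs stacked block-wise in
$Z_i$, a joint random-effects covariance $D$, and a diagonal residual
covariance $R_i$ holding $\sigma_P^2$ or $\sigma_E^2$ per row.  Residuals
of the two outcomes are independent given the random effects, including
when both are measured at the same visit; any shared subject-level
variation is carried entirely by the off-diagonal block of $D$.  Patients
observed on only one outcome still contribute: their likelihood simply
carries no cross-block information.

The association null hypothesis is $D_{PE} = 0$.  Both models are fitted
by full maximum likelihood (not REML — the fixed-effects design is
identical under both hypotheses, and ML keeps the likelihood comparison
unambiguous) and compared by $\Lambda = 2(\hat\ell_{\text{full}} -
\hat\ell_{\text{null}})$ against $\chi^2$ with $q_P\,q_E$ degrees of
freedom.  The constrained covariances are interior points of the parameter
space (the null pins cross-covariances, not variances), so no boundary
mixture correction applies.

### Spline basis

The time basis is a natural cubic spline with two degrees of freedom:
boundary knots at the minimum and maximum observed measurement times of
the variable, one interior knot at the median of the observed times
counted with multiplicity.  Knots are placed per variable because the
visit grids differ (echo 0/3/12, proteins 1/3/12 months).  The basis is
the truncated-power construction with the natural constraint absorbed; it
spans the same space as any standard natural-spline basis (verified
against R `splines::ns` by comparing projection matrices), and every model
quantity used downstream is invariant to the choice of basis within that
span.  Extrapolation beyond the boundary knots is exactly linear.

With fewer than three distinct observation times no spline basis exists;
the fixed-effect time trend then degrades to linear (or, with a single
time point, to none) and spline random structures are excluded.

### Estimation

The fixed effects are profiled out of the marginal likelihood by
generalized least squares, leaving an optimization over
$(\log\sigma_P, \log\sigma_E)$ and the log-Cholesky factor of $D$ (log
diagonal, free off-diagonal; per-block factors under the null).  The
objective and its *analytic* gradient — envelope theorem at the profiled
$\hat\beta$, trace identities $\partial\ell/\partial L = (Z^\top M Z)L$
with $M = \sum_i (V_i^{-1} - V_i^{-1} r_i r_i^\top V_i^{-1})$ — are fed to
L-BFGS-B.  Patients sharing an observation pattern share $V_i$, so the
per-pattern Cholesky factorization and triangular solves are batched
across patients; with the study's visit grids a cohort has at most a few
dozen patterns, which is what makes 500-replicate calibration studies and
multi-thousand-fit screens affordable on one CPU.

The null (block-diagonal) model is fitted as two independent
single-outcome ML fits and reassembled; this is exactly equivalent because
the joint likelihood factorizes over outcomes under the constraint.  The
full fit is warm-started from the null solution, which also guarantees the
nesting inequality $\hat\ell_{\text{full}} \ge \hat\ell_{\text{null}}$ up
to optimizer tolerance.

**Convergence contract.**  A fit converges iff the optimizer reports
success, the relative gradient norm
$\|\nabla\|_\infty / (1 + |\ell|)$ is below $10^{-4}$, the log-likelihood
is finite, and the condition number of $\hat D$ is below $10^{10}$ (a
random-effect variance collapsing to the boundary fails this, which is how
overparameterized structures are detected).  On failure, up to two
randomly perturbed restarts are tried before the candidate is declared
non-converged.

### Fallback ladder and FDR

Structures are tried in the order (splines, splines), (splines, slope),
(slope, splines), (slope, slope), (splines, RI), (RI, splines),
(slope, RI), (RI, slope), (RI, RI) — protein-side reduction first within a
tier; the order is configurable.  A candidate is skipped without fitting
when its structure is not identifiable from the visit grid: a structure of
dimension $q$ requires at least $q$ distinct cohort observation times and
at least one patient with more than $q$ observations of the variable
(otherwise subject-level and residual variance cannot be separated).  Data
with one visit per patient therefore exhaust the ladder and are reported
as non-converged, without a test.

The LRT is taken at the first candidate whose full *and* null fits both
meet the contract.  Benjamini–Hochberg is applied per echo variable over
the converged pairs (a pooled family is available by config); pairs
without a test are excluded from the family size and reported as such.
Per-pair optimizer randomness is seeded by a stable hash of the pair ids
mixed with the run seed, so screen results are independent of processing
order and bitwise reproducible.

### Direction summary

Random spline effects carry no natural sign, so each association's
direction is summarized by the Spearman correlation between within-patient
means of the echo variable and of the log-protein, with a Fisher-z 95%
interval using standard error $1/\sqrt{n-3}$.  Z-scoring marker means (a
plotting convention) cannot change a rank correlation; the descriptives
module asserts this identity rather than trusting it.

## Descriptive layer

Univariate trajectories use the same design conventions with a single
outcome block; the modeled mean is the population-average prediction at
the sample mean age and sex proportion, and the modeled SD is the marginal
one, $\sqrt{z(t)^\top \hat D z(t) + \hat\sigma^2}$ — between-patient plus
residual — with eval times outside the observed range flagged as
extrapolation.  Paired t-tests of change from discharge use raw
measurements matched to nominal visits within ±0.5 month, not modeled
values.

## Synthetic cohorts

The generator draws from the model above with known truth: default 246
patients, ages Uniform(40, 80), 19% female, echo at 0/3/12 months and
proteins at 1/3/12 (baseline protein draws are disallowed by
construction, mirroring the acute-phase exclusion: post-MI inflammation
makes baseline protein levels unrepresentative of chronic remodeling).
Protein trajectories are simulated on the natural-log scale and
exponentiated, so the pipeline's log-transform is exercised end to end.
Echo random effects are drawn first; a coupled protein's random intercept
is drawn conditionally on its partner's so the pair attains the configured
correlation $\rho$ while all other random-effect dimensions stay
independent.  Missingness is visit-level by default (one Bernoulli per
patient × time × modality, rate 0.05 — consistent with per-visit echo
availability of roughly 93–99% in cohorts of this kind) with a
measurement-level alternative.

Default echo population curves rise-then-flatten for AV and LVEDV and
recover for LVEF, anchored to modeled means typical of a first anterior
MI cohort (AV ≈ 20.5→25.4 mL/m², LVEDV ≈ 52→62 mL/m², LVEF ≈ 49→55%);
fixed effects in the recovery-study configuration are sized to be
clearly detectable at the design scale (every generating coefficient at
least ~3 per-replicate standard errors from zero), so recovery failures
indicate estimator bias rather than pure sampling noise.  What the
generator does *not* emulate: assay batch effects, aptamer
cross-reactivity, informative dropout, heavy-tailed residuals, or
residual correlation between outcomes measured at the same visit.
Passing calibration and recovery on these cohorts certifies the
machinery under its own assumptions; it does not certify robustness to
those violations on real data.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute:

* **Likelihood exactness** — pattern-batched evaluation vs a dense
  per-patient multivariate-normal density on 50 random small instances
  (agreement well below 1e-8).
* **Null calibration** — 500 replicates, n=150, complete 3-visit grids,
  random intercepts both sides: empirical rejection at α=0.05 should sit
  in the binomial band [0.030, 0.075].
* **Parameter recovery** — 100 replicates at n=300, ρ=0.6: median
  |ρ̂−ρ| ≤ 0.08; replicate-averaged fixed effects and residual variances
  within 10% of truth (averaging isolates bias from sampling noise).
* **Screen FDR/recall** — cohorts of 250 patients, 100 proteins with 10
  true couplings at ρ=0.7 over 20 generated cohorts (the acceptance test
  uses 6 cohorts of 60 proteins, same 10% prevalence): empirical FDR at
  q<0.05 stays below 0.10 with recall above 0.8.  These study sizes are
  the package's chosen validation scale; random-intercept structures are
  used throughout so the measured error rates are not confounded by
  ladder descent.
* **Determinism** — the full simulate→transform→screen→write pipeline run
  twice with one seed is byte-identical.

## Known limitations

* Residual covariance is diagonal; serial within-outcome correlation and
  same-visit cross-outcome residual correlation are not modeled.
* ML (not REML) variance estimates carry the usual small downward bias at
  small n; at the validation scales this is within the stated bands.
* The χ² reference for the cross-block LRT is asymptotic; at very small
  cohort sizes the calibration band is not guaranteed.
* The fallback ladder's order is a convention; data equally well fitted
  by several structures may be reported under different structures than
  another ordering would give (the LRT within any converged structure
  remains valid).
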