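# Methods

## Model and decomposition

The outcome is binary institutional delivery, modeled per residence group
$j \in \{U, R\}$ as $P(y=1 \mid x) = F(\beta^{j\top} x)$ with $F$ the
logistic CDF (default), the standard normal CDF, or the identity (linear
probability model). Groups are fit separately by maximum likelihood (OLS for
the linear link); the decomposition is a functional of the two fitted
coefficient vectors and the two group design matrices.

All components are built from counterfactual means
$m(\beta, X) = \tfrac1n\sum_i F(\beta^\top x_i)$. The three-fold
decomposition prices endowment differences with a reference group's
coefficients (urban or rural); the two-fold version prices them with the
blend $\beta^* = \omega\beta_U + (1-\omega)\beta_R$ and splits the remainder
into urban advantage $m(\beta_U,X_U) - m(\beta^*,X_U)$ and rural
disadvantage $m(\beta^*,X_R) - m(\beta_R,X_R)$. Components sum to the total
gap *by construction*, and result objects enforce the identity at 1e-10 —
a violated identity is a bug, never a rounding note.

Two printed-rows conventions are worth making explicit:

- Under the logit and linear links the decomposition total equals the raw
  difference in observed group means exactly (the score equations force the
  mean fitted probability to equal the observed rate per group). Probit
  matches only approximately; the discrepancy is the sum of the two groups'
  mean-residual terms and is typically <1e-3 at survey sizes.
- The urban-reference explained minus the rural-reference explained equals
  the rural-reference interaction, exactly, by algebra. This is the identity
  that lets three-fold results under both references be reported coherently.

**Scheme weights.** Oaxaca $\omega=1$, Blinder $\omega=0$, Reimers
$\omega=0.5$, Cotton $\omega = n_U/(n_U+n_R)$. The Cotton weight is computed
from the estimation sample after missing-data and window exclusions, since
that is the sample whose coefficients it blends; when a published analysis
reports the complementary (rural-share) weight, that is `1 - omega`.

## Detailed decomposition of the explained component

The explained component is allocated across covariate groups with
linearization weights $W_k = \Delta\bar x_k\beta^*_k / \sum_j \Delta\bar
x_j\beta^*_j$ evaluated on the index scale, then
$\text{contribution}_k = W_k \times \text{explained}$. For the linear link
this reduces to the exact per-term split $\Delta\bar x_k \beta^*_k$; for
logit/probit it is the standard first-order allocation for non-linear
decompositions. The residual is zero by construction and is reported as a
numerical audit. Only the explained component is decomposed per covariate;
per-variable splits of the unexplained part are not computed.

A note on the omitted-category problem: contributions of *individual dummy
terms* depend on which level is the reference, but the *variable-group*
totals reported here do not. On the index scale the group contribution is
$\sum_l \Delta\bar s_l \beta^*_l$ over all levels, and re-encoding with
reference $m$ replaces $\beta_l$ by $\beta_l - \beta_m$ while the level
shares still difference to zero — the group sum is unchanged (a property
the test suite asserts). Because the explained component is decomposed only
at the variable-group level, no reference-rotation normalization is needed;
reference categories are nevertheless fixed in the variable dictionary and
recorded on every fit so finer splits stay reproducible. The $\beta^*$ used
for the detailed split defaults to the Reimers blend ($\omega = 0.5$,
configurable via `detailed_omega`).

## Selection correction

Only women with a recent birth contribute outcome rows. The correction is
the classical two-step procedure: a probit for having had a birth on the
full sample of women (covariates: age band, education, wealth, religion,
ethnicity, marital status, residence, contraceptive use), then the inverse
Mills ratio $\lambda(z) = \phi(z)/\Phi(z)$ at the fitted selection index
appended to the outcome equation of the selected rows. The selection probit
is fit on the pooled sample — residence is one of its covariates — not per
group. $\lambda$ is evaluated as $\exp(\log\phi - \log\Phi)$ so the far
left tail is stable (at $z = -40$, $\lambda \approx 40$ with no 0/0).

With a *binary* second stage this two-step is an approximation, not an
efficient estimator: the Mills term absorbs the selection-induced mean
shift of the latent error, but cannot undo the variance rescaling that
selection also induces in a probit/logit index. Consequently the correction
is most effective when the outcome coefficients are moderate and the
selection equation has a real exclusion restriction; the simulation studies
below use exactly that regime, and the `compact_spec(small_effects=True)`
preset encodes it. This mirrors the procedure's standing in applied work: a
bias-reduction device, not a consistency guarantee.

## Synthetic data generator

A `PopulationSpec` fully determines the data-generating process: rural
birth share, per-group covariate distributions (categorical probability
vectors; Bernoulli rates; shifted negative-binomial counts for parity and
antenatal visits), link-scale coefficient vectors per group, and a
selection stage. Covariates are drawn *independently within group* — the
source descriptive table reports only marginal distributions, so no joint
dependence is imposed; passing tests therefore validate the estimators
under independent covariates, not under the correlation structure of real
DHS data (where, e.g., wealth and education are strongly associated).

The selection stage couples the outcome to selection through a Gaussian
copula: selection is $1\{\gamma^\top w + u > 0\}$ with $u \sim N(0,1)$, and
the outcome is $1\{\Phi(e) \le F(\beta^\top x)\}$ with
$\text{corr}(e, u) = \rho$. For the probit link this is exactly the
bivariate-probit selection model; for every link $\rho = 0$ reduces to
independent draws, so the no-selection limit is built in.

`default_ghana_spec()` is a preset calibrated once, by simulation at 400k
draws, to the pooled birth-sample margins of the three surveys: rural share
0.589; delivery rates 0.431 (rural) and 0.847 (urban); wealth, education,
age, ethnicity, religion, marital status, distance-barrier and
complication margins set to the published descriptive percentages; parity
means 4.05/3.13; antenatal-visit distributions matching both the means
(7.13/8.89) and the 4+-visit shares (0.742/0.910) via negative-binomial
dispersions 2.75/7.0. Slopes are plausible magnitudes for institutional
delivery (steep wealth/education gradients, strong antenatal association,
negative distance and parity effects), with moderate urban–rural slope
differences so both explained and unexplained components are nonzero.
Contraceptive-use rates (0.22/0.32) and reform-period shares are not in the
descriptive table and were chosen as realistic values. `rho_selection`
defaults to 0.

`population_components()` is the oracle: it averages true link-inverse
probabilities over fresh covariate draws (no outcome noise) for every
(coefficient vector, covariate group) pairing and returns the truth with
per-component Monte-Carlo standard errors. The reported SE is computed at
the Bernoulli-outcome level (covariate-draw variance plus outcome
variance), the natural yardstick when comparing a finite-sample estimate at
$n$ to the truth with `n_mc = n`. Note that a *fitted* decomposition has an
extra variance source the oracle cannot know — coefficient noise amplified
by cross-group extrapolation — so estimate-versus-truth comparisons combine
the estimate's bootstrap SE with the oracle SE in quadrature.

## Inference

Nonparametric pairs bootstrap, resampling rows with replacement within
strata defined by residence (and survey year when surveys are pooled),
refitting both group equations and recomputing every component per
replicate; B defaults to 1000 (tests and the acceptance script use 200 for
runtime). Standard errors are replicate SDs; intervals are percentile 95%;
the 5%-significance flag is "interval excludes zero". Replicates whose fits
fail (resampling-induced separation) are dropped and counted, with a hard
error if more than 5% fail. Analytic delta-method SEs and
cluster/design-effect bootstraps are out of scope.

## Numerical and design choices

- **Default link: logit.** Its score equations make the decomposition total
  equal the raw gap exactly, which keeps printed tables internally
  consistent; probit and linear are options.
- **Design matrices are built in-package** (fixed level orders, first level
  = reference) rather than via a formula engine, because detailed
  decompositions need stable, documented term names; the reference category
  per variable is recorded on every fit.
- **Antenatal care enters as the 4+-visits indicator by default** (the
  clinically meaningful threshold); the continuous count is available by
  putting `anc_visits` in the term list.
- **Sparse-cell exclusions.** Within an analysis window, design columns
  that are constant in either group (e.g. the survey-year effect inside a
  single survey), or that are dummies with fewer than 5 occupied rows or a
  single-class outcome in their occupied cell, are dropped from both
  groups' fits and logged. This prevents quasi-separation in small windows
  at the cost of pricing those rare categories at the reference level.
- **Fitting.** statsmodels Logit/Probit/OLS; Newton first, BFGS fallback if
  Newton stalls; non-convergence, perfect separation and single-class
  outcomes raise explicit errors — never silent garbage. Complete-case
  deletion per fitted equation, with dropped-row counts logged and carried
  in the report provenance.
- **Determinism.** Every random step flows from one integer seed through
  `numpy.random.default_rng`; identical config + seed reproduces
  byte-identical JSON reports (no timestamps in outputs).
- **Rounding in exported tables**: 3 decimals for coefficients, 1 for
  percentages; in-memory objects keep full precision.

## Validation problem sizes

The test suite validates margins at 50k draws; coefficient recovery at 50k
rows; component recovery at 20k rows against a 400k-draw oracle with
bootstrap B = 200; the selection study at 100 replicates of 4000 women
(probit link, $\rho = 0.7$, small-effects preset); and interval calibration
over 200 datasets of 2000 rows with B = 200, whose empirical coverage of
the true explained component must land in [0.89, 0.99]. These sizes were
chosen to make Monte-Carlo error small relative to the tolerances tested.

## Known limitations

- Covariate independence within groups (see above): real-data joint
  structure is not emulated, and no cluster/stratum survey design or
  sampling weights are modeled (an optional weight column is accepted on
  input but not used by the default fits).
- The two-step selection correction with a binary second stage reduces,
  but does not eliminate, selection bias (scale distortion remains).
- Detailed contributions finer than the variable-group level (individual
  dummy terms) are reference-category dependent; group-level totals are not.
- Only two groups and mean decompositions: no quantile/distributional
  decompositions.
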