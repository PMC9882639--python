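# Methods

This note documents the statistical procedures implemented in `sensefactor`,
the modeling choices behind them, and what the synthetic-data checks do and
do not establish.

## Scientific setting

Caregiver questionnaires measure three sensory response patterns in autistic
children — hyperreactivity (HYPER), hyporeactivity (HYPO), and sensory
seeking (SEEK) — with 5-point ordinal items spread across sensory modalities
(auditory, visual, tactile, olfactory, gustatory, oral-tactile, movement).
Whether a "supra-modal" total score for a response pattern is interpretable,
or whether only modality-specific subscores are, is a bifactor question: each
item is allowed one loading on a general response-pattern factor and at most
one loading on its modality's specific factor, and published index-based
decision rules adjudicate between the levels of analysis. The package
implements that full chain for pooled multi-study data: harmonization of
items across instrument versions, polychoric correlations, graded response
models (GRMs), ICLUST-based scale refinement, exploratory graph analysis,
bifactor indices with decision rules, and Bayesian random-effects models of
person-level correlates.

## Item harmonization

Instruments covered are the Sensory Profile 1/2 and short forms (SP1, SSP1,
SP2, SSP2) and the Sensory Experiences Questionnaire 2.1/3.0 (SEQ2, SEQ3).
SP1/SSP1 are scored opposite to the rest and are reverse-coded
(`k -> 6 - k`), so 5 always denotes more frequent behavior. When one person
has observations of the same harmonized item from two instruments, the
SEQ-sourced value is kept (SEQ versions contribute more items to the bank)
and the conflict is logged; no published rule exists for this case, so the
package makes the choice explicit and auditable. Missingness is structural
(an instrument not administered leaves its items missing) and is never
imputed; every downstream estimator works on pairwise-complete or
person-wise available data. Age eligibility is a closed interval (default
[3, 18] years).

## Polychoric correlations

Ordinal item pairs are modeled as discretized bivariate normals. Estimation
is two-stage (Olsson): thresholds from the inverse-normal marginal
cumulative proportions, then a bounded one-dimensional likelihood
maximization for the latent correlation with cell probabilities from the
Genz bivariate-normal routine. Choices that matter:

- **Pairwise deletion.** Planned missingness by questionnaire version makes
  listwise deletion unusable for pooled data.
- **Boundary guard** |rho| <= 0.999, so downstream factor routines keep
  finite information.
- **Collapsed categories** (never-observed response options) are merged into
  their neighbors rather than producing infinite thresholds.
- A pairwise matrix need not be positive semidefinite; an eigenvalue-clipped
  nearest-PSD repair (rescaled to unit diagonal) is applied and flagged.

## Graded response models

The GRM is parameterized in slope–intercept form: boundary probabilities
P(X >= k | theta) = logistic(a' theta + c_{k-1}) with strictly decreasing
intercepts. Estimation is Bock–Aitkin marginal maximum likelihood EM:

- **Quadrature:** 49 equally spaced nodes on [-6, 6] with renormalized
  normal weights for the general factor; 21 nodes for each specific factor.
- **Bifactor dimension reduction:** conditional on the general factor the
  specific factors are independent across item groups, so the E-step
  integrates each group's specific factor separately — cost
  O(Q_G · Q_S · items) instead of O(Q^(1+S)). A brute-force full-grid
  likelihood (`bifactor_loglik_bruteforce`) exists purely as a cross-check
  and matches to machine precision at the final parameters.
- **M-step:** per-item L-BFGS-B on the expected complete-data
  log-likelihood with analytic gradients; intercept ordering is enforced by
  a (rarely needed) sort repair.
- **Convergence:** maximum absolute parameter change < 1e-5, or a marginal
  log-likelihood increase < 1e-5 (EM's per-cycle gain decays long before
  weakly identified parameters stop drifting; the plateau rule terminates
  those flat directions). Cap 500 cycles; non-convergence is flagged on the
  solution, never raised. The log-likelihood path is recorded and is
  non-decreasing.
- **Starting values** are deterministic (unit slopes, intercepts from
  marginal proportions), so fits are reproducible bit-for-bit.

Standardized loadings use the conventional logistic-to-probit bridge
a* = a/1.702, lambda_d = a*_d / sqrt(1 + sum a*_d^2). EAP scores are
posterior means on the quadrature grid; for bifactor models the specific
factors are integrated out by the same dimension-reduction identity. A
person with no observed items receives the prior (0, 1) and is flagged.
Marginal reliability is 1 minus the mean posterior variance.

### Limited-information fit

SRMR is the root-mean-square lower-triangle difference between the sample
polychoric matrix and the model-implied correlation matrix (Lambda Lambda'
with unit diagonal). The C2-type statistic of the original analysis is not
replicated (its weight matrix is not public); instead RMSEA and TLI are
built from a residual-based quadratic form — each squared residual scaled
by the large-sample variance of a correlation, df = #correlations − #free
loadings, independence baseline — and consumed with the same retention
thresholds. With df <= 0 (3-item unidimensional scales) RMSEA/TLI are
reported as undefined and only SRMR and the reliabilities decide.

Two omega-total variants exist: the standardized-loading formula (used for
all index work) and the EAP-based marginal reliability. Printed omega cells
in the source tables are *not* reproducible from rounded loadings
(discrepancies ~0.01–0.03 were confirmed numerically), so omegas are
property-tested (unidimensional limit, permutation invariance) rather than
asserted against printed values.

## Scale refinement

For one modality × response-pattern subconstruct, candidates are first
clustered (ICLUST-style) on the polychoric matrix: agglomerative merging of
the most similar composites, a merge accepted when the merged cluster's
worst *balanced* split-half reliability beta is at least
max(0.45, weakest multi-item child's beta − 0.05). Beta is computed over
all balanced splits for clusters of <= 12 items and deterministic
contiguous/alternating splits above that. The slack of 0.05 exists because
at equal within-cluster correlations a merge leaves beta flat, so sampling
noise would otherwise reject valid growth; 0.45 is the floor below which a
cluster is not worth treating as a scale. The dominant cluster (>= 3 items)
then enters a fit–check–remove loop: unidimensional GRM, retention criteria
(TLI > 0.97, RMSEA < 0.089, SRMR < 0.05 or < 0.033 at exactly 3 items,
marginal reliability > 0.7, omega total > 0.7), and on failure removal of
the item with the largest maximum absolute residual polychoric correlation
(ties: lowest loading). The loop stops at retention, below 3 items, or when
removals stop improving SRMR; failures fall back to a single expert-flagged
"most global" item, carried as a bank annotation so the expert judgment is
data, not code. Every step lands in a machine-readable trace.

## Structure evaluation

- **One-factor CFA** of subconstruct scores: standardized ML discrepancy
  minimization for continuous scores (chi-square = (n−1)F, CFI/RMSEA/SRMR
  against the independence baseline), or unweighted least squares on a
  polychoric matrix with the residual-based statistic above. Robust (MLR/
  WLSMV) corrections are not implemented; no downstream decision consumes
  them.
- **Exploratory graph analysis:** graphical-lasso path over 50 log-spaced
  penalties, model selected by EBIC (gamma = 0.5), communities by Walktrap
  (4 steps) on absolute partial correlations. An empty selected graph
  returns singleton communities, flagged.
- **Bifactor indices** from standardized loadings under simple structure:
  omega total/hierarchical (and subscale analogs restricted to subscale
  items), general and per-subscale explained common variance, item ECV, and
  communality. Decision rules: a strong general factor needs omega_H >= .80,
  or omega_H >= .70 with ECV_G >= .60; a subscale has added value when its
  specific-factor saturation omega_HS or specific ECV_SS clears the cutoff
  of the nearer published reliability anchor (omega_HS >= .25 or
  ECV_SS >= .45 near omega_S = .60; omega_HS >= .20 or ECV_SS >= .30 near
  omega_S = .80). Verdicts carry a full rule trace.

## Bayesian random-effects correlate models

Person-level model with study random intercepts and slopes:
y_is = b0 + b1 x_is + u0_s + u1_s x_is + e_is, u0 ~ N(0, tau0^2),
u1 ~ N(0, tau1^2), e ~ N(0, sigma^2). Outcomes are standardized on the
pooled sample; continuous correlates are standardized (b1 read as r),
binary correlates stay 0/1 (b1 read as Cohen's d). Priors: N(0,1) on fixed
effects, half-t(3, 0.5) on tau0/tau1, half-t(3, 1.0) on sigma — stand-ins
for the original study's unavailable prior table, all configurable. Random
intercept and slope are independent (no correlation parameter). Models with
fewer than 100 complete pairs are refused, not fit.

**Sampler.** A collapsed Gibbs sampler: tau0 and tau1 are updated by slice
sampling on the log scale with the random effects integrated out
analytically (2×2 Woodbury per study) — this removes the funnel that
cripples centered Gibbs near tau = 0; the fixed effects are drawn by GLS
with the random effects likewise integrated out, so beta never moves in
lockstep with u; random effects and sigma^2 (half-t via its inverse-gamma
scale mixture) follow conjugately. Default 4 chains × (500 warmup + 500
draws); split-R̂ < 1.01 (ArviZ) is required before any summary is emitted.
Prior-matched simulation-based calibration (all parameters drawn from their
priors) yields 95% HDI coverage of the slope at the nominal rate with a
flat rank histogram; an earlier non-centered parameter-expanded sampler
failed this check in the large-tau regime and was replaced.

**Summaries.** Posterior median and 95% highest-density interval (shortest
sorted-draw window); P_ROPE and log BF_ROPE against a region of practical
equivalence of ±0.1 for r and ±0.2 for d, with prior odds computed
analytically from the N(0,1) effect prior and posterior proportions clipped
by a quarter draw to keep the log finite. Positive log BF is evidence for a
practically meaningful effect; ±log 3 and ±log 10 bound the five evidence
categories (strong/moderate effect, inconclusive, moderate/strong null).
Heterogeneity: tau (and tau^2), I^2 = tau1^2/(tau1^2 + v̄) with v̄ the mean
study-level sampling variance of the slope, ICC from the total-variance
decomposition, and a 95% prediction interval from draws of b1 + u_new,
u_new ~ N(0, tau1^2).

**Calibration caveat.** With ~10 studies, the half-t prior keeps the
posterior for tau inflated whenever the truth is smaller than a per-study
slope standard error; at fixed truth the 95% HDIs are therefore
conservative (empirically ~98–100% coverage at tau1 = 0.05), and I^2 has a
prior-driven floor. This is a property of weakly informative heterogeneity
priors at small study counts, not of the sampler. Calibration is therefore
demonstrated in the prior-matched regime, and heterogeneity checks are
comparative (tau = 0 vs tau = 0.2 orderings) rather than absolute.

## Synthetic data

The generator emulates pooled caregiver-report data: by default 12 studies
with sizes drawn log-uniformly on [30, 1300], study mean shifts of SD 0.35
on the general trait (putting study membership at roughly 10% of trait
variance, the order observed in multi-site pooling), items generated from
the normal-ogive bifactor representation with thresholds evenly spaced on
[-2, 2], version-dependent item coverage derived from the instrument tokens
in harmonized item names, and correlates built from the within-study part
of the general trait with analytically calibrated target r (or group shifts
for target d) and study-heterogeneous effects (tau1, default 0.05). The
packaged loading tables for the three response patterns are the default
generating structures. Because the marginal of the latent response is
exactly standard normal, population category frequencies and the population
polychoric matrix are known in closed form, and every estimator is tested
against them.

What the generator does not emulate: real SP/SEQ marginal shapes beyond the
GRM family, item-level differential functioning across studies or ages,
correlated specific factors, non-normal trait distributions, and
informative (non-structural) missingness. Passing tests therefore establish
internal correctness of the estimators under the model family, not
robustness to those real-data departures.

## Problem sizes in the test suite

Unit tests run at n = 300–2000 single-study; the end-to-end checks use
n = 3000 (loading recovery), 20 replicates of n = 1000 (refinement and
community detection), and 200 calibration replicates of 10 × 200 persons
with 2000 posterior draws each. These sizes were chosen so each check's
Monte-Carlo error is small relative to its assertion margin while the whole
suite stays comfortably runnable on a laptop core.

## Known limitations

- The C2-based fit statistics of the original analysis are approximated by
  a residual-based quadratic form; absolute RMSEA/TLI values are not
  comparable across software, only the retention decisions are.
- Omega estimates from thresholds (categorical omega) are not implemented;
  the standardized-loading formulas are used throughout.
- The IDA model fits one correlate at a time (no covariate adjustment, no
  intercept–slope correlation), matching the scope of the original
  analysis.
- EGA penalty selection can be sensitive near equal-EBIC solutions; the
  EBIC gamma and Walktrap steps are exposed as arguments.
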