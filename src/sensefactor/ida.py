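"""Bayesian random-effects integrative data analysis of sensory correlates.

Person-level model, pooled over studies s:

    y_is = beta0 + beta1 * x_is + u0_s + u1_s * x_is + eps_is
    u0_s ~ N(0, tau0^2),  u1_s ~ N(0, tau1^2),  eps_is ~ N(0, sigma^2)

with the outcome standardized on the pooled sample and the correlate
standardized (continuous) or coded 0/1 (binary).  The standardized slope is
read as a correlation r (continuous x) or Cohen's d (binary x).  Priors are
weakly informative: N(0, 1) on the fixed effects and half-Student-t(3)
scales on tau0, tau1 (scale 0.5) and sigma (scale 1.0).

Posterior sampling is by a fully conjugate Gibbs sampler: the half-t scale
priors are represented as inverse-gamma scale mixtures, making every block
(fixed effects, per-study random effects, variances, mixing parameters)
a standard conditional draw.  Convergence is checked with split-R-hat
(required < 1.01) computed by ArviZ.

Interval-null testing uses a region of practical equivalence (ROPE) of
[-0.1, 0.1] for r and [-0.2, 0.2] for d.  log BF_ROPE compares posterior to
prior odds of the effect lying outside versus inside the ROPE, so positive
values are evidence for a practically meaningful effect; +-log(3) and
+-log(10) (1.1 and 2.3) bound the moderate and strong evidence categories.

Models are refused outright below 100 observed cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
from scipy import stats

__all__ = [
    "IdaModelSpec",
    "IdaPosterior",
    "IdaRefusal",
    "IdaEffectSummary",
    "fit_ida_model",
    "effect_size_summary",
    "rope_bayes_factor",
    "heterogeneity_summary",
    "evidence_tally",
    "hdi",
    "EVIDENCE_CATEGORIES",
]

EVIDENCE_CATEGORIES = (
    "strong effect",
    "moderate effect",
    "inconclusive",
    "moderate null",
    "strong null",
)

_LOG3 = float(np.log(3.0))
_LOG10 = float(np.log(10.0))


@dataclass(frozen=True)
class IdaModelSpec:
    """Settings for one outcome × correlate integrative model."""

    correlate_type: str = "continuous"  # or "binary"
    rope_r: tuple[float, float] = (-0.1, 0.1)
    rope_d: tuple[float, float] = (-0.2, 0.2)
    prior_beta_sd: float = 1.0
    prior_tau_scale: float = 0.5
    prior_sigma_scale: float = 1.0
    prior_df: float = 3.0
    chains: int = 4
    draws: int = 500
    warmup: int = 500
    seed: int = 0
    min_cases: int = 100
    rhat_max: float = 1.01

    @property
    def rope(self) -> tuple[float, float]:
        return self.rope_r if self.correlate_type == "continuous" else self.rope_d


@dataclass
class IdaRefusal:
    reason: str
    n_cases: int


@dataclass
class IdaPosterior:
    """Stacked posterior draws from all chains, plus diagnostics."""

    beta0: np.ndarray
    beta1: np.ndarray
    tau0: np.ndarray
    tau1: np.ndarray
    sigma: np.ndarray
    u1: np.ndarray  # (draws, n_studies) random slopes
    rhat: dict
    converged: bool
    n_cases: int
    n_studies: int
    var_x: float
    slope_sampling_var: float  # mean study-level sampling variance of the slope
    spec: IdaModelSpec = field(default_factory=IdaModelSpec)

    @property
    def effect_draws(self) -> np.ndarray:
        return self.beta1


def _slice_sample(logpost, x0: float, rng: np.random.Generator,
                  width: float = 1.0, max_steps: int = 30) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    f0 = logpost(x0)
    level = f0 + np.log(rng.uniform(1e-300, 1.0))
    left = x0 - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if logpost(left) < level:
            break
        left -= width
    for _ in range(max_steps):
        if logpost(right) < level:
            break
        right += width
    for _ in range(100):
        prop = rng.uniform(left, right)
        if logpost(prop) >= level:
            return prop
        if prop < x0:
            left = prop
        else:
            right = prop
    return x0  # pathological shrinkage; keep current point


def _gibbs_chain(y, x, study_idx, n_studies, spec: IdaModelSpec,
                 rng: np.random.Generator) -> dict:
    """Collapsed Gibbs sampler for the random-slope model.

    The heterogeneity scales tau0, tau1 are updated by slice sampling on the
    log scale with the per-study random effects integrated out analytically
    (2x2 Woodbury per study), which removes the funnel that cripples
    centered Gibbs when a variance component is near zero.  The fixed
    effects are drawn by GLS with the random effects likewise integrated
    out, so beta never has to move in lockstep with u.  Random effects and
    the residual variance (half-t prior via its inverse-gamma scale mixture)
    then follow from standard conditionals.
    """
    n = y.size
    nu = spec.prior_df
    A_tau = spec.prior_tau_scale
    A_sig = spec.prior_sigma_scale

    # per-study sufficient statistics (fixed across iterations)
    n_s = np.bincount(study_idx, minlength=n_studies).astype(float)
    Sx = np.bincount(study_idx, weights=x, minlength=n_studies)
    Sxx = np.bincount(study_idx, weights=x * x, minlength=n_studies)
    Sy = np.bincount(study_idx, weights=y, minlength=n_studies)
    Sxy = np.bincount(study_idx, weights=x * y, minlength=n_studies)
    Syy = np.bincount(study_idx, weights=y * y, minlength=n_studies)

    def resid_stats(beta):
        b0, b1 = beta
        Sr = Sy - n_s * b0 - Sx * b1
        Srx = Sxy - Sx * b0 - Sxx * b1
        Srr = (Syy - 2 * b0 * Sy - 2 * b1 * Sxy
               + n_s * b0 ** 2 + 2 * b0 * b1 * Sx + b1 ** 2 * Sxx)
        return Sr, Srx, Srr

    def log_half_t(tau, scale):
        # half-t(nu, scale) log-density up to a constant (slice sampling
        # only needs relative values)
        return -0.5 * (nu + 1.0) * np.log1p((tau / scale) ** 2 / nu)

    def inv_gamma(shape, scale_):
        return scale_ / rng.gamma(shape)

    def marginal_loglik(t0_sq, t1_sq, s_sq, Sr, Srx, Srr):
        """Sum over studies of log N(r_s; 0, s_sq I + Z D Z') via Woodbury."""
        M00 = 1.0 / t0_sq + n_s / s_sq
        M01 = Sx / s_sq
        M11 = 1.0 / t1_sq + Sxx / s_sq
        detM = M00 * M11 - M01 ** 2
        b0v = Sr / s_sq
        b1v = Srx / s_sq
        quad = Srr / s_sq - (M11 * b0v ** 2 - 2 * M01 * b0v * b1v
                             + M00 * b1v ** 2) / detM
        logdetV = (n_s * np.log(s_sq) + np.log(t0_sq) + np.log(t1_sq)
                   + np.log(detM))
        return -0.5 * float(np.sum(logdetV + quad))

    beta = np.zeros(2)
    tau0, tau1 = 0.25, 0.25
    sig_sq, a_sig = float(np.var(y)), 1.0
    prior_prec = np.eye(2) / spec.prior_beta_sd ** 2

    total = spec.warmup + spec.draws
    out = {k: np.empty(spec.draws) for k in
           ("beta0", "beta1", "tau0", "tau1", "sigma")}
    out["u1"] = np.empty((spec.draws, n_studies))

    for t in range(total):
        Sr, Srx, Srr = resid_stats(beta)

        # heterogeneity scales: slice sampling on log tau, u collapsed
        def logpost_tau0(lt):
            tau = np.exp(lt)
            if tau < 1e-8 or tau > 1e3:
                return -np.inf
            return (marginal_loglik(tau ** 2, tau1 ** 2, sig_sq, Sr, Srx, Srr)
                    + log_half_t(tau, A_tau)
                    + lt)  # Jacobian of the log transform

        tau0 = float(np.exp(_slice_sample(logpost_tau0, np.log(tau0), rng)))

        def logpost_tau1(lt):
            tau = np.exp(lt)
            if tau < 1e-8 or tau > 1e3:
                return -np.inf
            return (marginal_loglik(tau0 ** 2, tau ** 2, sig_sq, Sr, Srx, Srr)
                    + log_half_t(tau, A_tau)
                    + lt)

        tau1 = float(np.exp(_slice_sample(logpost_tau1, np.log(tau1), rng)))

        # fixed effects by GLS with u integrated out (explicit 2x2 Woodbury)
        M00 = 1.0 / tau0 ** 2 + n_s / sig_sq
        M01 = Sx / sig_sq
        M11 = 1.0 / tau1 ** 2 + Sxx / sig_sq
        detM = M00 * M11 - M01 ** 2
        i00, i01, i11 = M11 / detM, -M01 / detM, M00 / detM
        p00, p01, p11 = n_s / sig_sq, Sx / sig_sq, Sxx / sig_sq
        # A = P M^-1 (per study), then correction terms P M^-1 P and P M^-1 q
        a00 = p00 * i00 + p01 * i01
        a01 = p00 * i01 + p01 * i11
        a10 = p01 * i00 + p11 * i01
        a11 = p01 * i01 + p11 * i11
        c2_00 = a00 * p00 + a01 * p01
        c2_01 = a00 * p01 + a01 * p11
        c2_11 = a10 * p01 + a11 * p11
        q0s, q1s = Sy / sig_sq, Sxy / sig_sq
        c1_0 = a00 * q0s + a01 * q1s
        c1_1 = a10 * q0s + a11 * q1s
        A_beta = np.array([
            [np.sum(p00 - c2_00), np.sum(p01 - c2_01)],
            [np.sum(p01 - c2_01), np.sum(p11 - c2_11)],
        ]) + prior_prec
        rhs = np.array([np.sum(q0s - c1_0), np.sum(q1s - c1_1)])
        cov_beta = np.linalg.inv(A_beta)
        mean_beta = cov_beta @ rhs
        lb = np.linalg.cholesky(cov_beta)
        beta = mean_beta + lb @ rng.standard_normal(2)

        # random effects | beta, tau, sigma
        Sr, Srx, Srr = resid_stats(beta)
        b0v = Sr / sig_sq
        b1v = Srx / sig_sq
        m0 = (M11 * b0v - M01 * b1v) / detM
        m1 = (-M01 * b0v + M00 * b1v) / detM
        c00, c01, c11 = M11 / detM, -M01 / detM, M00 / detM
        l00 = np.sqrt(c00)
        l10 = c01 / l00
        l11 = np.sqrt(np.clip(c11 - l10 ** 2, 1e-12, None))
        g0 = rng.standard_normal(n_studies)
        g1 = rng.standard_normal(n_studies)
        u0 = m0 + l00 * g0
        u1 = m1 + l10 * g0 + l11 * g1

        # residual variance | beta, u (half-t via inverse-gamma mixture)
        eps = (y - beta[0] - beta[1] * x
               - u0[study_idx] - u1[study_idx] * x)
        sig_sq = inv_gamma((nu + n) / 2.0,
                           (nu / a_sig + np.sum(eps ** 2)) / 2.0)
        a_sig = inv_gamma((nu + 1) / 2.0, nu / sig_sq + 1.0 / A_sig ** 2)

        if t >= spec.warmup:
            k = t - spec.warmup
            out["beta0"][k] = beta[0]
            out["beta1"][k] = beta[1]
            out["tau0"][k] = tau0
            out["tau1"][k] = tau1
            out["sigma"][k] = np.sqrt(sig_sq)
            out["u1"][k] = u1
    return out


def fit_ida_model(
    outcome: np.ndarray,
    correlate: np.ndarray,
    study_ids: Sequence,
    spec: IdaModelSpec = IdaModelSpec(),
    standardize: bool = True,
) -> IdaPosterior | IdaRefusal:
    """Fit the hierarchical random-intercept/random-slope model.

    Missing values (NaN) in either variable drop the person.  Returns an
    :class:`IdaRefusal` instead of fitting when fewer than ``min_cases``
    complete pairs remain.  ``standardize=False`` fits the raw scales
    (used when the inputs are already on the model's scale, e.g. in
    calibration experiments).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(correlate, dtype=float)
    study = np.asarray([str(s) for s in study_ids])
    ok = np.isfinite(y) & np.isfinite(x)
    y, x, study = y[ok], x[ok], study[ok]
    n = y.size
    if n < spec.min_cases:
        return IdaRefusal(
            reason=f"{n} observed cases < minimum of {spec.min_cases}",
            n_cases=n,
        )

    labels, study_idx = np.unique(study, return_inverse=True)
    n_studies = labels.size
    if standardize:
        y = (y - y.mean()) / y.std()
        if spec.correlate_type == "continuous":
            x = (x - x.mean()) / x.std()
        # binary x stays 0/1

    chains = []
    for c in range(spec.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, c]))
        chains.append(_gibbs_chain(y, x, study_idx, n_studies, spec, rng))

    stacked = {k: np.concatenate([c[k] for c in chains]) for k in
               ("beta0", "beta1", "tau0", "tau1", "sigma")}
    u1 = np.concatenate([c["u1"] for c in chains], axis=0)

    ds = az.from_dict({k: np.stack([c[k] for c in chains])
                       for k in ("beta0", "beta1", "tau0", "tau1", "sigma")})
    rhat_ds = az.rhat(ds)
    rhat = {k: float(rhat_ds[k].values) for k in rhat_ds.data_vars}
    converged = all(np.isfinite(v) and v < spec.rhat_max for v in rhat.values())

    # mean study-level sampling variance of a per-study OLS slope
    sig_hat = float(np.median(stacked["sigma"]) ** 2)
    ssx = np.bincount(study_idx, weights=(x - x.mean()) ** 2,
                      minlength=n_studies)
    ssx = np.clip(ssx, 1e-8, None)
    v_bar = float(np.mean(sig_hat / ssx))

    return IdaPosterior(
        beta0=stacked["beta0"], beta1=stacked["beta1"],
        tau0=stacked["tau0"], tau1=stacked["tau1"], sigma=stacked["sigma"],
        u1=u1, rhat=rhat, converged=converged, n_cases=n,
        n_studies=n_studies, var_x=float(np.var(x)),
        slope_sampling_var=v_bar, spec=spec,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws (exhaustive window)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = max(2, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _prior_inside_prob(rope: tuple[float, float], prior_sd: float) -> float:
    lo, hi = rope
    return float(stats.norm.cdf(hi / prior_sd) - stats.norm.cdf(lo / prior_sd))


def rope_bayes_factor(
    effect_draws: np.ndarray,
    rope: tuple[float, float],
    prior_sd: float = 1.0,
) -> tuple[float, float, str]:
    """(P_ROPE, log BF_ROPE, evidence category) from posterior effect draws.

    The Bayes factor compares posterior to prior odds of the effect lying
    outside versus inside the ROPE; the prior odds come analytically from
    the N(0, prior_sd^2) effect prior.  Posterior proportions are clipped
    away from 0 and 1 (by a quarter draw) so the log stays finite.  Positive
    log BF is evidence for a practically meaningful effect.
    """
    draws = np.asarray(effect_draws, dtype=float)
    if draws.size < 2000:
        raise ValueError("need at least 2000 posterior draws")
    lo, hi = rope
    p_in = float(np.mean((draws >= lo) & (draws <= hi)))
    eps = 1.0 / (4.0 * draws.size)
    p_in = min(max(p_in, eps), 1.0 - eps)
    prior_in = _prior_inside_prob(rope, prior_sd)
    prior_in = min(max(prior_in, 1e-12), 1 - 1e-12)
    log_bf = (np.log(1.0 - p_in) - np.log(p_in)
              - (np.log(1.0 - prior_in) - np.log(prior_in)))
    p_rope = float(np.mean((draws >= lo) & (draws <= hi)))
    return p_rope, float(log_bf), categorize_log_bf(float(log_bf))


def categorize_log_bf(log_bf: float) -> str:
    if log_bf > _LOG10:
        return "strong effect"
    if log_bf > _LOG3:
        return "moderate effect"
    if log_bf < -_LOG10:
        return "strong null"
    if log_bf < -_LOG3:
        return "moderate null"
    return "inconclusive"


def heterogeneity_summary(posterior: IdaPosterior) -> dict:
    """tau^2, I^2, ICC and the 95% prediction interval for a new study.

    I^2 = tau1^2 / (tau1^2 + v_bar) with v_bar the mean study-level sampling
    variance of the slope; ICC uses the total-variance decomposition with
    Var(x) from the analysis sample.  The prediction interval draws a new
    study's slope beta1 + u_new, u_new ~ N(0, tau1^2).
    """
    tau1_sq = np.median(posterior.tau1 ** 2)
    tau0_sq = np.median(posterior.tau0 ** 2)
    sig_sq = np.median(posterior.sigma ** 2)
    v_bar = posterior.slope_sampling_var
    i2 = float(tau1_sq / (tau1_sq + v_bar)) if (tau1_sq + v_bar) > 0 else 0.0
    vx = posterior.var_x
    icc = float((tau0_sq + tau1_sq * vx)
                / (tau0_sq + tau1_sq * vx + sig_sq))
    rng = np.random.default_rng(
        np.random.SeedSequence([posterior.spec.seed, 104729]))
    u_new = rng.standard_normal(posterior.beta1.size) * posterior.tau1
    pred = posterior.beta1 + u_new
    lo, hi = np.quantile(pred, [0.025, 0.975])
    return {
        "tau": float(np.median(posterior.tau1)),
        "tau_sq": float(tau1_sq),
        "i2": i2,
        "icc": icc,
        "prediction_interval": (float(lo), float(hi)),
    }


@dataclass
class IdaEffectSummary:
    """Posterior effect-size summary for one outcome × correlate model."""

    effect_type: str  # "r" | "d"
    median: float
    hdi_low: float
    hdi_high: float
    p_rope: float
    log_bf_rope: float
    category: str
    tau: float
    tau_sq: float
    i2: float
    icc: float
    prediction_interval: tuple[float, float]
    n_cases: int
    n_studies: int
    rhat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_rope <= 1.0:
            raise ValueError("P_ROPE outside [0, 1]")
        if not self.hdi_low <= self.median <= self.hdi_high:
            raise ValueError("median outside its HDI")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["prediction_interval"] = list(self.prediction_interval)
        return d


def effect_size_summary(
    posterior: IdaPosterior,
    spec: IdaModelSpec | None = None,
) -> IdaEffectSummary:
    """Summarize the standardized effect: median, 95% HDI, ROPE indices,
    heterogeneity, and prediction interval.

    Raises on a non-converged posterior (R-hat >= threshold): no summaries
    are emitted from a flagged fit.
    """
    spec = spec or posterior.spec
    if not posterior.converged:
        bad = {k: round(v, 4) for k, v in posterior.rhat.items()}
        raise RuntimeError(f"posterior not converged (R-hat {bad}); "
                           "no summaries emitted")
    draws = posterior.effect_draws
    med = float(np.median(draws))
    lo, hi = hdi(draws, 0.95)
    p_rope, log_bf, category = rope_bayes_factor(
        draws, spec.rope, prior_sd=spec.prior_beta_sd)
    het = heterogeneity_summary(posterior)
    return IdaEffectSummary(
        effect_type="r" if spec.correlate_type == "continuous" else "d",
        median=med, hdi_low=lo, hdi_high=hi,
        p_rope=p_rope, log_bf_rope=log_bf, category=category,
        tau=het["tau"], tau_sq=het["tau_sq"], i2=het["i2"], icc=het["icc"],
        prediction_interval=het["prediction_interval"],
        n_cases=posterior.n_cases, n_studies=posterior.n_studies,
        rhat=posterior.rhat,
    )


def evidence_tally(summaries: Sequence[IdaEffectSummary]) -> dict:
    """Five-way evidence-category tally with percentages."""
    counts = {c: 0 for c in EVIDENCE_CATEGORIES}
    for s in summaries:
        counts[s.category] += 1
    total = max(len(summaries), 1)
    return {
        "counts": counts,
        "percent": {c: 100.0 * v / total for c, v in counts.items()},
        "total": len(summaries),
    }
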