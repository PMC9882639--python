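"""Supra-modal structure evaluation.

Four pieces decide whether a response pattern (hyperreactivity,
hyporeactivity, sensory seeking) is interpretable above the single-modality
level:

* a one-factor confirmatory factor analysis of the modality subconstruct
  scores (continuous maximum likelihood or unweighted least squares on a
  polychoric matrix);
* exploratory graph analysis — an EBIC-tuned graphical-lasso partial
  correlation network whose Walktrap communities should recreate the
  designed modality partition;
* bifactor statistical indices (omega total/hierarchical/subscale variants,
  explained common variance, item ECV, communality) computed from
  standardized loadings;
* published decision rules: a strong general factor requires
  omega_H >= .80, or omega_H >= .70 together with ECV_G >= .60; a modality
  subscale adds value beyond the total score when its specific-factor
  saturation or specific ECV clears a cutoff that depends on subscale
  reliability (omega_HS >= .25 or ECV_SS >= .45 near omega_S = .60;
  omega_HS >= .20 or ECV_SS >= .30 near omega_S = .80).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import numpy as np
from scipy import optimize
from sklearn.covariance import graphical_lasso

__all__ = [
    "CfaFit",
    "EgaResult",
    "BifactorIndexSet",
    "DecisionOutcome",
    "one_factor_cfa",
    "ega",
    "bifactor_indices",
    "interpretability_rules",
]


# ---------------------------------------------------------------------------
# one-factor CFA
# ---------------------------------------------------------------------------

@dataclass
class CfaFit:
    loadings: np.ndarray
    chi2: float
    df: int
    cfi: float
    rmsea: float
    srmr: float
    estimator: str  # "ML-continuous" | "ULS-polychoric"
    converged: bool = True
    improper: bool = False  # negative residual variance encountered

    def __post_init__(self) -> None:
        if not (np.isnan(self.cfi) or 0.0 <= self.cfi <= 1.0):
            raise ValueError("CFI outside [0, 1]")
        if not (np.isnan(self.rmsea) or self.rmsea >= 0):
            raise ValueError("RMSEA negative")


def _implied(lam: np.ndarray) -> np.ndarray:
    sigma = np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def one_factor_cfa(
    data: np.ndarray,
    n: int | None = None,
    estimator: str = "ML",
) -> CfaFit:
    """Fit a standardized one-factor model.

    ``data`` is either a cases × indicators score matrix (``estimator="ML"``,
    n inferred) or a correlation matrix (requires ``n``; ``estimator="ULS"``
    for polychoric input).  At least 3 indicators are required; exactly 3
    gives a just-identified model reported with df = 0 and perfect fit.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D")
    is_corr = data.shape[0] == data.shape[1] and np.allclose(np.diag(data), 1.0)
    if is_corr:
        if n is None:
            raise ValueError("sample size n required with a correlation matrix")
        S = (data + data.T) / 2.0
    else:
        if n is None:
            n = data.shape[0]
        S = np.corrcoef(data, rowvar=False)
    p = S.shape[0]
    if p < 3:
        raise ValueError("one-factor CFA needs at least 3 indicators")

    start = np.sqrt(np.clip(np.abs(S[0, 1:]).mean(), 0.1, 0.9)) * np.ones(p)

    if estimator.upper().startswith("ML"):
        logdet_S = np.linalg.slogdet(S)[1]

        def discrepancy(lam: np.ndarray) -> float:
            lam = np.clip(lam, -0.999, 0.999)
            sigma = _implied(lam)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e6
            return float(logdet + np.trace(S @ np.linalg.inv(sigma))
                         - logdet_S - p)

        res = optimize.minimize(discrepancy, start, method="L-BFGS-B",
                                bounds=[(-0.999, 0.999)] * p)
        lam = res.x
        F = discrepancy(lam)
        chi2 = (n - 1) * F
        base_F = float(-logdet_S)  # independence model: Sigma0 = I
        chi2_0 = (n - 1) * base_F
        tag = "ML-continuous"
        conv = bool(res.success)
    elif estimator.upper().startswith("ULS"):
        iu = np.tril_indices(p, k=-1)

        def uls(lam: np.ndarray) -> float:
            resid = (S - _implied(lam))[iu]
            return float(np.sum(resid ** 2))

        res = optimize.minimize(uls, start, method="L-BFGS-B",
                                bounds=[(-0.999, 0.999)] * p)
        lam = res.x
        # residual-based statistic with large-sample correlation variances
        sigma = _implied(lam)
        v = np.clip((1.0 - sigma[iu] ** 2) ** 2, 1e-6, None)
        chi2 = float(n * np.sum((S - sigma)[iu] ** 2 / v))
        chi2_0 = float(n * np.sum(S[iu] ** 2))
        tag = "ULS-polychoric"
        conv = bool(res.success)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    df = p * (p - 1) // 2 - p
    df0 = p * (p - 1) // 2
    if df < 0:
        raise ValueError("model under-identified with fewer than 3 indicators")
    iu = np.tril_indices(p, k=-1)
    srmr = float(np.sqrt(np.mean((S - _implied(lam))[iu] ** 2)))
    if df == 0:
        cfi, rmsea = 1.0, 0.0
    else:
        num = max(chi2 - df, 0.0)
        den = max(chi2_0 - df0, num, 1e-12)
        cfi = float(1.0 - num / den)
        rmsea = float(np.sqrt(num / (df * max(n - 1, 1))))
    improper = bool(np.any(np.abs(lam) >= 0.999))
    return CfaFit(loadings=lam, chi2=float(chi2), df=df, cfi=cfi, rmsea=rmsea,
                  srmr=srmr, estimator=tag, converged=conv, improper=improper)


# ---------------------------------------------------------------------------
# exploratory graph analysis
# ---------------------------------------------------------------------------

@dataclass
class EgaResult:
    item_ids: list[str]
    network: np.ndarray  # regularized partial correlations
    communities: list[int]
    n_communities: int
    penalty: float
    empty_graph: bool = False


def ega(
    corr: np.ndarray,
    n: int,
    item_ids: Sequence[str] | None = None,
    gamma: float = 0.5,
    n_penalties: int = 50,
    walktrap_steps: int = 4,
) -> EgaResult:
    """Exploratory graph analysis on a (polychoric) correlation matrix.

    A graphical-lasso path over ``n_penalties`` log-spaced penalties is
    scored by EBIC with hyperparameter ``gamma``; Walktrap community
    detection (``walktrap_steps`` random-walk steps) on absolute partial
    correlation weights gives the dimensionality estimate.  An empty
    selected graph returns each item as its own community, flagged.
    """
    S = np.asarray(corr, dtype=float)
    p = S.shape[0]
    ids = list(item_ids) if item_ids is not None else [f"V{i + 1}" for i in range(p)]
    alpha_max = max(np.abs(S - np.eye(p)).max(), 1e-3)
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 0.01),
                         n_penalties)

    best = None
    import warnings

    for alpha in alphas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # near-convergence is fine here
                cov, prec = graphical_lasso(S, alpha=alpha, max_iter=500)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        E = int(np.count_nonzero(np.triu(prec, k=1) != 0))
        sign, logdet = np.linalg.slogdet(prec)
        if sign <= 0:
            continue
        loglik = (n / 2.0) * (logdet - np.trace(S @ prec))
        ebic = -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)
        if best is None or ebic < best[0]:
            best = (ebic, alpha, prec)
    if best is None:
        raise RuntimeError("graphical lasso failed at every penalty")
    _, alpha_star, prec = best

    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    pc[np.abs(pc) < 1e-8] = 0.0

    weights_idx = np.transpose(np.nonzero(np.triu(np.abs(pc) > 0, k=1)))
    if weights_idx.size == 0:
        return EgaResult(item_ids=ids, network=pc,
                         communities=list(range(p)), n_communities=p,
                         penalty=float(alpha_star), empty_graph=True)
    g = ig.Graph(n=p, edges=[tuple(e) for e in weights_idx])
    g.es["weight"] = [abs(pc[i, j]) for i, j in weights_idx]
    dendro = g.community_walktrap(weights="weight", steps=walktrap_steps)
    clustering = dendro.as_clustering()
    membership = list(clustering.membership)
    return EgaResult(item_ids=ids, network=pc, communities=membership,
                     n_communities=len(set(membership)),
                     penalty=float(alpha_star))


# ---------------------------------------------------------------------------
# bifactor indices
# ---------------------------------------------------------------------------

@dataclass
class BifactorIndexSet:
    """Reliability and explained-common-variance indices of a bifactor solution."""

    omega_t: float
    omega_h: float
    ecv_g: float
    omega_s: dict[str, float]
    omega_hs: dict[str, float]
    ecv_g_sub: dict[str, float]
    ecv_ss: dict[str, float]
    i_ecv: np.ndarray
    h2: np.ndarray
    item_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "omega_t": self.omega_t,
            "omega_h": self.omega_h,
            "ecv_g": self.ecv_g,
            "omega_s": self.omega_s,
            "omega_hs": self.omega_hs,
            "ecv_g_sub": self.ecv_g_sub,
            "ecv_ss": self.ecv_ss,
            "i_ecv": list(map(float, self.i_ecv)),
            "h2": list(map(float, self.h2)),
            "item_ids": self.item_ids,
        }


def bifactor_indices(
    lambda_g: Sequence[float],
    lambda_s: Sequence[float],
    groups: Sequence[str],
    item_ids: Sequence[str] | None = None,
) -> BifactorIndexSet:
    """Bifactor indices from standardized loadings under simple structure.

    ``groups[i]`` names the specific factor of item i ("" for general-only
    items).  Uniquenesses are 1 - h^2 with h^2 = lambda_G^2 + lambda_S^2.
    """
    lg = np.asarray(lambda_g, dtype=float)
    ls = np.asarray(lambda_s, dtype=float)
    groups = ["" if g is None else str(g) for g in groups]
    if not (lg.shape == ls.shape and len(groups) == lg.size):
        raise ValueError("loading vectors and groups must have equal length")
    labels = sorted({g for g in groups if g})
    h2 = lg ** 2 + ls ** 2
    uniq = 1.0 - h2
    if np.any(uniq < 0):
        raise ValueError("communality >= 1 for some item")

    sum_g = lg.sum()
    spec_sq = {s: ls[[g == s for g in groups]].sum() ** 2 for s in labels}
    common = sum_g ** 2 + sum(spec_sq.values())
    total = common + uniq.sum()
    omega_t = float(common / total)
    omega_h = float(sum_g ** 2 / total)
    ecv_g = float(np.sum(lg ** 2) / np.sum(h2))

    omega_s, omega_hs, ecv_g_sub, ecv_ss = {}, {}, {}, {}
    for s in labels:
        m = np.array([g == s for g in groups])
        num_g = lg[m].sum() ** 2
        num_s = ls[m].sum() ** 2
        tot_s = num_g + num_s + uniq[m].sum()
        omega_s[s] = float((num_g + num_s) / tot_s)
        omega_hs[s] = float(num_s / tot_s)
        gg = np.sum(lg[m] ** 2)
        ss = np.sum(ls[m] ** 2)
        ecv_g_sub[s] = float(gg / (gg + ss))
        ecv_ss[s] = float(ss / (gg + ss))

    with np.errstate(invalid="ignore", divide="ignore"):
        i_ecv = np.where(h2 > 0, lg ** 2 / h2, np.nan)
    return BifactorIndexSet(
        omega_t=omega_t, omega_h=omega_h, ecv_g=ecv_g,
        omega_s=omega_s, omega_hs=omega_hs,
        ecv_g_sub=ecv_g_sub, ecv_ss=ecv_ss,
        i_ecv=i_ecv, h2=h2,
        item_ids=list(item_ids) if item_ids is not None else
        [f"item{i + 1}" for i in range(lg.size)],
    )


# ---------------------------------------------------------------------------
# decision rules
# ---------------------------------------------------------------------------

#: Added-value cutoffs at the two published reliability anchors.
_ADDED_VALUE_RULES = {
    "low": {"anchor": 0.60, "omega_hs": 0.25, "ecv_ss": 0.45},
    "high": {"anchor": 0.80, "omega_hs": 0.20, "ecv_ss": 0.30},
}


@dataclass
class DecisionOutcome:
    general_verdict: str  # "strong" | "not supported"
    subscale_added_value: dict[str, bool]
    trace: list[str] = field(default_factory=list)


def interpretability_rules(indices: BifactorIndexSet) -> DecisionOutcome:
    """Apply the general-factor and subscale added-value decision rules.

    The reliability regime for each subscale's added-value cutoffs is the
    nearer of the two published anchors (omega_S near .60 vs near .80).
    """
    trace: list[str] = []
    strong = indices.omega_h >= 0.80
    if strong:
        trace.append(f"omega_H = {indices.omega_h:.3f} >= 0.80: "
                     "strong general factor")
    elif indices.omega_h >= 0.70 and indices.ecv_g >= 0.60:
        strong = True
        trace.append(f"omega_H = {indices.omega_h:.3f} >= 0.70 and ECV_G = "
                     f"{indices.ecv_g:.3f} >= 0.60: strong general factor")
    else:
        trace.append(f"omega_H = {indices.omega_h:.3f}, ECV_G = "
                     f"{indices.ecv_g:.3f}: general factor not supported")

    added: dict[str, bool] = {}
    for s, ws in indices.omega_s.items():
        regime = "low" if abs(ws - 0.60) < abs(ws - 0.80) else "high"
        rule = _ADDED_VALUE_RULES[regime]
        ok = (indices.omega_hs[s] >= rule["omega_hs"]
              or indices.ecv_ss[s] >= rule["ecv_ss"])
        added[s] = bool(ok)
        trace.append(
            f"{s}: omega_S = {ws:.3f} ({regime}-reliability regime), "
            f"omega_HS = {indices.omega_hs[s]:.3f} (cutoff {rule['omega_hs']}), "
            f"ECV_SS = {indices.ecv_ss[s]:.3f} (cutoff {rule['ecv_ss']}) -> "
            f"added value {'YES' if ok else 'NO'}"
        )
    return DecisionOutcome(
        general_verdict="strong" if strong else "not supported",
        subscale_added_value=added,
        trace=trace,
    )
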