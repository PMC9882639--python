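"""Graded response models (unidimensional and confirmatory bifactor).

The graded response model treats each 5-point item as a set of ordered
logistic boundary curves: P(X_i >= k | theta) = logistic(a_i' theta + c_{ik})
with strictly decreasing intercepts c_{i1} > ... > c_{i,K-1}.  Estimation is
marginal maximum likelihood via the Bock–Aitkin EM algorithm on a fixed
quadrature grid; persons contribute whichever items they answered, so the
planned missingness of pooled multi-questionnaire data is handled exactly.

Bifactor models (one general factor plus orthogonal modality-specific
factors, each item on at most one specific factor) use the standard
dimension-reduction identity: conditional on the general factor, the
specific factors are independent across item groups, so the multi-way
integral factors into a product of one-dimensional integrals and the E-step
costs O(Q_G * Q_S * items) instead of O(Q^(1+S)).

Standardized loadings bridge the logistic slopes to the factor-analytic
metric via the scaling constant D = 1.702:
a* = a / D, lambda_d = a*_d / sqrt(1 + sum_d a*_d^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .item_bank import MISSING, OrdinalResponseMatrix
from .polychoric import PolychoricResult

__all__ = [
    "D_SCALE",
    "QuadratureSpec",
    "GrmItemParams",
    "GrmSolution",
    "EapScores",
    "fit_unidimensional_grm",
    "fit_bifactor_grm",
    "standardize_loadings",
    "loadings_to_slopes",
    "eap_scores",
    "marginal_reliability",
    "limited_information_fit",
]

D_SCALE = 1.702


@dataclass(frozen=True)
class QuadratureSpec:
    """Fixed quadrature grid: equally spaced nodes with normal weights."""

    n_nodes: int = 49
    bound: float = 6.0
    n_nodes_specific: int = 21

    def grid(self, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_nodes if n is None else n
        nodes = np.linspace(-self.bound, self.bound, n)
        w = stats.norm.pdf(nodes)
        return nodes, w / w.sum()


@dataclass
class GrmItemParams:
    """Slope–intercept parameters and standardized loadings for one item."""

    item_id: str
    a_general: float
    a_specific: float
    intercepts: np.ndarray  # strictly decreasing, length K-1
    specific_factor: str = ""

    @property
    def lambda_general(self) -> float:
        return standardize_loadings(self.a_general, self.a_specific)[0]

    @property
    def lambda_specific(self) -> float:
        return standardize_loadings(self.a_general, self.a_specific)[1]

    @property
    def communality(self) -> float:
        lg, ls = standardize_loadings(self.a_general, self.a_specific)
        return lg * lg + ls * ls


def standardize_loadings(a_general: float, a_specific: float = 0.0
                         ) -> tuple[float, float]:
    """Convert logistic slopes to standardized factor loadings."""
    ag, as_ = a_general / D_SCALE, a_specific / D_SCALE
    denom = np.sqrt(1.0 + ag * ag + as_ * as_)
    return float(ag / denom), float(as_ / denom)


def loadings_to_slopes(lambda_general: float, lambda_specific: float = 0.0
                       ) -> tuple[float, float]:
    """Inverse of :func:`standardize_loadings`."""
    h2 = lambda_general ** 2 + lambda_specific ** 2
    if h2 >= 1.0:
        raise ValueError("communality must be < 1")
    scale = D_SCALE / np.sqrt(1.0 - h2)
    return float(lambda_general * scale), float(lambda_specific * scale)


@dataclass
class GrmSolution:
    """Fitted (bi)factor graded response model."""

    items: list[GrmItemParams]
    n_persons: int
    log_likelihood: float
    converged: bool
    n_cycles: int
    loglik_path: list[float] = field(default_factory=list)
    heywood: bool = False
    model: str = "unidimensional"  # or "bifactor"
    quadrature: QuadratureSpec = field(default_factory=QuadratureSpec)
    n_categories: int = 5

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def loading_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(lambda_G, lambda_S, group labels) arrays over items."""
        lg = np.array([it.lambda_general for it in self.items])
        ls = np.array([it.lambda_specific for it in self.items])
        groups = [it.specific_factor for it in self.items]
        return lg, ls, groups

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_persons": self.n_persons,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_cycles": self.n_cycles,
            "heywood": self.heywood,
            "items": [
                {
                    "item_id": it.item_id,
                    "a_general": it.a_general,
                    "a_specific": it.a_specific,
                    "intercepts": list(map(float, it.intercepts)),
                    "specific_factor": it.specific_factor,
                    "lambda_general": it.lambda_general,
                    "lambda_specific": it.lambda_specific,
                }
                for it in self.items
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# category probabilities and the per-item M-step
# ---------------------------------------------------------------------------

def _category_probs(z: np.ndarray, intercepts: np.ndarray) -> np.ndarray:
    """P(X = k) for each node row given linear predictor z (nodes,) and c (K-1,).

    Returns (nodes, K).  Boundary curves: sigma(z + c_k), k = 1..K-1.
    """
    logits = z[:, None] + intercepts[None, :]
    bound = 1.0 / (1.0 + np.exp(-logits))
    K = intercepts.size + 1
    p = np.empty((z.size, K))
    p[:, 0] = 1.0 - bound[:, 0]
    p[:, 1:-1] = bound[:, :-1] - bound[:, 1:]
    p[:, -1] = bound[:, -1]
    return np.clip(p, 1e-10, 1.0)


def _item_nll_grad(params: np.ndarray, theta: np.ndarray, counts: np.ndarray
                   ) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood and gradient for one item.

    theta: (nodes, d) latent coordinates; counts: (nodes, K) expected counts.
    params = [a_1..a_d, c_1..c_{K-1}].
    """
    d = theta.shape[1]
    a = params[:d]
    c = params[d:]
    z = theta @ a
    logits = z[:, None] + c[None, :]
    sig = 1.0 / (1.0 + np.exp(-logits))
    K = c.size + 1
    p = np.empty((z.size, K))
    p[:, 0] = 1.0 - sig[:, 0]
    p[:, 1:-1] = sig[:, :-1] - sig[:, 1:]
    p[:, -1] = sig[:, -1]
    p = np.clip(p, 1e-10, None)
    nll = -float(np.sum(counts * np.log(p)))

    ratio = counts / p  # (nodes, K)
    sig_d = sig * (1.0 - sig)  # derivative of each boundary curve
    # d logL / d c_m = sum_nodes sig'_m * (ratio[:, m+1] - ratio[:, m])
    diff = ratio[:, 1:] - ratio[:, :-1]  # (nodes, K-1)
    gc = np.sum(sig_d * diff, axis=0)
    ga = theta.T @ np.sum(sig_d * diff, axis=1)
    return nll, -np.concatenate([ga, gc])


def _mstep_item(theta: np.ndarray, counts: np.ndarray, start: np.ndarray
                ) -> np.ndarray:
    res = optimize.minimize(
        _item_nll_grad, start, args=(theta, counts), jac=True,
        method="L-BFGS-B", options={"maxiter": 50, "ftol": 1e-10},
    )
    out = res.x.copy()
    d = theta.shape[1]
    c = out[d:]
    if np.any(np.diff(c) >= 0):  # enforce ordered intercepts (rare repair)
        out[d:] = -np.sort(-c)
    return out


def _start_values(codes: np.ndarray, n_categories: int, d: int) -> np.ndarray:
    """Deterministic starts: unit slopes, intercepts from marginal proportions."""
    obs = codes[codes != MISSING]
    counts = np.bincount(obs.astype(np.int64), minlength=n_categories + 1)[1:]
    counts = counts + 0.5
    cum = np.cumsum(counts)[:-1] / counts.sum()
    c = -stats.norm.ppf(cum) * D_SCALE  # decreasing
    a = np.full(d, 1.0)
    return np.concatenate([a, np.sort(c)[::-1]])


# ---------------------------------------------------------------------------
# unidimensional EM
# ---------------------------------------------------------------------------

def _prob_tables(items_params: list[np.ndarray], theta: np.ndarray, K: int
                 ) -> list[np.ndarray]:
    """Per-item (nodes, K) probability tables; params rows are [a..., c...]."""
    d = theta.shape[1]
    return [_category_probs(theta @ p[:d], p[d:]) for p in items_params]


def fit_unidimensional_grm(
    matrix: OrdinalResponseMatrix,
    item_ids: Sequence[str] | None = None,
    quadrature: QuadratureSpec = QuadratureSpec(),
    tol: float = 1e-5,
    loglik_tol: float = 1e-5,
    max_cycles: int = 500,
) -> GrmSolution:
    """Bock–Aitkin MML-EM fit of a one-factor graded response model.

    Convergence is declared when either the maximum absolute parameter change
    falls below ``tol`` or the marginal log-likelihood increases by less than
    ``loglik_tol``; non-convergence after ``max_cycles`` is flagged on the
    returned solution, never raised.
    """
    items = list(item_ids) if item_ids is not None else list(matrix.item_ids)
    sub = matrix.select_items(items)
    keep = sub.observed.any(axis=1)
    codes = sub.codes[keep]
    n, p = codes.shape
    K = matrix.n_categories
    nodes, wts = quadrature.grid()
    theta = nodes[:, None]

    params = [_start_values(codes[:, j], K, 1) for j in range(p)]
    loglik_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    cycles = 0

    def _estep():
        tables = _prob_tables(params, theta, K)
        L = np.ones((n, nodes.size))
        for j in range(p):
            obs = codes[:, j] != MISSING
            L[obs] *= tables[j][:, codes[obs, j] - 1].T
        marg = L @ wts
        return L, marg, float(np.sum(np.log(marg)))

    for cycles in range(1, max_cycles + 1):
        L, marg, ll = _estep()
        loglik_path.append(ll)
        post = L * wts[None, :] / marg[:, None]  # (n, Q)

        new_params = []
        max_change = 0.0
        for j in range(p):
            obs = codes[:, j] != MISSING
            counts = np.zeros((nodes.size, K))
            cj = codes[obs, j]
            pj = post[obs]
            for k in range(1, K + 1):
                sel = cj == k
                if sel.any():
                    counts[:, k - 1] = pj[sel].sum(axis=0)
            upd = _mstep_item(theta, counts, params[j])
            max_change = max(max_change, float(np.max(np.abs(upd - params[j]))))
            new_params.append(upd)
        params = new_params
        if max_change < tol or (ll - prev_ll) < loglik_tol and cycles > 2:
            converged = True
            break
        prev_ll = ll

    loglik_path.append(_estep()[2])  # likelihood at the final parameters
    item_objs = [
        GrmItemParams(item_id=items[j], a_general=float(params[j][0]),
                      a_specific=0.0, intercepts=params[j][1:].copy())
        for j in range(p)
    ]
    heywood = any(abs(it.a_general) > 25 for it in item_objs)
    return GrmSolution(
        items=item_objs, n_persons=n, log_likelihood=loglik_path[-1],
        converged=converged, n_cycles=cycles, loglik_path=loglik_path,
        heywood=heywood, model="unidimensional", quadrature=quadrature,
        n_categories=K,
    )


# ---------------------------------------------------------------------------
# bifactor EM with dimension reduction
# ---------------------------------------------------------------------------

def _validate_structure(items: Sequence[str], structure: Mapping[str, str]) -> dict:
    """Map item -> group label ('' = general only); groups need >= 2 items."""
    spec = {i: structure.get(i, "") or "" for i in items}
    groups: dict[str, list[str]] = {}
    for i, g in spec.items():
        if g:
            groups.setdefault(g, []).append(i)
    for g, members in groups.items():
        if len(members) < 2:
            raise ValueError(
                f"specific factor {g!r} has {len(members)} item(s); "
                "single-item indicators must load on the general factor only"
            )
    return spec


def fit_bifactor_grm(
    matrix: OrdinalResponseMatrix,
    structure: Mapping[str, str],
    item_ids: Sequence[str] | None = None,
    quadrature: QuadratureSpec = QuadratureSpec(),
    tol: float = 1e-5,
    loglik_tol: float = 1e-5,
    max_cycles: int = 500,
) -> GrmSolution:
    """MML-EM fit of a confirmatory bifactor graded response model.

    ``structure`` maps item_id to the label of its specific factor; items
    absent from the map (or mapped to "") load on the general factor only.
    """
    items = list(item_ids) if item_ids is not None else list(matrix.item_ids)
    spec = _validate_structure(items, structure)
    sub = matrix.select_items(items)
    keep = sub.observed.any(axis=1)
    codes = sub.codes[keep]
    n, p = codes.shape
    K = matrix.n_categories

    g_nodes, g_wts = quadrature.grid()
    s_nodes, s_wts = quadrature.grid(quadrature.n_nodes_specific)
    Qg, Qs = g_nodes.size, s_nodes.size
    group_labels = sorted({g for g in spec.values() if g})
    group_items = {g: [j for j, i in enumerate(items) if spec[i] == g]
                   for g in group_labels}
    general_only = [j for j, i in enumerate(items) if not spec[i]]

    # joint latent grid per specific group: (Qg*Qs, 2) columns [theta_G, theta_S]
    GG, SS = np.meshgrid(g_nodes, s_nodes, indexing="ij")
    joint_theta = np.column_stack([GG.ravel(), SS.ravel()])
    theta_g = g_nodes[:, None]

    params: list[np.ndarray] = []
    for j in range(p):
        d = 2 if spec[items[j]] else 1
        start = _start_values(codes[:, j], K, d)
        if d == 2:
            start[1] = 0.5  # modest starting specific slope
        params.append(start)

    loglik_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    cycles = 0

    def _estep_bf():
        tab_g = {j: _category_probs(theta_g @ params[j][:1], params[j][1:])
                 for j in general_only}
        tab_s = {j: _category_probs(joint_theta @ params[j][:2], params[j][2:])
                 .reshape(Qg, Qs, K) for g in group_labels for j in group_items[g]}
        # conditional group likelihoods A_g[person, Qg, Qs] and their
        # specific-factor integrals G_g[person, Qg]
        Lg = np.ones((n, Qg))
        for j in general_only:
            obs = codes[:, j] != MISSING
            Lg[obs] *= tab_g[j][:, codes[obs, j] - 1].T
        A: dict[str, np.ndarray] = {}
        Gint: dict[str, np.ndarray] = {}
        for g in group_labels:
            Ag = np.ones((n, Qg, Qs))
            for j in group_items[g]:
                obs = codes[:, j] != MISSING
                Ag[obs] *= np.moveaxis(tab_s[j][:, :, codes[obs, j] - 1], -1, 0)
            A[g] = Ag
            Gint[g] = np.clip(Ag @ s_wts, 1e-300, None)
            Lg *= Gint[g]
        marg = Lg @ g_wts
        ll = float(np.sum(np.log(np.clip(marg, 1e-300, None))))
        return Lg, A, Gint, marg, ll

    for cycles in range(1, max_cycles + 1):
        Lg, A, Gint, marg, ll = _estep_bf()
        loglik_path.append(ll)
        post_g = Lg * g_wts[None, :] / marg[:, None]  # (n, Qg)

        new_params = [None] * p
        max_change = 0.0
        # general-only items: 1-D expected counts
        for j in general_only:
            obs = codes[:, j] != MISSING
            counts = np.zeros((Qg, K))
            cj = codes[obs, j]
            pj = post_g[obs]
            for k in range(1, K + 1):
                sel = cj == k
                if sel.any():
                    counts[:, k - 1] = pj[sel].sum(axis=0)
            upd = _mstep_item(theta_g, counts, params[j])
            max_change = max(max_change, float(np.max(np.abs(upd - params[j]))))
            new_params[j] = upd
        # grouped items: joint (Qg, Qs) expected counts
        for g in group_labels:
            # W[j_person, q, m]: joint posterior over (theta_G, theta_s)
            W = (post_g / Gint[g])[:, :, None] * (A[g] * s_wts[None, None, :])
            for j in group_items[g]:
                obs = codes[:, j] != MISSING
                counts = np.zeros((Qg, Qs, K))
                cj = codes[obs, j]
                Wj = W[obs]
                for k in range(1, K + 1):
                    sel = cj == k
                    if sel.any():
                        counts[:, :, k - 1] = Wj[sel].sum(axis=0)
                upd = _mstep_item(joint_theta, counts.reshape(Qg * Qs, K),
                                  params[j])
                max_change = max(max_change, float(np.max(np.abs(upd - params[j]))))
                new_params[j] = upd
        params = new_params
        if max_change < tol or (ll - prev_ll) < loglik_tol and cycles > 2:
            converged = True
            break
        prev_ll = ll

    loglik_path.append(_estep_bf()[4])  # likelihood at the final parameters
    item_objs = []
    for j in range(p):
        if spec[items[j]]:
            item_objs.append(GrmItemParams(
                item_id=items[j], a_general=float(params[j][0]),
                a_specific=float(params[j][1]), intercepts=params[j][2:].copy(),
                specific_factor=spec[items[j]],
            ))
        else:
            item_objs.append(GrmItemParams(
                item_id=items[j], a_general=float(params[j][0]),
                a_specific=0.0, intercepts=params[j][1:].copy(),
            ))
    heywood = any(max(abs(it.a_general), abs(it.a_specific)) > 25
                  for it in item_objs)
    return GrmSolution(
        items=item_objs, n_persons=n, log_likelihood=loglik_path[-1],
        converged=converged, n_cycles=cycles, loglik_path=loglik_path,
        heywood=heywood, model="bifactor", quadrature=quadrature,
        n_categories=K,
    )


def bifactor_loglik_bruteforce(
    solution: GrmSolution, matrix: OrdinalResponseMatrix
) -> float:
    """Marginal log-likelihood by brute-force full-dimensional quadrature.

    Cross-check for the dimension-reduction identity; only practical for one
    specific factor group (2-D grid) or tiny models.
    """
    items = solution.item_ids
    sub = matrix.select_items(items)
    keep = sub.observed.any(axis=1)
    codes = sub.codes[keep]
    n = codes.shape[0]
    K = solution.n_categories
    q = solution.quadrature
    g_nodes, g_wts = q.grid()
    s_nodes, s_wts = q.grid(q.n_nodes_specific)
    groups = sorted({it.specific_factor for it in solution.items
                     if it.specific_factor})
    # full grid over (theta_G, theta_s1, ..., theta_sS)
    axes = [g_nodes] + [s_nodes] * len(groups)
    wt_axes = [g_wts] + [s_wts] * len(groups)
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    wts = np.ones_like(flat[0])
    for mw in np.meshgrid(*wt_axes, indexing="ij"):
        wts *= mw.ravel()

    L = np.ones((n, flat[0].size))
    for j, it in enumerate(solution.items):
        gi = groups.index(it.specific_factor) + 1 if it.specific_factor else None
        z = it.a_general * flat[0]
        if gi is not None:
            z = z + it.a_specific * flat[gi]
        tab = _category_probs(z, it.intercepts)
        obs = codes[:, j] != MISSING
        L[obs] *= tab[:, codes[obs, j] - 1].T
    marg = L @ wts
    return float(np.sum(np.log(np.clip(marg, 1e-300, None))))


# ---------------------------------------------------------------------------
# EAP scoring and reliability
# ---------------------------------------------------------------------------

@dataclass
class EapScores:
    person_ids: list[str]
    theta: np.ndarray  # posterior means
    sd: np.ndarray  # posterior SDs
    factor: str = "general"
    all_missing: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "person_id": self.person_ids,
            "theta": self.theta,
            "sd": self.sd,
        })

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def eap_scores(solution: GrmSolution, matrix: OrdinalResponseMatrix) -> EapScores:
    """Expected a posteriori scores on the (general) factor.

    For bifactor solutions the specific factors are integrated out with the
    same dimension-reduction identity used in estimation.  Persons with no
    observed items get the prior (mean 0, SD 1) and are flagged.
    """
    items = solution.item_ids
    sub = matrix.select_items(items)
    codes = sub.codes
    n = codes.shape[0]
    K = solution.n_categories
    q = solution.quadrature
    g_nodes, g_wts = q.grid()
    Qg = g_nodes.size

    L = np.ones((n, Qg))
    if solution.model == "bifactor":
        s_nodes, s_wts = q.grid(q.n_nodes_specific)
        groups: dict[str, list[int]] = {}
        for j, it in enumerate(solution.items):
            if it.specific_factor:
                groups.setdefault(it.specific_factor, []).append(j)
        GG, SS = np.meshgrid(g_nodes, s_nodes, indexing="ij")
        for j, it in enumerate(solution.items):
            if it.specific_factor:
                continue
            tab = _category_probs(it.a_general * g_nodes, it.intercepts)
            obs = codes[:, j] != MISSING
            L[obs] *= tab[:, codes[obs, j] - 1].T
        for g, members in groups.items():
            Ag = np.ones((n, Qg, s_nodes.size))
            for j in members:
                it = solution.items[j]
                z = it.a_general * GG.ravel() + it.a_specific * SS.ravel()
                tab = _category_probs(z, it.intercepts).reshape(
                    Qg, s_nodes.size, K)
                obs = codes[:, j] != MISSING
                Ag[obs] *= np.moveaxis(tab[:, :, codes[obs, j] - 1], -1, 0)
            L *= np.clip(Ag @ s_wts, 1e-300, None)
    else:
        for j, it in enumerate(solution.items):
            tab = _category_probs(it.a_general * g_nodes, it.intercepts)
            obs = codes[:, j] != MISSING
            L[obs] *= tab[:, codes[obs, j] - 1].T

    post = L * g_wts[None, :]
    marg = post.sum(axis=1)
    post /= marg[:, None]
    mean = post @ g_nodes
    var = post @ (g_nodes ** 2) - mean ** 2
    all_missing = ~sub.observed.any(axis=1)
    mean[all_missing] = 0.0
    var[all_missing] = 1.0
    return EapScores(
        person_ids=list(sub.person_ids), theta=mean,
        sd=np.sqrt(np.clip(var, 0.0, None)),
        factor="general", all_missing=all_missing,
    )


def marginal_reliability(scores: EapScores, include_all_missing: bool = False
                         ) -> float:
    """Marginal (EAP) reliability: 1 - mean posterior variance, prior variance 1."""
    var = scores.sd ** 2
    if not include_all_missing and scores.all_missing is not None:
        var = var[~scores.all_missing]
    if var.size == 0:
        return np.nan
    return float(1.0 - var.mean())


# ---------------------------------------------------------------------------
# limited-information fit
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    srmr: float
    rmsea: float | None
    tli: float | None
    statistic: float | None
    df: int
    defined: bool

    def passes(self, srmr_max: float, tli_min: float, rmsea_max: float) -> bool:
        ok = self.srmr < srmr_max
        if self.defined:
            ok = ok and self.tli > tli_min and self.rmsea < rmsea_max
        return ok


def limited_information_fit(
    solution: GrmSolution, polychoric: PolychoricResult, n: int | None = None
) -> FitIndices:
    """Fit indices from residual polychoric correlations.

    SRMR is the root mean square of the lower-triangle differences between
    the sample polychoric correlations and the model-implied correlations
    Lambda Lambda' (unit diagonal).  The RMSEA/TLI approximations are built
    from a residual-based quadratic-form statistic with each residual scaled
    by the large-sample variance of a correlation, df = #correlations -
    #free slope parameters, and the independence model as baseline.  With
    df <= 0 (e.g. a just-identified 3-item unidimensional model) RMSEA/TLI
    are undefined and omitted.
    """
    order = [polychoric.item_ids.index(i) for i in solution.item_ids]
    S = polychoric.corr[np.ix_(order, order)]
    lg, ls, groups = solution.loading_matrix
    p = lg.size
    labels = sorted({g for g in groups if g})
    Lam = np.zeros((p, 1 + len(labels)))
    Lam[:, 0] = lg
    for j, g in enumerate(groups):
        if g:
            Lam[j, 1 + labels.index(g)] = ls[j]
    Sigma = Lam @ Lam.T
    np.fill_diagonal(Sigma, 1.0)

    iu = np.tril_indices(p, k=-1)
    resid = (S - Sigma)[iu]
    srmr = float(np.sqrt(np.mean(resid ** 2)))

    n_corr = p * (p - 1) // 2
    n_free = int(np.count_nonzero(Lam))
    df = n_corr - n_free
    if n is None:
        n = solution.n_persons
    if df <= 0:
        return FitIndices(srmr=srmr, rmsea=None, tli=None, statistic=None,
                          df=df, defined=False)
    v = (1.0 - Sigma[iu] ** 2) ** 2  # per-correlation large-sample variance * n
    T = float(n * np.sum(resid ** 2 / np.clip(v, 1e-6, None)))
    T0 = float(n * np.sum(S[iu] ** 2 / (1.0 - 0.0) ** 2))
    df0 = n_corr
    rmsea = float(np.sqrt(max(0.0, (T - df) / (df * n))))
    denom = (T0 / df0) - 1.0
    tli = float(((T0 / df0) - (T / df)) / denom) if denom > 0 else np.nan
    return FitIndices(srmr=srmr, rmsea=rmsea, tli=tli, statistic=T, df=df,
                      defined=True)
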