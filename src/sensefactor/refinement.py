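"""Iterative single-subconstruct scale refinement.

Starting from all items theoretically assigned to one modality × response
pattern subconstruct, the procedure (1) clusters items hierarchically on the
polychoric correlation matrix (an ICLUST-style algorithm guided by cluster
alpha and worst-split-half beta), (2) fits the surviving cluster to a
unidimensional graded response model, (3) checks fit and reliability against
fixed retention criteria, and (4) on failure removes the item with the worst
local misfit (largest maximum absolute residual polychoric correlation,
ties broken by the lowest loading) and repeats.  When fewer than three items
remain, or no removal improves SRMR, the subconstruct falls back to a single
expert-designated "most global" item.

Retention criteria (all must hold for a multi-item scale):
TLI > 0.97, RMSEA < 0.089, SRMR < 0.05 (< 0.033 for exactly 3 items),
marginal reliability rho_xx > 0.7, omega total > 0.7.  TLI/RMSEA are skipped
when the model is just-identified (df <= 0) and they are undefined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .grm import (
    eap_scores,
    fit_unidimensional_grm,
    limited_information_fit,
    marginal_reliability,
)
from .item_bank import ItemBank, OrdinalResponseMatrix
from .polychoric import PolychoricResult, polychoric_matrix

__all__ = [
    "RefinementCriteria",
    "ClusterTree",
    "RefinementTrace",
    "iclust",
    "refine_scale",
    "omega_total_unidimensional",
]

#: Minimum worst-split-half reliability for an ICLUST merge to be accepted.
BETA_MIN = 0.45

#: Tolerated drop in beta relative to the weakest multi-item child cluster.
#: At equal within-cluster correlations the merge is borderline by
#: construction (beta stays flat), so a small slack absorbs sampling noise.
BETA_DROP = 0.05


@dataclass(frozen=True)
class RefinementCriteria:
    """Retention thresholds for a refined unidimensional subconstruct scale."""

    tli_min: float = 0.97
    rmsea_max: float = 0.089
    srmr_max: float = 0.05
    srmr_max_3item: float = 0.033
    rho_min: float = 0.7
    omega_min: float = 0.7

    def __post_init__(self) -> None:
        for name in ("tli_min", "rmsea_max", "srmr_max", "srmr_max_3item",
                     "rho_min", "omega_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def srmr_limit(self, n_items: int) -> float:
        return self.srmr_max_3item if n_items == 3 else self.srmr_max

    def evaluate(self, n_items: int, srmr: float, tli: float | None,
                 rmsea: float | None, rho_xx: float, omega_t: float) -> dict:
        """Rule-by-rule evaluation; undefined TLI/RMSEA rows are skipped."""
        checks = {
            "srmr": srmr < self.srmr_limit(n_items),
            "rho_xx": rho_xx > self.rho_min,
            "omega_t": omega_t > self.omega_min,
        }
        if tli is not None:
            checks["tli"] = tli > self.tli_min
        if rmsea is not None:
            checks["rmsea"] = rmsea < self.rmsea_max
        checks["pass"] = all(v for k, v in checks.items() if k != "pass")
        return checks


def omega_total_unidimensional(loadings: Sequence[float]) -> float:
    """Omega total from standardized loadings of a one-factor model."""
    lam = np.asarray(loadings, dtype=float)
    num = lam.sum() ** 2
    return float(num / (num + np.sum(1.0 - lam ** 2)))


# ---------------------------------------------------------------------------
# ICLUST
# ---------------------------------------------------------------------------

def _balanced_splits(k: int):
    """Index splits into floor(k/2) vs the rest: exhaustive for small
    clusters, deterministic heuristics (contiguous midpoint, alternating)
    for larger ones."""
    from itertools import combinations

    half = k // 2
    if k <= 12:
        seen = set()
        for left in combinations(range(k), half):
            right = tuple(i for i in range(k) if i not in left)
            key = min(left, right)
            if key in seen:
                continue
            seen.add(key)
            yield list(left), list(right)
    else:
        yield list(range(half)), list(range(half, k))
        yield list(range(0, k, 2)), list(range(1, k, 2))


def _cluster_stats(R: np.ndarray, members: list[int],
                   children: tuple[list[int], list[int]] | None = None
                   ) -> tuple[float, float]:
    """(alpha, beta) for a cluster of items on correlation matrix R.

    alpha is standardized Cronbach's alpha.  beta is the worst split-half
    reliability over balanced splits of the cluster, 4*cov(half1, half2) /
    var(total).  Singleton clusters carry alpha = beta = 1 by definition but
    are treated as reliability-unknown by the merge rule.
    """
    k = len(members)
    if k == 1:
        return 1.0, 1.0
    sub = R[np.ix_(members, members)]
    V = float(sub.sum())
    if V <= 0:
        return 0.0, 0.0
    alpha = (k / (k - 1)) * (1.0 - k / V)
    beta = np.inf
    for left, right in _balanced_splits(k):
        c_ab = float(sub[np.ix_(left, right)].sum())
        beta = min(beta, 4.0 * c_ab / V)
    return float(alpha), float(beta)


@dataclass
class ClusterTree:
    """Merge history and final clusters of the item-clustering pass."""

    item_ids: list[str]
    merges: list[dict] = field(default_factory=list)
    clusters: list[dict] = field(default_factory=list)  # final, each with items/alpha/beta

    def largest_cluster(self, min_items: int = 3) -> list[str] | None:
        best = None
        for cl in self.clusters:
            if len(cl["items"]) >= min_items:
                if best is None or len(cl["items"]) > len(best["items"]):
                    best = cl
        return list(best["items"]) if best else None


def iclust(poly: PolychoricResult, item_ids: Sequence[str] | None = None,
           beta_min: float = BETA_MIN) -> ClusterTree:
    """Agglomerative item clustering guided by worst-split-half beta.

    At each step the two most similar clusters (correlation between their
    unit-weighted composites) are considered for merging; the merge is
    accepted when the merged cluster's beta is at least ``beta_min`` and not
    lower than the beta of any multi-item candidate.  Merging stops when no
    candidate pair is acceptable.
    """
    items = list(item_ids) if item_ids is not None else list(poly.item_ids)
    idx = [poly.item_ids.index(i) for i in items]
    R = poly.corr[np.ix_(idx, idx)]
    p = len(items)

    clusters: list[dict] = [
        {"items": [j], "alpha": 1.0, "beta": 1.0, "single": True}
        for j in range(p)
    ]
    tree = ClusterTree(item_ids=items)

    def composite_corr(a: list[int], b: list[int]) -> float:
        va = float(R[np.ix_(a, a)].sum())
        vb = float(R[np.ix_(b, b)].sum())
        c = float(R[np.ix_(a, b)].sum())
        return c / np.sqrt(va * vb) if va > 0 and vb > 0 else 0.0

    while len(clusters) > 1:
        # rank candidate pairs by composite correlation, most similar first
        pairs = sorted(
            ((composite_corr(clusters[i]["items"], clusters[j]["items"]), i, j)
             for i in range(len(clusters)) for j in range(i + 1, len(clusters))),
            reverse=True,
        )
        merged_any = False
        for sim, i, j in pairs:
            a, b = clusters[i], clusters[j]
            merged_members = a["items"] + b["items"]
            alpha, beta = _cluster_stats(R, merged_members,
                                         (a["items"], b["items"]))
            child_betas = [c["beta"] for c in (a, b) if not c["single"]]
            floor = max(beta_min, min(child_betas) - BETA_DROP) \
                if child_betas else beta_min
            accepted = beta >= floor
            tree.merges.append({
                "left": [items[m] for m in a["items"]],
                "right": [items[m] for m in b["items"]],
                "similarity": sim,
                "alpha": alpha,
                "beta": beta,
                "accepted": accepted,
            })
            if accepted:
                clusters.pop(j)
                clusters.pop(i)
                clusters.append({"items": merged_members, "alpha": alpha,
                                 "beta": beta, "single": False})
                merged_any = True
                break
        if not merged_any:
            break

    tree.clusters = [
        {"items": [items[m] for m in c["items"]],
         "alpha": c["alpha"], "beta": c["beta"]}
        for c in clusters
    ]
    return tree


# ---------------------------------------------------------------------------
# refinement loop
# ---------------------------------------------------------------------------

@dataclass
class RefinementTrace:
    steps: list[dict] = field(default_factory=list)
    final_items: list[str] = field(default_factory=list)
    decision: str = ""  # "scale retained" | "single-item fallback"
    fallback_item: str | None = None

    def removed_items(self) -> list[str]:
        return [s["removed"] for s in self.steps if s.get("removed")]

    def to_json(self) -> str:
        return json.dumps({
            "decision": self.decision,
            "final_items": self.final_items,
            "fallback_item": self.fallback_item,
            "steps": self.steps,
        }, indent=1, default=str)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _model_implied(loadings: np.ndarray) -> np.ndarray:
    sigma = np.outer(loadings, loadings)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def refine_scale(
    matrix: OrdinalResponseMatrix,
    candidate_items: Sequence[str],
    criteria: RefinementCriteria = RefinementCriteria(),
    bank: ItemBank | None = None,
    fallback_item: str | None = None,
    grm_kwargs: dict | None = None,
) -> tuple[list[str] | str, RefinementTrace]:
    """Run the iterative refinement loop for one subconstruct.

    Returns either (final item list, trace) when a scale is retained, or
    (fallback item id, trace) when the subconstruct cannot support a
    multi-item scale.  The fallback item comes from ``fallback_item``, the
    bank's 'most global' annotation, or — absent both — the candidate item
    with the largest summed absolute polychoric correlation.
    """
    candidates = list(candidate_items)
    if not candidates:
        raise ValueError("empty candidate item set")
    grm_kwargs = grm_kwargs or {}
    trace = RefinementTrace()

    poly_all = polychoric_matrix(matrix, candidates)

    def pick_fallback() -> str:
        if fallback_item is not None:
            return fallback_item
        if bank is not None:
            for it in bank.items:
                if it.item_id in candidates and it.most_global:
                    return it.item_id
        sums = np.abs(poly_all.corr).sum(axis=1)
        return candidates[int(np.argmax(sums))]

    if len(candidates) < 3:
        fb = pick_fallback()
        trace.steps.append({"action": "fallback",
                            "reason": f"only {len(candidates)} candidate items "
                                      "(minimum of three needed for a scale)"})
        trace.decision = "single-item fallback"
        trace.fallback_item = fb
        return fb, trace

    # cluster once on the full candidate pool; keep the dominant cluster
    tree = iclust(poly_all, candidates)
    current = tree.largest_cluster(min_items=3)
    if current is None:
        fb = pick_fallback()
        trace.steps.append({"action": "fallback",
                            "reason": "no item cluster of three or more items"})
        trace.decision = "single-item fallback"
        trace.fallback_item = fb
        return fb, trace
    dropped_at_clustering = [i for i in candidates if i not in current]
    if dropped_at_clustering:
        trace.steps.append({"action": "cluster-restrict",
                            "kept": list(current),
                            "dropped": dropped_at_clustering,
                            "reason": "items outside the dominant ICLUST cluster"})

    prev_srmr = np.inf
    while True:
        poly = polychoric_matrix(matrix, current)
        sol = fit_unidimensional_grm(matrix, current, **grm_kwargs)
        fit = limited_information_fit(sol, poly)
        scores = eap_scores(sol, matrix.select_items(current))
        rho = marginal_reliability(scores)
        lams = [it.lambda_general for it in sol.items]
        omega = omega_total_unidimensional(lams)
        checks = criteria.evaluate(len(current), fit.srmr, fit.tli, fit.rmsea,
                                   rho, omega)
        step = {
            "action": "evaluate",
            "items": list(current),
            "srmr": fit.srmr, "tli": fit.tli, "rmsea": fit.rmsea,
            "rho_xx": rho, "omega_t": omega,
            "checks": checks,
        }
        if checks["pass"]:
            step["result"] = "scale retained"
            trace.steps.append(step)
            trace.decision = "scale retained"
            trace.final_items = list(current)
            return list(current), trace

        if len(current) <= 3:
            step["result"] = "reject scale, use single item"
            trace.steps.append(step)
            fb = pick_fallback()
            trace.steps.append({"action": "fallback",
                                "reason": "criteria unmet at minimum scale size"})
            trace.decision = "single-item fallback"
            trace.fallback_item = fb
            return fb, trace

        if fit.srmr >= prev_srmr and checks.get("srmr") is False:
            step["result"] = "reject scale, removals no longer improve SRMR"
            trace.steps.append(step)
            fb = pick_fallback()
            trace.steps.append({"action": "fallback",
                                "reason": "no removal improves SRMR"})
            trace.decision = "single-item fallback"
            trace.fallback_item = fb
            return fb, trace
        prev_srmr = fit.srmr

        # local misfit: residual polychoric correlations against the implied
        lam = np.array([it.lambda_general for it in sol.items])
        resid = np.abs(poly.corr - _model_implied(lam))
        np.fill_diagonal(resid, 0.0)
        worst = resid.max(axis=1)
        top = np.flatnonzero(np.isclose(worst, worst.max(), atol=1e-12))
        if top.size > 1:  # tie-break: lowest loading
            top = top[np.argsort(np.abs(lam[top]))][:1]
        removed = current[int(top[0])]
        step["removed"] = removed
        step["result"] = (f"removed {removed} "
                          f"(max |residual r| = {worst.max():.3f})")
        trace.steps.append(step)
        current = [i for i in current if i != removed]
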