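"""Thresholds and polychoric correlations for ordinal questionnaire items.

Two ordinal items are modeled as discretizations of a latent bivariate
normal: item-specific thresholds cut each latent variate into ordered
categories, and the polychoric correlation is the latent correlation that
best explains the observed contingency table.  Estimation is two-stage
(Olsson): thresholds are fixed at the inverse-normal transforms of the
marginal cumulative proportions, then the correlation maximizes the
bivariate-normal cell likelihood by bounded one-dimensional optimization.

Missing responses are handled by pairwise deletion — planned missingness by
questionnaire version makes listwise deletion unusable for pooled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .item_bank import MISSING, OrdinalResponseMatrix

__all__ = [
    "PolychoricResult",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
    "nearest_psd",
]

#: Keep |rho| away from 1 so downstream factor routines have finite information.
RHO_BOUND = 0.999

_CLIP = 8.0  # treat thresholds beyond +-8 as infinite for CDF purposes


def estimate_thresholds(column: np.ndarray, n_categories: int = 5) -> np.ndarray:
    """Normal-theory thresholds for one ordinal item.

    threshold_k = Phi^{-1}(P(code <= k)), k = 1..K-1.  Categories that are
    never observed produce infinite thresholds (collapsed categories), which
    downstream code treats as absent cut-points.

    Raises ValueError on an all-missing column.
    """
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise ValueError("cannot estimate thresholds from an all-missing column")
    counts = np.bincount(obs.astype(np.int64), minlength=n_categories + 1)[1:]
    cum = np.cumsum(counts)[:-1] / obs.size
    return stats.norm.ppf(cum)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal cell probabilities on the grid cut by two threshold sets."""
    ax = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ay = np.concatenate(([-np.inf], tau_y, [np.inf]))
    ax = np.clip(ax, -_CLIP, _CLIP)
    ay = np.clip(ay, -_CLIP, _CLIP)
    # CDF at every grid node, via the Genz bivariate normal routine
    gx, gy = np.meshgrid(ax, ay, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cdf = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]],
                                    allow_singular=True).cdf(pts)
    cdf = cdf.reshape(gx.shape)
    cells = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(cells, 1e-12, 1.0)


@dataclass
class PairResult:
    rho: float
    n: int
    converged: bool


def polychoric_pair(x: np.ndarray, y: np.ndarray, n_categories: int = 5
                    ) -> PairResult:
    """Two-stage ML polychoric correlation for one item pair.

    Requires at least two observed categories on each margin after pairwise
    deletion; degenerate margins return a non-converged result with rho NaN.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    both = (x != MISSING) & (y != MISSING)
    xs, ys = x[both].astype(np.int64), y[both].astype(np.int64)
    n = int(both.sum())
    if n == 0:
        return PairResult(np.nan, 0, False)
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        return PairResult(np.nan, n, False)

    table = np.zeros((n_categories, n_categories))
    np.add.at(table, (xs - 1, ys - 1), 1.0)
    tau_x = estimate_thresholds(xs, n_categories)
    tau_y = estimate_thresholds(ys, n_categories)
    # drop infinite thresholds (collapsed categories) together with their rows
    fx = np.isfinite(tau_x)
    fy = np.isfinite(tau_y)
    # collapse the table to observed-category blocks delimited by finite taus
    table = _collapse(table, fx, axis=0)
    table = _collapse(table, fy, axis=1)
    tx, ty = tau_x[fx], tau_y[fy]

    nz = table > 0

    def nll(rho: float) -> float:
        p = _cell_probs(tx, ty, rho)
        return -float(np.sum(table[nz] * np.log(p[nz])))

    res = optimize.minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return PairResult(float(res.x), n, bool(res.success))


def _collapse(table: np.ndarray, finite: np.ndarray, axis: int) -> np.ndarray:
    """Merge contingency-table slices separated only by infinite thresholds."""
    # finite has K-1 entries; group boundaries are where finite is True
    groups = np.concatenate(([0], np.cumsum(finite)))
    k = groups[-1] + 1
    idx = groups
    shape = list(table.shape)
    shape[axis] = k
    out = np.zeros(shape)
    for src, dst in enumerate(idx):
        sl_src = [slice(None)] * 2
        sl_dst = [slice(None)] * 2
        sl_src[axis] = src
        sl_dst[axis] = dst
        out[tuple(sl_dst)] += table[tuple(sl_src)]
    return out


@dataclass
class PolychoricResult:
    """Item × item polychoric correlation matrix with estimation metadata."""

    item_ids: list[str]
    corr: np.ndarray
    thresholds: dict[str, np.ndarray]
    pairwise_n: np.ndarray
    converged: np.ndarray
    min_eigenvalue: float = np.nan
    psd_repaired: bool = False

    def validate(self) -> None:
        if not np.allclose(self.corr, self.corr.T, atol=1e-8):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("diagonal not 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.corr, index=self.item_ids, columns=self.item_ids)

    def save(self, path) -> None:
        self.to_frame().to_csv(path)


def nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def polychoric_matrix(
    matrix: OrdinalResponseMatrix,
    item_ids: list[str] | None = None,
    repair: bool = True,
) -> PolychoricResult:
    """Pairwise polychoric correlation matrix over the requested items.

    Non-convergent or empty pairs are flagged and their entries set to 0
    (so downstream linear algebra stays finite).  When the pairwise matrix
    is indefinite and ``repair`` is set, the nearest-PSD repair is applied
    and flagged.
    """
    items = item_ids if item_ids is not None else list(matrix.item_ids)
    p = len(items)
    cols = {i: matrix.column(i) for i in items}
    corr = np.eye(p)
    ns = np.zeros((p, p), dtype=np.int64)
    conv = np.ones((p, p), dtype=bool)
    thresholds = {}
    for i in items:
        obs = cols[i][cols[i] != MISSING]
        thresholds[i] = (estimate_thresholds(cols[i], matrix.n_categories)
                         if obs.size else np.full(matrix.n_categories - 1, np.nan))
    for a in range(p):
        ns[a, a] = int((cols[items[a]] != MISSING).sum())
        for b in range(a + 1, p):
            pr = polychoric_pair(cols[items[a]], cols[items[b]],
                                 matrix.n_categories)
            rho = pr.rho if np.isfinite(pr.rho) else 0.0
            corr[a, b] = corr[b, a] = rho
            ns[a, b] = ns[b, a] = pr.n
            conv[a, b] = conv[b, a] = pr.converged and np.isfinite(pr.rho)

    vals = np.linalg.eigvalsh(corr)
    min_eig = float(vals.min())
    repaired = False
    if repair and min_eig < 0:
        corr = nearest_psd(corr)
        repaired = True
    out = PolychoricResult(
        item_ids=list(items),
        corr=corr,
        thresholds=thresholds,
        pairwise_n=ns,
        converged=conv,
        min_eigenvalue=min_eig,
        psd_repaired=repaired,
    )
    out.validate()
    return out
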