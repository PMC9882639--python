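"""Synthetic multi-study sensory questionnaire data with known ground truth.

The generator emulates the statistical structure of pooled caregiver-report
data: a dozen studies of widely varying size, 5-point ordinal items driven
by a bifactor common-factor model, questionnaire-version-dependent item
coverage (structural missingness), between-study shifts in the latent trait
mean, and demographic/clinical correlates with study-heterogeneous effect
sizes.

Items are generated from the normal-ogive representation of the graded
response model: the latent response y* = lambda_G theta_G + lambda_S theta_S
+ sqrt(1 - h^2) eps is cut at fixed thresholds (default evenly spaced on
[-2, 2]).  The marginal of y* is standard normal, so population category
probabilities and the population polychoric matrix (Lambda Lambda' off the
diagonal) are known exactly — every downstream estimator can be tested
against closed-form truth.

Default study conditions: 12 studies (matching the number of pooled data
sources emulated), study sizes drawn log-uniformly between 30 and 1300,
study-mean SD 0.35 on the general trait, and slope heterogeneity tau_1 as
requested per correlate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .item_bank import (
    MISSING,
    CorrelateTable,
    ItemBank,
    ItemDefinition,
    OrdinalResponseMatrix,
)
from .tables import load_loading_table, loading_arrays

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "default_thresholds",
    "make_fixture_suite",
    "planted_scale_dataset",
    "toy_item_bank",
]


def default_thresholds(n_categories: int = 5) -> np.ndarray:
    """Evenly spaced latent-response thresholds on [-2, 2]."""
    return np.linspace(-2.0, 2.0, n_categories - 1)


def _instruments_of(item_id: str) -> set[str]:
    """Source instruments read off a harmonized item label like 'SP1 Q1/SP2 Q1'."""
    out = set()
    for part in str(item_id).split("/"):
        token = part.strip().split(" ")[0]
        if token:
            out.add(token)
    return out


@dataclass
class SyntheticSpec:
    """Generating conditions for one synthetic multi-study dataset."""

    loading_table: pd.DataFrame = field(
        default_factory=lambda: load_loading_table("HYPER"))
    n_studies: int = 12
    study_sizes: Sequence[int] | None = None  # drawn 30..1300 when None
    thresholds: np.ndarray | None = None  # per-item rows or single vector
    study_mean_sd: float = 0.35
    coverage: Mapping[str, Sequence[str]] | None = None  # study -> instruments
    correlate_r: Mapping[str, float] = field(default_factory=dict)
    correlate_d: Mapping[str, float] = field(default_factory=dict)
    tau1: float = 0.05
    binary_prevalence: float = 0.3
    n_categories: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name, r in self.correlate_r.items():
            if abs(r) >= 1:
                raise ValueError(f"target correlation for {name!r} must be in (-1, 1)")
        lam_g, lam_s, _ = loading_arrays(self.loading_table)
        if np.any(lam_g ** 2 + lam_s ** 2 >= 1):
            raise ValueError("item communalities must be < 1")


@dataclass
class SyntheticDataset:
    matrix: OrdinalResponseMatrix
    correlates: CorrelateTable
    truth: dict


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the spec; fully reproducible from its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lam_g, lam_s, groups = loading_arrays(spec.loading_table)
    items = list(spec.loading_table["item"])
    p = len(items)
    K = spec.n_categories

    if spec.thresholds is None:
        tau = np.tile(default_thresholds(K), (p, 1))
    else:
        tau = np.asarray(spec.thresholds, dtype=float)
        tau = np.tile(tau, (p, 1)) if tau.ndim == 1 else tau

    if spec.study_sizes is not None:
        sizes = list(spec.study_sizes)
    else:
        sizes = np.exp(rng.uniform(np.log(30), np.log(1300),
                                   spec.n_studies)).astype(int).tolist()
    n_studies = len(sizes)
    study_labels = [f"S{i + 1}" for i in range(n_studies)]
    n = int(sum(sizes))
    study_of = np.repeat(np.arange(n_studies), sizes)

    # latent traits: within-study standard normal + study shift on theta_G
    study_shift = rng.normal(0.0, spec.study_mean_sd, n_studies)
    z = rng.standard_normal(n)
    theta_g = z + study_shift[study_of]

    group_labels = sorted({g for g in groups if g})
    theta_s = {g: rng.standard_normal(n) for g in group_labels}

    # binary correlates shift theta_G by the target within-study d
    bin_values: dict[str, np.ndarray] = {}
    for name, d_target in spec.correlate_d.items():
        d_s = d_target + rng.normal(0.0, spec.tau1, n_studies)
        b = (rng.uniform(size=n) < spec.binary_prevalence).astype(int)
        theta_g = theta_g + d_s[study_of] * (b - spec.binary_prevalence)
        bin_values[name] = b

    # ordinal responses from the normal-ogive bifactor model
    h2 = lam_g ** 2 + lam_s ** 2
    eps_sd = np.sqrt(1.0 - h2)
    codes = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        y = lam_g[j] * theta_g
        if groups[j]:
            y = y + lam_s[j] * theta_s[groups[j]]
        y = y + eps_sd[j] * rng.standard_normal(n)
        codes[:, j] = 1 + np.searchsorted(tau[j], y)

    # continuous correlates built from the within-study part of theta_G
    cont_values: dict[str, np.ndarray] = {}
    for name, r_target in spec.correlate_r.items():
        r_s = np.clip(r_target + rng.normal(0.0, spec.tau1, n_studies),
                      -0.99, 0.99)
        rr = r_s[study_of]
        cont_values[name] = rr * z + np.sqrt(1.0 - rr ** 2) * rng.standard_normal(n)

    # instrument coverage -> structural missingness
    if spec.coverage is not None:
        inst_of_item = [_instruments_of(i) for i in items]
        for s_idx, label in enumerate(study_labels):
            admin = set(spec.coverage.get(label, []))
            if not admin:
                continue
            rows = study_of == s_idx
            for j, inst in enumerate(inst_of_item):
                if not (inst & admin):
                    codes[rows, j] = MISSING
        versions = ["+".join(sorted(spec.coverage.get(study_labels[s], ["ALL"])))
                    for s in study_of]
    else:
        versions = ["ALL"] * n

    person_ids = [f"P{i + 1:05d}" for i in range(n)]
    matrix = OrdinalResponseMatrix(
        person_ids=person_ids,
        item_ids=items,
        codes=codes,
        study_ids=[study_labels[s] for s in study_of],
        instrument_versions=versions,
        n_categories=K,
    )

    rows = []
    for name, vals in cont_values.items():
        rows.append(pd.DataFrame({
            "person_id": person_ids, "name": name, "value": vals,
            "value_type": "continuous"}))
    for name, vals in bin_values.items():
        rows.append(pd.DataFrame({
            "person_id": person_ids, "name": name, "value": vals,
            "value_type": "binary"}))
    corr_df = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=list(CorrelateTable.REQUIRED)))
    correlates = CorrelateTable(corr_df)

    truth = {
        "lambda_g": lam_g,
        "lambda_s": lam_s,
        "groups": groups,
        "thresholds": tau,
        "theta_g": theta_g,
        "theta_s": theta_s,
        "study_shift": study_shift,
        "study_sizes": sizes,
        "correlate_r": dict(spec.correlate_r),
        "correlate_d": dict(spec.correlate_d),
        "tau1": spec.tau1,
    }
    return SyntheticDataset(matrix=matrix, correlates=correlates, truth=truth)


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures
# ---------------------------------------------------------------------------

def toy_item_bank() -> ItemBank:
    """Six-item single-modality bank with SP1/SEQ3 crosswalk and a fallback item."""
    defs = []
    for i in range(1, 7):
        sources = [("SEQ3", f"Q{i}")]
        if i <= 3:
            sources.append(("SP1", f"Q{i}"))
        defs.append(ItemDefinition(
            item_id=f"AUD_HYPER_{i}",
            source_codes=tuple(sources),
            modality="Auditory",
            response_pattern="HYPER",
            reverse_scored=(i <= 3),
            most_global=(i == 1),
        ))
    return ItemBank(defs)


def planted_scale_dataset(
    n: int = 1000,
    seed: int = 0,
    scale_loading: float = 0.75,
    n_scale: int = 4,
    n_distractor: int = 2,
) -> SyntheticDataset:
    """A clean unidimensional scale plus unrelated distractor items.

    The first ``n_scale`` items load ``scale_loading`` on a common factor;
    the distractors are generated from independent latent variates.  Ground
    truth (the planted item set) is recorded in ``truth['planted']``.
    """
    items = ([f"SCALE_{i + 1}" for i in range(n_scale)]
             + [f"NOISE_{i + 1}" for i in range(n_distractor)])
    table = pd.DataFrame({
        "item": items,
        "specific_factor": [""] * len(items),
        "lambda_g": [scale_loading] * n_scale + [0.0] * n_distractor,
        "lambda_s": [np.nan] * len(items),
    })
    spec = SyntheticSpec(
        loading_table=table, n_studies=1, study_sizes=[n],
        study_mean_sd=0.0, seed=seed,
    )
    ds = generate(spec)
    ds.truth["planted"] = items[:n_scale]
    return ds


def planted_blocks_dataset(
    n: int = 1000,
    seed: int = 0,
    n_blocks: int = 2,
    block_size: int = 3,
    within_loading: float = 0.707,
) -> SyntheticDataset:
    """Items forming independent blocks (zero between-block correlation).

    Each block is a one-factor cluster with within-block latent correlation
    ``within_loading**2``; blocks share no general factor.  Used as ground
    truth for community detection and item clustering.
    """
    items, groups = [], []
    for b in range(n_blocks):
        for i in range(block_size):
            items.append(f"B{b + 1}_I{i + 1}")
            groups.append(f"BLOCK{b + 1}")
    table = pd.DataFrame({
        "item": items,
        "specific_factor": groups,
        "lambda_g": [0.0] * len(items),
        "lambda_s": [within_loading] * len(items),
    })
    spec = SyntheticSpec(
        loading_table=table, n_studies=1, study_sizes=[n],
        study_mean_sd=0.0, seed=seed,
    )
    ds = generate(spec)
    ds.truth["blocks"] = {f"BLOCK{b + 1}": items[b * block_size:(b + 1) * block_size]
                          for b in range(n_blocks)}
    return ds


def make_fixture_suite(seed: int = 0) -> dict:
    """Small deterministic bundles for unit tests.

    Contents: the toy 6-item bank, a planted-cluster dataset with its known
    partition, a null-effect multi-study correlate dataset, and the three
    printed loading tables.
    """
    null_spec = SyntheticSpec(
        loading_table=load_loading_table("HYPO"),
        n_studies=6, study_sizes=[120] * 6,
        correlate_r={"null_corr": 0.0}, tau1=0.0, seed=seed + 17,
    )
    return {
        "toy_bank": toy_item_bank(),
        "planted_clusters": planted_blocks_dataset(n=600, seed=seed + 3,
                                                   n_blocks=3),
        "null_effects": generate(null_spec),
        "loading_tables": {c: load_loading_table(c)
                           for c in ("HYPER", "HYPO", "SEEK")},
    }
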