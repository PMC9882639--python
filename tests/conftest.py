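"""Shared fixtures: small synthetic datasets, fitted models, loading tables.

Expensive objects (fitted GRMs, generated datasets) are session-scoped so
the suite pays for them once.
"""

import numpy as np
import pandas as pd
import pytest

from sensefactor.grm import QuadratureSpec, fit_unidimensional_grm
from sensefactor.synthetic import SyntheticSpec, generate
from sensefactor.tables import load_loading_table


@pytest.fixture(scope="session")
def hyper_table():
    return load_loading_table("HYPER")


@pytest.fixture(scope="session")
def hypo_table():
    return load_loading_table("HYPO")


@pytest.fixture(scope="session")
def seek_table():
    return load_loading_table("SEEK")


def make_uni_table(n_items: int, loading: float, prefix: str = "I") -> pd.DataFrame:
    return pd.DataFrame({
        "item": [f"{prefix}{i + 1}" for i in range(n_items)],
        "specific_factor": [""] * n_items,
        "lambda_g": [loading] * n_items,
        "lambda_s": [np.nan] * n_items,
    })


@pytest.fixture(scope="session")
def uni6_dataset():
    """Six-item unidimensional dataset, one study, n = 2000, loading 0.66."""
    spec = SyntheticSpec(loading_table=make_uni_table(6, 0.66), n_studies=1,
                         study_sizes=[2000], study_mean_sd=0.0, seed=42)
    return generate(spec)


@pytest.fixture(scope="session")
def uni6_solution(uni6_dataset):
    return fit_unidimensional_grm(uni6_dataset.matrix, tol=1e-4, max_cycles=200)


@pytest.fixture(scope="session")
def hypo_dataset():
    """Dataset simulated from the 11-item hyporeactivity bifactor structure."""
    spec = SyntheticSpec(loading_table=load_loading_table("HYPO"),
                         n_studies=1, study_sizes=[1500],
                         study_mean_sd=0.0, seed=101)
    return generate(spec)
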