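"""Packaged standardized bifactor loading tables for the three sensory response patterns.

Each table gives, per harmonized questionnaire item, the standardized loading
on the general response-pattern factor (``lambda_g``) and — for items that
belong to a multi-item modality subscale — the loading on that modality's
specific factor (``lambda_s``).  Single-item indicators load on the general
factor only and carry no specific loading.

These matrices are the fixed inputs for bifactor index computation
(:func:`sensefactor.structure.bifactor_indices`) and the default generating
structures for the synthetic-data module.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_loading_table", "loading_arrays", "CONSTRUCTS"]

CONSTRUCTS = ("HYPER", "HYPO", "SEEK")

_FILES = {
    "HYPER": "hyper_loadings.csv",
    "HYPO": "hypo_loadings.csv",
    "SEEK": "seek_loadings.csv",
}


def load_loading_table(construct: str) -> pd.DataFrame:
    """Return the loading table for one response pattern.

    Parameters
    ----------
    construct
        One of ``"HYPER"``, ``"HYPO"``, ``"SEEK"``.

    Returns
    -------
    DataFrame with columns ``item``, ``specific_factor`` (empty string for
    general-only items), ``lambda_g``, ``lambda_s`` (NaN for general-only).
    """
    key = construct.upper()
    if key not in _FILES:
        raise KeyError(f"unknown construct {construct!r}; expected one of {CONSTRUCTS}")
    with resources.files("sensefactor.data").joinpath(_FILES[key]).open() as fh:
        df = pd.read_csv(fh, dtype={"item": str, "specific_factor": str})
    df["specific_factor"] = df["specific_factor"].fillna("")
    return df


def loading_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Convert a loading table to (lambda_g vector, lambda_s vector, group labels).

    ``lambda_s`` is 0 for general-only items; the group label is ``""`` there.
    """
    lam_g = table["lambda_g"].to_numpy(dtype=float)
    lam_s = table["lambda_s"].fillna(0.0).to_numpy(dtype=float)
    groups = list(table["specific_factor"])
    return lam_g, lam_s, groups
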