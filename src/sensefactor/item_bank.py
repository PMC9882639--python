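"""Harmonized item bank and ordinal response containers for multi-study pooling.

Caregiver sensory questionnaires (Sensory Profile 1/2 and their short forms,
Sensory Experiences Questionnaire 2.1/3.0) overlap in content but not in item
numbering or scoring direction.  This module holds the crosswalk between
original instrument item codes and harmonized items, merges raw per-instrument
response tables into a single persons × items ordinal matrix, and applies the
two harmonization rules used throughout the pipeline:

* SP1/SSP1 items are scored in the opposite direction of the other
  instruments and are reverse-coded (``k -> 6 - k`` on a 5-point scale) so
  that a 5 always denotes more frequent behavior;
* a person who completed two instruments that map to the same harmonized
  item keeps the SEQ-sourced value (the SEQ versions contribute more items
  to the bank); the conflict is recorded.

Missing responses use the explicit sentinel ``MISSING = 0`` — planned
missingness by questionnaire version is structural, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MODALITIES",
    "RESPONSE_PATTERNS",
    "MISSING",
    "REVERSED_INSTRUMENTS",
    "ItemDefinition",
    "ItemBank",
    "OrdinalResponseMatrix",
    "CorrelateTable",
    "StudyMetadata",
    "BankValidationError",
    "load_item_bank",
    "harmonize_responses",
    "filter_eligible",
    "reverse_code",
    "derive_id_status",
]

MODALITIES = (
    "Auditory",
    "Visual",
    "Tactile",
    "Olfactory",
    "Gustatory",
    "OralTactile",
    "Movement",
)
RESPONSE_PATTERNS = ("HYPER", "HYPO", "SEEK")

#: Sentinel for a structurally missing response (codes are 1..n_categories).
MISSING = 0

#: Instruments scored opposite to the harmonized direction.
REVERSED_INSTRUMENTS = frozenset({"SP1", "SSP1"})

#: Instruments whose value wins when a person has duplicate observations
#: of one harmonized item (higher priority first).
INSTRUMENT_PRIORITY = ("SEQ3", "SEQ2", "SP2", "SSP2", "SP1", "SSP1")


class BankValidationError(ValueError):
    """Raised when an item bank violates its structural invariants."""


@dataclass(frozen=True)
class ItemDefinition:
    """One harmonized questionnaire item.

    ``source_codes`` lists (instrument, original item code) pairs, e.g.
    ``("SP1", "Q1")``.  ``most_global`` marks the item an expert designated
    as the single-item fallback for its subconstruct.
    """

    item_id: str
    source_codes: tuple[tuple[str, str], ...]
    modality: str
    response_pattern: str
    reverse_scored: bool = False
    n_categories: int = 5
    single_item_indicator: bool = False
    most_global: bool = False

    def __post_init__(self) -> None:
        if not self.source_codes:
            raise BankValidationError(f"item {self.item_id!r} has no source codes")
        if self.modality not in MODALITIES:
            raise BankValidationError(
                f"item {self.item_id!r}: unknown modality {self.modality!r}"
            )
        if self.response_pattern not in RESPONSE_PATTERNS:
            raise BankValidationError(
                f"item {self.item_id!r}: unknown response pattern "
                f"{self.response_pattern!r}"
            )
        if self.n_categories < 2:
            raise BankValidationError(
                f"item {self.item_id!r}: n_categories must be >= 2"
            )


@dataclass
class ItemBank:
    """Validated collection of harmonized items."""

    items: list[ItemDefinition]

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_sources: dict[tuple[str, str], str] = {}
        for it in self.items:
            if it.item_id in seen_ids:
                raise BankValidationError(f"duplicate item_id {it.item_id!r}")
            seen_ids.add(it.item_id)
            for src in it.source_codes:
                if src in seen_sources:
                    raise BankValidationError(
                        f"source code {src!r} appears under both "
                        f"{seen_sources[src]!r} and {it.item_id!r}"
                    )
                seen_sources[src] = it.item_id
        if not self.items:
            raise BankValidationError("item bank is empty")

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, modality: str | None = None, response_pattern: str | None = None
               ) -> list[ItemDefinition]:
        out = self.items
        if modality is not None:
            out = [it for it in out if it.modality == modality]
        if response_pattern is not None:
            out = [it for it in out if it.response_pattern == response_pattern]
        return out

    def fallback_item(self, modality: str, response_pattern: str) -> ItemDefinition | None:
        """The expert-annotated 'most global' single-item fallback, if any."""
        for it in self.subset(modality, response_pattern):
            if it.most_global:
                return it
        return None

    def source_index(self) -> dict[tuple[str, str], ItemDefinition]:
        return {src: it for it in self.items for src in it.source_codes}

    # ---- I/O -------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": it.item_id,
                    "source_codes": [list(s) for s in it.source_codes],
                    "modality": it.modality,
                    "response_pattern": it.response_pattern,
                    "reverse_scored": it.reverse_scored,
                    "n_categories": it.n_categories,
                    "single_item_indicator": it.single_item_indicator,
                    "most_global": it.most_global,
                }
                for it in self.items
            ]
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ItemBank":
        raw = payload.get("items")
        if not raw:
            raise BankValidationError("bank config defines no items")
        items = [
            ItemDefinition(
                item_id=str(entry["item_id"]),
                source_codes=tuple(tuple(s) for s in entry["source_codes"]),
                modality=entry["modality"],
                response_pattern=entry["response_pattern"],
                reverse_scored=bool(entry.get("reverse_scored", False)),
                n_categories=int(entry.get("n_categories", 5)),
                single_item_indicator=bool(entry.get("single_item_indicator", False)),
                most_global=bool(entry.get("most_global", False)),
            )
            for entry in raw
        ]
        return cls(items)


def load_item_bank(path: str | Path) -> ItemBank:
    """Load and validate an item bank from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise BankValidationError(f"{path} is empty")
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, Mapping):
        raise BankValidationError(f"{path} does not contain a mapping")
    return ItemBank.from_dict(payload)


@dataclass
class OrdinalResponseMatrix:
    """Persons × items ordinal codes with study membership.

    ``codes`` holds integers in ``1..n_categories`` or :data:`MISSING`.
    """

    person_ids: list[str]
    item_ids: list[str]
    codes: np.ndarray
    study_ids: list[str]
    instrument_versions: list[str]
    n_categories: int = 5

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        n, p = self.codes.shape
        if len(self.person_ids) != n or len(self.item_ids) != p:
            raise ValueError("codes shape does not match id lists")
        if len(self.study_ids) != n or len(self.instrument_versions) != n:
            raise ValueError("per-person metadata length mismatch")
        bad = (self.codes != MISSING) & (
            (self.codes < 1) | (self.codes > self.n_categories)
        )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"out-of-range code {self.codes[i, j]} for person "
                f"{self.person_ids[i]!r}, item {self.item_ids[j]!r}"
            )

    @property
    def n_persons(self) -> int:
        return self.codes.shape[0]

    @property
    def observed(self) -> np.ndarray:
        return self.codes != MISSING

    def column(self, item_id: str) -> np.ndarray:
        return self.codes[:, self.item_ids.index(item_id)]

    def select_items(self, item_ids: Sequence[str]) -> "OrdinalResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return OrdinalResponseMatrix(
            person_ids=list(self.person_ids),
            item_ids=list(item_ids),
            codes=self.codes[:, idx].copy(),
            study_ids=list(self.study_ids),
            instrument_versions=list(self.instrument_versions),
            n_categories=self.n_categories,
        )

    def select_persons(self, mask: np.ndarray) -> "OrdinalResponseMatrix":
        mask = np.asarray(mask, dtype=bool)
        return OrdinalResponseMatrix(
            person_ids=[p for p, m in zip(self.person_ids, mask) if m],
            item_ids=list(self.item_ids),
            codes=self.codes[mask].copy(),
            study_ids=[s for s, m in zip(self.study_ids, mask) if m],
            instrument_versions=[v for v, m in zip(self.instrument_versions, mask) if m],
            n_categories=self.n_categories,
        )

    # ---- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.item_ids)
        df.insert(0, "person_id", self.person_ids)
        df.insert(1, "study_id", self.study_ids)
        df.insert(2, "instrument_version", self.instrument_versions)
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_categories: int = 5
                   ) -> "OrdinalResponseMatrix":
        meta = ["person_id", "study_id", "instrument_version"]
        items = [c for c in df.columns if c not in meta]
        return cls(
            person_ids=[str(v) for v in df["person_id"]],
            item_ids=items,
            codes=df[items].to_numpy(dtype=np.int64),
            study_ids=[str(v) for v in df["study_id"]],
            instrument_versions=[str(v) for v in df["instrument_version"]],
            n_categories=n_categories,
        )

    @classmethod
    def load(cls, path: str | Path, n_categories: int = 5) -> "OrdinalResponseMatrix":
        return cls.from_frame(pd.read_csv(path), n_categories=n_categories)


@dataclass
class CorrelateTable:
    """Long-format person-level correlate values.

    Columns: ``person_id``, ``name``, ``value``, ``value_type`` (``continuous``
    or ``binary``).
    """

    data: pd.DataFrame

    REQUIRED = ("person_id", "name", "value", "value_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"correlate table missing columns {missing}")
        bad = ~self.data["value_type"].isin(["continuous", "binary"])
        if bad.any():
            raise ValueError("value_type must be 'continuous' or 'binary'")

    def get(self, name: str) -> pd.Series:
        sub = self.data[self.data["name"] == name]
        return pd.Series(sub["value"].to_numpy(), index=sub["person_id"].to_numpy())

    def names(self) -> list[str]:
        return sorted(self.data["name"].unique())

    def save(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CorrelateTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class StudyMetadata:
    study_id: str
    n_persons: int
    instruments: tuple[str, ...]


def reverse_code(codes: np.ndarray, n_categories: int = 5) -> np.ndarray:
    """Reverse-score ordinal codes (``k -> K + 1 - k``), leaving MISSING alone.

    An involution: applying it twice restores the input.
    """
    codes = np.asarray(codes)
    out = codes.copy()
    obs = codes != MISSING
    out[obs] = n_categories + 1 - codes[obs]
    return out


def derive_id_status(fsiq: float | None, nviq: float | None,
                     is_dq: bool = False) -> int | None:
    """Binary intellectual-disability indicator.

    FSIQ < 70; when FSIQ is missing, NVIQ < 70.  Developmental-quotient
    analogs are excluded from the rule, returning None.
    """
    if is_dq:
        return None
    if fsiq is not None and not np.isnan(fsiq):
        return int(fsiq < 70)
    if nviq is not None and not np.isnan(nviq):
        return int(nviq < 70)
    return None


def harmonize_responses(
    raw_tables: Mapping[str, pd.DataFrame],
    bank: ItemBank,
    study_ids: Mapping[str, str] | None = None,
) -> tuple[OrdinalResponseMatrix, list[dict]]:
    """Merge per-instrument raw response tables into one harmonized matrix.

    Parameters
    ----------
    raw_tables
        Maps instrument name (e.g. ``"SP1"``) to a table with a ``person_id``
        column and one column per original item code.  Codes are 1..5 or
        missing (NaN / 0).
    bank
        The harmonization crosswalk.
    study_ids
        Optional person_id -> study_id map (default: single study ``"S1"``).

    Returns
    -------
    (matrix, conflicts) where each conflict records a person/item pair that
    had observations from two instruments; the higher-priority instrument's
    value (SEQ before SP) was kept.
    """
    src_index = bank.source_index()
    item_ids = bank.item_ids
    item_pos = {iid: j for j, iid in enumerate(item_ids)}

    persons: list[str] = []
    person_pos: dict[str, int] = {}
    person_instruments: dict[str, list[str]] = {}
    for inst, df in raw_tables.items():
        for pid in df["person_id"].astype(str):
            if pid not in person_pos:
                person_pos[pid] = len(persons)
                persons.append(pid)
                person_instruments[pid] = []
            person_instruments[pid].append(inst)

    codes = np.full((len(persons), len(item_ids)), MISSING, dtype=np.int64)
    # priority rank of the instrument that produced each stored value
    rank = {inst: r for r, inst in enumerate(INSTRUMENT_PRIORITY)}
    provenance = np.full((len(persons), len(item_ids)), len(rank) + 1, dtype=np.int64)
    conflicts: list[dict] = []

    for inst, df in raw_tables.items():
        inst_rank = rank.get(inst, len(rank))
        reversed_inst = inst in REVERSED_INSTRUMENTS
        for col in df.columns:
            if col == "person_id":
                continue
            item = src_index.get((inst, col))
            if item is None:
                continue
            j = item_pos[item.item_id]
            vals = df[col].to_numpy()
            pids = df["person_id"].astype(str).to_numpy()
            for pid, v in zip(pids, vals):
                if v is None or (isinstance(v, float) and np.isnan(v)) or v == MISSING:
                    continue
                v = int(v)
                if not 1 <= v <= item.n_categories:
                    raise ValueError(
                        f"out-of-range raw code {v} (person {pid!r}, "
                        f"instrument {inst!r}, item {col!r})"
                    )
                if reversed_inst:
                    v = item.n_categories + 1 - v
                i = person_pos[pid]
                if codes[i, j] != MISSING and provenance[i, j] != inst_rank:
                    kept_new = inst_rank < provenance[i, j]
                    conflicts.append(
                        {
                            "person_id": pid,
                            "item_id": item.item_id,
                            "kept_instrument": inst if kept_new
                            else INSTRUMENT_PRIORITY[provenance[i, j]],
                            "discarded_value": codes[i, j] if kept_new else v,
                        }
                    )
                    if not kept_new:
                        continue
                codes[i, j] = v
                provenance[i, j] = inst_rank

    matrix = OrdinalResponseMatrix(
        person_ids=persons,
        item_ids=item_ids,
        codes=codes,
        study_ids=[study_ids.get(p, "S1") if study_ids else "S1" for p in persons],
        instrument_versions=["+".join(sorted(set(person_instruments[p])))
                             for p in persons],
    )
    return matrix, conflicts


def filter_eligible(
    matrix: OrdinalResponseMatrix,
    ages: Mapping[str, float] | pd.Series,
    min_age: float = 3.0,
    max_age: float = 18.0,
) -> tuple[OrdinalResponseMatrix, dict]:
    """Retain persons whose age lies in the closed interval [min_age, max_age].

    Persons without a recorded age are retained (ages are not universally
    available across pooled studies).  Returns the filtered matrix and a
    summary of counts.
    """
    if isinstance(ages, pd.Series):
        ages = dict(zip((str(i) for i in ages.index), ages.to_numpy()))
    keep = np.ones(matrix.n_persons, dtype=bool)
    n_out = 0
    for i, pid in enumerate(matrix.person_ids):
        a = ages.get(str(pid))
        if a is None or (isinstance(a, float) and np.isnan(a)):
            continue
        if not (min_age <= a <= max_age):
            keep[i] = False
            n_out += 1
    out = matrix.select_persons(keep)
    return out, {"n_in": matrix.n_persons, "n_removed": n_out, "n_kept": out.n_persons}
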