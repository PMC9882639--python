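"""Item bank validation, harmonization rules, and eligibility filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensefactor.item_bank import (
    MISSING,
    BankValidationError,
    ItemBank,
    ItemDefinition,
    OrdinalResponseMatrix,
    filter_eligible,
    harmonize_responses,
    load_item_bank,
    reverse_code,
)
from sensefactor.synthetic import SyntheticSpec, generate, toy_item_bank
from sensefactor.tables import load_loading_table

MODALITY_OF = {
    "Auditory": "Auditory", "Visual": "Visual", "Tactile": "Tactile",
    "Gustatory": "Gustatory", "Olfactory": "Olfactory", "Movement": "Movement",
}


def hyper_bank():
    """The 23-item hyperreactivity bank built from the packaged loading table."""
    table = load_loading_table("HYPER")
    defs = []
    for row in table.itertuples():
        sources = tuple(
            (part.strip().split(" ")[0], part.strip().split(" ", 1)[1])
            for part in row.item.split("/")
        )
        defs.append(ItemDefinition(
            item_id=row.item, source_codes=sources,
            modality=MODALITY_OF[row.specific_factor],
            response_pattern="HYPER",
            reverse_scored=any(s[0] in ("SP1", "SSP1") for s in sources),
        ))
    return ItemBank(defs)


class TestItemBank:
    def test_hyper_bank_has_23_items_across_6_modalities(self):
        bank = hyper_bank()
        assert len(bank) == 23
        assert len({it.modality for it in bank.items}) == 6

    def test_empty_config_rejected(self, tmp_path):
        f = tmp_path / "bank.yaml"
        f.write_text("")
        with pytest.raises(BankValidationError):
            load_item_bank(f)

    def test_duplicate_source_code_rejected(self):
        items = [
            ItemDefinition("A", (("SP1", "Q1"),), "Auditory", "HYPER"),
            ItemDefinition("B", (("SP1", "Q1"),), "Visual", "HYPER"),
        ]
        with pytest.raises(BankValidationError, match="SP1"):
            ItemBank(items)

    def test_unknown_modality_rejected(self):
        with pytest.raises(BankValidationError, match="modality"):
            ItemDefinition("A", (("SP1", "Q1"),), "Telepathic", "HYPER")

    def test_roundtrip_yaml_and_json(self, tmp_path):
        bank = toy_item_bank()
        for name in ("bank.yaml", "bank.json"):
            path = tmp_path / name
            bank.save(path)
            again = load_item_bank(path)
            assert again.to_dict() == bank.to_dict()


class TestHarmonization:
    def _raw(self):
        sp1 = pd.DataFrame({
            "person_id": ["p1", "p2"],
            "Q1": [1, 4], "Q2": [2, np.nan], "Q3": [5, 3],
        })
        seq3 = pd.DataFrame({
            "person_id": ["p2", "p3"],
            "Q1": [3, 2], "Q4": [4, 1], "Q5": [np.nan, 5], "Q6": [2, 2],
        })
        return {"SP1": sp1, "SEQ3": seq3}

    def test_sp1_reverse_scored(self):
        matrix, _ = harmonize_responses(self._raw(), toy_item_bank())
        # p1's SP1 Q1 raw 1 -> 5 after reversal
        assert matrix.column("AUD_HYPER_1")[matrix.person_ids.index("p1")] == 5

    def test_seq_identity_scoring(self):
        matrix, _ = harmonize_responses(self._raw(), toy_item_bank())
        # p3's SEQ3 Q4 raw 1 stays 1
        assert matrix.column("AUD_HYPER_4")[matrix.person_ids.index("p3")] == 1

    def test_duplicate_resolved_in_favor_of_seq(self):
        matrix, conflicts = harmonize_responses(self._raw(), toy_item_bank())
        # p2 answered SP1 Q1 (raw 4 -> 2) and SEQ3 Q1 (3); SEQ wins
        assert matrix.column("AUD_HYPER_1")[matrix.person_ids.index("p2")] == 3
        assert any(c["person_id"] == "p2" and c["kept_instrument"] == "SEQ3"
                   for c in conflicts)

    def test_missingness_equals_instrument_coverage(self):
        matrix, _ = harmonize_responses(self._raw(), toy_item_bank())
        # p1 completed only SP1 -> items 4-6 (SEQ3-only) must be missing
        i1 = matrix.person_ids.index("p1")
        for item in ("AUD_HYPER_4", "AUD_HYPER_5", "AUD_HYPER_6"):
            assert matrix.column(item)[i1] == MISSING
        # p3 completed only SEQ3 -> item 1 observed via SEQ3 Q1
        assert matrix.column("AUD_HYPER_1")[matrix.person_ids.index("p3")] == 2

    def test_no_observation_without_source(self):
        matrix, _ = harmonize_responses(self._raw(), toy_item_bank())
        raw = self._raw()
        for i, pid in enumerate(matrix.person_ids):
            for j, item_id in enumerate(matrix.item_ids):
                if matrix.codes[i, j] == MISSING:
                    continue
                item = toy_item_bank()[item_id]
                has_source = False
                for inst, code in item.source_codes:
                    df = raw.get(inst)
                    if df is None or code not in df.columns \
                            or pid not in set(df["person_id"]):
                        continue
                    v = df.loc[df["person_id"] == pid, code]
                    if v.size and not pd.isna(v.iloc[0]):
                        has_source = True
                assert has_source

    def test_out_of_range_raw_code_rejected(self):
        raw = self._raw()
        raw["SP1"].loc[0, "Q1"] = 7
        with pytest.raises(ValueError, match="out-of-range"):
            harmonize_responses(raw, toy_item_bank())

    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_reverse_coding_is_involution(self, codes):
        arr = np.array(codes)
        assert np.array_equal(reverse_code(reverse_code(arr)), arr)


class TestEligibility:
    def _matrix(self, pids):
        n = len(pids)
        return OrdinalResponseMatrix(
            person_ids=pids, item_ids=["X"],
            codes=np.ones((n, 1), dtype=int),
            study_ids=["S1"] * n, instrument_versions=["SEQ3"] * n,
        )

    def test_closed_interval_boundaries(self):
        matrix = self._matrix(["a", "b", "c", "d"])
        ages = {"a": 2.9, "b": 3.0, "c": 18.0, "d": 18.1}
        out, info = filter_eligible(matrix, ages, 3.0, 18.0)
        assert out.person_ids == ["b", "c"]
        assert info["n_removed"] == 2

    def test_empty_input(self):
        matrix = self._matrix(["a"]).select_persons(np.array([False]))
        out, info = filter_eligible(matrix, {}, 3.0, 18.0)
        assert out.n_persons == 0

    def test_known_out_of_range_fraction(self):
        spec = SyntheticSpec(n_studies=1, study_sizes=[200], seed=5)
        ds = generate(spec)
        rng = np.random.default_rng(5)
        ages = rng.uniform(3.0, 18.0, 200)
        out_idx = rng.choice(200, 20, replace=False)  # plant 10% out of range
        ages[out_idx] = 20.0
        age_map = dict(zip(ds.matrix.person_ids, ages))
        out, info = filter_eligible(ds.matrix, age_map, 3.0, 18.0)
        assert info["n_removed"] == 20
        assert out.n_persons == 180


class TestRoundTrip:
    def test_response_matrix_csv_roundtrip(self, tmp_path, uni6_dataset):
        path = tmp_path / "m.csv"
        uni6_dataset.matrix.save(path)
        again = OrdinalResponseMatrix.load(path)
        assert again.person_ids == uni6_dataset.matrix.person_ids
        assert again.item_ids == uni6_dataset.matrix.item_ids
        assert np.array_equal(again.codes, uni6_dataset.matrix.codes)
        assert again.study_ids == uni6_dataset.matrix.study_ids
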