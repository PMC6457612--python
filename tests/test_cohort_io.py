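"""Loading, the variability filter, dummy expansion, the missingness basis,
and threshold-derived outcome labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynasl import (
    CohortTable,
    ColumnMeta,
    build_missingness_basis,
    coagulopathy_definition,
    derive_outcome_labels,
    expand_dummies,
    filter_variability,
    load_cohort,
    massive_transfusion_definition,
)
from dynasl.cohort_io import OBS_SUFFIX, OBSVAL_SUFFIX


class TestLoad:
    def test_csv_roundtrip_with_missing_cell(self, tiny_table, tmp_path):
        path = tmp_path / "cohort.csv"
        tiny_table.to_csv(path)
        loaded = CohortTable.from_csv(path)
        assert loaded.n_patients == 3
        assert loaded.data["lactate_t0"].isna().sum() == 1
        assert loaded.meta["lactate_t0"].time == 0.0

    def test_dta_roundtrip_matches_csv(self, tiny_table, tmp_path):
        csv_path = tmp_path / "c.csv"
        dta_path = tmp_path / "c.dta"
        tiny_table.to_csv(csv_path)
        tiny_table.data.to_stata(dta_path, write_index=False)
        from_csv = load_cohort(csv_path)
        from_dta = load_cohort(dta_path, metadata=tiny_table.meta)
        for col in tiny_table.meta:
            np.testing.assert_allclose(
                from_csv.data[col].to_numpy(dtype=float),
                from_dta.data[col].to_numpy(dtype=float),
                rtol=1e-6,
            )

    def test_duplicate_patient_id_names_the_id(self):
        frame = pd.DataFrame({"patient_id": [1, 1], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="1"):
            CohortTable(frame, {"x": ColumnMeta(kind="continuous")})

    def test_undeclared_column_type_rejected(self):
        frame = pd.DataFrame({"patient_id": [1], "x": [0.0]})
        with pytest.raises(ValueError, match="x"):
            CohortTable(frame, {})

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_cohort(tmp_path / "nope.csv")


def _table(columns, kinds):
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame({"patient_id": range(n), **columns})
    meta = {c: ColumnMeta(kind=k) for c, k in kinds.items()}
    return CohortTable(frame, meta)


class TestVariabilityFilter:
    def test_level_below_threshold_dropped(self):
        # 49 positives of 1494 is below the 50-per-level floor
        vals = np.zeros(1494)
        vals[:49] = 1.0
        table = _table({"tobacco": vals}, {"tobacco": "binary"})
        filtered, report = filter_variability(table, min_count=50)
        assert "tobacco" not in filtered.meta
        assert report.decisions.iloc[0]["reason"] == "level below threshold"

    def test_exactly_fifty_per_level_retained(self):
        vals = np.zeros(1494)
        vals[:50] = 1.0
        table = _table({"tobacco": vals}, {"tobacco": "binary"})
        filtered, _ = filter_variability(table, min_count=50)
        assert "tobacco" in filtered.meta

    def test_constant_column_dropped_with_reason(self):
        table = _table({"c": np.ones(100)}, {"c": "continuous"})
        filtered, report = filter_variability(table, min_count=50)
        assert "c" not in filtered.meta
        assert report.decisions.iloc[0]["reason"] == "constant"

    def test_continuous_needs_enough_nonmissing(self):
        vals = np.r_[np.random.default_rng(0).normal(size=30), [np.nan] * 70]
        table = _table({"lab": vals}, {"lab": "continuous"})
        filtered, report = filter_variability(table, min_count=50)
        assert "lab" not in filtered.meta
        assert report.decisions.iloc[0]["reason"] == "insufficient non-missing"

    def test_min_count_one_drops_only_constants(self):
        rng = np.random.default_rng(1)
        table = _table(
            {"a": rng.normal(size=50), "b": np.full(50, 7.0), "c": (rng.random(50) < 0.1) * 1.0},
            {"a": "continuous", "b": "continuous", "c": "binary"},
        )
        filtered, report = filter_variability(table, min_count=1)
        assert set(filtered.meta) == {"a", "c"}
        assert report.decisions.set_index("variable").loc["b", "reason"] == "constant"

    def test_report_partitions_variables(self):
        rng = np.random.default_rng(2)
        table = _table(
            {"a": rng.normal(size=100), "b": np.ones(100)},
            {"a": "continuous", "b": "continuous"},
        )
        _, report = filter_variability(table, min_count=10)
        assert sorted(report.retained() + report.dropped()) == ["a", "b"]

    def test_outcome_columns_never_filtered(self, tiny_table):
        filtered, _ = filter_variability(tiny_table, min_count=50)
        assert "death" in filtered.meta and "death_time" in filtered.meta


class TestDummyExpansion:
    def test_three_level_column_gives_three_indicators(self):
        table = _table({"site": ["A", "B", "C", "A", np.nan]}, {"site": "categorical"})
        out = expand_dummies(table)
        cols = [c for c in out.meta if c.startswith("site=")]
        assert sorted(cols) == ["site=A", "site=B", "site=C"]
        observed = out.data[cols].dropna()
        assert (observed.sum(axis=1) == 1.0).all()

    def test_missing_value_propagates_to_all_indicators(self):
        table = _table({"site": ["A", "B", np.nan]}, {"site": "categorical"})
        out = expand_dummies(table)
        row = out.data.iloc[2][[c for c in out.meta if c.startswith("site=")]]
        assert row.isna().all()

    def test_idempotent_on_binary_columns(self):
        table = _table({"male": [1.0, 0.0, 1.0]}, {"male": "binary"})
        once = expand_dummies(table)
        twice = expand_dummies(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_level_cap_enforced(self):
        table = _table({"id2": [str(i) for i in range(30)]}, {"id2": "categorical"})
        with pytest.raises(ValueError, match="id2"):
            expand_dummies(table, max_levels=20)


class TestMissingnessBasis:
    def test_spec_mapping(self):
        table = _table({"x": [5.1, np.nan, 3.0]}, {"x": "continuous"})
        out = build_missingness_basis(table)
        assert list(out.data["x" + OBS_SUFFIX]) == [1.0, 0.0, 1.0]
        assert list(out.data["x" + OBSVAL_SUFFIX]) == [5.1, 0.0, 3.0]
        assert "x" not in out.meta
        assert out.meta["x" + OBS_SUFFIX].missingness_indicator

    def test_fully_observed_column_passes_through(self):
        table = _table({"x": [1.0, 2.0, 3.0]}, {"x": "continuous"})
        out = build_missingness_basis(table)
        assert list(out.meta) == ["x"]
        pd.testing.assert_frame_equal(out.data, table.data)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**20), n=st.integers(3, 30), miss=st.floats(0.0, 0.9))
    def test_roundtrip_property(self, seed, n, miss):
        # (Delta, Delta*X) reconstructs X on observed cells; output has no NaN
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        mask = rng.random(n) < miss
        x_miss = x.copy()
        x_miss[mask] = np.nan
        table = _table({"x": x_miss, "z": rng.normal(size=n)},
                       {"x": "continuous", "z": "continuous"})
        out = build_missingness_basis(table)
        preds = out.data[out.predictor_columns()]
        assert preds.notna().all().all()
        if mask.any():
            delta = out.data["x" + OBS_SUFFIX].to_numpy()
            prod = out.data["x" + OBSVAL_SUFFIX].to_numpy()
            np.testing.assert_array_equal(delta, (~mask).astype(float))
            np.testing.assert_allclose(prod[~mask], x[~mask])
            np.testing.assert_array_equal(prod[mask], 0.0)

    def test_pipeline_composition_yields_numeric_complete_table(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        x[rng.random(n) < 0.2] = np.nan
        table = _table(
            {"x": x, "site": rng.choice(["A", "B"], size=n), "flat": np.ones(n)},
            {"x": "continuous", "site": "categorical", "flat": "continuous"},
        )
        filtered, _ = filter_variability(table, min_count=10)
        encoded = build_missingness_basis(expand_dummies(filtered))
        preds = encoded.data[encoded.predictor_columns()]
        assert preds.notna().all().all()
        assert all(np.issubdtype(d, np.number) for d in preds.dtypes)


class TestOutcomeLabels:
    @pytest.mark.parametrize(
        "inr, ptt, expected",
        [
            (1.5, 30.0, 1.0),   # INR strictly above 1.4 qualifies
            (1.4, 34.9, 0.0),   # both on the non-qualifying side
            (1.0, 35.0, 1.0),   # PTT at the inclusive threshold qualifies
        ],
    )
    def test_coagulopathy_thresholds(self, inr, ptt, expected):
        table = _table({"inr": [inr], "ptt": [ptt]},
                       {"inr": "continuous", "ptt": "continuous"})
        out = derive_outcome_labels(table, [coagulopathy_definition()])
        assert out.data["coagulopathy"].iloc[0] == expected
        assert out.meta["coagulopathy"].role == "outcome"

    def test_missing_source_gives_missing_label(self):
        table = _table({"inr": [np.nan], "ptt": [30.0]},
                       {"inr": "continuous", "ptt": "continuous"})
        out = derive_outcome_labels(table, [coagulopathy_definition()])
        assert np.isnan(out.data["coagulopathy"].iloc[0])

    def test_massive_transfusion_volume_threshold(self):
        table = _table({"transfused_volume_24h": [10.0, 10.5]},
                       {"transfused_volume_24h": "continuous"})
        out = derive_outcome_labels(table, [massive_transfusion_definition()])
        assert list(out.data["massive_transfusion"]) == [0.0, 1.0]

    def test_missing_source_column_named_in_error(self, tiny_table):
        with pytest.raises(KeyError, match="inr"):
            derive_outcome_labels(tiny_table, [coagulopathy_definition()])
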