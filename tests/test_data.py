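"""Reading, outcome derivation, filtering, encoding and descriptive stats."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest

from dwscrash import data, schema
from dwscrash.data import (
    EmptyInputError,
    EmptySampleError,
    MissingDataWarning,
    SchemaError,
    apply_filters,
    code_temporal,
    derive_dws_count,
    descriptive_table,
    encode_design,
    percentages_from_counts,
    read_crash_table,
)
from dwscrash.simulate import default_scenario, generate_scenario


def _csv(table: pd.DataFrame) -> io.StringIO:
    return io.StringIO(table.to_csv(index=False))


@pytest.fixture(scope="module")
def raw_table():
    return generate_scenario(default_scenario(n=60, seed=5)).table


class TestReadCrashTable:
    def test_roundtrip_preserves_rows_and_values(self, raw_table):
        got = read_crash_table(_csv(raw_table))
        assert got.shape[0] == raw_table.shape[0]
        assert not (got[list(schema.ENUM_COLUMNS)] == schema.MISSING).any().any()
        pd.testing.assert_frame_equal(
            got.drop(columns="crash_id"),
            raw_table.drop(columns=["crash_id", "dws_count"]),
            check_dtype=False,
        )

    def test_missing_mandatory_column_is_schema_error(self, raw_table):
        broken = raw_table.drop(columns=["latitude"])
        with pytest.raises(SchemaError, match="latitude"):
            read_crash_table(_csv(broken))

    def test_empty_file_is_distinct_error(self):
        with pytest.raises(EmptyInputError):
            read_crash_table(io.StringIO(""))
        header_only = io.StringIO(",".join(schema.COLUMNS) + "\n")
        with pytest.raises(EmptyInputError):
            read_crash_table(header_only)

    def test_blank_cell_becomes_missing_others_intact(self, raw_table):
        t = raw_table.copy()
        t.loc[t.index[1], "gender"] = ""
        got = read_crash_table(_csv(t))
        assert got.loc[1, "gender"] == schema.MISSING
        assert got.loc[0, "gender"] == raw_table.loc[0, "gender"]
        assert got.loc[1, "season"] == raw_table.loc[1, "season"]

    def test_column_map_renames(self, raw_table):
        t = raw_table.rename(columns={"latitude": "LAT"})
        got = read_crash_table(_csv(t), column_map={"latitude": "LAT"})
        assert np.allclose(got["latitude"], raw_table["latitude"])

    def test_out_of_range_coordinates_become_nan(self, raw_table):
        t = raw_table.copy()
        t.loc[t.index[0], "latitude"] = 123.0
        got = read_crash_table(_csv(t))
        assert np.isnan(got.loc[0, "latitude"])


class TestDeriveDwsCount:
    def test_all_sixteen_code_pairs_match_decision_table(self):
        codes = ("Standard", "Optional", "Not Available", schema.MISSING)
        for f, b in itertools.product(codes, codes):
            got = derive_dws_count(f, b)
            if "Optional" in (f, b) or schema.MISSING in (f, b):
                expected = data.EXCLUDED
            else:
                expected = (f == "Standard") + (b == "Standard")
            assert got == expected, (f, b)

    def test_both_standard_is_two(self):
        assert derive_dws_count("Standard", "Standard") == 2

    def test_vectorized_outcome_matches_scalar(self, raw_table):
        coded = data.add_dws_outcome(raw_table)
        for _, row in coded.head(20).iterrows():
            scalar = derive_dws_count(row["fcws_code"], row["bsm_code"])
            if scalar == data.EXCLUDED:
                assert np.isnan(row["dws_count"])
            else:
                assert row["dws_count"] == scalar


class TestApplyFilters:
    def test_single_vehicle_rule_counts(self, raw_table):
        t = raw_table.copy()
        t.loc[t.index[:2], "n_vehicles"] = 1
        kept, report = apply_filters(t)
        assert report.removed_single_vehicle == 2
        assert kept.shape[0] == t.shape[0] - 2

    def test_report_matches_brute_force_recount(self):
        contaminated = default_scenario(
            n=50, seed=9, missing_rate=0.1, optional_rate=0.1, single_vehicle_rate=0.1
        )
        t = generate_scenario(contaminated).table
        with warnings_ignored():
            kept, report = apply_filters(t)
        # independent per-rule recount with the same precedence
        single = opt = unk = miss = 0
        for _, row in t.iterrows():
            if row["n_vehicles"] < 2:
                single += 1
            elif "Optional" in (row["fcws_code"], row["bsm_code"]):
                opt += 1
            elif schema.MISSING in (row["fcws_code"], row["bsm_code"]):
                unk += 1
            else:
                missing = any(
                    (row[c] == schema.MISSING)
                    if isinstance(row[c], str)
                    else pd.isna(row[c])
                    for c in data.MODEL_FIELDS
                )
                miss += missing
        assert (
            report.removed_single_vehicle,
            report.removed_optional_dws,
            report.removed_unknown,
            report.removed_missing,
        ) == (single, opt, unk, miss)
        assert report.n_retained == kept.shape[0]

    def test_missing_fraction_warning_threshold(self, raw_table):
        t = pd.concat([raw_table] * 2, ignore_index=True).head(100)
        t.loc[t.index[:3], "gender"] = schema.MISSING
        with pytest.warns(MissingDataWarning):
            apply_filters(t)
        t2 = t.copy()
        t2["gender"] = raw_table["gender"].iloc[0]
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("error", MissingDataWarning)
            apply_filters(t2)

    def test_idempotent(self, raw_table):
        kept, _ = apply_filters(raw_table)
        again, report = apply_filters(kept)
        assert report.n_removed == 0
        assert again.shape[0] == kept.shape[0]

    def test_all_rows_removed_is_error(self, raw_table):
        t = raw_table.copy()
        t["n_vehicles"] = 1
        with pytest.raises(EmptySampleError):
            apply_filters(t)


class warnings_ignored:
    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore", MissingDataWarning)

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


class TestCodeTemporal:
    @pytest.mark.parametrize("year,index", [(2016, 1), (2018, 3), (2020, 5)])
    def test_linear_index(self, raw_table, year, index):
        t = raw_table.copy()
        t["year"] = year
        assert (code_temporal(t)["year_index"] == index).all()

    def test_out_of_range_year_is_error(self, raw_table):
        t = raw_table.copy()
        t.loc[t.index[0], "year"] = 2015
        with pytest.raises(ValueError):
            code_temporal(t)


@pytest.fixture(scope="module")
def filtered(raw_table):
    kept, _ = apply_filters(raw_table)
    return code_temporal(kept)


class TestEncodeDesign:
    def test_reference_levels_give_zero_dummies(self, filtered):
        t = filtered.copy()
        t["season"] = "Summer"
        design = encode_design(t, drop_constant=False)
        assert design.X[["season_winter", "season_spring", "season_fall"]].to_numpy().sum() == 0

    def test_female_over_65_dummies(self, filtered):
        t = filtered.copy()
        t.loc[:, "gender"] = "Female"
        t.loc[:, "driver_age"] = 70.0
        d = encode_design(t, drop_constant=False)
        assert (d.X["female"] == 1).all()
        assert (d.X["age_gt65"] == 1).all()
        assert d.X[["age_lt24", "age_40_65"]].to_numpy().sum() == 0

    def test_column_sums_equal_category_counts(self, filtered):
        design = encode_design(filtered, drop_constant=False)
        for col, (src, category) in data._DUMMY_MAP.items():
            if src == "age_band":
                source = filtered["driver_age"].map(schema.age_band)
            else:
                source = filtered[src]
            assert design.X[col].sum() == (source == category).sum(), col

    def test_dummy_groups_sum_to_zero_or_one_per_row(self, filtered):
        design = encode_design(filtered, drop_constant=False)
        groups = {}
        for col, (src, _) in data._DUMMY_MAP.items():
            groups.setdefault(src, []).append(col)
        for src, cols in groups.items():
            if src == "gender":
                continue  # single dummy
            sums = design.X[cols].sum(axis=1)
            assert set(np.unique(sums)) <= {0.0, 1.0}, src

    def test_row_count_and_outcome_range(self, filtered):
        design = encode_design(filtered)
        assert design.n_rows == filtered.shape[0]
        assert set(np.unique(design.outcome)) <= {0, 1, 2}

    def test_missing_random_column_is_error(self, filtered):
        with pytest.raises(SchemaError):
            encode_design(filtered, random_columns=("no_such_column",))

    def test_year_enters_numeric(self, filtered):
        design = encode_design(filtered)
        assert set(np.unique(design.X["year_index"])) <= {1.0, 2.0, 3.0, 4.0, 5.0}


class TestDescriptiveTable:
    def test_percentages_sum_to_100_per_variable(self, filtered):
        desc = descriptive_table(filtered)
        for _, grp in desc.groupby("variable"):
            assert abs(grp["percent"].sum() - 100.0) < 0.01

    def test_counts_match_value_counts_oracle(self, filtered):
        desc = descriptive_table(filtered)
        vc = filtered["season"].value_counts()
        got = desc[desc["variable"] == "Season"].set_index("category")["count"]
        for cat in schema.SEASON:
            assert got[cat] == vc.get(cat, 0)

    def test_single_category_is_100_percent(self):
        table = percentages_from_counts({"v": {"only": 17}})
        assert table["percent"].iloc[0] == 100.0

    def test_empty_table_is_error(self, filtered):
        with pytest.raises(EmptyInputError):
            descriptive_table(filtered.iloc[:0])
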