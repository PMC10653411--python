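"""Codebook decoding, cycle combination, derived covariates, cohort filters."""

import numpy as np
import pandas as pd
import pytest

from svyequity.harmonize import (
    AnalysisTable,
    Codebook,
    CodebookError,
    SurveyDesign,
    categorize_pir,
    combine_cycles,
    derive_insurance,
    drop_missing,
    filter_cohort,
    harmonize_education,
    load_codebooks,
    read_table,
)
from svyequity.simulate import write_fixture


@pytest.fixture()
def pregnancy_book():
    return Codebook(variable="pregnant", codes={1: "yes", 2: "no"}, missing=frozenset({9}))


class TestCodebook:
    def test_declared_missing_code_becomes_absent(self, tmp_path, pregnancy_book):
        path = tmp_path / "t.csv"
        pd.DataFrame({"pregnant": [1, 9, 2]}).to_csv(path, index=False)
        df = read_table(path, codebooks={"pregnant": pregnancy_book})
        assert df["pregnant"].tolist() == ["yes", None, "no"]

    def test_code_outside_domain_raises_naming_variable_row_code(self, tmp_path, pregnancy_book):
        path = tmp_path / "t.csv"
        pd.DataFrame({"pregnant": [1, 4]}).to_csv(path, index=False)
        with pytest.raises(CodebookError, match=r"'pregnant'.*row 1.*4"):
            read_table(path, codebooks={"pregnant": pregnancy_book})

    def test_overlapping_missing_and_value_codes_rejected(self):
        with pytest.raises(ValueError, match="both valid and missing"):
            Codebook(variable="x", codes={1: "a"}, missing=frozenset({1}))

    def test_csv_and_xpt_encodings_agree(self, tmp_path, small_sample):
        """Dual writers of the same 10 rows decode to the same raw table."""
        sample, _ = small_sample
        ten = sample.head(10)[
            ["id", "weight", "stratum", "psu", "age", "gender", "race", "educ", "pregnant"]
        ]
        paths_csv = write_fixture(ten, tmp_path / "c", format="csv", name="ten")
        paths_xpt = write_fixture(ten, tmp_path / "x", format="xpt", name="ten")
        books = load_codebooks(paths_csv["codebooks"])
        df_csv = read_table(paths_csv["data"], format="csv", codebooks=books)
        df_xpt = read_table(paths_xpt["data"], format="xpt", codebooks=books)
        for col in df_csv.columns:
            a, b = df_csv[col], df_xpt[col]
            if a.dtype.kind in "if":
                np.testing.assert_allclose(a.to_numpy(float), b.to_numpy(float), rtol=1e-12)
            else:
                assert a.astype(str).tolist() == b.astype(str).tolist()


class TestCombineCycles:
    def _cycle(self, label, ids, weight=30000.0):
        return pd.DataFrame(
            {"id": ids, "cycle": label, "weight": weight, "stratum": 1, "psu": 1}
        )

    def test_three_cycles_divide_weight_by_three(self, flat_design):
        tables = [self._cycle(c, [f"{c}{i}" for i in range(3)]) for c in "abc"]
        combined, design = combine_cycles(tables, flat_design)
        assert (combined["weight"] == 10000.0).all()
        assert design.cycles_combined == 3

    def test_single_cycle_weights_unchanged(self, flat_design):
        combined, design = combine_cycles([self._cycle("a", ["1", "2"])], flat_design)
        assert (combined["weight"] == 30000.0).all()
        assert design.cycles_combined == 1

    def test_combined_total_is_mean_of_cycle_totals(self, flat_design):
        rng = np.random.default_rng(7)
        tables = []
        for c in "abc":
            t = self._cycle(c, [f"{c}{i}" for i in range(50)])
            t["weight"] = rng.uniform(5000, 60000, size=50)
            tables.append(t)
        combined, _ = combine_cycles(tables, flat_design)
        mean_total = np.mean([t["weight"].sum() for t in tables])
        assert combined["weight"].sum() == pytest.approx(mean_total, rel=1e-9)

    def test_duplicate_ids_across_cycles_error(self, flat_design):
        with pytest.raises(ValueError, match="duplicate respondent id"):
            combine_cycles(
                [self._cycle("a", ["1", "2"]), self._cycle("b", ["2", "3"])], flat_design
            )


class TestDeriveInsurance:
    def test_all_flags_false_is_uninsured(self):
        flags = {"private": False, "medicare": False, "medicaid": False, "other": False}
        assert derive_insurance(flags) == "uninsured"

    @pytest.mark.parametrize(
        "flags,expected",
        [
            ({"private": True, "medicaid": True, "medicare": False, "other": False}, "private"),
            ({"private": False, "medicare": True, "medicaid": True, "other": False}, "Medicare"),
            ({"private": False, "medicare": False, "medicaid": True, "other": True}, "Medicaid"),
            ({"private": False, "medicare": False, "medicaid": False, "other": True}, "other non-private"),
        ],
    )
    def test_priority_order(self, flags, expected):
        assert derive_insurance(flags) == expected

    def test_no_positive_flag_with_absent_flag_is_missing(self):
        flags = {"private": False, "medicare": None, "medicaid": False, "other": False}
        assert derive_insurance(flags) is None

    def test_exhaustive_truth_table(self):
        """Every complete flag combination resolves to exactly one class."""
        from itertools import product

        for combo in product([True, False, None], repeat=4):
            flags = dict(zip(("private", "medicare", "medicaid", "other"), combo))
            result = derive_insurance(flags)
            truthy = [p for p, v in flags.items() if v is True]
            if truthy:
                order = ["private", "medicare", "medicaid", "other"]
                first = min(truthy, key=order.index)
                expected = {
                    "private": "private",
                    "medicare": "Medicare",
                    "medicaid": "Medicaid",
                    "other": "other non-private",
                }[first]
                assert result == expected
            elif all(v is False for v in combo):
                assert result == "uninsured"
            else:
                assert result is None


class TestCategorizePir:
    @pytest.mark.parametrize(
        "pir,expected",
        [
            (0.0, "poor"),
            (0.5, "poor"),
            (1.0, "near poor"),
            (1.95, "near poor"),
            (2.0, "middle income"),
            (3.99, "middle income"),
            (4.0, "higher income"),
            (5.0, "higher income"),
        ],
    )
    def test_half_open_bands(self, pir, expected):
        assert categorize_pir(pir) == expected

    def test_negative_pir_rejected(self):
        with pytest.raises(ValueError):
            categorize_pir(-0.1)


class TestHarmonizeEducation:
    @pytest.fixture()
    def edu_book(self):
        return Codebook(
            variable="educ",
            codes={1: "less than 9th grade", 2: "9-11th grade", 3: "12th grade no diploma"},
            groups={
                "less than 9th grade": "less than 9th grade",
                "9-11th grade": "9-11th grade",
                "12th grade no diploma": "9-11th grade",
            },
        )

    def test_twelfth_grade_no_diploma_grouped_into_9_11(self, edu_book):
        assert harmonize_education(3, edu_book) == "9-11th grade"

    def test_identity_group_map(self, edu_book):
        assert harmonize_education(1, edu_book) == "less than 9th grade"

    def test_idempotent_through_identity_codebook(self, edu_book):
        label = harmonize_education(2, edu_book)
        identity = Codebook(variable="educ", codes={label: label}, groups={label: label})
        assert harmonize_education(label, identity) == label

    def test_label_without_group_mapping_errors(self):
        book = Codebook(variable="educ", codes={1: "a", 2: "b"}, groups={"a": "a"})
        with pytest.raises(CodebookError, match="no group mapping"):
            harmonize_education(2, book)


def _table(df):
    return AnalysisTable(df=df, design=SurveyDesign())


class TestCohortFilters:
    @pytest.fixture()
    def people(self):
        return pd.DataFrame(
            {
                "id": list("abcdef"),
                "age": [19, 20, 35, 60, 70, 25],
                "pregnant": [False, False, True, False, None, False],
                "diagnosed_t2dm": [True, True, False, True, True, None],
                "weight": 1.0,
                "stratum": 1,
                "psu": 1,
            }
        )

    def test_age_19_excluded_everywhere(self, people):
        for cohort in ("hav_hbv", "hpv", "t2dm"):
            out = filter_cohort(_table(people), cohort)
            assert "a" not in out.df["id"].tolist()

    def test_hpv_upper_age_bound(self, people):
        out = filter_cohort(_table(people), "hpv")
        assert set(out.df["id"]) == {"b", "f"}  # 60 and 70 out, pregnant out

    def test_pregnant_excluded_missing_pregnancy_retained(self, people):
        out = filter_cohort(_table(people), "hav_hbv")
        ids = set(out.df["id"])
        assert "c" not in ids and "e" in ids

    def test_t2dm_requires_diagnosis(self, people):
        out = filter_cohort(_table(people), "t2dm")
        assert set(out.df["id"]) == {"b", "d", "e"}

    def test_decoded_label_flags_handled(self, people):
        """Flags may arrive as yes/no labels or 0/1 codes after decoding."""
        labelled = people.assign(
            pregnant=["no", "no", "yes", "no", None, "no"],
            diagnosed_t2dm=[1, 1, 0, 1, 1, 0],
        )
        out = filter_cohort(_table(labelled), "t2dm")
        assert set(out.df["id"]) == {"b", "d", "e"}

    def test_unknown_cohort_errors(self, people):
        with pytest.raises(ValueError, match="unknown cohort"):
            filter_cohort(_table(people), "nope")

    def test_empty_input_empty_output_with_provenance(self, people):
        out = filter_cohort(_table(people.iloc[:0]), "hpv")
        assert out.df.empty
        assert out.provenance[-1]["rows_after"] == 0

    def test_filters_never_alter_retained_rows(self, people):
        out = filter_cohort(_table(people), "hav_hbv")
        kept = people.set_index("id").loc[out.df["id"]]
        pd.testing.assert_frame_equal(
            out.df.set_index("id"), kept, check_like=True
        )


class TestDropMissing:
    def test_counts_and_identity(self):
        df = pd.DataFrame({"pir": [1.0, None, 2.0, None] + [3.0] * 6, "x": range(10)})
        out = drop_missing(_table(df), ["pir"])
        assert len(out.df) == 8
        assert out.provenance[-1]["dropped"] == 2
        same = drop_missing(_table(df.dropna()), ["pir"])
        assert len(same.df) == len(df.dropna())

    def test_never_observed_column_empties_table(self):
        df = pd.DataFrame({"pir": [None, None], "x": [1, 2]})
        out = drop_missing(_table(df), ["pir"])
        assert out.df.empty

    def test_provenance_counts_non_increasing(self):
        df = pd.DataFrame({"pir": [1.0, None], "x": [1, 2]})
        out = drop_missing(_table(df), ["pir"])
        before = [p["rows_before"] for p in out.provenance]
        after = [p["rows_after"] for p in out.provenance]
        assert all(b >= a for b, a in zip(before, after))
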