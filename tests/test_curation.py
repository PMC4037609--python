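"""IEDB B-cell assay CSV curation pipeline."""

import io

import pandas as pd
import pytest

from epibench import (
    FixtureSpec,
    SchemaError,
    UnitError,
    curate,
    generate_fixture,
    read_iedb_csv,
    shannon_entropy,
)
from epibench.curation import (
    annotate_effects,
    assay_category,
    filter_biological_activity,
    quantitative_frame,
    select_quantitative,
    summarize_counts,
)

HEADER = (
    "BCell ID,Epitope ID,PubMed ID,Type,1st Immunogen Epitope Relation,"
    "Method/Technique,Qualitative Measure,Quantitative measurement,"
    "Measurement Inequality,Assay Type Units"
)


def make_csv(rows):
    return io.StringIO(HEADER + "\n" + "\n".join(rows) + "\n")


ROWS = [
    "1,10,100,Linear peptide,Epitope,Neutralization/inhibition of antigen activity,Positive,43.0,,inhibition [%]",
    "2,11,101,Linear peptide,Epitope,Survival after challenge,Positive-Low,70,,survival [%]",
    "3,12,102,Linear peptide,Epitope,Neutralization/inhibition of antigen activity,Positive,90,>,inhibition [%]",
    "4,13,103,Linear peptide,Epitope,Survival after challenge,Negative,,,survival [%]",
    "5,14,104,Linear peptide,Epitope,ELISA,Positive,1.2,,OD units",
]


class TestReadIedbCsv:
    def test_count_preservation(self):
        records = read_iedb_csv(make_csv(ROWS[:3]))
        assert len(records) == 3
        assert records[0].bcell_id == "1"
        assert records[0].quantitative_measurement == "43.0"

    def test_missing_required_column_is_schema_error(self):
        broken = HEADER.replace("Quantitative measurement,", "")
        bad_rows = [r.rsplit(",", 3)[0] + ",," for r in ROWS[:2]]
        with pytest.raises(SchemaError, match="quantitative_measurement"):
            read_iedb_csv(io.StringIO(broken + "\n" + "\n".join(bad_rows)))

    def test_two_row_grouped_header_dialect(self, tmp_path):
        spec = FixtureSpec(n_quant_point=4, n_inequality=1, n_empty=2,
                           n_nonbiological=1, seed=11, grouped_header=True)
        path = tmp_path / "grouped.csv"
        frame, truth = generate_fixture(spec, path)
        records = read_iedb_csv(path)
        assert len(records) == spec.n_total
        assert {r.bcell_id for r in records} == set(frame["BCell ID"])

    def test_duplicate_bcell_id_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            read_iedb_csv(make_csv([ROWS[0], ROWS[0]]))

    def test_column_map_override(self):
        renamed = HEADER.replace("BCell ID", "Assay ID")
        records = read_iedb_csv(
            io.StringIO(renamed + "\n" + ROWS[0]),
            column_map={"bcell_id": "Assay ID"},
        )
        assert records[0].bcell_id == "1"

    def test_extra_columns_preserved(self):
        extended = HEADER + ",Comments"
        records = read_iedb_csv(io.StringIO(extended + "\n" + ROWS[0] + ",note"))
        assert records[0].extras["Comments"] == "note"


class TestFiltering:
    def test_biological_activity_partition(self):
        records = read_iedb_csv(make_csv(ROWS))
        kept, excluded = filter_biological_activity(records)
        assert len(kept) + len(excluded) == 5
        assert {r.bcell_id for r in excluded} == {"5"}

    def test_case_insensitive_matching(self):
        row = ROWS[0].replace(
            "Neutralization/inhibition of antigen activity",
            "NEUTRALIZATION/INHIBITION  of antigen ACTIVITY",
        )
        kept, _ = filter_biological_activity(read_iedb_csv(make_csv([row])))
        assert len(kept) == 1

    def test_select_quantitative_partitions_by_reason(self):
        records = read_iedb_csv(make_csv(ROWS[:4]))
        kept, excluded = select_quantitative(records)
        assert {r.bcell_id for r in kept} == {"1", "2"}
        assert {r.bcell_id for r in excluded["inequality"]} == {"3"}
        assert {r.bcell_id for r in excluded["empty"]} == {"4"}

    def test_nonnumeric_measurement_warned_and_tallied(self):
        row = ROWS[0].replace("43.0", "ca. forty")
        with pytest.warns(UserWarning, match="non-numeric"):
            kept, excluded = select_quantitative(read_iedb_csv(make_csv([row])))
        assert not kept and len(excluded["nonnumeric"]) == 1

    @pytest.mark.parametrize("symbol", ["<", ">", "<=", ">=", "≤", "≥"])
    def test_all_inequality_symbols_excluded(self, symbol):
        row = ROWS[0].replace(",,inhibition", f",{symbol},inhibition")
        kept, excluded = select_quantitative(read_iedb_csv(make_csv([row])))
        assert not kept and len(excluded["inequality"]) == 1


class TestAnnotateEffects:
    def test_percent_conversion_and_entropy(self):
        records = read_iedb_csv(make_csv(ROWS[:2]))
        obs = annotate_effects(records)
        by_id = {o.source_id: o for o in obs}
        assert by_id["1"].q == pytest.approx(0.43)
        assert by_id["1"].entropy == pytest.approx(float(shannon_entropy(0.43)))
        assert by_id["1"].assay_category == "inhibition"
        assert by_id["2"].q == pytest.approx(0.70)
        assert by_id["2"].assay_category == "survival"

    @pytest.mark.parametrize(
        "percent,q,h", [("50", 0.5, 1.0), ("0", 0.0, 0.0), ("100", 1.0, 0.0),
                        ("25", 0.25, 0.8112781244591328)]
    )
    def test_endpoint_and_midpoint_entropies(self, percent, q, h):
        row = ROWS[0].replace("43.0", percent)
        obs = annotate_effects(read_iedb_csv(make_csv([row])))
        assert obs[0].q == pytest.approx(q)
        assert obs[0].entropy == pytest.approx(h, abs=1e-12)

    def test_ranking_decreasing_q_with_id_tiebreak(self):
        rows = [
            "1,10,100,Linear peptide,Epitope,Survival after challenge,Positive,30,,survival [%]",
            "2,11,101,Linear peptide,Epitope,Survival after challenge,Positive,80,,survival [%]",
            "4,13,103,Linear peptide,Epitope,Survival after challenge,Positive,30,,survival [%]",
            "3,12,102,Linear peptide,Epitope,Survival after challenge,Positive,30,,survival [%]",
        ]
        obs = annotate_effects(read_iedb_csv(make_csv(rows)))
        assert [o.source_id for o in obs] == ["2", "1", "3", "4"]

    def test_units_strictness(self):
        no_units = ROWS[0].replace("inhibition [%]", "")
        records = read_iedb_csv(make_csv([no_units]))
        with pytest.raises(UnitError):
            annotate_effects(records)
        with pytest.warns(UserWarning, match="blank units"):
            obs = annotate_effects(records, strict_units=False)
        assert obs[0].q == pytest.approx(0.43)
        odd_units = ROWS[0].replace("inhibition [%]", "titer")
        with pytest.raises(UnitError):
            annotate_effects(read_iedb_csv(make_csv([odd_units])), strict_units=False)

    def test_assay_category_mapping(self):
        assert assay_category("Neutralization/Inhibition of Antigen Activity") == "inhibition"
        assert assay_category("Survival After Challenge") == "survival"
        assert assay_category("Protection after challenge") == "survival"
        assert assay_category("Hypersensitivity") == "other"


class TestSummarizeCounts:
    def test_single_type_split(self):
        rows = [
            f"{i},1{i},10{i},Linear peptide,Epitope,Survival after challenge,{qual},,,survival [%]"
            for i, qual in enumerate(["Positive", "Positive-High", "Positive-Low", "Negative"], 1)
        ]
        table = summarize_counts(read_iedb_csv(make_csv(rows)))
        row = table.rows["Survival after challenge"]
        assert (row["total"], row["positive"], row["negative"]) == (4, 3, 1)

    def test_two_types_conserve_grand_total(self):
        records = read_iedb_csv(make_csv(ROWS[:4]))
        table = summarize_counts(records)
        assert table.grand_total == 4
        assert len(table.rows) == 2
        for row in table.rows.values():
            assert row["total"] == row["positive"] + row["negative"] + row["unclassified"]

    def test_unmappable_qualitative_goes_unclassified(self):
        row = ROWS[0].replace(",Positive,", ",Borderline,")
        with pytest.warns(UserWarning, match="unmappable"):
            table = summarize_counts(read_iedb_csv(make_csv([row])))
        r = next(iter(table.rows.values()))
        assert r["unclassified"] == 1 and r["positive"] == 0 and r["negative"] == 0


class TestFullPipeline:
    def test_tally_conservation(self, tmp_path):
        spec = FixtureSpec(n_quant_point=7, n_inequality=3, n_empty=4,
                           n_nonbiological=2, seed=3)
        path = tmp_path / "fix.csv"
        _, truth = generate_fixture(spec, path)
        report = curate(path)
        t = report.tallies()
        assert t["n_input"] == sum(
            t[k]
            for k in (
                "n_scope_excluded",
                "n_excluded_assay_type",
                "n_excluded_empty",
                "n_excluded_inequality",
                "n_excluded_nonnumeric",
                "n_quantitative",
            )
        )
        for key in ("n_quantitative", "n_excluded_inequality", "n_excluded_empty",
                    "n_excluded_assay_type"):
            assert t[key] == truth[key]

    def test_ranking_is_permutation_of_retained(self, tmp_path):
        spec = FixtureSpec(n_quant_point=9, seed=5)
        path = tmp_path / "fix.csv"
        _, truth = generate_fixture(spec, path)
        report = curate(path)
        ranked_ids = [o.source_id for o in report.records]
        assert sorted(ranked_ids) == sorted(truth["q_by_bcell_id"])
        qs = [o.q for o in report.records]
        assert qs == sorted(qs, reverse=True)

    def test_round_trip_preserves_q_and_entropy(self, tmp_path):
        spec = FixtureSpec(n_quant_point=8, seed=9)
        path = tmp_path / "fix.csv"
        generate_fixture(spec, path)
        report = curate(path)
        out = tmp_path / "quant.csv"
        quantitative_frame(report).to_csv(out, index=False)
        back = pd.read_csv(out, dtype={"bcell_id": str}, float_precision="round_trip")
        for o in report.records:
            row = back[back["bcell_id"] == o.source_id].iloc[0]
            assert row["q"] == o.q  # bit-for-bit through CSV text
            assert row["entropy_bits"] == o.entropy
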