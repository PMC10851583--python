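"""Burden tables, grouping, comparisons, carrier matrix."""

import numpy as np
import pytest

from varprio.cohort import (
    Cohort,
    GROUP2_GENES,
    assign_groups,
    burden_to_frame,
    carrier_matrix,
    gene_burden_table,
    round_half_up,
    summarize_and_compare,
)
from varprio.variants import AutoRule, PathogenicityCall


def _call(pathogenic: bool) -> PathogenicityCall:
    if pathogenic:
        return PathogenicityCall("pathogenic", 4, True)
    return PathogenicityCall("benign", 0, False)


CALLS = {
    "APOA5:c.553G>T": _call(True),
    "APOA5:c.104G>A": _call(True),
    "APOA5:c.457G>A": _call(False),
    "LPL:c.10A>G": _call(True),
    "PLA2G6:c.10A>G": _call(True),
}


@pytest.fixture
def small_cohort(patient_factory):
    return Cohort(
        (
            # double APOA5 pathogenic carrier, counts once per gene
            patient_factory(
                "A1", genotypes={"APOA5:c.553G>T": "het", "APOA5:c.104G>A": "het"}
            ),
            # pathogenic APOA5 + pathogenic LPL: group I precedence
            patient_factory(
                "A2", genotypes={"APOA5:c.553G>T": "hom", "LPL:c.10A>G": "het"}
            ),
            # 25-gene pathogenic only: group II
            patient_factory("A3", genotypes={"PLA2G6:c.10A>G": "het"}),
            # benign APOA5 only: group III, but an any-variant carrier
            patient_factory("A4", genotypes={"APOA5:c.457G>A": "het"}),
            patient_factory("A5"),
            patient_factory("B1", arm="BAP", genotypes={"APOA5:c.553G>T": "het"}),
            patient_factory("B2", arm="BAP"),
        )
    )


class TestGeneBurden:
    def test_distinct_carrier_counts(self, small_cohort):
        rows = {r.gene: r for r in gene_burden_table(small_cohort, CALLS)}
        apoa5 = rows["APOA5"]
        assert (apoa5.n_any_hlap, apoa5.n_path_hlap) == (3, 2)  # A1 counts once
        assert (apoa5.n_any_bap, apoa5.n_path_bap) == (1, 1)
        assert rows["LPL"].n_path_hlap == 1
        assert rows["PLA2G6"].n_path_hlap == 1

    def test_percentages_recompute_from_counts(self, small_cohort):
        frame = burden_to_frame(gene_burden_table(small_cohort, CALLS))
        apoa5 = frame.set_index("gene").loc["APOA5"]
        assert apoa5["pct_path_hlap"] == round_half_up(100 * 2 / 5)
        assert apoa5["pct_path_bap"] == round_half_up(100 * 1 / 2)

    def test_empty_genotypes_give_zero_rows(self, patient_factory):
        cohort = Cohort((patient_factory("A1"), patient_factory("B1", arm="BAP")))
        rows = gene_burden_table(cohort, CALLS)
        assert all(r.n_any_hlap == r.n_path_hlap == 0 for r in rows)

    def test_unknown_variant_rejected(self, patient_factory):
        cohort = Cohort((patient_factory("A1", genotypes={"GHOST:c.1A>G": "het"}),))
        with pytest.raises(ValueError, match="unclassified"):
            gene_burden_table(cohort, CALLS)


class TestAssignGroups:
    def test_partition(self, small_cohort):
        groups = assign_groups(small_cohort.hlap, CALLS)
        assert groups == {"A1": "I", "A2": "I", "A3": "II", "A4": "III", "A5": "III"}

    def test_group_i_precedence_over_ii(self, small_cohort):
        # A2 carries pathogenic APOA5 and pathogenic LPL
        assert assign_groups(small_cohort.hlap, CALLS)["A2"] == "I"

    def test_partition_is_exhaustive(self, small_cohort):
        groups = assign_groups(small_cohort.hlap, CALLS)
        assert len(groups) == len(small_cohort.hlap)

    def test_bap_patient_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="HLAP-only"):
            assign_groups(small_cohort.patients, CALLS)

    def test_group2_gene_list_has_25_entries(self):
        assert len(GROUP2_GENES) == 25
        assert GROUP2_GENES[0] == "PLA2G6" and GROUP2_GENES[-1] == "TIMD4"


class TestSummarizeAndCompare:
    def test_severity_percentages_match_printed_style(self, default_cohort):
        cohort, _ = default_cohort
        result = summarize_and_compare(
            {"HLAP": cohort.hlap, "BAP": cohort.bap}, "msap_sap"
        )
        a, b = result.summaries
        assert (a["n"], a["total"], a["pct_1dp"]) == (83, 163, 50.9)
        assert (b["n"], b["total"], b["pct"]) == (5, 30, 17)

    def test_identical_groups_contingency_p_is_one(self, patient_factory):
        group = [patient_factory(f"A{i}", diabetes=(i % 2 == 0)) for i in range(40)]
        result = summarize_and_compare({"x": group, "y": list(group)}, "diabetes")
        assert result.p_value == pytest.approx(1.0)

    def test_continuous_summary_and_welch(self, patient_factory):
        rng = np.random.default_rng(0)
        a = [patient_factory(f"A{i}", bmi=float(v))
             for i, v in enumerate(rng.normal(27, 3, 60))]
        b = [patient_factory(f"B{i}", arm="BAP", bmi=float(v))
             for i, v in enumerate(rng.normal(25, 3, 60))]
        result = summarize_and_compare({"HLAP": a, "BAP": b}, "bmi")
        assert result.test_name == "Welch t"
        assert result.summaries[0]["mean"] == pytest.approx(
            np.mean([p.bmi for p in a])
        )

    def test_skewed_variable_falls_back_to_mannwhitney(self, patient_factory):
        rng = np.random.default_rng(1)
        a = [patient_factory(f"A{i}", tg=float(v))
             for i, v in enumerate(rng.lognormal(1.0, 1.5, 80))]
        b = [patient_factory(f"B{i}", arm="BAP", tg=float(v))
             for i, v in enumerate(rng.lognormal(1.0, 1.5, 80))]
        result = summarize_and_compare({"HLAP": a, "BAP": b}, "tg")
        assert result.test_name == "Mann-Whitney U"

    def test_small_cells_use_fisher(self, patient_factory):
        a = [patient_factory(f"A{i}", ards=(i < 2)) for i in range(30)]
        b = [patient_factory(f"B{i}", arm="BAP", ards=(i < 1)) for i in range(10)]
        result = summarize_and_compare({"HLAP": a, "BAP": b}, "ards")
        assert result.test_name == "Fisher exact"

    def test_empty_group_rejected(self, patient_factory):
        with pytest.raises(ValueError, match="empty"):
            summarize_and_compare({"x": [patient_factory("A1")], "y": []}, "bmi")

    def test_unknown_variable_rejected(self, patient_factory):
        with pytest.raises(ValueError, match="unknown clinical variable"):
            summarize_and_compare(
                {"x": [patient_factory("A1")], "y": [patient_factory("A2")]}, "shoe_size"
            )


class TestCarrierMatrix:
    def test_counts_distinct_pathogenic_mutations(self, small_cohort):
        matrix = carrier_matrix(small_cohort, CALLS)
        assert matrix.loc["A1", "APOA5"] == 2
        assert matrix.loc["A2", "APOA5"] == 1
        assert matrix.loc["A2", "LPL"] == 1
        assert matrix.loc["A4"].sum() == 0  # benign-only carrier

    def test_indicator_column_sums_equal_burden(self, default_cohort):
        cohort, calls = default_cohort
        matrix = carrier_matrix(cohort, calls)
        burden = {r.gene: r for r in gene_burden_table(cohort, calls)}
        indicator = (matrix > 0).astype(int)
        hlap_ids = [p.id for p in cohort.hlap]
        for gene in matrix.columns:
            assert indicator.loc[hlap_ids, gene].sum() == (
                burden[gene].n_path_hlap
            )


class TestPatientInvariants:
    def test_repeated_recurrence_requires_recurrence(self, patient_factory):
        with pytest.raises(ValueError, match="implies"):
            patient_factory("A1", repeated_recurrence=True, recurrence=False)

    def test_negative_lab_rejected(self, patient_factory):
        with pytest.raises(ValueError, match=">= 0"):
            patient_factory("A1", tg=-1.0)

    def test_cohort_tsv_round_trip(self, small_cohort, tmp_path):
        small_cohort.to_tsv(tmp_path / "cohort.tsv", tmp_path / "geno.tsv")
        loaded = Cohort.from_tsv(tmp_path / "cohort.tsv", tmp_path / "geno.tsv")
        assert [p.id for p in loaded] == [p.id for p in small_cohort]
        assert loaded.patients[0].genotypes == small_cohort.patients[0].genotypes
        assert loaded.patients[1].arm == "HLAP"
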