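"""Consensus rule engine: per-program thresholds, verdicts, monotonicity."""

import dataclasses

import pytest

from varprio.classifier import (
    Program,
    classify_pathogenicity,
    classify_records,
    predictor_damaging,
)
from varprio.variants import (
    AutoRule,
    GeneticVariant,
    PredictorProfile,
    parse_cdna_hgvs,
    parse_protein_hgvs,
)


@pytest.mark.parametrize(
    "program, value, expected",
    [
        (Program.SIFT, "D", True),
        (Program.SIFT, "T", False),
        (Program.SIFT, None, False),
        (Program.POLYPHEN_HDIV, "D", True),
        (Program.POLYPHEN_HDIV, "P", True),
        (Program.POLYPHEN_HDIV, "B", False),
        (Program.LRT, "D", True),
        (Program.LRT, "N", False),
        (Program.LRT, "U", False),
        (Program.MUTATION_TASTER, "D", True),
        (Program.MUTATION_TASTER, "A", True),
        (Program.MUTATION_TASTER, "N", False),
        (Program.MUTATION_TASTER, "P", False),
        (Program.MUTATION_ASSESSOR, "H", True),
        (Program.MUTATION_ASSESSOR, "M", True),
        (Program.MUTATION_ASSESSOR, "L", False),
        (Program.MUTATION_ASSESSOR, "N", False),
        (Program.CADD, 29.0, True),
        (Program.CADD, 15.0, False),   # strict inequality at the cut-off
        (Program.CADD, 15.01, True),
        (Program.CADD, 3.66, False),
        (Program.CADD, None, False),
    ],
)
def test_predictor_damaging(program, value, expected):
    assert predictor_damaging(program, value) is expected


def test_predictor_damaging_rejects_unknown_category():
    with pytest.raises(ValueError, match="unknown"):
        predictor_damaging(Program.SIFT, "X")


def _variant(cdna: str, protein: str) -> GeneticVariant:
    return GeneticVariant(
        gene="APOA5",
        cdna=parse_cdna_hgvs(cdna),
        protein=parse_protein_hgvs(protein),
    )


class TestClassify:
    def test_unanimous_pathogenic(self):
        call = classify_pathogenicity(
            _variant("c.667C>T", "p.R223C"),
            PredictorProfile("D", "D", "D", "D", "M", 29.0),
        )
        assert call.verdict == "pathogenic"
        assert call.damaging_votes == 6

    def test_sift_tolerated_blocks_pathogenicity(self):
        # four damaging votes, but SIFT says tolerated -> benign
        call = classify_pathogenicity(
            _variant("c.77G>T", "p.G26V"),
            PredictorProfile("T", "P", "N", "D", "M", 24.0),
        )
        assert call.verdict == "benign"
        assert call.damaging_votes == 4
        assert not call.sift_damaging

    def test_frameshift_auto_rule_with_all_predictors_missing(self):
        call = classify_pathogenicity(
            _variant("c.544_545insGGTGC", "p.H182fs"), PredictorProfile()
        )
        assert call.verdict == "pathogenic"
        assert call.auto_rule is AutoRule.FRAMESHIFT
        assert call.damaging_votes == 0

    @pytest.mark.parametrize(
        "protein, rule",
        [("p.R100*", AutoRule.STOPGAIN), ("p.*367R", AutoRule.STOPLOSS)],
    )
    def test_stop_auto_rules(self, protein, rule):
        call = classify_pathogenicity(
            _variant("c.298C>T", protein), PredictorProfile("T", "B", "N", "N", "N", 1.0)
        )
        assert call.verdict == "pathogenic"
        assert call.auto_rule is rule

    def test_all_benign_votes(self):
        call = classify_pathogenicity(
            _variant("c.457G>A", "p.V153M"),
            PredictorProfile("T", "B", "N", "P", "L", 3.66),
        )
        assert call.verdict == "benign"
        assert call.damaging_votes == 0

    def test_sift_plus_one_other_suffices(self):
        call = classify_pathogenicity(
            _variant("c.104G>A", "p.S35N"),
            PredictorProfile(sift="D", cadd=16.0),
        )
        assert call.verdict == "pathogenic"
        assert call.damaging_votes == 2

    def test_sift_alone_is_not_enough(self):
        call = classify_pathogenicity(
            _variant("c.104G>A", "p.S35N"), PredictorProfile(sift="D")
        )
        assert call.verdict == "benign"

    def test_unresolved_protein_consequence_rejected(self):
        variant = GeneticVariant(gene="APOA5", cdna=parse_cdna_hgvs("c.104G>A"))
        with pytest.raises(ValueError, match="unresolved"):
            classify_pathogenicity(variant, PredictorProfile())


def test_fixture_partition(table4, table4_calls):
    """The packaged variant table splits exactly into the six pathogenic and
    four benign calls, with the printed vote counts."""
    verdicts = {
        str(rec.variant.protein): table4_calls[rec.variant.variant_id] for rec in table4
    }
    pathogenic = {p for p, c in verdicts.items() if c.is_pathogenic}
    assert pathogenic == {"p.S35N", "p.D167V", "p.G185C", "p.K188I", "p.R223C", "p.H182fs"}
    assert len(verdicts) == 10
    assert verdicts["p.R223C"].damaging_votes == 6
    assert verdicts["p.S35N"].damaging_votes == 4


_UPGRADES = {
    "sift": "D",
    "polyphen_hdiv": "D",
    "lrt": "D",
    "mutation_taster": "D",
    "mutation_assessor": "H",
    "cadd": 30.0,
}


def test_monotonicity_on_fixture(table4):
    """Flipping any non-damaging program to damaging never turns a
    pathogenic verdict benign."""
    for rec in table4:
        base = classify_pathogenicity(rec.variant, rec.profile)
        for program, upgraded in _UPGRADES.items():
            if predictor_damaging(Program(program), getattr(rec.profile, program)):
                continue
            profile = dataclasses.replace(rec.profile, **{program: upgraded})
            upgraded_call = classify_pathogenicity(rec.variant, profile)
            assert upgraded_call.damaging_votes == base.damaging_votes + 1
            if base.is_pathogenic:
                assert upgraded_call.is_pathogenic


def test_verdict_ignores_non_rule_annotations(table4):
    """Allele frequencies, conservation and rsid never affect the verdict."""
    for rec in table4:
        base = classify_pathogenicity(rec.variant, rec.profile)
        stripped = dataclasses.replace(
            rec.variant, rsid=None, status="novel", af_all=None, af_eas=None,
            af_amr=None, phylo_hmm=None,
        )
        assert classify_pathogenicity(stripped, rec.profile).verdict == base.verdict


def test_duplicate_rows_rejected(table4):
    with pytest.raises(ValueError, match="duplicate"):
        classify_records(list(table4) + [table4[0]])
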