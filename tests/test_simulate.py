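"""Synthetic-data generators: exact counts, determinism, moment matching."""

import numpy as np
import pytest

from varprio.classifier import classify_records
from varprio.cohort import gene_burden_table
from varprio.consequence import translate
from varprio.simulate import (
    CohortConfig,
    build_synthetic_cds,
    generate_cohort,
    generate_msa_fixture,
    table4_fixture,
    _draw_continuous,
    _CONTINUOUS_DEFAULTS,
)


class TestTable4Fixture:
    def test_ten_variants(self, table4):
        assert len(table4) == 10

    def test_r223c_row(self, table4):
        rec = {r.variant.variant_id: r for r in table4}["APOA5:c.667C>T"]
        profile = rec.profile
        assert (
            profile.sift, profile.polyphen_hdiv, profile.lrt,
            profile.mutation_taster, profile.mutation_assessor,
        ) == ("D", "D", "D", "D", "M")
        assert profile.cadd == 29
        assert rec.variant.status == "novel"

    def test_g263d_conservation_score(self, table4):
        rec = {str(r.variant.protein): r for r in table4}["p.G263D"]
        assert rec.variant.phylo_hmm == pytest.approx(-0.042)

    def test_frameshift_row_has_all_predictors_missing(self, table4):
        rec = {str(r.variant.protein): r for r in table4}["p.H182fs"]
        assert rec.profile == type(rec.profile)()  # all fields None

    def test_carrier_counts_for_common_variant(self, table4):
        rec = {r.variant.variant_id: r for r in table4}["APOA5:c.553G>T"]
        counts = rec.carriers
        assert (counts.n_het_hlap, counts.n_hom_hlap, counts.n_het_bap) == (42, 7, 1)


class TestGenerateCohort:
    def test_arm_sizes(self, default_cohort):
        cohort, _ = default_cohort
        assert (len(cohort.hlap), len(cohort.bap)) == (163, 30)

    def test_exact_apoa5_pathogenic_carriers(self, default_cohort):
        cohort, calls = default_cohort
        rows = {r.gene: r for r in gene_burden_table(cohort, calls)}
        assert rows["APOA5"].n_path_hlap == 52
        assert rows["APOA5"].n_path_bap == 1
        assert rows["APOA5"].n_any_hlap == 97
        assert rows["APOA5"].n_any_bap == 13

    def test_configured_burden_reproduced_for_every_gene(self, default_cohort):
        cohort, calls = default_cohort
        config = CohortConfig()
        rows = {r.gene: r for r in gene_burden_table(cohort, calls)}
        for gene, (any_h, any_b, path_h, path_b) in config.gene_burden.items():
            row = rows[gene]
            assert (row.n_any_hlap, row.n_any_bap) == (any_h, any_b), gene
            assert (row.n_path_hlap, row.n_path_bap) == (path_h, path_b), gene

    def test_named_double_carriers(self, default_cohort):
        cohort, _ = default_cohort
        by_id = {p.id: p for p in cohort}
        assert set(by_id["A10"].genotypes) >= {"APOA5:c.553G>T", "APOA5:c.104G>A"}
        assert set(by_id["A46"].genotypes) >= {"APOA5:c.553G>T", "APOA5:c.667C>T"}
        assert "APOA5:c.544_545insGGTGC" in by_id["A30"].genotypes
        assert by_id["B25"].genotypes.get("APOA5:c.553G>T") == "het"

    def test_flag_and_severity_counts_exact(self, default_cohort):
        cohort, _ = default_cohort
        hlap = cohort.hlap
        assert sum(p.sex == "M" for p in hlap) == 128
        assert sum(p.diabetes for p in hlap) == 87
        assert sum(p.severity in ("MSAP", "SAP") for p in hlap) == 83
        assert sum(p.severity == "SAP" for p in hlap) == 10
        assert sum(p.repeated_recurrence for p in hlap) == 61
        bap = cohort.bap
        assert sum(p.hypertension for p in bap) == 12
        assert sum(p.severity in ("MSAP", "SAP") for p in bap) == 5

    def test_same_seed_identical_two_runs(self):
        c1, _ = generate_cohort(CohortConfig(), seed=42)
        c2, _ = generate_cohort(CohortConfig(), seed=42)
        for p1, p2 in zip(c1, c2):
            assert p1 == p2

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(CohortConfig(), seed=1)
        c2, _ = generate_cohort(CohortConfig(), seed=2)
        assert any(p1.tg != p2.tg for p1, p2 in zip(c1, c2))

    def test_infeasible_carrier_count_raises(self):
        config = CohortConfig()
        config.gene_burden = dict(config.gene_burden)
        config.gene_burden["LPL"] = (200, 6, 16, 4)
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(config, seed=0)

    def test_infeasible_flag_count_raises(self):
        config = CohortConfig()
        config.flags = dict(config.flags, diabetes=(200, 4))
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(config, seed=0)

    def test_tg_carrier_shift_optional_coupling(self):
        config = CohortConfig(tg_carrier_shift=50.0)
        cohort, records = generate_cohort(config, seed=3)
        calls = classify_records(records)
        path_vids = {v for v, c in calls.items() if c.is_pathogenic and v.startswith("APOA5")}
        carriers = [p for p in cohort.hlap if set(p.genotypes) & path_vids]
        others = [p for p in cohort.hlap if not set(p.genotypes) & path_vids]
        assert np.mean([p.tg for p in carriers]) > np.mean([p.tg for p in others]) + 30


class TestMomentMatching:
    def test_tg_mean_coverage_across_replicates(self):
        """Over 500 simulated HLAP arms, the sample TG mean falls within
        2 standard errors of the configured mean in >= 94% of replicates."""
        rng = np.random.default_rng(77)
        mean, sd = _CONTINUOUS_DEFAULTS["tg"]["hlap"]
        se = sd / np.sqrt(163)
        hits = 0
        for _ in range(500):
            draws = _draw_continuous(rng, _CONTINUOUS_DEFAULTS["tg"], "hlap", 163)
            hits += abs(draws.mean() - mean) <= 2 * se
        assert hits / 500 >= 0.94

    def test_lognormal_moments_match_at_large_n(self):
        rng = np.random.default_rng(5)
        for var in ("tg", "tc", "crp"):
            mean, sd = _CONTINUOUS_DEFAULTS[var]["hlap"]
            draws = _draw_continuous(rng, _CONTINUOUS_DEFAULTS[var], "hlap", 200_000)
            assert draws.mean() == pytest.approx(mean, rel=0.02)
            assert draws.std(ddof=1) == pytest.approx(sd, rel=0.05)
            assert draws.min() >= 0


class TestSyntheticCds:
    def test_default_pins_wild_type_residues(self, default_cds):
        protein = translate(default_cds)
        expected = {26: "G", 35: "S", 153: "V", 167: "D", 180: "V",
                    182: "H", 185: "G", 188: "K", 223: "R", 263: "G"}
        for residue, aa in expected.items():
            assert protein[residue - 1] == aa

    def test_length_366_gives_1101_nucleotides(self, default_cds):
        assert len(default_cds.nucleotides) == 1101
        assert default_cds.protein_length == 366

    def test_minimal_constraint_starts_atg(self):
        cds = build_synthetic_cds({1: "M"}, length=20, seed=9)
        assert cds.nucleotides.startswith("ATG")

    def test_amino_acid_constraints_honoured(self):
        cds = build_synthetic_cds({1: "M", 5: "W", 10: "K"}, length=12, seed=9)
        protein = translate(cds)
        assert (protein[4], protein[9]) == ("W", "K")

    def test_seed_determinism(self):
        assert build_synthetic_cds(seed=4) == build_synthetic_cds(seed=4)
        assert build_synthetic_cds(seed=4) != build_synthetic_cds(seed=5)

    def test_impossible_constraint_rejected(self):
        with pytest.raises(ValueError, match="impossible|sense"):
            build_synthetic_cds({1: "M", 5: "TAA"}, length=10, seed=0)

    def test_constraint_beyond_length_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            build_synthetic_cds({400: "G"}, length=366, seed=0)


class TestMsaFixture:
    def test_six_species(self):
        aln = generate_msa_fixture(seed=0)
        assert [rec.id for rec in aln] == ["HUMAN", "RAT", "MOUSE", "NEOSC", "ACIJB", "PHOVI"]

    def test_reference_has_366_residues(self):
        aln = generate_msa_fixture(seed=0)
        human = str(aln[0].seq)
        assert len(human.replace("-", "")) == 366

    def test_seed_determinism(self):
        a1 = generate_msa_fixture(seed=8)
        a2 = generate_msa_fixture(seed=8)
        assert [str(r.seq) for r in a1] == [str(r.seq) for r in a2]

    def test_variability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            generate_msa_fixture(seed=0, variability=1.5)
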