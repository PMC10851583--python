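"""Synthetic study data with the structure the analysis assumes.

The study whose design this package models deposited no raw data, so
every pipeline stage is exercised on synthetic inputs built here:

* :func:`table4_fixture` — the ten annotated APOA5 coding variants
  (six pathogenic, four benign) with their predictor categories, CADD
  scores, allele frequencies, conservation scores and per-arm carrier
  counts, packaged as a TSV;
* :func:`generate_cohort` — a two-arm clinical cohort (163 HLAP / 30
  BAP by default) whose carrier counts, comorbidity counts and severity
  counts are *assigned exactly* as configured, while continuous
  covariates are drawn per arm from moment-matched distributions
  (log-normal for the right-skewed labs, zero-truncated normal for the
  rest);
* :func:`build_synthetic_cds` — a coding sequence of 366 codons plus
  stop whose translation pins the wild-type residues the variant set
  refers to (G26, S35, V153, D167, V180, H182, G185, K188, R223, G263);
* :func:`generate_msa_fixture` — a six-species protein alignment
  (human reference plus rat, mouse, Hawaiian monk seal, cheetah, harbor
  seal stand-ins) strictly conserved at residues 35, 167 and 223 and
  variable elsewhere at a configured rate.

Exact counts are assigned without replacement rather than sampled, so
count-based outputs (burden tables, group sizes, severity percentages)
are deterministic surfaces; only the continuous covariates and the
anonymous carrier identities depend on the random seed.  All generators
are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio.Align import MultipleSeqAlignment
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classifier import classify_records
from .cohort import Cohort, GROUP2_GENES, Patient
from .consequence import CodingSequence, translate
from .variants import (
    AMINO_ACIDS,
    CarrierCounts,
    GeneticVariant,
    PredictorProfile,
    VariantRecord,
    parse_cdna_hgvs,
    parse_protein_hgvs,
    read_variant_table,
)

__all__ = [
    "CohortConfig",
    "DEFAULT_CDS_CONSTRAINTS",
    "MSA_SPECIES",
    "table4_path",
    "table4_fixture",
    "variant_records",
    "generate_cohort",
    "build_synthetic_cds",
    "generate_msa_fixture",
    "write_msa_fasta",
]


def table4_path() -> Path:
    """Path of the packaged APOA5 variant annotation table."""
    return Path(resources.files("varprio").joinpath("data/apoa5_variants.tsv"))


def table4_fixture() -> list[VariantRecord]:
    """The ten packaged APOA5 variants (6 pathogenic, 4 benign)."""
    return read_variant_table(table4_path())


# --- cohort configuration ---------------------------------------------------

# (mean, sd) per arm and the sampling family.  Right-skewed labs whose SD
# approaches or exceeds the mean (TG, TC, CRP, BUN) use a moment-matched
# log-normal; the remaining covariates use a normal truncated at zero.
_CONTINUOUS_DEFAULTS: dict[str, dict] = {
    "age":        {"hlap": (39.71, 9.86),    "bap": (58.30, 15.95), "family": "truncnorm"},
    "bmi":        {"hlap": (27.76, 3.72),    "bap": (25.11, 4.32),  "family": "truncnorm"},
    "wbc":        {"hlap": (14.14, 4.18),    "bap": (11.69, 3.84),  "family": "truncnorm"},
    "crp":        {"hlap": (185.08, 115.24), "bap": (61.66, 64.39), "family": "lognormal"},
    "bun":        {"hlap": (5.76, 9.17),     "bap": (4.73, 1.84),   "family": "lognormal"},
    "creatinine": {"hlap": (70.04, 27.18),   "bap": (68.36, 13.34), "family": "truncnorm"},
    "calcium":    {"hlap": (2.06, 0.23),     "bap": (2.09, 0.22),   "family": "truncnorm"},
    "glucose":    {"hlap": (10.68, 5.20),    "bap": (7.38, 2.70),   "family": "truncnorm"},
    "tg":         {"hlap": (18.00, 19.30),   "bap": (0.91, 0.34),   "family": "lognormal"},
    "tc":         {"hlap": (9.20, 5.27),     "bap": (4.02, 0.90),   "family": "lognormal"},
}

# Exact per-arm counts for flags (assigned without replacement).
_FLAG_DEFAULTS: dict[str, tuple[int, int]] = {
    "male": (128, 11),
    "diabetes": (87, 4),
    "hypertension": (36, 12),
    "fatty_liver": (138, 7),
    "ards": (10, 2),
    "ctsi_gt4": (72, 5),
    "recurrence": (91, 7),
    "repeated_recurrence": (61, 3),
}

# Severity partition per arm: (MAP, MSAP, SAP).
_SEVERITY_DEFAULTS: dict[str, tuple[int, int, int]] = {
    "hlap": (80, 73, 10),
    "bap": (25, 3, 2),
}

# Per-gene distinct-carrier totals (any variant / pathogenic only) per
# arm for the 52 non-APOA5 candidate genes: gene -> (any_hlap, any_bap,
# path_hlap, path_bap).  The KLHL8 BAP any-variant count is raised from
# the printed 1 to 2 so that pathogenic carriers never exceed carriers of
# any variant.
_GENE_BURDEN_DEFAULTS: dict[str, tuple[int, int, int, int]] = {
    "PLA2G6": (44, 7, 9, 0),
    "LIPC": (163, 30, 8, 0),
    "LRP1": (163, 30, 13, 1),
    "LMF2": (163, 30, 6, 0),
    "FGR": (7, 1, 5, 0),
    "CETP": (111, 25, 15, 2),
    "PLTP": (21, 2, 4, 0),
    "PINX1": (12, 4, 4, 0),
    "FRMD5": (104, 14, 3, 0),
    "GCKR": (84, 16, 3, 0),
    "IRS1": (102, 17, 2, 0),
    "HAVCR1": (144, 29, 2, 0),
    "SORL1": (163, 30, 7, 1),
    "PPARG": (83, 8, 1, 0),
    "APOBEC1": (141, 25, 1, 0),
    "PPARD": (151, 27, 1, 0),
    "TRIB1": (86, 15, 1, 0),
    "FADS2": (1, 0, 1, 0),
    "FADS3": (2, 0, 1, 0),
    "ANGPTL4": (36, 7, 1, 0),
    "MLXIPL": (162, 30, 1, 0),
    "GALNT2": (153, 29, 1, 0),
    "PPARA": (17, 4, 1, 0),
    "GPIHBP1": (144, 29, 1, 0),
    "TIMD4": (134, 30, 1, 0),
    "USF1": (1, 0, 0, 0),
    "APOC2": (0, 0, 0, 0),
    "MSL2L1": (0, 0, 0, 0),
    "MTP": (0, 0, 0, 0),
    "ZNF664": (3, 1, 0, 0),
    "FADS1": (2, 1, 0, 0),
    "CYP26A1": (1, 1, 0, 0),
    "CILP2": (18, 5, 0, 0),
    "APOC3": (83, 23, 0, 0),
    "CAPN3": (43, 6, 5, 1),
    "NCAN": (92, 16, 1, 1),
    "ANGPTL3": (9, 1, 1, 1),
    "XKR6": (5, 1, 1, 1),
    "LDLR": (155, 29, 1, 1),
    "LDLRAP1": (110, 20, 0, 1),
    "CTF1": (2, 2, 0, 1),
    "LPL": (22, 6, 16, 4),
    "TYW1B": (122, 25, 56, 12),
    "KLHL8": (3, 2, 1, 2),
    "PEPD": (133, 24, 28, 7),
    "APOE": (90, 20, 22, 6),
    "MAP3K1": (153, 25, 5, 3),
    "NAT2": (134, 30, 9, 4),
    "LMF1": (141, 25, 10, 5),
    "COBLL1": (52, 15, 17, 7),
    "JMJD1C": (151, 30, 21, 9),
    "APOB": (144, 30, 111, 30),
}

# Named carriers of the five rare pathogenic APOA5 variants.  A10 and A46
# are the two double carriers (each also carries the common c.553G>T),
# which is how 54 carrier-events collapse onto 52 distinct carriers.
_PINNED_HLAP_CARRIERS: dict[str, str] = {
    "APOA5:c.104G>A": "A10",      # p.S35N
    "APOA5:c.500A>T": "A15",      # p.D167V
    "APOA5:c.563A>T": "A61",      # p.K188I
    "APOA5:c.667C>T": "A46",      # p.R223C
    "APOA5:c.544_545insGGTGC": "A30",  # p.H182fs
}
_G185C_DOUBLE_CARRIERS = ("A10", "A46")
_PINNED_BAP_G185C_CARRIER = "B25"

# APOA5 distinct-carrier totals over any variant (pathogenic + benign).
_APOA5_ANY_CARRIERS = {"hlap": 97, "bap": 13}


@dataclass
class CohortConfig:
    """Parameters of the synthetic two-arm cohort.

    Defaults reproduce the study conditions: arm sizes 163/30, the
    printed clinical moments and flag counts, the APOA5 variant-level
    carrier counts and the per-gene pathogenic carrier totals.  Counts
    are assigned exactly; only continuous covariates are stochastic.
    """

    n_hlap: int = 163
    n_bap: int = 30
    continuous: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in _CONTINUOUS_DEFAULTS.items()}
    )
    flags: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(_FLAG_DEFAULTS))
    severity: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_SEVERITY_DEFAULTS)
    )
    gene_burden: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(_GENE_BURDEN_DEFAULTS)
    )
    apoa5_any_carriers: dict[str, int] = field(
        default_factory=lambda: dict(_APOA5_ANY_CARRIERS)
    )
    # Size of the designated pool of HLAP patients (outside group I) that
    # absorbs the pathogenic mutations of the 25 group-II genes.
    group2_size: int = 50
    # Optional additive TG shift (mmol/L) for pathogenic APOA5 carriers;
    # off by default (covariate-genotype coupling is not modelled).
    tg_carrier_shift: float = 0.0

    def validate(self) -> None:
        for arm, n in (("HLAP", self.n_hlap), ("BAP", self.n_bap)):
            if n < 1:
                raise ValueError(f"{arm} arm size must be >= 1")
        for name, (k_hlap, k_bap) in self.flags.items():
            for k, n, arm in ((k_hlap, self.n_hlap, "HLAP"), (k_bap, self.n_bap, "BAP")):
                if not 0 <= k <= n:
                    raise ValueError(
                        f"flag {name!r}: count {k} infeasible for {arm} arm of {n}"
                    )
        if self.flags["repeated_recurrence"][0] > self.flags["recurrence"][0]:
            raise ValueError("repeated recurrence count exceeds recurrence count (HLAP)")
        if self.flags["repeated_recurrence"][1] > self.flags["recurrence"][1]:
            raise ValueError("repeated recurrence count exceeds recurrence count (BAP)")
        for arm_key, n in (("hlap", self.n_hlap), ("bap", self.n_bap)):
            if sum(self.severity[arm_key]) != n:
                raise ValueError(
                    f"severity counts {self.severity[arm_key]} do not sum to the "
                    f"{arm_key.upper()} arm size {n}"
                )
        for gene, (any_h, any_b, path_h, path_b) in self.gene_burden.items():
            if not 0 <= path_h <= any_h <= self.n_hlap:
                raise ValueError(f"{gene}: infeasible HLAP carrier counts "
                                 f"(path {path_h}, any {any_h}, arm {self.n_hlap})")
            if not 0 <= path_b <= any_b <= self.n_bap:
                raise ValueError(f"{gene}: infeasible BAP carrier counts "
                                 f"(path {path_b}, any {any_b}, arm {self.n_bap})")
        for name, spec in self.continuous.items():
            for arm_key in ("hlap", "bap"):
                mean, sd = spec[arm_key]
                if mean <= 0 or sd < 0:
                    raise ValueError(f"{name}/{arm_key}: need mean > 0 and sd >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        """Load a config, overriding defaults with a flat YAML mapping."""
        overrides = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        config = cls()
        for key, value in overrides.items():
            if not hasattr(config, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(config, key)
            if isinstance(current, dict) and isinstance(value, dict):
                merged = dict(current)
                for sub, sub_value in value.items():
                    merged[sub] = tuple(sub_value) if isinstance(sub_value, list) else sub_value
                setattr(config, key, merged)
            else:
                setattr(config, key, value)
        return config


# --- variant annotation records ---------------------------------------------

_SYNTH_PATH_PROFILE = PredictorProfile(
    sift="D", polyphen_hdiv="D", lrt="D", mutation_taster="D",
    mutation_assessor="H", cadd=25.0,
)
_SYNTH_BENIGN_PROFILE = PredictorProfile(
    sift="T", polyphen_hdiv="B", lrt="N", mutation_taster="N",
    mutation_assessor="N", cadd=3.0,
)


def variant_records(config: CohortConfig | None = None) -> list[VariantRecord]:
    """Annotation records for every variant the generator can assign.

    APOA5 contributes the ten packaged real variants; every other
    candidate gene contributes one synthetic pathogenic missense and one
    synthetic benign missense (their identities are not study data, only
    their carrier counts are).
    """
    config = config or CohortConfig()
    records = list(table4_fixture())
    for gene in config.gene_burden:
        records.append(
            VariantRecord(
                GeneticVariant(
                    gene=gene,
                    cdna=parse_cdna_hgvs("c.10A>G"),
                    protein=parse_protein_hgvs("p.K4E"),
                    rsid=None,
                    status="novel",
                ),
                _SYNTH_PATH_PROFILE,
                CarrierCounts(),
            )
        )
        records.append(
            VariantRecord(
                GeneticVariant(
                    gene=gene,
                    cdna=parse_cdna_hgvs("c.20C>T"),
                    protein=parse_protein_hgvs("p.P7L"),
                    rsid=None,
                    status="novel",
                ),
                _SYNTH_BENIGN_PROFILE,
                CarrierCounts(),
            )
        )
    return records


# --- cohort generation ------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_continuous(rng: np.random.Generator, spec: dict, arm_key: str, n: int) -> np.ndarray:
    mean, sd = spec[arm_key]
    if sd == 0:
        return np.full(n, mean)
    if spec["family"] == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        return rng.lognormal(mu, sigma, size=n)
    if spec["family"] == "truncnorm":
        # rejection sampling from N(mean, sd) truncated at 0; vectorized
        out = np.empty(0)
        while out.size < n:
            draw = rng.normal(mean, sd, size=2 * (n - out.size) + 8)
            out = np.concatenate([out, draw[draw >= 0]])
        return out[:n]
    raise ValueError(f"unknown sampling family {spec['family']!r}")


def _pick(rng: np.random.Generator, candidates: Sequence[str], k: int, what: str) -> list[str]:
    if k > len(candidates):
        raise ValueError(f"infeasible assignment: need {k} patients for {what}, "
                         f"only {len(candidates)} available")
    if k == 0:
        return []
    return list(rng.choice(np.asarray(candidates, dtype=object), size=k, replace=False))


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[Cohort, list[VariantRecord]]:
    """Generate the synthetic cohort and the matching variant records.

    Counts (carriers, flags, severities) are assigned exactly as
    configured; continuous covariates are drawn per arm.  Two runs with
    the same seed produce identical cohorts.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    hlap_ids = [f"A{i}" for i in range(1, config.n_hlap + 1)]
    bap_ids = [f"B{i}" for i in range(1, config.n_bap + 1)]
    genotypes: dict[str, dict[str, str]] = {pid: {} for pid in hlap_ids + bap_ids}

    # -- APOA5, variant level --------------------------------------------
    fixture = {rec.variant.variant_id: rec for rec in table4_fixture()}
    pinned = {
        vid: pid for vid, pid in _PINNED_HLAP_CARRIERS.items() if vid in fixture
    }
    for vid, pid in pinned.items():
        if pid not in genotypes:
            raise ValueError(f"pinned carrier {pid} outside the HLAP arm")

    g185c = "APOA5:c.553G>T"
    fixture_calls = classify_records(fixture.values())
    pathogenic_apoa5 = [vid for vid, call in fixture_calls.items() if call.is_pathogenic]
    # carriers of the common variant: the two pinned double carriers plus
    # randomly chosen singles, disjoint from the pinned rare-variant carriers
    g185c_counts = fixture[g185c].carriers
    doubles = [p for p in _G185C_DOUBLE_CARRIERS if p in hlap_ids]
    reserved = set(pinned.values()) - set(doubles)
    pool = [p for p in hlap_ids if p not in reserved and p not in doubles]
    n_het_extra = g185c_counts.n_het_hlap - len(doubles)
    if n_het_extra < 0:
        raise ValueError("c.553G>T heterozygote count smaller than its pinned carriers")
    het_extra = _pick(rng, pool, n_het_extra, "c.553G>T het (HLAP)")
    remaining = [p for p in pool if p not in set(het_extra)]
    hom = _pick(rng, remaining, g185c_counts.n_hom_hlap, "c.553G>T hom (HLAP)")
    for pid in doubles + het_extra:
        genotypes[pid][g185c] = "het"
    for pid in hom:
        genotypes[pid][g185c] = "hom"
    for vid, pid in pinned.items():
        genotypes[pid][vid] = "het"
    if g185c_counts.n_het_bap:
        bap_g185c = [_PINNED_BAP_G185C_CARRIER] if _PINNED_BAP_G185C_CARRIER in bap_ids else []
        bap_g185c += _pick(
            rng,
            [p for p in bap_ids if p not in bap_g185c],
            g185c_counts.n_het_bap - len(bap_g185c),
            "c.553G>T het (BAP)",
        )
        for pid in bap_g185c:
            genotypes[pid][g185c] = "het"

    apoa5_path_carriers = {
        "HLAP": {pid for pid in hlap_ids
                 if any(vid in pathogenic_apoa5 for vid in genotypes[pid])},
        "BAP": {pid for pid in bap_ids
                if any(vid in pathogenic_apoa5 for vid in genotypes[pid])},
    }

    # benign APOA5 variants: place carriers so the distinct any-variant
    # totals match the configured 97 / 13; the required overlap with the
    # pathogenic carrier set follows from the counts themselves
    for arm_key, arm_ids, het_attr, hom_attr in (
        ("hlap", hlap_ids, "n_het_hlap", "n_hom_hlap"),
        ("bap", bap_ids, "n_het_bap", "n_hom_bap"),
    ):
        benign_events = sum(
            getattr(rec.carriers, het_attr) + getattr(rec.carriers, hom_attr)
            for vid, rec in fixture.items()
            if vid not in pathogenic_apoa5
        )
        path_set = apoa5_path_carriers[arm_key.upper()]
        target_any = config.apoa5_any_carriers[arm_key]
        overlap = len(path_set) + benign_events - target_any
        if overlap < 0 or overlap > min(len(path_set), benign_events):
            raise ValueError(
                f"APOA5 any-carrier target {target_any} ({arm_key}) inconsistent with "
                f"{len(path_set)} pathogenic carriers and {benign_events} benign events"
            )
        overlap_ids = _pick(rng, sorted(path_set), overlap, f"APOA5 benign overlap ({arm_key})")
        fresh_pool = [p for p in arm_ids if p not in path_set]
        slots: list[str] = list(overlap_ids) + _pick(
            rng, fresh_pool, benign_events - overlap, f"APOA5 benign carriers ({arm_key})"
        )
        i = 0
        for vid, rec in fixture.items():
            if vid in pathogenic_apoa5:
                continue
            for zyg, attr in (("het", het_attr), ("hom", hom_attr)):
                for _ in range(getattr(rec.carriers, attr)):
                    genotypes[slots[i]][vid] = zyg
                    i += 1

    # -- other genes -------------------------------------------------------
    group1 = sorted(apoa5_path_carriers["HLAP"])
    non_group1 = [p for p in hlap_ids if p not in set(group1)]
    group2_pool = _pick(rng, non_group1, min(config.group2_size, len(non_group1)),
                        "group II pool")
    cursor = 0
    for gene in config.gene_burden:
        any_h, any_b, path_h, path_b = config.gene_burden[gene]
        path_vid = f"{gene}:c.10A>G"
        benign_vid = f"{gene}:c.20C>T"
        if gene in GROUP2_GENES and group2_pool:
            # round-robin over the pool: with enough events every pool
            # member carries at least one group-II pathogenic mutation
            carriers_h = [
                group2_pool[(cursor + j) % len(group2_pool)] for j in range(path_h)
            ]
            cursor += path_h
        else:
            carriers_h = _pick(rng, hlap_ids, path_h, f"{gene} pathogenic (HLAP)")
        carriers_b = _pick(rng, bap_ids, path_b, f"{gene} pathogenic (BAP)")
        for pid in carriers_h + carriers_b:
            genotypes[pid][path_vid] = "het"
        for arm_ids, n_any, n_path, carriers in (
            (hlap_ids, any_h, path_h, set(carriers_h)),
            (bap_ids, any_b, path_b, set(carriers_b)),
        ):
            extra = n_any - len(carriers)
            candidates = [p for p in arm_ids if p not in carriers]
            for pid in _pick(rng, candidates, extra, f"{gene} benign carriers"):
                genotypes[pid][benign_vid] = "het"

    # -- clinical covariates ----------------------------------------------
    covariates: dict[str, dict[str, np.ndarray]] = {}
    for name, spec in config.continuous.items():
        covariates[name] = {
            "hlap": _draw_continuous(rng, spec, "hlap", config.n_hlap),
            "bap": _draw_continuous(rng, spec, "bap", config.n_bap),
        }

    flag_sets: dict[str, set[str]] = {}
    for name, (k_hlap, k_bap) in config.flags.items():
        if name == "repeated_recurrence":
            continue  # assigned inside the recurrence set below
        chosen = set(_pick(rng, hlap_ids, k_hlap, f"{name} (HLAP)"))
        chosen |= set(_pick(rng, bap_ids, k_bap, f"{name} (BAP)"))
        flag_sets[name] = chosen
    rr_h, rr_b = config.flags["repeated_recurrence"]
    rec_h = sorted(p for p in flag_sets["recurrence"] if p.startswith("A"))
    rec_b = sorted(p for p in flag_sets["recurrence"] if p.startswith("B"))
    flag_sets["repeated_recurrence"] = set(
        _pick(rng, rec_h, rr_h, "repeated recurrence (HLAP)")
    ) | set(_pick(rng, rec_b, rr_b, "repeated recurrence (BAP)"))

    severity_by_patient: dict[str, str] = {}
    for arm_key, arm_ids in (("hlap", hlap_ids), ("bap", bap_ids)):
        n_map, n_msap, n_sap = config.severity[arm_key]
        order = list(rng.permutation(np.asarray(arm_ids, dtype=object)))
        for pid in order[:n_map]:
            severity_by_patient[pid] = "MAP"
        for pid in order[n_map : n_map + n_msap]:
            severity_by_patient[pid] = "MSAP"
        for pid in order[n_map + n_msap :]:
            severity_by_patient[pid] = "SAP"

    patients = []
    for arm, arm_key, arm_ids in (("HLAP", "hlap", hlap_ids), ("BAP", "bap", bap_ids)):
        for i, pid in enumerate(arm_ids):
            tg = float(covariates["tg"][arm_key][i])
            if config.tg_carrier_shift and pid in apoa5_path_carriers[arm]:
                tg += config.tg_carrier_shift
            patients.append(
                Patient(
                    id=pid,
                    arm=arm,
                    age=float(covariates["age"][arm_key][i]),
                    sex="M" if pid in flag_sets["male"] else "F",
                    bmi=float(covariates["bmi"][arm_key][i]),
                    wbc=float(covariates["wbc"][arm_key][i]),
                    crp=float(covariates["crp"][arm_key][i]),
                    bun=float(covariates["bun"][arm_key][i]),
                    creatinine=float(covariates["creatinine"][arm_key][i]),
                    calcium=float(covariates["calcium"][arm_key][i]),
                    glucose=float(covariates["glucose"][arm_key][i]),
                    tg=tg,
                    tc=float(covariates["tc"][arm_key][i]),
                    diabetes=pid in flag_sets["diabetes"],
                    hypertension=pid in flag_sets["hypertension"],
                    fatty_liver=pid in flag_sets["fatty_liver"],
                    ards=pid in flag_sets["ards"],
                    recurrence=pid in flag_sets["recurrence"],
                    repeated_recurrence=pid in flag_sets["repeated_recurrence"],
                    severity=severity_by_patient[pid],
                    ctsi_gt4=pid in flag_sets["ctsi_gt4"],
                    genotypes=genotypes[pid],
                )
            )
    return Cohort(tuple(patients)), variant_records(config)


# --- synthetic coding sequence ----------------------------------------------

# Explicit codons pinning the wild-type residues referenced by the
# packaged variant set; chosen so that each table substitution produces
# exactly the printed amino-acid exchange.
DEFAULT_CDS_CONSTRAINTS: dict[int, str] = {
    1: "ATG",    # Met1
    26: "GGC",   # Gly26   (c.77G>T  -> GTC, Val)
    35: "AGC",   # Ser35   (c.104G>A -> AAC, Asn)
    153: "GTG",  # Val153  (c.457G>A -> ATG, Met)
    167: "GAC",  # Asp167  (c.500A>T -> GTC, Val)
    180: "GTG",  # Val180  (c.538G>C -> CTG, Leu)
    182: "CAC",  # His182  (anchor of the GGTGC insertion frameshift)
    185: "GGC",  # Gly185  (c.553G>T -> TGC, Cys)
    188: "AAA",  # Lys188  (c.563A>T -> ATA, Ile)
    223: "CGC",  # Arg223  (c.667C>T -> TGC, Cys)
    263: "GGC",  # Gly263  (c.788G>A -> GAC, Asp)
}

_SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
_CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, tuple())
_CODONS_FOR_AA = {
    aa: tuple(sorted(c for c, a in standard_dna_table.forward_table.items() if a == aa))
    for aa in set(standard_dna_table.forward_table.values())
}


def build_synthetic_cds(
    residue_constraints: Mapping[int, str] | None = None,
    length: int = 366,
    seed: int = 0,
    name: str = "APOA5_synthetic_CDS",
) -> CodingSequence:
    """A random CDS of ``length`` codons (plus stop) honouring constraints.

    ``residue_constraints`` maps 1-based codon numbers to either a
    one-letter amino acid or an explicit codon.  Unconstrained codons are
    random sense codons, deterministic under ``seed``.  With no arguments
    this yields the synthetic 366-residue apoA-V stand-in (1101 nt
    including the stop codon).
    """
    constraints = dict(
        DEFAULT_CDS_CONSTRAINTS if residue_constraints is None else residue_constraints
    )
    if constraints and max(constraints) > length:
        raise ValueError(
            f"constraint at codon {max(constraints)} beyond protein length {length}"
        )
    rng = np.random.default_rng(seed)
    codons: list[str] = []
    for i in range(1, length + 1):
        spec = constraints.get(i)
        if spec is None:
            codon = "ATG" if i == 1 else str(rng.choice(_SENSE_CODONS))
        elif len(spec) == 3:
            codon = spec.upper()
            if codon not in _SENSE_CODONS:
                raise ValueError(f"codon {i}: {spec!r} is not a sense codon")
        elif len(spec) == 1:
            aa = spec.upper()
            if aa not in AMINO_ACIDS or aa not in _CODONS_FOR_AA:
                raise ValueError(f"codon {i}: impossible residue {spec!r}")
            codon = _CODONS_FOR_AA[aa][0]
        else:
            raise ValueError(f"codon {i}: constraint must be an amino acid or a codon")
        if i == 1 and codon != "ATG":
            raise ValueError(f"codon 1 must encode the initiator Met (ATG), got {spec!r}")
        codons.append(codon)
    return CodingSequence("".join(codons) + "TAA", name=name)


# --- synthetic multi-species alignment ---------------------------------------

MSA_SPECIES = ("HUMAN", "RAT", "MOUSE", "NEOSC", "ACIJB", "PHOVI")
_STRICT_COLUMNS = (35, 167, 223)
# residues inserted in the seal lineages, after this reference residue;
# yields reference-gap alignment columns so gapped coordinate mapping is
# exercised by the fixture itself
_SEAL_INSERTION_AFTER = 300
_SEAL_INSERTION = "QST"
_AA_LIST = tuple(sorted(AMINO_ACIDS))


def generate_msa_fixture(
    seed: int = 0,
    variability: float = 0.08,
    conserved_positions: Sequence[int] = _STRICT_COLUMNS,
) -> MultipleSeqAlignment:
    """Six aligned protein sequences emulating the cross-species comparison.

    The human reference is the translation of the default synthetic CDS;
    the five other species differ at a ``variability`` fraction of
    residues, never at ``conserved_positions`` (35, 167 and 223 by
    default), and the two seal lineages share a three-residue insertion
    that puts gap columns into the reference row.
    """
    if not 0.0 <= variability <= 1.0:
        raise ValueError("variability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reference = translate(build_synthetic_cds(seed=seed))
    conserved = set(conserved_positions)
    rows: dict[str, list[str]] = {"HUMAN": list(reference)}
    for species in MSA_SPECIES[1:]:
        residues = []
        for pos, aa in enumerate(reference, start=1):
            if pos not in conserved and rng.random() < variability:
                choices = [x for x in _AA_LIST if x != aa]
                residues.append(str(rng.choice(choices)))
            else:
                residues.append(aa)
        rows[species] = residues

    insert_at = _SEAL_INSERTION_AFTER
    aligned: dict[str, str] = {}
    for species, residues in rows.items():
        extra = _SEAL_INSERTION if species in ("NEOSC", "PHOVI") else "-" * len(_SEAL_INSERTION)
        aligned[species] = (
            "".join(residues[:insert_at]) + extra + "".join(residues[insert_at:])
        )
    return MultipleSeqAlignment(
        SeqRecord(Seq(aligned[species]), id=species, description="")
        for species in MSA_SPECIES
    )


def write_msa_fasta(alignment: MultipleSeqAlignment, path: str | Path) -> None:
    from Bio import AlignIO

    AlignIO.write(alignment, str(path), "fasta")
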