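"""Cohort-level aggregation and group comparison.

A cohort is the two-arm case-control design of the study this package
models: patients with hyperlipidemic acute pancreatitis (HLAP, the case
arm) versus biliary acute pancreatitis (BAP, the comparison arm), each
with clinical covariates, comorbidity/severity flags and per-variant
genotypes.  The module derives:

* per-gene burden tables (distinct carriers of any variant and of
  pathogenic mutations, per arm, with percentages);
* the three-way grouping of the HLAP arm (I: pathogenic APOA5 carrier;
  II: pathogenic carrier in the 25 other candidate genes; III: the rest);
* two-group clinical comparisons (mean +- SD with Welch's t-test or the
  Mann-Whitney U test for continuous variables; n (%) with Pearson's
  chi-squared or Fisher's exact test for categorical ones);
* the patient x gene pathogenic-mutation count matrix behind the heat
  map.

Carriers are counted once per gene regardless of how many mutations of
that gene they carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import PathogenicityCall

__all__ = [
    "Patient",
    "Cohort",
    "GeneBurdenRow",
    "GROUP2_GENES",
    "CONTINUOUS_VARIABLES",
    "CATEGORICAL_VARIABLES",
    "ComparisonResult",
    "gene_of",
    "gene_burden_table",
    "burden_to_frame",
    "assign_groups",
    "summarize_and_compare",
    "carrier_matrix",
    "round_half_up",
    "format_p",
]

SEVERITIES = ("MAP", "MSAP", "SAP")
ZYGOSITIES = ("het", "hom")

# The 25 candidate genes (besides APOA5) whose pathogenic mutations were
# enriched in the HLAP arm; carrying one of these without a pathogenic
# APOA5 mutation defines group II.
GROUP2_GENES: tuple[str, ...] = (
    "PLA2G6", "LIPC", "LRP1", "LMF2", "FGR", "CETP", "PLTP", "PINX1",
    "FRMD5", "GCKR", "IRS1", "HAVCR1", "SORL1", "PPARG", "APOBEC1",
    "PPARD", "TRIB1", "FADS2", "FADS3", "ANGPTL4", "MLXIPL", "GALNT2",
    "PPARA", "GPIHBP1", "TIMD4",
)

CONTINUOUS_VARIABLES = (
    "age", "bmi", "wbc", "crp", "bun", "creatinine", "calcium",
    "glucose", "tg", "tc",
)
FLAG_VARIABLES = (
    "diabetes", "hypertension", "fatty_liver", "ards", "recurrence",
    "repeated_recurrence", "ctsi_gt4",
)
# Derived booleans: male from sex, sap / msap_sap from severity.
CATEGORICAL_VARIABLES = FLAG_VARIABLES + ("male", "sap", "msap_sap")


@dataclass
class Patient:
    """One study participant: clinical covariates, flags and genotypes."""

    id: str
    arm: str  # "HLAP" | "BAP"
    age: float
    sex: str  # "M" | "F"
    bmi: float
    wbc: float
    crp: float
    bun: float
    creatinine: float
    calcium: float
    glucose: float
    tg: float
    tc: float
    diabetes: bool = False
    hypertension: bool = False
    fatty_liver: bool = False
    ards: bool = False
    recurrence: bool = False
    repeated_recurrence: bool = False
    severity: str = "MAP"
    ctsi_gt4: bool = False
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ("HLAP", "BAP"):
            raise ValueError(f"arm must be HLAP or BAP, got {self.arm!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES}, got {self.severity!r}")
        for name in CONTINUOUS_VARIABLES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for patient {self.id}")
        if self.repeated_recurrence and not self.recurrence:
            raise ValueError(
                f"patient {self.id}: repeated_recurrence implies recurrence"
            )
        for vid, zyg in self.genotypes.items():
            if zyg not in ZYGOSITIES:
                raise ValueError(f"patient {self.id}: bad zygosity {zyg!r} for {vid}")

    def value(self, variable: str):
        """A clinical variable, including the derived booleans."""
        if variable == "male":
            return self.sex == "M"
        if variable == "sap":
            return self.severity == "SAP"
        if variable == "msap_sap":
            return self.severity in ("MSAP", "SAP")
        return getattr(self, variable)


@dataclass
class Cohort:
    """The full two-arm cohort."""

    patients: tuple[Patient, ...]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def arm(self, which: str) -> list[Patient]:
        return [p for p in self.patients if p.arm == which]

    @property
    def hlap(self) -> list[Patient]:
        return self.arm("HLAP")

    @property
    def bap(self) -> list[Patient]:
        return self.arm("BAP")

    # -- TSV round trip ------------------------------------------------------

    _BOOL_COLUMNS = (
        "diabetes", "hypertension", "fatty_liver", "ards", "recurrence",
        "repeated_recurrence", "ctsi_gt4",
    )

    def to_tsv(self, cohort_path: str | Path, genotypes_path: str | Path) -> None:
        """Write patient table and long-format genotype table."""
        rows = []
        for p in self.patients:
            row = {
                "id": p.id, "arm": p.arm, "age": p.age, "sex": p.sex,
                "bmi": p.bmi, "wbc": p.wbc, "crp": p.crp, "bun": p.bun,
                "creatinine": p.creatinine, "calcium": p.calcium,
                "glucose": p.glucose, "tg": p.tg, "tc": p.tc,
                "severity": p.severity,
            }
            for name in self._BOOL_COLUMNS:
                row[name] = int(getattr(p, name))
            rows.append(row)
        pd.DataFrame(rows).to_csv(cohort_path, sep="\t", index=False)

        geno_rows = [
            {"patient_id": p.id, "variant_id": vid, "zygosity": zyg}
            for p in self.patients
            for vid, zyg in sorted(p.genotypes.items())
        ]
        pd.DataFrame(geno_rows, columns=["patient_id", "variant_id", "zygosity"]).to_csv(
            genotypes_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, cohort_path: str | Path, genotypes_path: str | Path) -> "Cohort":
        table = pd.read_csv(cohort_path, sep="\t", dtype={"id": str})
        geno = pd.read_csv(genotypes_path, sep="\t", dtype=str)
        genotypes: dict[str, dict[str, str]] = {}
        for row in geno.itertuples(index=False):
            genotypes.setdefault(row.patient_id, {})[row.variant_id] = row.zygosity
        patients = []
        for row in table.itertuples(index=False):
            data = row._asdict()
            for name in cls._BOOL_COLUMNS:
                data[name] = bool(int(data[name]))
            data["genotypes"] = genotypes.get(data["id"], {})
            patients.append(Patient(**data))
        unknown = set(genotypes) - {p.id for p in patients}
        if unknown:
            raise ValueError(f"genotype rows for unknown patients: {sorted(unknown)}")
        return cls(tuple(patients))


def gene_of(variant_id: str) -> str:
    """Gene symbol from a canonical ``GENE:c.…`` variant id."""
    gene, _, rest = variant_id.partition(":")
    if not rest:
        raise ValueError(f"variant id {variant_id!r} lacks a GENE: prefix")
    return gene


def round_half_up(value: float) -> int:
    """Round half away from zero, the convention of the printed tables."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


@dataclass(frozen=True)
class GeneBurdenRow:
    """Per-gene distinct-carrier counts for both arms."""

    gene: str
    n_any_hlap: int
    n_any_bap: int
    n_path_hlap: int
    n_path_bap: int
    hlap_size: int
    bap_size: int

    def __post_init__(self) -> None:
        if not self.n_path_hlap <= self.n_any_hlap <= self.hlap_size:
            raise ValueError(f"{self.gene}: inconsistent HLAP carrier counts")
        if not self.n_path_bap <= self.n_any_bap <= self.bap_size:
            raise ValueError(f"{self.gene}: inconsistent BAP carrier counts")

    def pct(self, count: int, arm: str) -> int:
        denom = self.hlap_size if arm == "HLAP" else self.bap_size
        return round_half_up(100.0 * count / denom) if denom else 0


def _carriers_by_gene(
    cohort: Cohort, calls: Mapping[str, PathogenicityCall]
) -> tuple[dict[str, dict[str, set[str]]], dict[str, dict[str, set[str]]]]:
    """Distinct carrier ids per gene per arm, for any variant and pathogenic only."""
    any_c: dict[str, dict[str, set[str]]] = {}
    path_c: dict[str, dict[str, set[str]]] = {}
    for patient in cohort:
        for vid in patient.genotypes:
            if vid not in calls:
                raise ValueError(
                    f"patient {patient.id} genotype references unclassified variant {vid}"
                )
            gene = gene_of(vid)
            any_c.setdefault(gene, {"HLAP": set(), "BAP": set()})[patient.arm].add(patient.id)
            if calls[vid].is_pathogenic:
                path_c.setdefault(gene, {"HLAP": set(), "BAP": set()})[patient.arm].add(
                    patient.id
                )
    return any_c, path_c


def gene_burden_table(
    cohort: Cohort,
    calls: Mapping[str, PathogenicityCall],
    genes: Sequence[str] | None = None,
) -> list[GeneBurdenRow]:
    """Distinct-carrier burden per gene, both columns (all variants /
    pathogenic only) and both arms.

    ``genes`` fixes the row order; by default all genes seen in the
    classified calls appear, sorted.  A patient with several mutations in
    one gene counts once for that gene.
    """
    any_c, path_c = _carriers_by_gene(cohort, calls)
    if genes is None:
        genes = sorted({gene_of(vid) for vid in calls})
    n_hlap, n_bap = len(cohort.hlap), len(cohort.bap)
    rows = []
    for gene in genes:
        a = any_c.get(gene, {"HLAP": set(), "BAP": set()})
        p = path_c.get(gene, {"HLAP": set(), "BAP": set()})
        rows.append(
            GeneBurdenRow(
                gene=gene,
                n_any_hlap=len(a["HLAP"]),
                n_any_bap=len(a["BAP"]),
                n_path_hlap=len(p["HLAP"]),
                n_path_bap=len(p["BAP"]),
                hlap_size=n_hlap,
                bap_size=n_bap,
            )
        )
    return rows


def burden_to_frame(rows: Iterable[GeneBurdenRow]) -> pd.DataFrame:
    """Burden rows as a DataFrame with percentage columns."""
    records = []
    for r in rows:
        records.append(
            {
                "gene": r.gene,
                "n_any_hlap": r.n_any_hlap,
                "pct_any_hlap": r.pct(r.n_any_hlap, "HLAP"),
                "n_any_bap": r.n_any_bap,
                "pct_any_bap": r.pct(r.n_any_bap, "BAP"),
                "n_path_hlap": r.n_path_hlap,
                "pct_path_hlap": r.pct(r.n_path_hlap, "HLAP"),
                "n_path_bap": r.n_path_bap,
                "pct_path_bap": r.pct(r.n_path_bap, "BAP"),
            }
        )
    return pd.DataFrame(records)


def assign_groups(
    patients: Iterable[Patient],
    calls: Mapping[str, PathogenicityCall],
    apoa5_gene: str = "APOA5",
    group2_genes: Sequence[str] = GROUP2_GENES,
) -> dict[str, str]:
    """Partition HLAP patients into groups I / II / III.

    I: carries >= 1 pathogenic APOA5 mutation (takes precedence);
    II: no pathogenic APOA5 but >= 1 pathogenic mutation in the 25
    candidate genes; III: everyone else.  Raises if a BAP patient is
    passed — the grouping is defined on the HLAP arm only.
    """
    group2_set = set(group2_genes)
    groups: dict[str, str] = {}
    for patient in patients:
        if patient.arm != "HLAP":
            raise ValueError(f"patient {patient.id} is {patient.arm}; grouping is HLAP-only")
        path_genes = set()
        for vid in patient.genotypes:
            if vid not in calls:
                raise ValueError(
                    f"patient {patient.id} genotype references unclassified variant {vid}"
                )
            if calls[vid].is_pathogenic:
                path_genes.add(gene_of(vid))
        if apoa5_gene in path_genes:
            groups[patient.id] = "I"
        elif path_genes & group2_set:
            groups[patient.id] = "II"
        else:
            groups[patient.id] = "III"
    return groups


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group summary plus the selected significance test."""

    variable: str
    kind: str  # "continuous" | "categorical"
    group_names: tuple[str, str]
    summaries: tuple[dict, dict]
    test_name: str
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""

    @property
    def p_text(self) -> str:
        return format_p(self.p_value)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "kind": self.kind,
            "groups": {
                name: summary for name, summary in zip(self.group_names, self.summaries)
            },
            "test": self.test_name,
            "statistic": None if math.isnan(self.statistic) else float(self.statistic),
            "p_value": float(self.p_value),
            "p_text": self.p_text,
            "stars": self.stars,
        }


def format_p(p: float) -> str:
    """Three-decimal p-value with the printed-table conventions."""
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"


_SKEW_FALLBACK_THRESHOLD = 2.0


def summarize_and_compare(
    groups: Mapping[str, Sequence[Patient]], variable: str
) -> ComparisonResult:
    """Summarize one clinical variable in two groups and test the contrast.

    Continuous variables: mean +- SD per group; Welch's t-test, replaced
    by the Mann-Whitney U test when either group's sample skewness
    exceeds 2 in magnitude.  Categorical variables: n (%) per group;
    Pearson's chi-squared, replaced by Fisher's exact test when any
    expected cell count falls below 5.  All tests two-tailed.
    """
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    (name_a, patients_a), (name_b, patients_b) = groups.items()
    if not patients_a or not patients_b:
        raise ValueError("empty group passed to summarize_and_compare")

    if variable in CONTINUOUS_VARIABLES:
        a = np.asarray([p.value(variable) for p in patients_a], dtype=float)
        b = np.asarray([p.value(variable) for p in patients_b], dtype=float)
        skewed = any(
            len(x) >= 3 and abs(stats.skew(x)) > _SKEW_FALLBACK_THRESHOLD for x in (a, b)
        )
        if skewed:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney U"
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "Welch t"
        summaries = tuple(
            {
                "n": int(len(x)),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            }
            for x in (a, b)
        )
        return ComparisonResult(
            variable, "continuous", (name_a, name_b), summaries, test, float(stat), float(p)
        )

    if variable in CATEGORICAL_VARIABLES:
        counts = []
        for patients in (patients_a, patients_b):
            k = sum(bool(p.value(variable)) for p in patients)
            counts.append((k, len(patients)))
        table = np.array(
            [[k, n - k] for k, n in counts], dtype=float
        )
        if table.sum(axis=0).min() == 0:
            # degenerate margin (all yes or all no): no association testable
            test, stat, p = "Pearson chi2", 0.0, 1.0
        else:
            expected = stats.contingency.expected_freq(table)
            if expected.min() < 5:
                stat, p = stats.fisher_exact(table.astype(int))
                test = "Fisher exact"
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "Pearson chi2"
        summaries = tuple(
            {
                "n": int(k),
                "total": int(n),
                "pct": round_half_up(100.0 * k / n),
                "pct_1dp": round(100.0 * k / n, 1),
            }
            for k, n in counts
        )
        return ComparisonResult(
            variable, "categorical", (name_a, name_b), summaries, test, float(stat), float(p)
        )

    raise ValueError(f"unknown clinical variable {variable!r}")


def carrier_matrix(
    cohort: Cohort,
    calls: Mapping[str, PathogenicityCall],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Patient x gene matrix of distinct pathogenic-mutation counts.

    The indicator version (cell > 0) column-sums to the pathogenic
    carrier counts of :func:`gene_burden_table`.
    """
    if genes is None:
        genes = sorted({gene_of(vid) for vid in calls})
    matrix = pd.DataFrame(
        0, index=[p.id for p in cohort], columns=list(genes), dtype=int
    )
    for patient in cohort:
        for vid in patient.genotypes:
            if vid not in calls:
                raise ValueError(
                    f"patient {patient.id} genotype references unclassified variant {vid}"
                )
            gene = gene_of(vid)
            if calls[vid].is_pathogenic and gene in matrix.columns:
                matrix.loc[patient.id, gene] += 1
    return matrix
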