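"""Data model and I/O for coding variants and their annotations.

The unit of analysis is a single coding change described in HGVS ``c.``
(nucleotide) and ``p.`` (protein) notation, together with the categorical
outputs of six in-silico pathogenicity predictors (SIFT, PolyPhen2-HDIV,
LRT, MutationTaster, MutationAssessor, CADD), population allele
frequencies, and a per-residue phylo-HMM conservation score.

Only the HGVS subset actually needed for coding SNVs and simple indels is
supported: single-nucleotide substitutions (``c.553G>T``), insertions
between two consecutive positions (``c.544_545insGGTGC``) and simple
deletions (``c.10_12del``).  No delins, no intronic offsets, no genomic
(``g.``) coordinates.  Coding-nucleotide numbering starts at the A of the
initiator ATG (position 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

__all__ = [
    "HgvsParseError",
    "VariantTableError",
    "CdnaKind",
    "CdnaChange",
    "ProteinKind",
    "ProteinChange",
    "PredictorProfile",
    "GeneticVariant",
    "CarrierCounts",
    "VariantRecord",
    "AutoRule",
    "PathogenicityCall",
    "parse_cdna_hgvs",
    "parse_protein_hgvs",
    "read_variant_table",
    "write_variant_table",
]

NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class HgvsParseError(ValueError):
    """Raised for malformed or out-of-scope HGVS strings."""


class VariantTableError(ValueError):
    """Raised for structural problems in a variant annotation table."""


class CdnaKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class CdnaChange:
    """A coding-nucleotide (``c.``) change.

    ``start``/``end`` are 1-based coding-nucleotide indices.  For a
    substitution ``start == end``; for an insertion the inserted sequence
    sits between the consecutive positions ``start`` and ``end``; for a
    deletion the closed interval ``[start, end]`` is removed.
    """

    kind: CdnaKind
    start: int
    end: int
    ref_base: str | None = None
    alt_base: str | None = None
    inserted_seq: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"coding position must be >= 1, got {self.start}")
        if self.kind is CdnaKind.SUBSTITUTION:
            if self.start != self.end:
                raise ValueError("substitution must have start == end")
            if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
                raise ValueError("substitution requires single A/C/G/T ref and alt bases")
            if self.ref_base == self.alt_base:
                raise ValueError("substitution ref and alt bases must differ")
        elif self.kind is CdnaKind.INSERTION:
            if self.end != self.start + 1:
                raise ValueError(
                    f"insertion flanks must be consecutive, got {self.start}_{self.end}"
                )
            if not self.inserted_seq:
                raise ValueError("insertion requires a non-empty inserted sequence")
            bad = set(self.inserted_seq) - NUCLEOTIDES
            if bad:
                raise ValueError(f"invalid nucleotide(s) in inserted sequence: {sorted(bad)}")
        elif self.kind is CdnaKind.DELETION:
            if self.end < self.start:
                raise ValueError("deletion end must be >= start")

    @property
    def position(self) -> int:
        """1-based position of a substitution (alias for ``start``)."""
        return self.start

    @property
    def deleted_len(self) -> int:
        if self.kind is not CdnaKind.DELETION:
            raise ValueError("deleted_len only defined for deletions")
        return self.end - self.start + 1

    def __str__(self) -> str:
        if self.kind is CdnaKind.SUBSTITUTION:
            return f"c.{self.start}{self.ref_base}>{self.alt_base}"
        if self.kind is CdnaKind.INSERTION:
            return f"c.{self.start}_{self.end}ins{self.inserted_seq}"
        if self.start == self.end:
            return f"c.{self.start}del"
        return f"c.{self.start}_{self.end}del"


class ProteinKind(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT = "frameshift"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    INFRAME = "inframe"


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level (``p.``) consequence anchored at a 1-based residue."""

    kind: ProteinKind
    position: int
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"residue position must be >= 1, got {self.position}")
        for aa in (self.ref_aa, self.alt_aa):
            if aa is not None and aa not in AMINO_ACIDS and aa != "*":
                raise ValueError(f"invalid amino-acid letter {aa!r}")
        if self.kind is ProteinKind.MISSENSE and self.ref_aa == self.alt_aa:
            raise ValueError("missense ref and alt residues must differ")

    def __str__(self) -> str:
        if self.kind in (ProteinKind.MISSENSE, ProteinKind.SYNONYMOUS):
            return f"p.{self.ref_aa}{self.position}{self.alt_aa}"
        if self.kind is ProteinKind.FRAMESHIFT:
            ref = self.ref_aa or ""
            return f"p.{ref}{self.position}fs"
        if self.kind is ProteinKind.STOPGAIN:
            return f"p.{self.ref_aa}{self.position}*"
        if self.kind is ProteinKind.STOPLOSS:
            return f"p.*{self.position}{self.alt_aa}"
        return f"p.{self.ref_aa}{self.position}inframe"


_SIFT_CATEGORIES = frozenset("DT")
_POLYPHEN_CATEGORIES = frozenset("DPB")
_LRT_CATEGORIES = frozenset("DNU")
# "A" (disease_causing_automatic) accepted as a conservative superset of the
# documented D/N/P categories.
_MUTATION_TASTER_CATEGORIES = frozenset("DNPA")
_MUTATION_ASSESSOR_CATEGORIES = frozenset("HMLN")


@dataclass(frozen=True)
class PredictorProfile:
    """Outputs of the six in-silico predictors for one variant.

    Categorical predictors hold single-letter categories; CADD holds a
    non-negative scaled score.  ``None`` means the predictor made no call
    (e.g. frameshifts, which the missense predictors do not score).
    Missing values never count as damaging.
    """

    sift: str | None = None
    polyphen_hdiv: str | None = None
    lrt: str | None = None
    mutation_taster: str | None = None
    mutation_assessor: str | None = None
    cadd: float | None = None

    def __post_init__(self) -> None:
        _check_category("SIFT", self.sift, _SIFT_CATEGORIES)
        _check_category("PolyPhen2-HDIV", self.polyphen_hdiv, _POLYPHEN_CATEGORIES)
        _check_category("LRT", self.lrt, _LRT_CATEGORIES)
        _check_category("MutationTaster", self.mutation_taster, _MUTATION_TASTER_CATEGORIES)
        _check_category("MutationAssessor", self.mutation_assessor, _MUTATION_ASSESSOR_CATEGORIES)
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"CADD score must be >= 0, got {self.cadd}")


def _check_category(name: str, value: str | None, allowed: frozenset[str]) -> None:
    if value is not None and value not in allowed:
        raise ValueError(f"unknown {name} category {value!r}; expected one of {sorted(allowed)}")


@dataclass(frozen=True)
class GeneticVariant:
    """One coding variant of a gene, with database annotations."""

    gene: str
    cdna: CdnaChange
    protein: ProteinChange | None = None
    rsid: str | None = None
    status: str = "novel"  # "known" | "novel"
    af_all: float | None = None
    af_eas: float | None = None
    af_amr: float | None = None
    phylo_hmm: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("known", "novel"):
            raise ValueError(f"status must be 'known' or 'novel', got {self.status!r}")
        # Novelty convention: a variant is novel iff it has no dbSNP identifier.
        if (self.rsid is None) != (self.status == "novel"):
            raise ValueError(
                f"status {self.status!r} inconsistent with rsid {self.rsid!r}: "
                "novel variants carry no rsid and known variants must carry one"
            )
        for name in ("af_all", "af_eas", "af_amr"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    @property
    def variant_id(self) -> str:
        """Canonical identifier, e.g. ``APOA5:c.553G>T``."""
        return f"{self.gene}:{self.cdna}"


@dataclass(frozen=True)
class CarrierCounts:
    """Per-arm carrier counts by zygosity for one variant."""

    n_het_hlap: int = 0
    n_hom_hlap: int = 0
    n_het_bap: int = 0
    n_hom_bap: int = 0

    def __post_init__(self) -> None:
        for name in ("n_het_hlap", "n_hom_hlap", "n_het_bap", "n_hom_bap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class VariantRecord:
    """One row of a variant annotation table."""

    variant: GeneticVariant
    profile: PredictorProfile
    carriers: CarrierCounts


class AutoRule(str, Enum):
    NONE = "none"
    FRAMESHIFT = "frameshift"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"


@dataclass(frozen=True)
class PathogenicityCall:
    """Classification verdict for one variant under the consensus rule."""

    verdict: str  # "pathogenic" | "benign"
    damaging_votes: int
    sift_damaging: bool
    auto_rule: AutoRule = AutoRule.NONE
    rationale: str = ""
    per_program: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in ("pathogenic", "benign"):
            raise ValueError(f"verdict must be 'pathogenic' or 'benign', got {self.verdict!r}")
        if not 0 <= self.damaging_votes <= 6:
            raise ValueError(f"damaging_votes must lie in 0..6, got {self.damaging_votes}")
        if self.verdict == "pathogenic":
            if self.auto_rule is AutoRule.NONE and not (
                self.sift_damaging and self.damaging_votes >= 2
            ):
                raise ValueError(
                    "pathogenic verdict requires an auto rule or "
                    "SIFT damaging with >= 2 damaging votes"
                )

    @property
    def is_pathogenic(self) -> bool:
        return self.verdict == "pathogenic"


# --- HGVS parsing -----------------------------------------------------------

_SUB_RE = re.compile(r"(\d+)([A-Za-z])>([A-Za-z])")
_INS_RE = re.compile(r"(\d+)_(\d+)ins([A-Za-z]+)")
_DEL_RE = re.compile(r"(\d+)(?:_(\d+))?del([ACGTacgt]*)")


def parse_cdna_hgvs(text: str) -> CdnaChange:
    """Parse an HGVS coding-DNA string into a :class:`CdnaChange`.

    Accepts the substitution, simple-insertion and simple-deletion forms
    used for coding SNVs/indels, tolerating whitespace around tokens
    (``"c.544_545 insGGTGC"`` and ``"c.553G > T"`` both parse).

    >>> parse_cdna_hgvs("c.553G > T")
    CdnaChange(kind=<CdnaKind.SUBSTITUTION: 'substitution'>, ...)
    """
    stripped = text.strip()
    if not stripped.startswith("c."):
        raise HgvsParseError(f"not a coding-DNA (c.) description: {text!r}")
    body = "".join(stripped[2:].split())
    if not body:
        raise HgvsParseError(f"empty c. description: {text!r}")

    m = _SUB_RE.fullmatch(body)
    if m:
        pos, ref, alt = m.groups()
        ref, alt = ref.upper(), alt.upper()
        for base in (ref, alt):
            if base not in NUCLEOTIDES:
                raise HgvsParseError(f"invalid nucleotide {base!r} in {text!r}")
        try:
            return CdnaChange(CdnaKind.SUBSTITUTION, int(pos), int(pos), ref_base=ref, alt_base=alt)
        except ValueError as exc:
            raise HgvsParseError(f"{exc} (in {text!r})") from exc

    m = _INS_RE.fullmatch(body)
    if m:
        start, end, seq = int(m.group(1)), int(m.group(2)), m.group(3).upper()
        if end != start + 1:
            raise HgvsParseError(
                f"insertion flanks {start}_{end} are not consecutive in {text!r}"
            )
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise HgvsParseError(f"invalid nucleotide(s) {sorted(bad)} in {text!r}")
        return CdnaChange(CdnaKind.INSERTION, start, end, inserted_seq=seq)

    m = _DEL_RE.fullmatch(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if end < start:
            raise HgvsParseError(f"deletion range {start}_{end} reversed in {text!r}")
        return CdnaChange(CdnaKind.DELETION, start, end)

    raise HgvsParseError(f"unsupported or malformed c. description: {text!r}")


_MISSENSE_RE = re.compile(r"([A-Z\*])(\d+)([A-Z\*])")
_FS_RE = re.compile(r"([A-Z])(\d+)fs")


def parse_protein_hgvs(text: str) -> ProteinChange:
    """Parse an HGVS protein string (one-letter codes) into a :class:`ProteinChange`.

    Accepts missense/synonymous (``p.G185C``), frameshift (``p.H182fs``),
    stopgain (``p.R100*``) and stoploss (``p.*367R``) forms.
    """
    stripped = text.strip()
    if not stripped.startswith("p."):
        raise HgvsParseError(f"not a protein (p.) description: {text!r}")
    body = "".join(stripped[2:].split())
    if not body:
        raise HgvsParseError(f"empty p. description: {text!r}")

    try:
        m = _FS_RE.fullmatch(body)
        if m:
            ref, pos = m.group(1), int(m.group(2))
            if ref not in AMINO_ACIDS:
                raise HgvsParseError(f"invalid amino acid {ref!r} in {text!r}")
            return ProteinChange(ProteinKind.FRAMESHIFT, pos, ref_aa=ref)

        m = _MISSENSE_RE.fullmatch(body)
        if m:
            ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
            for aa in (ref, alt):
                if aa not in AMINO_ACIDS and aa != "*":
                    raise HgvsParseError(f"invalid amino acid {aa!r} in {text!r}")
            if ref == "*" and alt == "*":
                raise HgvsParseError(f"degenerate stop-to-stop change: {text!r}")
            if ref == "*":
                return ProteinChange(ProteinKind.STOPLOSS, pos, ref_aa="*", alt_aa=alt)
            if alt == "*":
                return ProteinChange(ProteinKind.STOPGAIN, pos, ref_aa=ref, alt_aa="*")
            kind = ProteinKind.SYNONYMOUS if ref == alt else ProteinKind.MISSENSE
            return ProteinChange(kind, pos, ref_aa=ref, alt_aa=alt)
    except ValueError as exc:
        if isinstance(exc, HgvsParseError):
            raise
        raise HgvsParseError(f"{exc} (in {text!r})") from exc

    raise HgvsParseError(f"unsupported or malformed p. description: {text!r}")


# --- Variant annotation tables ----------------------------------------------

VARIANT_TABLE_COLUMNS = (
    "gene",
    "exon",
    "cdna",
    "protein",
    "rsid",
    "status",
    "sift",
    "polyphen_hdiv",
    "lrt",
    "mutation_taster",
    "mutation_assessor",
    "cadd",
    "af_all",
    "af_eas",
    "af_amr",
    "phylo_hmm",
    "n_het_hlap",
    "n_hom_hlap",
    "n_het_bap",
    "n_hom_bap",
)

_MISSING = "na"


def _opt(value: str) -> str | None:
    return None if value == _MISSING else value


def _opt_float(value: str, column: str, lineno: int) -> float | None:
    if value == _MISSING:
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise VariantTableError(f"line {lineno}: bad number {value!r} in column {column!r}") from exc


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-delimited variant annotation table.

    The table is UTF-8, tab-delimited, with the exact header of
    :data:`VARIANT_TABLE_COLUMNS`; the string ``"na"`` marks a missing
    value in any annotation column and is preserved as missing (never
    coerced to zero).  Errors are reported with their 1-based line number.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        lines = [line.rstrip("\n") for line in handle if line.strip()]
    if not lines:
        raise VariantTableError(f"{path}: empty file, expected a header row")
    header = tuple(lines[0].split("\t"))
    if header != VARIANT_TABLE_COLUMNS:
        unknown = set(header) - set(VARIANT_TABLE_COLUMNS)
        missing = set(VARIANT_TABLE_COLUMNS) - set(header)
        raise VariantTableError(
            f"{path}: unexpected header (unknown columns {sorted(unknown)}, "
            f"missing columns {sorted(missing)})"
        )

    records: list[VariantRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise VariantTableError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        try:
            cdna = parse_cdna_hgvs(row["cdna"])
            protein = parse_protein_hgvs(row["protein"]) if row["protein"] != _MISSING else None
            variant = GeneticVariant(
                gene=row["gene"],
                cdna=cdna,
                protein=protein,
                rsid=_opt(row["rsid"]),
                status=row["status"],
                af_all=_opt_float(row["af_all"], "af_all", lineno),
                af_eas=_opt_float(row["af_eas"], "af_eas", lineno),
                af_amr=_opt_float(row["af_amr"], "af_amr", lineno),
                phylo_hmm=_opt_float(row["phylo_hmm"], "phylo_hmm", lineno),
            )
            profile = PredictorProfile(
                sift=_opt(row["sift"]),
                polyphen_hdiv=_opt(row["polyphen_hdiv"]),
                lrt=_opt(row["lrt"]),
                mutation_taster=_opt(row["mutation_taster"]),
                mutation_assessor=_opt(row["mutation_assessor"]),
                cadd=_opt_float(row["cadd"], "cadd", lineno),
            )
            carriers = CarrierCounts(
                n_het_hlap=int(row["n_het_hlap"]),
                n_hom_hlap=int(row["n_hom_hlap"]),
                n_het_bap=int(row["n_het_bap"]),
                n_hom_bap=int(row["n_hom_bap"]),
            )
        except (ValueError, HgvsParseError) as exc:
            raise VariantTableError(f"{path}, line {lineno}: {exc}") from exc
        records.append(VariantRecord(variant, profile, carriers))
    return records


def write_variant_table(records: list[VariantRecord], path: str | Path, exon: str = "na") -> None:
    """Write records back to the tab-delimited table format."""

    def fmt(value) -> str:
        if value is None:
            return _MISSING
        if isinstance(value, float):
            return repr(value)
        return str(value)

    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(VARIANT_TABLE_COLUMNS) + "\n")
        for rec in records:
            v, p, c = rec.variant, rec.profile, rec.carriers
            fields = [
                v.gene,
                exon,
                str(v.cdna),
                str(v.protein) if v.protein is not None else _MISSING,
                fmt(v.rsid),
                v.status,
                fmt(p.sift),
                fmt(p.polyphen_hdiv),
                fmt(p.lrt),
                fmt(p.mutation_taster),
                fmt(p.mutation_assessor),
                fmt(p.cadd),
                fmt(v.af_all),
                fmt(v.af_eas),
                fmt(v.af_amr),
                fmt(v.phylo_hmm),
                str(c.n_het_hlap),
                str(c.n_hom_hlap),
                str(c.n_het_bap),
                str(c.n_hom_bap),
            ]
            handle.write("\t".join(fields) + "\n")
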