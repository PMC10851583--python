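"""Protein-level annotation of apoA-V residues.

Three facilities:

* a domain map of apolipoprotein A-V (366 residues, full-length numbering
  with Met1 = 1) — signal peptide, AlphaFold-supported alpha-helices,
  lipid-binding regions, the nine positively charged receptor-binding
  domains (RBDs), the heparin-binding region and the LPL-activation
  region — with interval queries by residue;
* a residue-property table (charge at physiological pH, polarity,
  hydropathy) used to describe what a missense change does to the local
  chemistry;
* column conservation in a multiple protein alignment, mapped through the
  gapped reference coordinate system.

Domain coordinates are 1-based and inclusive on both ends.  Intervals of
different classes overlap freely (R223, for instance, sits in a helix,
a lipid-binding region, the heparin-binding region and the
LPL-activation region at once).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .variants import AMINO_ACIDS

__all__ = [
    "DomainClass",
    "Domain",
    "DomainMap",
    "APOA5_PROTEIN_LENGTH",
    "APOA5_DOMAINS",
    "domains_at",
    "ResiduePropertyDelta",
    "property_change",
    "CHARGE",
    "POLAR_RESIDUES",
    "KYTE_DOOLITTLE",
    "read_alignment",
    "reference_column",
    "column_to_reference_residue",
    "column_conservation",
]


class DomainClass(str, Enum):
    SIGNAL_PEPTIDE = "signal_peptide"
    HELIX = "helix"
    LIPID_BINDING = "lipid_binding"
    RECEPTOR_BINDING = "receptor_binding"
    HEPARIN_BINDING = "heparin_binding"
    LPL_ACTIVATION = "lpl_activation"


@dataclass(frozen=True)
class Domain:
    """A named residue interval, 1-based and inclusive on both ends."""

    name: str
    domain_class: DomainClass
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval {self.start}..{self.end} for {self.name}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class DomainMap:
    """An ordered set of domains over a protein of fixed length."""

    entries: tuple[Domain, ...]
    protein_length: int

    def __post_init__(self) -> None:
        for dom in self.entries:
            if dom.end > self.protein_length:
                raise ValueError(
                    f"{dom.name} ends at {dom.end}, beyond protein length {self.protein_length}"
                )

    def at(self, position: int) -> list[Domain]:
        return domains_at(position, self)

    def to_tsv(self, path: str | Path) -> None:
        """BED-like TSV: name, class, start, end (1-based, inclusive)."""
        with Path(path).open("w", encoding="utf-8") as handle:
            handle.write("name\tclass\tstart\tend\n")
            for dom in self.entries:
                handle.write(f"{dom.name}\t{dom.domain_class.value}\t{dom.start}\t{dom.end}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, protein_length: int) -> "DomainMap":
        entries = []
        with Path(path).open(encoding="utf-8") as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header != ["name", "class", "start", "end"]:
                raise ValueError(f"{path}: unexpected domain-map header {header}")
            for line in handle:
                if not line.strip():
                    continue
                name, klass, start, end = line.rstrip("\n").split("\t")
                entries.append(Domain(name, DomainClass(klass), int(start), int(end)))
        return cls(tuple(entries), protein_length)


APOA5_PROTEIN_LENGTH = 366

# Full-length apoA-V numbering (Met1 = 1).  Helices are the four
# AlphaFold-supported segments (pLDDT > 70); RBD1..RBD9 are the nine
# positively charged receptor-binding segments.
APOA5_DOMAINS = DomainMap(
    entries=(
        Domain("signal peptide", DomainClass.SIGNAL_PEPTIDE, 1, 23),
        Domain("helix 1", DomainClass.HELIX, 112, 153),
        Domain("helix 2", DomainClass.HELIX, 173, 213),
        Domain("helix 3", DomainClass.HELIX, 221, 262),
        Domain("helix 4", DomainClass.HELIX, 275, 314),
        Domain("lipid binding 1", DomainClass.LIPID_BINDING, 24, 169),
        Domain("lipid binding 2", DomainClass.LIPID_BINDING, 194, 268),
        Domain("lipid binding 3", DomainClass.LIPID_BINDING, 316, 366),
        Domain("RBD1", DomainClass.RECEPTOR_BINDING, 21, 26),
        Domain("RBD2", DomainClass.RECEPTOR_BINDING, 36, 43),
        Domain("RBD3", DomainClass.RECEPTOR_BINDING, 48, 54),
        Domain("RBD4", DomainClass.RECEPTOR_BINDING, 90, 98),
        Domain("RBD5", DomainClass.RECEPTOR_BINDING, 146, 152),
        Domain("RBD6", DomainClass.RECEPTOR_BINDING, 182, 190),
        Domain("RBD7", DomainClass.RECEPTOR_BINDING, 232, 237),
        Domain("RBD8", DomainClass.RECEPTOR_BINDING, 251, 257),
        Domain("RBD9", DomainClass.RECEPTOR_BINDING, 281, 292),
        Domain("heparin binding", DomainClass.HEPARIN_BINDING, 209, 250),
        Domain("LPL activation", DomainClass.LPL_ACTIVATION, 215, 261),
    ),
    protein_length=APOA5_PROTEIN_LENGTH,
)


def domains_at(position: int, domain_map: DomainMap = APOA5_DOMAINS) -> list[Domain]:
    """All domains overlapping a residue position, in map order.

    >>> [d.name for d in domains_at(223)]
    ['helix 3', 'lipid binding 2', 'heparin binding', 'LPL activation']
    """
    if not 1 <= position <= domain_map.protein_length:
        raise ValueError(
            f"residue {position} outside protein (1..{domain_map.protein_length})"
        )
    return [dom for dom in domain_map.entries if position in dom]


# --- residue properties -----------------------------------------------------

# Net side-chain charge at physiological pH; histidine counted +1 with the
# other basic residues.
CHARGE: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
CHARGE.update({"D": -1, "E": -1, "K": +1, "R": +1, "H": +1})

# Polar residues (charged residues are polar by definition).
POLAR_RESIDUES = frozenset("RNDCEQHKSTY")

# Kyte-Doolittle hydropathy; > 0 is counted hydrophobic, <= 0 hydrophilic.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class ResiduePropertyDelta:
    """Charge / polarity / hydropathy comparison for one substitution."""

    ref_aa: str
    alt_aa: str
    charge_before: int
    charge_after: int
    polarity_before: str  # "polar" | "nonpolar"
    polarity_after: str
    hydropathy_before: str  # "hydrophilic" | "hydrophobic"
    hydropathy_after: str
    position: int | None = None

    @property
    def charge_changed(self) -> bool:
        return self.charge_before != self.charge_after

    @property
    def polarity_changed(self) -> bool:
        return self.polarity_before != self.polarity_after

    @property
    def hydropathy_changed(self) -> bool:
        return self.hydropathy_before != self.hydropathy_after

    @property
    def any_changed(self) -> bool:
        return self.charge_changed or self.polarity_changed or self.hydropathy_changed

    def describe(self) -> str:
        if not self.any_changed:
            return (
                f"{self.ref_aa}->{self.alt_aa}: no change in charge, polarity "
                "or hydropathy"
            )
        parts = []
        if self.charge_changed:
            parts.append(f"charge {self.charge_before:+d} -> {self.charge_after:+d}")
        if self.polarity_changed:
            parts.append(f"{self.polarity_before} -> {self.polarity_after}")
        if self.hydropathy_changed:
            parts.append(f"{self.hydropathy_before} -> {self.hydropathy_after}")
        return f"{self.ref_aa}->{self.alt_aa}: " + ", ".join(parts)


def property_change(ref_aa: str, alt_aa: str, position: int | None = None) -> ResiduePropertyDelta:
    """Describe how a substitution alters residue chemistry.

    >>> delta = property_change("D", "V")
    >>> delta.charge_before, delta.charge_after
    (-1, 0)
    >>> delta.hydropathy_changed
    True
    """
    for aa in (ref_aa, alt_aa):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard amino acid {aa!r}")

    def polarity(aa: str) -> str:
        return "polar" if aa in POLAR_RESIDUES else "nonpolar"

    def hydropathy(aa: str) -> str:
        return "hydrophobic" if KYTE_DOOLITTLE[aa] > 0 else "hydrophilic"

    return ResiduePropertyDelta(
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        charge_before=CHARGE[ref_aa],
        charge_after=CHARGE[alt_aa],
        polarity_before=polarity(ref_aa),
        polarity_after=polarity(alt_aa),
        hydropathy_before=hydropathy(ref_aa),
        hydropathy_after=hydropathy(alt_aa),
        position=position,
    )


# --- alignment-column conservation ------------------------------------------

def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA file (equal-length, gap '-')."""
    alignment = AlignIO.read(str(path), "fasta")
    return alignment


def _rows(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, MultipleSeqAlignment):
        rows = [(rec.id, str(rec.seq).upper()) for rec in alignment]
    else:
        rows = [(f"seq{i}", str(seq).upper()) for i, seq in enumerate(alignment)]
    if len(rows) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    return rows


def reference_column(alignment, residue: int, reference: int = 0) -> int:
    """0-based alignment column holding the reference's 1-based residue ``residue``."""
    rows = _rows(alignment)
    ref_seq = rows[reference][1]
    seen = 0
    for col, symbol in enumerate(ref_seq):
        if symbol != "-":
            seen += 1
            if seen == residue:
                return col
    raise ValueError(f"reference has only {seen} residues, requested {residue}")


def column_to_reference_residue(alignment, column: int, reference: int = 0) -> int:
    """1-based reference residue at a 0-based alignment column (gap -> error)."""
    rows = _rows(alignment)
    ref_seq = rows[reference][1]
    if not 0 <= column < len(ref_seq):
        raise ValueError(f"column {column} outside alignment of width {len(ref_seq)}")
    if ref_seq[column] == "-":
        raise ValueError(f"reference is gapped at column {column}")
    return sum(1 for symbol in ref_seq[: column + 1] if symbol != "-")


def column_conservation(
    alignment, residue: int, reference: int = 0
) -> tuple[float, bool]:
    """Conservation of the reference residue's column across the alignment.

    Returns ``(fraction_identical, strict)`` where the fraction is over
    the non-reference sequences matching the reference residue (gaps count
    as mismatches) and ``strict`` means every sequence matches.

    >>> aln = ["MKR", "MKR", "MQR"]
    >>> column_conservation(aln, 2)
    (0.5, False)
    """
    rows = _rows(alignment)
    col = reference_column(alignment, residue, reference=reference)
    ref_symbol = rows[reference][1][col]
    others = [seq[col] for i, (_, seq) in enumerate(rows) if i != reference]
    matches = sum(1 for symbol in others if symbol == ref_symbol)
    fraction = matches / len(others)
    return fraction, fraction == 1.0
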