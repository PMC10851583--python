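"""Map coding-nucleotide changes to protein consequences.

Works on a single coding sequence (CDS) given in coding-strand
orientation: ATG first, exactly one stop codon, at the end.  Coding
position 1 is the A of the initiator ATG, so codon *k* occupies
nucleotides ``3k-2 .. 3k``.

Consequence classes: substitutions become missense / synonymous /
stopgain / stoploss by comparing translations; indels whose length is not
a multiple of three are frameshifts, anchored at the codon containing the
first shifted nucleotide (for an insertion between ``i`` and ``i+1`` that
is the codon of ``i+1``); in-frame indels are reported as ``inframe`` and
are not subject to the frameshift auto-pathogenicity rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import CdnaChange, CdnaKind, ProteinChange, ProteinKind, NUCLEOTIDES

__all__ = [
    "CodingSequence",
    "ReferenceMismatchError",
    "codon_index",
    "translate",
    "call_consequence",
    "read_cds_fasta",
    "write_cds_fasta",
]

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ReferenceMismatchError(ValueError):
    """The change's stated reference base disagrees with the CDS."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: starts with ATG, ends with its single stop codon."""

    nucleotides: str
    name: str = "cds"

    def __post_init__(self) -> None:
        seq = self.nucleotides
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise ValueError(f"non-ACGT letters in CDS: {sorted(bad)}")
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
        if len(seq) < 6:
            raise ValueError("CDS must contain at least a start and a stop codon")
        if seq[:3] != "ATG":
            raise ValueError(f"CDS must start with ATG, got {seq[:3]}")
        if seq[-3:] not in _STOP_CODONS:
            raise ValueError(f"CDS must end with a stop codon, got {seq[-3:]}")
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in _STOP_CODONS:
                raise ValueError(f"internal stop codon at codon {i // 3 + 1}")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def protein_length(self) -> int:
        """Number of amino-acid residues (codons before the stop)."""
        return len(self.nucleotides) // 3 - 1

    def codon(self, number: int) -> str:
        """The codon at 1-based codon ``number`` (stop codon included)."""
        if not 1 <= number <= len(self.nucleotides) // 3:
            raise ValueError(f"codon number {number} out of range")
        return self.nucleotides[3 * (number - 1) : 3 * number]


def codon_index(cds_position: int) -> int:
    """1-based codon number containing 1-based coding-nucleotide ``cds_position``.

    >>> codon_index(553)
    185
    """
    if cds_position < 1:
        raise ValueError(f"coding position must be >= 1, got {cds_position}")
    return (cds_position + 2) // 3


def translate(cds: CodingSequence) -> str:
    """Standard-genetic-code translation of the CDS, stop excluded."""
    protein = str(Seq(cds.nucleotides).translate())
    # CodingSequence validation guarantees the single terminal stop.
    assert protein.endswith("*") and "*" not in protein[:-1]
    return protein[:-1]


def _translate_raw(seq: str) -> str:
    """Translate an arbitrary frame-0 nucleotide string, keeping stops."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def call_consequence(cds: CodingSequence, change: CdnaChange) -> ProteinChange:
    """Determine the protein consequence of ``change`` applied to ``cds``.

    Substitutions are classified by mutate-and-compare at the affected
    codon; a substitution in the stop codon that yields a sense codon is a
    stoploss.  Indels are frameshift or inframe by length modulo 3.
    """
    seq = cds.nucleotides
    n = len(seq)

    if change.kind is CdnaKind.SUBSTITUTION:
        pos = change.position
        if pos > n:
            raise ValueError(f"position {pos} beyond CDS length {n}")
        found = seq[pos - 1]
        if found != change.ref_base:
            raise ReferenceMismatchError(
                f"reference mismatch at c.{pos}: change states {change.ref_base}, "
                f"CDS holds {found}"
            )
        codon_no = codon_index(pos)
        mutant_codon = _apply_sub(cds.codon(codon_no), (pos - 1) % 3, change.alt_base)
        ref_is_stop = codon_no == n // 3
        alt_is_stop = mutant_codon in _STOP_CODONS
        if ref_is_stop:
            if alt_is_stop:
                return ProteinChange(ProteinKind.SYNONYMOUS, codon_no, ref_aa="*", alt_aa="*")
            alt_aa = _translate_raw(mutant_codon)
            return ProteinChange(ProteinKind.STOPLOSS, codon_no, ref_aa="*", alt_aa=alt_aa)
        ref_aa = _translate_raw(cds.codon(codon_no))
        if alt_is_stop:
            return ProteinChange(ProteinKind.STOPGAIN, codon_no, ref_aa=ref_aa, alt_aa="*")
        alt_aa = _translate_raw(mutant_codon)
        kind = ProteinKind.SYNONYMOUS if ref_aa == alt_aa else ProteinKind.MISSENSE
        return ProteinChange(kind, codon_no, ref_aa=ref_aa, alt_aa=alt_aa)

    if change.kind is CdnaKind.INSERTION:
        if change.end > n:
            raise ValueError(f"insertion flank {change.end} beyond CDS length {n}")
        anchor = codon_index(change.end)  # codon of the first shifted nucleotide
        ref_aa = _anchor_residue(cds, anchor)
        if len(change.inserted_seq) % 3 != 0:
            return ProteinChange(ProteinKind.FRAMESHIFT, anchor, ref_aa=ref_aa)
        return ProteinChange(ProteinKind.INFRAME, anchor, ref_aa=ref_aa)

    # deletion
    if change.end > n:
        raise ValueError(f"deletion end {change.end} beyond CDS length {n}")
    anchor = codon_index(change.start)
    ref_aa = _anchor_residue(cds, anchor)
    if change.deleted_len % 3 != 0:
        return ProteinChange(ProteinKind.FRAMESHIFT, anchor, ref_aa=ref_aa)
    return ProteinChange(ProteinKind.INFRAME, anchor, ref_aa=ref_aa)


def _apply_sub(codon: str, offset: int, alt: str) -> str:
    return codon[:offset] + alt + codon[offset + 1 :]


def _anchor_residue(cds: CodingSequence, codon_no: int) -> str | None:
    if codon_no > cds.protein_length:
        return "*"
    return _translate_raw(cds.codon(codon_no))


def read_cds_fasta(path: str | Path) -> CodingSequence:
    """Read a single-record FASTA file as a coding sequence (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return CodingSequence(str(rec.seq).upper(), name=rec.id)


def write_cds_fasta(cds: CodingSequence, path: str | Path) -> None:
    record = SeqRecord(Seq(cds.nucleotides), id=cds.name, description="")
    SeqIO.write([record], str(path), "fasta")
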