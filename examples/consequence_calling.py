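"""Map coding-nucleotide changes to protein consequences.

Builds the synthetic 366-residue apoA-V coding sequence (wild-type
residues pinned at the positions the variant set references) and runs
the consequence caller on the study's coding changes.  The codon number
printed for each substitution is ceil(position / 3).
"""

from varprio import build_synthetic_cds, call_consequence, codon_index, parse_cdna_hgvs

cds = build_synthetic_cds(seed=0)
print(f"synthetic CDS: {len(cds.nucleotides)} nt -> {cds.protein_length} residues\n")

for text in ["c.104G>A", "c.500A>T", "c.553G>T", "c.563A>T", "c.667C>T",
             "c.544_545insGGTGC"]:
    change = parse_cdna_hgvs(text)
    consequence = call_consequence(cds, change)
    print(f"{text:20s} -> {str(consequence):10s} ({consequence.kind.value})")

print("\nSubstitutions land in the codon given by ceil(position/3); the 5-nt "
      "insertion shifts the reading frame from the first displaced codon (182).")
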