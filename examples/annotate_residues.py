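"""Annotate pathogenic missense residues on the apoA-V domain map.

For each residue: the overlapping functional domains, what the
substitution does to residue chemistry, and how conserved the position
is across the six-species synthetic alignment (fraction of non-human
sequences matching the human residue; 1.0 = strictly conserved).
"""

from varprio import column_conservation, domains_at, generate_msa_fixture, property_change

alignment = generate_msa_fixture(seed=0)
changes = [(35, "S", "N"), (167, "D", "V"), (185, "G", "C"), (188, "K", "I"), (223, "R", "C")]

for position, ref, alt in changes:
    domains = ", ".join(d.name for d in domains_at(position))
    delta = property_change(ref, alt, position=position)
    fraction, strict = column_conservation(alignment, position)
    conservation = "strict" if strict else f"{fraction:.2f}"
    print(f"p.{ref}{position}{alt}")
    print(f"  domains:      {domains}")
    print(f"  chemistry:    {delta.describe()}")
    print(f"  conservation: {conservation}")

print("\nResidue 223 sits where helix, lipid-binding, heparin-binding and "
      "LPL-activation regions overlap; losing its positive charge is what "
      "makes p.R223C functionally suspicious.")
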