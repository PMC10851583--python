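"""Classify the packaged APOA5 variant table with the consensus rule.

Each variant is called pathogenic when SIFT plus at least one of the
other five predictors judge it damaging, or automatically for
frameshift/stopgain/stoploss changes.  The printed vote count is the
number of damaging programs out of six.
"""

from varprio import classify_records, table4_fixture

records = table4_fixture()
calls = classify_records(records)

print(f"{'variant':28s} {'protein':10s} verdict     votes  auto rule")
for rec in records:
    call = calls[rec.variant.variant_id]
    print(
        f"{rec.variant.variant_id:28s} {str(rec.variant.protein):10s} "
        f"{call.verdict:10s} {call.damaging_votes:>4d}   {call.auto_rule.value}"
    )

n_path = sum(call.is_pathogenic for call in calls.values())
print(f"\n{n_path} pathogenic / {len(calls) - n_path} benign — a pathogenic call "
      "needs SIFT plus a corroborating program, or a protein-truncating change.")
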