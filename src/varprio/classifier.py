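"""Consensus in-silico pathogenicity rule engine.

A coding variant is called *pathogenic* when at least two of the six
predictors (SIFT, PolyPhen2-HDIV, LRT, MutationTaster, MutationAssessor,
CADD) judge it damaging **and** SIFT is among them — i.e. SIFT damaging
plus any one corroborating program suffices.  Frameshift, stopgain and
stoploss variants are pathogenic automatically, without a predictor vote.
Everything else is *benign*.

Per-program damaging categories:

========================  ==========================  =================
program                   damaging                    benign / neutral
========================  ==========================  =================
SIFT                      D                           T
PolyPhen2-HDIV            D, P                        B
LRT                       D                           N, U
MutationTaster            D, A                        N, P
MutationAssessor          H, M                        L, N
CADD                      score > 15                  score <= 15
========================  ==========================  =================

A missing annotation never counts as damaging.  Allele frequencies and
conservation scores never enter the verdict; they are reported alongside
it for interpretation only.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .variants import (
    AutoRule,
    GeneticVariant,
    PathogenicityCall,
    PredictorProfile,
    ProteinKind,
    VariantRecord,
)

__all__ = [
    "Program",
    "CADD_DELETERIOUS_THRESHOLD",
    "predictor_damaging",
    "classify_pathogenicity",
    "classify_records",
    "calls_to_json",
    "calls_from_json",
]


class Program(str, Enum):
    SIFT = "sift"
    POLYPHEN_HDIV = "polyphen_hdiv"
    LRT = "lrt"
    MUTATION_TASTER = "mutation_taster"
    MUTATION_ASSESSOR = "mutation_assessor"
    CADD = "cadd"


# Scaled CADD above this is counted deleterious (strict inequality);
# CADD >= 20 additionally flags the top 1% most deleterious substitutions
# genome-wide, which is noted in the rationale but does not change voting.
CADD_DELETERIOUS_THRESHOLD = 15.0
_CADD_TOP_PERCENTILE = 20.0

_DAMAGING_CATEGORIES: dict[Program, frozenset[str]] = {
    Program.SIFT: frozenset("D"),
    Program.POLYPHEN_HDIV: frozenset("DP"),
    Program.LRT: frozenset("D"),
    Program.MUTATION_TASTER: frozenset("DA"),
    Program.MUTATION_ASSESSOR: frozenset("HM"),
}

_KNOWN_CATEGORIES: dict[Program, frozenset[str]] = {
    Program.SIFT: frozenset("DT"),
    Program.POLYPHEN_HDIV: frozenset("DPB"),
    Program.LRT: frozenset("DNU"),
    Program.MUTATION_TASTER: frozenset("DNPA"),
    Program.MUTATION_ASSESSOR: frozenset("HMLN"),
}


def predictor_damaging(program: Program, value: str | float | None) -> bool:
    """Whether one predictor's output counts as damaging/deleterious.

    ``None`` (missing) is never damaging.  For CADD the value is a scaled
    score and the cut-off is strictly greater than 15; for the other five
    programs it is a single-letter category.
    """
    if value is None:
        return False
    program = Program(program)
    if program is Program.CADD:
        score = float(value)
        if score < 0:
            raise ValueError(f"CADD score must be >= 0, got {score}")
        return score > CADD_DELETERIOUS_THRESHOLD
    if not isinstance(value, str) or value not in _KNOWN_CATEGORIES[program]:
        raise ValueError(
            f"unknown {program.value} category {value!r}; "
            f"expected one of {sorted(_KNOWN_CATEGORIES[program])}"
        )
    return value in _DAMAGING_CATEGORIES[program]


_AUTO_KINDS = {
    ProteinKind.FRAMESHIFT: AutoRule.FRAMESHIFT,
    ProteinKind.STOPGAIN: AutoRule.STOPGAIN,
    ProteinKind.STOPLOSS: AutoRule.STOPLOSS,
}


def classify_pathogenicity(
    variant: GeneticVariant, profile: PredictorProfile
) -> PathogenicityCall:
    """Apply the consensus rule to one variant.

    Requires a resolved protein consequence on ``variant``; frameshift,
    stopgain and stoploss short-circuit to pathogenic, otherwise the
    SIFT-anchored two-vote rule decides.
    """
    if variant.protein is None:
        raise ValueError(f"{variant.variant_id}: protein consequence unresolved")

    votes = {
        prog.value: predictor_damaging(prog, getattr(profile, prog.value))
        for prog in Program
    }
    n_votes = sum(votes.values())
    sift_damaging = votes[Program.SIFT.value]

    auto_rule = _AUTO_KINDS.get(variant.protein.kind, AutoRule.NONE)
    if auto_rule is not AutoRule.NONE:
        rationale = (
            f"{variant.protein} is a {variant.protein.kind.value} change; "
            "classified pathogenic automatically, independent of predictor votes"
        )
        return PathogenicityCall(
            verdict="pathogenic",
            damaging_votes=n_votes,
            sift_damaging=sift_damaging,
            auto_rule=auto_rule,
            rationale=rationale,
            per_program=votes,
        )

    pathogenic = sift_damaging and n_votes >= 2
    parts = [f"{n_votes}/6 programs damaging", f"SIFT {'damaging' if sift_damaging else 'tolerated/missing'}"]
    if profile.cadd is not None and profile.cadd >= _CADD_TOP_PERCENTILE:
        parts.append(f"CADD {profile.cadd:g} places it in the top 1% genome-wide")
    if pathogenic:
        parts.append("consensus rule met (SIFT plus >= 1 corroborating program)")
    else:
        parts.append("consensus rule not met")
    return PathogenicityCall(
        verdict="pathogenic" if pathogenic else "benign",
        damaging_votes=n_votes,
        sift_damaging=sift_damaging,
        auto_rule=AutoRule.NONE,
        rationale="; ".join(parts),
        per_program=votes,
    )


def classify_records(records: Iterable[VariantRecord]) -> dict[str, PathogenicityCall]:
    """Classify a variant table, keyed by canonical variant id.

    Duplicate variant ids are rejected: the rule has no defined semantics
    for conflicting duplicate annotation rows.
    """
    calls: dict[str, PathogenicityCall] = {}
    for rec in records:
        vid = rec.variant.variant_id
        if vid in calls:
            raise ValueError(f"duplicate annotation rows for variant {vid}")
        calls[vid] = classify_pathogenicity(rec.variant, rec.profile)
    return calls


def calls_to_json(calls: Mapping[str, PathogenicityCall], path: str | Path) -> None:
    """Serialize calls as a JSON report (one object per variant id)."""
    payload = {
        vid: {
            "verdict": call.verdict,
            "damaging_votes": call.damaging_votes,
            "sift_damaging": call.sift_damaging,
            "auto_rule": call.auto_rule.value,
            "per_program": dict(call.per_program),
            "rationale": call.rationale,
        }
        for vid, call in calls.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def calls_from_json(path: str | Path) -> dict[str, PathogenicityCall]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        vid: PathogenicityCall(
            verdict=obj["verdict"],
            damaging_votes=obj["damaging_votes"],
            sift_damaging=obj["sift_damaging"],
            auto_rule=AutoRule(obj["auto_rule"]),
            rationale=obj.get("rationale", ""),
            per_program=obj.get("per_program", {}),
        )
        for vid, obj in payload.items()
    }
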