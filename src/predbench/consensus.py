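"""Three-program consensus categorization and pairwise concordance.

A natural hope is that combining the top few prediction programs beats the
single best one.  The scheme evaluated here takes exactly three programs and
buckets each variant by the pattern of correct/incorrect usable calls:
all-correct, two-correct, two-incorrect, all-incorrect, with variants whose
calls cannot form a two-way agreement flagged inconsistent, and variants
missing output from two or more programs excluded.  "Trustworthy correct"
variants are the all-correct plus two-correct ones; their fraction is the
consensus analogue of a single program's weighted accuracy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

from .harmonization import CanonicalCall, HarmonizedCall
from .variant_model import CredibilityLabel

__all__ = [
    "ConsensusCategory",
    "ConsensusRecord",
    "ConsensusSummary",
    "categorize",
    "categorize_dataset",
    "summarize_consensus",
    "pairwise_concordance",
]

PANEL_SIZE = 3

#: The shipped default program triple (the top performers after removing
#: SIFT, which Condel already incorporates, and the low-coverage structure-
#: dependent program).
DEFAULT_TRIPLE = ("MutPred", "Condel", "FATHMM-Weighted")


class ConsensusCategory(str, enum.Enum):
    ALL_CORRECT = "all_correct"
    TWO_CORRECT = "two_correct"
    TWO_INCORRECT = "two_incorrect"
    ALL_INCORRECT = "all_incorrect"
    INCONSISTENT = "inconsistent"
    EXCLUDED_MISSING = "excluded_missing"


@dataclass(frozen=True)
class ConsensusRecord:
    variant_id: str
    label: CredibilityLabel
    category: ConsensusCategory
    n_correct: int
    n_incorrect: int
    n_missing: int
    n_possible: int  # neither-correct-nor-incorrect non-missing calls

    def __post_init__(self) -> None:
        total = self.n_correct + self.n_incorrect + self.n_missing + self.n_possible
        if total != PANEL_SIZE:
            raise ValueError(f"counts sum to {total}, expected {PANEL_SIZE}")


@dataclass(frozen=True)
class ConsensusSummary:
    """Category histogram plus the two headline percentages (fractions)."""

    histogram: Dict[ConsensusCategory, int]
    by_label: Dict[ConsensusCategory, Dict[str, int]]
    n_total: int
    n_evaluated: int  # total minus excluded_missing
    trustworthy_correct_pct: float
    strict_pct: float


def categorize(
    calls: Sequence[HarmonizedCall],
    label: CredibilityLabel,
) -> ConsensusRecord:
    """Bucket one variant from its three harmonized calls.

    A call is *correct* iff usable and matching the credibility label,
    *incorrect* iff usable and contradicting it.  PossiblyDamaging and
    unreliable calls count as neither.  Two or more Missing calls exclude
    the variant; otherwise three-way and two-way agreement in correctness
    define the categories, and everything else (no two usable calls agreeing
    in correctness) is inconsistent.
    """
    if len(calls) != PANEL_SIZE:
        raise ValueError(f"expected {PANEL_SIZE} calls, got {len(calls)}")
    if label not in (
        CredibilityLabel.CREDIBLY_PATHOGENIC,
        CredibilityLabel.CREDIBLY_BENIGN,
    ):
        raise ValueError(f"variant label must be credible, got {label.value}")
    variant_ids = {c.variant_id for c in calls}
    if len(variant_ids) != 1:
        raise ValueError(f"calls span multiple variants: {sorted(variant_ids)}")

    correct_call = (
        CanonicalCall.DAMAGING
        if label is CredibilityLabel.CREDIBLY_PATHOGENIC
        else CanonicalCall.BENIGN
    )
    n_correct = n_incorrect = n_missing = n_possible = 0
    for c in calls:
        if c.call is CanonicalCall.MISSING:
            n_missing += 1
        elif c.usable:
            if c.call is correct_call:
                n_correct += 1
            else:
                n_incorrect += 1
        else:
            n_possible += 1

    if n_missing >= 2:
        category = ConsensusCategory.EXCLUDED_MISSING
    elif n_correct == 3:
        category = ConsensusCategory.ALL_CORRECT
    elif n_incorrect == 3:
        category = ConsensusCategory.ALL_INCORRECT
    elif n_correct == 2:
        category = ConsensusCategory.TWO_CORRECT
    elif n_incorrect == 2:
        category = ConsensusCategory.TWO_INCORRECT
    else:
        category = ConsensusCategory.INCONSISTENT

    return ConsensusRecord(
        variant_id=calls[0].variant_id,
        label=label,
        category=category,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_missing=n_missing,
        n_possible=n_possible,
    )


def categorize_dataset(
    calls: Sequence[HarmonizedCall],
    labels: Mapping[str, CredibilityLabel],
    programs: Sequence[str] = DEFAULT_TRIPLE,
) -> list[ConsensusRecord]:
    """Categorize every labeled variant that all three programs were given.

    A program with no record at all for a variant contributes a Missing call.
    """
    if len(set(programs)) != PANEL_SIZE:
        raise ValueError(f"need exactly {PANEL_SIZE} distinct programs")
    by_variant: Dict[str, Dict[str, HarmonizedCall]] = {}
    for c in calls:
        if c.program not in programs:
            continue
        prev = by_variant.setdefault(c.variant_id, {})
        if c.program in prev:
            raise ValueError(f"duplicate call: ({c.variant_id}, {c.program})")
        prev[c.program] = c

    records = []
    for variant_id in sorted(by_variant):
        label = labels.get(variant_id)
        if label is None:
            raise ValueError(f"variant {variant_id!r} has no credibility label")
        triple = [
            by_variant[variant_id].get(
                p,
                HarmonizedCall(variant_id, p, CanonicalCall.MISSING, reliable=False),
            )
            for p in programs
        ]
        records.append(categorize(triple, label))
    return records


def summarize_consensus(records: Sequence[ConsensusRecord]) -> ConsensusSummary:
    """Histogram plus trustworthy-correct percentages.

    ``trustworthy_correct_pct`` = (all_correct + two_correct) over variants
    retained after the missing-data exclusion; ``strict_pct`` additionally
    drops inconsistent variants from the denominator.  Both are fractions.
    """
    histogram = {cat: 0 for cat in ConsensusCategory}
    by_label: Dict[ConsensusCategory, Dict[str, int]] = {
        cat: {} for cat in ConsensusCategory
    }
    for r in records:
        histogram[r.category] += 1
        lbl = r.label.value
        by_label[r.category][lbl] = by_label[r.category].get(lbl, 0) + 1

    n_total = len(records)
    n_evaluated = n_total - histogram[ConsensusCategory.EXCLUDED_MISSING]
    if n_evaluated == 0:
        raise ValueError("no variants remain after excluding missing-data variants")
    n_trustworthy = (
        histogram[ConsensusCategory.ALL_CORRECT]
        + histogram[ConsensusCategory.TWO_CORRECT]
    )
    n_strict_den = n_evaluated - histogram[ConsensusCategory.INCONSISTENT]
    return ConsensusSummary(
        histogram=histogram,
        by_label=by_label,
        n_total=n_total,
        n_evaluated=n_evaluated,
        trustworthy_correct_pct=n_trustworthy / n_evaluated,
        strict_pct=n_trustworthy / n_strict_den if n_strict_den else float("nan"),
    )


def pairwise_concordance(
    calls_a: Sequence[HarmonizedCall],
    calls_b: Sequence[HarmonizedCall],
) -> float:
    """Fraction of variants on which two programs agree with usable calls.

    Concordance requires both calls usable and identical; the denominator is
    the full shared variant set, so missing/possible/unreliable pairs drag
    the fraction down.
    """
    a = {c.variant_id: c for c in calls_a}
    b = {c.variant_id: c for c in calls_b}
    if len(a) != len(calls_a) or len(b) != len(calls_b):
        raise ValueError("duplicate variant in a call vector")
    if set(a) != set(b):
        raise ValueError("programs were scored on different variant sets")
    if not a:
        raise ValueError("empty variant set")
    n_agree = sum(
        1
        for vid, ca in a.items()
        if ca.usable and b[vid].usable and ca.call is b[vid].call
    )
    return n_agree / len(a)
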