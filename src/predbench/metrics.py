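"""Confusion-matrix tabulation and coverage-weighted performance statistics.

Because prediction programs differ enormously in how many variants they can
score at all (VarCall) and how many of those scores are clearly dichotomous
and reliable (VarUse), raw accuracy is a misleading ranking criterion.  The
performance weight PWeight = VarUse/VarCall penalizes programs whose outputs
are frequently "possible" or low-reliability, and the headline statistic is

    WAccuracy = Accuracy x PWeight = (TP + TN) / VarCall,

computed on unrounded intermediates.  Metrics with a zero denominator are
undefined (``None``) and propagate, never silently 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .harmonization import CanonicalCall, HarmonizedCall
from .variant_model import CredibilityLabel

__all__ = [
    "ConfusionSummary",
    "MetricSet",
    "PerClassCorrect",
    "tabulate",
    "compute_metrics",
    "per_class_correct",
    "round_report",
    "pool",
    "metrics_table",
]

METRIC_COLUMNS = [
    "PPV",
    "NPV",
    "Specificity",
    "Sensitivity",
    "Accuracy",
    "PWeight",
    "WAccuracy",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts for one program on one dataset.

    TP/FP/TN/FN are over usable calls only; VarCall counts variants with any
    non-Missing output (usable or not); N_dataset is the number of variants
    presented to the program.
    """

    program: str
    dataset: str
    TP: int
    FP: int
    TN: int
    FN: int
    VarUse: int
    VarCall: int
    N_dataset: int

    def __post_init__(self) -> None:
        counts = (self.TP, self.FP, self.TN, self.FN, self.VarUse, self.VarCall)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in {self}")
        if self.TP + self.FP + self.TN + self.FN != self.VarUse:
            raise ValueError(
                f"TP+FP+TN+FN = {self.TP + self.FP + self.TN + self.FN} "
                f"!= VarUse = {self.VarUse}"
            )
        if not (self.VarUse <= self.VarCall <= self.N_dataset):
            raise ValueError(
                f"need VarUse <= VarCall <= N_dataset, got "
                f"{self.VarUse}, {self.VarCall}, {self.N_dataset}"
            )


@dataclass(frozen=True)
class MetricSet:
    """The seven performance statistics; ``None`` marks an undefined value."""

    PPV: Optional[float]
    NPV: Optional[float]
    specificity: Optional[float]
    sensitivity: Optional[float]
    accuracy: Optional[float]
    pweight: Optional[float]
    waccuracy: Optional[float]


@dataclass(frozen=True)
class PerClassCorrect:
    """Per-class correctness as displayed in coverage-aware bar charts.

    Denominators count variants of the class with any non-Missing output
    (including unreliable and "possible" calls); numerators count correct
    usable calls.  This deliberately differs from the VarUse denominator.
    """

    pct_pathogenic_correct: Optional[float]
    pct_benign_correct: Optional[float]
    n_pathogenic_with_output: int
    n_benign_with_output: int


def _check_calls(
    calls: Sequence[HarmonizedCall],
    labels: Mapping[str, CredibilityLabel],
) -> None:
    seen = set()
    for c in calls:
        key = (c.variant_id, c.program)
        if key in seen:
            raise ValueError(f"duplicate (variant, program) row: {key}")
        seen.add(key)
        label = labels.get(c.variant_id)
        if label is None:
            raise ValueError(f"variant {c.variant_id!r} has no credibility label")
        if label not in (
            CredibilityLabel.CREDIBLY_PATHOGENIC,
            CredibilityLabel.CREDIBLY_BENIGN,
        ):
            raise ValueError(
                f"variant {c.variant_id!r} is {label.value}; only credibly "
                "pathogenic/benign variants may enter tabulation"
            )


def tabulate(
    calls: Sequence[HarmonizedCall],
    labels: Mapping[str, CredibilityLabel],
    program: str,
    dataset: str = "",
) -> ConfusionSummary:
    """Count TP/FP/TN/FN, VarUse and VarCall for one program.

    Every call's variant must carry a credibly-pathogenic or credibly-benign
    label; duplicate (variant, program) rows are an error.
    """
    calls = [c for c in calls if c.program == program]
    _check_calls(calls, labels)

    tp = fp = tn = fn = varcall = 0
    for c in calls:
        if c.call is not CanonicalCall.MISSING:
            varcall += 1
        if not c.usable:
            continue
        pathogenic = labels[c.variant_id] is CredibilityLabel.CREDIBLY_PATHOGENIC
        if c.call is CanonicalCall.DAMAGING:
            if pathogenic:
                tp += 1
            else:
                fp += 1
        else:  # usable implies Damaging or Benign
            if pathogenic:
                fn += 1
            else:
                tn += 1

    return ConfusionSummary(
        program=program,
        dataset=dataset,
        TP=tp,
        FP=fp,
        TN=tn,
        FN=fn,
        VarUse=tp + fp + tn + fn,
        VarCall=varcall,
        N_dataset=len(calls),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def compute_metrics(cs: ConfusionSummary) -> MetricSet:
    """Derive the seven statistics from a confusion summary.

    WAccuracy is the product of *unrounded* accuracy and performance weight
    (equivalently (TP+TN)/VarCall); rounding happens only at report time.
    """
    accuracy = _ratio(cs.TP + cs.TN, cs.VarUse)
    pweight = _ratio(cs.VarUse, cs.VarCall)
    waccuracy = (
        accuracy * pweight if accuracy is not None and pweight is not None else None
    )
    return MetricSet(
        PPV=_ratio(cs.TP, cs.TP + cs.FP),
        NPV=_ratio(cs.TN, cs.TN + cs.FN),
        specificity=_ratio(cs.TN, cs.TN + cs.FP),
        sensitivity=_ratio(cs.TP, cs.TP + cs.FN),
        accuracy=accuracy,
        pweight=pweight,
        waccuracy=waccuracy,
    )


def per_class_correct(
    calls: Sequence[HarmonizedCall],
    labels: Mapping[str, CredibilityLabel],
    program: str,
) -> PerClassCorrect:
    """Fraction of each credibility class predicted correctly.

    The denominator is the number of variants of that class with any
    non-Missing output from the program, not the usable-call count.
    """
    calls = [c for c in calls if c.program == program]
    _check_calls(calls, labels)

    n_out = {True: 0, False: 0}  # keyed by "is pathogenic"
    n_correct = {True: 0, False: 0}
    for c in calls:
        if c.call is CanonicalCall.MISSING:
            continue
        pathogenic = labels[c.variant_id] is CredibilityLabel.CREDIBLY_PATHOGENIC
        n_out[pathogenic] += 1
        if c.usable:
            correct_call = (
                CanonicalCall.DAMAGING if pathogenic else CanonicalCall.BENIGN
            )
            if c.call is correct_call:
                n_correct[pathogenic] += 1

    return PerClassCorrect(
        pct_pathogenic_correct=_ratio(n_correct[True], n_out[True]),
        pct_benign_correct=_ratio(n_correct[False], n_out[False]),
        n_pathogenic_with_output=n_out[True],
        n_benign_with_output=n_out[False],
    )


def round_report(x: float, places: int) -> float:
    """Round-half-up decimal rounding for report output (0.8235 -> 0.824).

    Applied only when formatting tables, never inside computations.
    """
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pool(summaries: Iterable[ConfusionSummary], dataset: str = "combined") -> Dict[str, ConfusionSummary]:
    """Pool confusion counts across datasets, per program.

    Combined-dataset metrics are computed from summed counts, not by
    averaging per-dataset metrics.
    """
    acc: Dict[str, List[ConfusionSummary]] = {}
    for s in summaries:
        acc.setdefault(s.program, []).append(s)
    out: Dict[str, ConfusionSummary] = {}
    for program, rows in acc.items():
        out[program] = ConfusionSummary(
            program=program,
            dataset=dataset,
            TP=sum(r.TP for r in rows),
            FP=sum(r.FP for r in rows),
            TN=sum(r.TN for r in rows),
            FN=sum(r.FN for r in rows),
            VarUse=sum(r.VarUse for r in rows),
            VarCall=sum(r.VarCall for r in rows),
            N_dataset=sum(r.N_dataset for r in rows),
        )
    return out


def metrics_table(
    summaries: Sequence[ConfusionSummary], places: int = 3
) -> pd.DataFrame:
    """Report table: one row per program, rounded and unrounded metrics.

    Rounded columns mirror the standard presentation order (Program, PPV,
    NPV, Specificity, Sensitivity, Accuracy, PWeight, WAccuracy) followed by
    VarUse/VarCall counts and unrounded values; undefined renders as NA.
    """
    rows = []
    for cs in summaries:
        m = compute_metrics(cs)
        vals = [
            m.PPV,
            m.NPV,
            m.specificity,
            m.sensitivity,
            m.accuracy,
            m.pweight,
            m.waccuracy,
        ]
        row: Dict[str, object] = {"Program": cs.program, "Dataset": cs.dataset}
        for name, v in zip(METRIC_COLUMNS, vals):
            row[name] = round_report(v, places) if v is not None else None
        row["VarUse"] = cs.VarUse
        row["VarCall"] = cs.VarCall
        row["TP"], row["FP"], row["TN"], row["FN"] = cs.TP, cs.FP, cs.TN, cs.FN
        for name, v in zip(METRIC_COLUMNS, vals):
            row[f"{name}_unrounded"] = v
        rows.append(row)
    return pd.DataFrame(rows)
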