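"""Harmonization of heterogeneous predictor outputs.

Pathogenicity prediction programs emit either word labels ("Deleterious",
"Tolerated", "Disease-Causing", ...) or numeric scores, some with a 0-9
reliability index.  Benchmarking requires mapping every output onto one
canonical trichotomy — Damaging / PossiblyDamaging / Benign — plus Missing
for variants a program could not score, and then deciding *usability*: only
clearly dichotomous calls (Damaging or Benign) at or above the reliability
threshold enter the statistics.  "Possible" calls and low-reliability calls
are recorded (they count toward a program's output coverage) but are never
scored as correct or incorrect.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

__all__ = [
    "CanonicalCall",
    "PredictionRecord",
    "HarmonizedCall",
    "Band",
    "ProgramConfig",
    "UnknownLabelError",
    "DEFAULT_WORD_MAP",
    "DEFAULT_RELIABILITY_THRESHOLD",
    "harmonize_word",
    "harmonize_numeric",
    "apply_reliability",
    "harmonize_record",
    "audit_counts",
]

DEFAULT_RELIABILITY_THRESHOLD = 5


class CanonicalCall(str, enum.Enum):
    DAMAGING = "Damaging"
    POSSIBLY_DAMAGING = "PossiblyDamaging"
    BENIGN = "Benign"
    MISSING = "Missing"


#: Shipped vocabulary covering the word-based programs' documented outputs.
DEFAULT_WORD_MAP: Dict[str, CanonicalCall] = {
    "probably damaging": CanonicalCall.DAMAGING,
    "damaging": CanonicalCall.DAMAGING,
    "pathological": CanonicalCall.DAMAGING,
    "deleterious": CanonicalCall.DAMAGING,
    "disease-causing": CanonicalCall.DAMAGING,
    "disease": CanonicalCall.DAMAGING,
    "non-neutral": CanonicalCall.DAMAGING,
    "possibly damaging": CanonicalCall.POSSIBLY_DAMAGING,
    "possibly deleterious": CanonicalCall.POSSIBLY_DAMAGING,
    "benign": CanonicalCall.BENIGN,
    "tolerated": CanonicalCall.BENIGN,
    "non-deleterious": CanonicalCall.BENIGN,
    "polymorphism": CanonicalCall.BENIGN,
    "neutral": CanonicalCall.BENIGN,
}

_MISSING_TOKENS = {"", "n/a", "na"}


class UnknownLabelError(ValueError):
    """Raised when a word label is outside a program's vocabulary.

    Unknown labels are hard errors rather than Missing: silently coercing
    them would corrupt the output-coverage denominator (VarCall).
    """

    def __init__(self, program: str, label: str):
        self.program = program
        self.label = label
        super().__init__(
            f"program {program!r}: unrecognized output label {label!r}"
        )


@dataclass(frozen=True)
class PredictionRecord:
    """One program's raw output for one variant."""

    variant_id: str
    program: str
    raw_label: Optional[str] = None
    raw_score: Optional[float] = None
    reliability: Optional[int] = None

    def __post_init__(self) -> None:
        if self.reliability is not None and not (0 <= self.reliability <= 9):
            raise ValueError(
                f"reliability must be in [0, 9], got {self.reliability} "
                f"({self.program} / {self.variant_id})"
            )

    @property
    def is_missing(self) -> bool:
        return self.raw_label is None and self.raw_score is None


@dataclass(frozen=True)
class HarmonizedCall:
    """Canonical call plus reliability and usability flags.

    Invariant: ``usable == (call in {Damaging, Benign}) and reliable``.
    """

    variant_id: str
    program: str
    call: CanonicalCall
    reliable: bool

    @property
    def usable(self) -> bool:
        return (
            self.call in (CanonicalCall.DAMAGING, CanonicalCall.BENIGN)
            and self.reliable
        )


@dataclass(frozen=True)
class Band:
    """A score interval with individually open/closed ends (default closed)."""

    low: float
    high: float
    closed_low: bool = True
    closed_high: bool = True

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"band low {self.low} > high {self.high}")

    def contains(self, x: float) -> bool:
        above = x >= self.low if self.closed_low else x > self.low
        below = x <= self.high if self.closed_high else x < self.high
        return above and below

    def overlaps(self, other: "Band") -> bool:
        # Closed-interval overlap test, then discount shared endpoints that
        # are open on at least one side.
        lo, hi = max(self.low, other.low), min(self.high, other.high)
        if lo > hi:
            return False
        if lo < hi:
            return True
        # single shared point
        return self.contains(lo) and other.contains(lo)


@dataclass
class ProgramConfig:
    """Per-program harmonization settings.

    Word-mode programs need a ``word_map`` (case-insensitive after whitespace
    normalization); numeric-mode programs need disjoint damaging/benign score
    bands — scores in neither band become PossiblyDamaging.  Programs with a
    reliability index keep only calls at or above ``reliability_threshold``.
    """

    program: str
    mode: str = "word"  # "word" | "numeric"
    word_map: Mapping[str, CanonicalCall] = field(
        default_factory=lambda: dict(DEFAULT_WORD_MAP)
    )
    damaging_band: Optional[Band] = None
    benign_band: Optional[Band] = None
    has_reliability: bool = False
    reliability_threshold: int = DEFAULT_RELIABILITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("word", "numeric"):
            raise ValueError(f"mode must be 'word' or 'numeric', got {self.mode!r}")
        if self.mode == "numeric":
            if self.damaging_band is None or self.benign_band is None:
                raise ValueError(
                    f"program {self.program!r}: numeric mode requires both bands"
                )
            if self.damaging_band.overlaps(self.benign_band):
                raise ValueError(
                    f"program {self.program!r}: damaging and benign bands overlap"
                )
        if not (0 <= self.reliability_threshold <= 9):
            raise ValueError("reliability_threshold must be in [0, 9]")
        # normalize word_map keys once
        self.word_map = {
            _normalize_label(k): CanonicalCall(v) for k, v in self.word_map.items()
        }


def _normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).lower()


def harmonize_word(raw_label: Optional[str], config: ProgramConfig) -> CanonicalCall:
    """Map a word label onto the canonical call set.

    Empty strings and "N/A" mean the program produced no output (Missing).
    A non-empty label outside the vocabulary raises :class:`UnknownLabelError`.
    """
    if raw_label is None:
        return CanonicalCall.MISSING
    key = _normalize_label(raw_label)
    if key in _MISSING_TOKENS:
        return CanonicalCall.MISSING
    try:
        return config.word_map[key]
    except KeyError:
        raise UnknownLabelError(config.program, raw_label) from None


def harmonize_numeric(
    raw_score: Optional[float], config: ProgramConfig
) -> CanonicalCall:
    """Map a numeric score onto the canonical call set via the config bands."""
    if raw_score is None or (isinstance(raw_score, float) and math.isnan(raw_score)):
        return CanonicalCall.MISSING
    assert config.damaging_band is not None and config.benign_band is not None
    if config.damaging_band.contains(raw_score):
        return CanonicalCall.DAMAGING
    if config.benign_band.contains(raw_score):
        return CanonicalCall.BENIGN
    return CanonicalCall.POSSIBLY_DAMAGING


def apply_reliability(
    call: CanonicalCall,
    reliability: Optional[int],
    config: ProgramConfig,
    variant_id: str = "",
) -> HarmonizedCall:
    """Attach the reliability decision to a canonical call.

    A call is reliable when the program has no reliability index, or when
    the index is at or above the threshold (inclusive).  A missing index on
    a reliability-scored program counts as unreliable.
    """
    if reliability is not None and not (0 <= reliability <= 9):
        raise ValueError(f"reliability must be in [0, 9], got {reliability}")
    if not config.has_reliability:
        reliable = True
    else:
        reliable = reliability is not None and reliability >= config.reliability_threshold
    return HarmonizedCall(
        variant_id=variant_id,
        program=config.program,
        call=call,
        reliable=reliable,
    )


def harmonize_record(
    record: PredictionRecord, config: ProgramConfig
) -> HarmonizedCall:
    """Full harmonization of one raw prediction record."""
    if record.program != config.program:
        raise ValueError(
            f"record program {record.program!r} does not match config "
            f"{config.program!r}"
        )
    if record.is_missing:
        call = CanonicalCall.MISSING
    elif config.mode == "word":
        call = harmonize_word(record.raw_label, config)
    else:
        call = harmonize_numeric(record.raw_score, config)
    return apply_reliability(call, record.reliability, config, record.variant_id)


def audit_counts(calls: Iterable[HarmonizedCall]) -> Dict[str, Dict[str, int]]:
    """Per-program totality audit.

    Returns, per program, counts of Damaging / PossiblyDamaging / Benign /
    Missing / unreliable that sum to the number of records (unreliable counts
    the non-Missing calls failing the reliability threshold; the per-call
    categories count the reliable remainder).
    """
    out: Dict[str, Dict[str, int]] = {}
    for c in calls:
        d = out.setdefault(
            c.program,
            {
                "Damaging": 0,
                "PossiblyDamaging": 0,
                "Benign": 0,
                "Missing": 0,
                "unreliable": 0,
                "total": 0,
            },
        )
        d["total"] += 1
        if c.call is CanonicalCall.MISSING:
            d["Missing"] += 1
        elif not c.reliable:
            d["unreliable"] += 1
        else:
            d[c.call.value] += 1
    return out
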