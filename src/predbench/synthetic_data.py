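"""Synthetic prediction data with the statistical structure the benchmark assumes.

Two generators live here:

* :func:`generate_dataset` draws stochastic prediction matrices for a
  two-panel variant study — each program profile has its own call rate
  (chance of producing any output), "possible"-call rate, reliability-score
  distribution, and class-conditional correctness probabilities (sensitivity
  on pathogenic variants, specificity on benign ones).  Missingness for
  structure-dependent programs is forced at gene granularity, emulating
  predictors that require a solved protein structure.

* :func:`build_fixture` deterministically materializes a prediction block
  with exact TP/FP/TN/FN/possible/missing composition, so any printed
  confusion matrix can be replayed through the harmonization and metrics
  stages bit-exactly.

The default panel sizes are the study conditions: 35 pathogenic + 19 benign
RASopathy variants and 36 pathogenic + 32 benign LGMD variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .consensus import DEFAULT_TRIPLE, ConsensusCategory
from .harmonization import CanonicalCall, HarmonizedCall
from .variant_model import CredibilityLabel, Panel

__all__ = [
    "ProgramProfile",
    "PanelSpec",
    "FixtureBlock",
    "default_panels",
    "generate_dataset",
    "build_fixture",
    "build_consensus_fixture",
]

_AA3 = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]


@dataclass(frozen=True)
class ProgramProfile:
    """Stochastic behavior of one simulated prediction program.

    ``call_rate`` is the probability a variant receives any output;
    ``possible_rate`` the probability an emitted call is PossiblyDamaging;
    ``sensitivity``/``specificity`` the probabilities a dichotomous call is
    correct given the variant class.  ``reliability_dist`` is a length-10
    probability vector over the 0-9 index (uniform when ``has_reliability``
    and no distribution is given).  ``structure_dependent`` programs emit
    Missing for every variant in a gene without a solved structure.
    """

    program: str
    call_rate: float = 1.0
    possible_rate: float = 0.0
    sensitivity: float = 0.9
    specificity: float = 0.9
    has_reliability: bool = False
    reliability_dist: Optional[Sequence[float]] = None
    structure_dependent: bool = False

    def __post_init__(self) -> None:
        for name in ("call_rate", "possible_rate", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reliability_dist is not None:
            d = np.asarray(self.reliability_dist, dtype=float)
            if d.shape != (10,) or (d < 0).any() or not np.isclose(d.sum(), 1.0):
                raise ValueError("reliability_dist must be 10 probabilities summing to 1")


@dataclass(frozen=True)
class PanelSpec:
    """One disease panel: class sizes and genes with structure availability."""

    name: str
    n_pathogenic: int
    n_benign: int
    genes: Tuple[Tuple[str, bool], ...] = (("GENE1", True),)

    def __post_init__(self) -> None:
        if self.n_pathogenic < 0 or self.n_benign < 0:
            raise ValueError("panel counts must be >= 0")
        if not self.genes:
            raise ValueError("panel needs at least one gene")


def default_panels() -> List[PanelSpec]:
    """The two-panel study design: RAS/MAPK-pathway genes (structures absent
    for RAF1, MAP2K2, SHOC2) and muscle-complex genes (structure available
    only for CAPN3)."""
    ras = PanelSpec(
        name="RAS",
        n_pathogenic=35,
        n_benign=19,
        genes=(
            ("PTPN11", True), ("SOS1", True), ("KRAS", True), ("BRAF", True),
            ("MAP2K1", True), ("HRAS", True), ("NRAS", True),
            ("RAF1", False), ("MAP2K2", False), ("SHOC2", False),
        ),
    )
    lgmd = PanelSpec(
        name="LGMD",
        n_pathogenic=36,
        n_benign=32,
        genes=(
            ("CAPN3", True),
            ("SGCA", False), ("SGCB", False), ("SGCG", False), ("SGCD", False),
            ("DYSF", False), ("ANO5", False), ("FKRP", False),
        ),
    )
    return [ras, lgmd]


def _evidence_for(label: CredibilityLabel, panel: Panel) -> Dict[str, object]:
    """Evidence fields consistent with the intended credibility label."""
    if label is CredibilityLabel.CREDIBLY_PATHOGENIC:
        return dict(
            published_disease_associated=True,
            in_curated_disease_db=True,
            clinical_case_or_validation=True,
            sequenced_in_lab=True,
            different_aa_at_known_codon=False,
            n_large_population_sources=0,
            max_population_maf=None,
            dbsnp_validated=False,
            published_benign=False,
        )
    maf = 0.005 if panel is Panel.RAS else 0.05
    return dict(
        published_disease_associated=False,
        in_curated_disease_db=False,
        clinical_case_or_validation=False,
        sequenced_in_lab=False,
        different_aa_at_known_codon=False,
        n_large_population_sources=2,
        max_population_maf=maf,
        dbsnp_validated=True,
        published_benign=False,
    )


def _make_variants(panels: Sequence[PanelSpec], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for spec in panels:
        panel = Panel(spec.name)
        classes = [CredibilityLabel.CREDIBLY_PATHOGENIC] * spec.n_pathogenic + [
            CredibilityLabel.CREDIBLY_BENIGN
        ] * spec.n_benign
        for i, label in enumerate(classes):
            gene = spec.genes[i % len(spec.genes)][0]
            ref, alt = rng.choice(len(_AA3), size=2, replace=False)
            pos = int(rng.integers(2, 900))
            rows.append(
                {
                    "variant_id": f"{spec.name}_{i:03d}",
                    "gene": gene,
                    "panel": spec.name,
                    "protein_change": f"p.{_AA3[ref]}{pos}{_AA3[alt]}",
                    "coding_change": f"c.{3 * pos - 1}N>N",
                    "consequence": "missense",
                    **_evidence_for(label, panel),
                    "credibility_label": label.value,
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(
    panels: Optional[Sequence[PanelSpec]] = None,
    profiles: Sequence[ProgramProfile] = (),
    seed: int = 0,
    correlation: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a variant table and a long-form predictions table.

    ``correlation`` is an optional shared-uniform copula: with that
    probability a variant's correctness draw is shared across all programs,
    inducing inter-program agreement beyond chance (default 0, independent).
    Fully reproducible given ``seed``.
    """
    if not profiles:
        raise ValueError("at least one program profile is required")
    if not (0.0 <= correlation <= 1.0):
        raise ValueError(f"correlation must be in [0, 1], got {correlation}")
    if panels is None:
        panels = default_panels()
    structure_by_gene = {g: ok for spec in panels for g, ok in spec.genes}

    rng = np.random.default_rng(seed)
    variants = _make_variants(panels, rng)

    rows = []
    for _, v in variants.iterrows():
        pathogenic = v["credibility_label"] == CredibilityLabel.CREDIBLY_PATHOGENIC.value
        shared_u = rng.uniform()
        use_shared = rng.uniform(size=len(profiles)) < correlation
        for j, prof in enumerate(profiles):
            rel = (
                int(rng.choice(10, p=prof.reliability_dist))
                if prof.has_reliability and prof.reliability_dist is not None
                else int(rng.integers(0, 10))
                if prof.has_reliability
                else None
            )
            forced_missing = prof.structure_dependent and not structure_by_gene.get(
                v["gene"], True
            )
            if forced_missing or rng.uniform() >= prof.call_rate:
                label = None
            elif rng.uniform() < prof.possible_rate:
                label = "Possibly Damaging"
            else:
                p_correct = prof.sensitivity if pathogenic else prof.specificity
                u = shared_u if use_shared[j] else rng.uniform()
                correct = u < p_correct
                if correct == pathogenic:
                    label = "Damaging"
                else:
                    label = "Benign"
            rows.append(
                {
                    "variant_id": v["variant_id"],
                    "program": prof.program,
                    "raw_label": label,
                    "raw_score": None,
                    "reliability": rel if label is not None else None,
                }
            )
    predictions = pd.DataFrame(rows)
    return variants, predictions


@dataclass(frozen=True)
class FixtureBlock:
    """A deterministic prediction block plus the matching variant labels."""

    variants: pd.DataFrame
    predictions: pd.DataFrame

    @property
    def labels(self) -> Dict[str, CredibilityLabel]:
        return {
            r["variant_id"]: CredibilityLabel(r["credibility_label"])
            for _, r in self.variants.iterrows()
        }

    def harmonized(self) -> List[HarmonizedCall]:
        """Harmonize the block's word-mode records with default settings."""
        from .harmonization import ProgramConfig, PredictionRecord, harmonize_record

        configs: Dict[str, ProgramConfig] = {}
        out = []
        for _, r in self.predictions.iterrows():
            cfg = configs.setdefault(r["program"], ProgramConfig(program=r["program"]))
            rec = PredictionRecord(
                variant_id=r["variant_id"],
                program=r["program"],
                raw_label=r["raw_label"] if pd.notna(r["raw_label"]) else None,
                raw_score=None,
                reliability=None,
            )
            out.append(harmonize_record(rec, cfg))
        return out


def build_fixture(
    tp: int,
    fp: int,
    tn: int,
    fn: int,
    n_possible: int = 0,
    n_missing: int = 0,
    program: str = "prog",
    panel: str = "RAS",
) -> FixtureBlock:
    """Materialize a block realizing an exact confusion-matrix composition.

    Emits word-mode records: ``tp``+``fn`` pathogenic variants called
    Damaging/Benign respectively, ``fp``+``tn`` benign variants called
    Damaging/Benign, ``n_possible`` PossiblyDamaging records and
    ``n_missing`` records with no output (possible and missing records
    alternate between the two classes).  Running tabulation and the metrics
    stage on the harmonized block recovers the requested counts exactly.
    """
    for name, v in [("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn),
                    ("n_possible", n_possible), ("n_missing", n_missing)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    panel_enum = Panel(panel)
    path = CredibilityLabel.CREDIBLY_PATHOGENIC
    ben = CredibilityLabel.CREDIBLY_BENIGN
    plan: List[Tuple[CredibilityLabel, Optional[str]]] = (
        [(path, "Damaging")] * tp
        + [(path, "Benign")] * fn
        + [(ben, "Damaging")] * fp
        + [(ben, "Benign")] * tn
        + [(path if i % 2 == 0 else ben, "Possibly Damaging") for i in range(n_possible)]
        + [(path if i % 2 == 0 else ben, None) for i in range(n_missing)]
    )

    vrows, prows = [], []
    for i, (label, raw) in enumerate(plan):
        vid = f"{panel}_{program}_{i:03d}"
        vrows.append(
            {
                "variant_id": vid,
                "gene": "GENE1",
                "panel": panel,
                "protein_change": f"p.Ala{i + 2}Val",
                "coding_change": None,
                "consequence": "missense",
                **_evidence_for(label, panel_enum),
                "credibility_label": label.value,
            }
        )
        prows.append(
            {
                "variant_id": vid,
                "program": program,
                "raw_label": raw,
                "raw_score": None,
                "reliability": None,
            }
        )
    return FixtureBlock(variants=pd.DataFrame(vrows), predictions=pd.DataFrame(prows))


# Call patterns realizing each consensus category; "C" correct, "I" incorrect,
# "P" possible, "M" missing.
_CATEGORY_PATTERNS: Dict[ConsensusCategory, Tuple[str, str, str]] = {
    ConsensusCategory.ALL_CORRECT: ("C", "C", "C"),
    ConsensusCategory.TWO_CORRECT: ("C", "C", "I"),
    ConsensusCategory.TWO_INCORRECT: ("I", "I", "C"),
    ConsensusCategory.ALL_INCORRECT: ("I", "I", "I"),
    ConsensusCategory.INCONSISTENT: ("C", "I", "P"),
    ConsensusCategory.EXCLUDED_MISSING: ("C", "M", "M"),
}


def build_consensus_fixture(
    category_counts: Mapping[ConsensusCategory, Mapping[str, int]],
    programs: Sequence[str] = DEFAULT_TRIPLE,
    panel: str = "RAS",
) -> Tuple[List[HarmonizedCall], Dict[str, CredibilityLabel]]:
    """Build harmonized call triples realizing exact consensus category counts.

    ``category_counts`` maps each category to per-class counts, e.g.
    ``{ALL_CORRECT: {"credibly_pathogenic": 18, "credibly_benign": 11}}``.
    Returns the flat call list and the variant-label map, ready for
    :func:`predbench.consensus.categorize_dataset`.
    """
    if len(set(programs)) != 3:
        raise ValueError("need exactly 3 distinct programs")
    calls: List[HarmonizedCall] = []
    labels: Dict[str, CredibilityLabel] = {}
    i = 0
    for category in ConsensusCategory:
        per_label = category_counts.get(category, {})
        pattern = _CATEGORY_PATTERNS[category]
        for label_value, n in sorted(per_label.items()):
            label = CredibilityLabel(label_value)
            correct = (
                CanonicalCall.DAMAGING
                if label is CredibilityLabel.CREDIBLY_PATHOGENIC
                else CanonicalCall.BENIGN
            )
            incorrect = (
                CanonicalCall.BENIGN
                if correct is CanonicalCall.DAMAGING
                else CanonicalCall.DAMAGING
            )
            for _ in range(n):
                vid = f"{panel}_cons_{i:03d}"
                i += 1
                labels[vid] = label
                for prog, code in zip(programs, pattern):
                    call = {
                        "C": correct,
                        "I": incorrect,
                        "P": CanonicalCall.POSSIBLY_DAMAGING,
                        "M": CanonicalCall.MISSING,
                    }[code]
                    calls.append(
                        HarmonizedCall(
                            variant_id=vid,
                            program=prog,
                            call=call,
                            reliable=call is not CanonicalCall.MISSING,
                        )
                    )
    return calls, labels
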