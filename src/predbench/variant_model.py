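"""Variant representation and credibility classification.

Variants enter the benchmark only if they can be assigned a credible class
from curation evidence: *credibly pathogenic* (published or database-listed
disease association, observed in a clinical case or validation specimen, and
confirmed by in-house sequencing) or *credibly benign* (seen in multiple
large-population resources at a minor allele frequency above a panel-specific
threshold, and validated in dbSNP or published as benign).  Everything else
is excluded or left unclassified and never contributes to predictor metrics.

The two panels carry different MAF thresholds because the disease mechanisms
differ: gain-of-function RAS/MAPK-pathway variants are dominant and must be
very rare in healthy populations (0.1%), whereas loss-of-function
limb-girdle muscular dystrophy variants are recessive and tolerate higher
carrier frequencies (1%).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Panel",
    "Consequence",
    "CredibilityLabel",
    "Variant",
    "EvidenceRecord",
    "ClassificationConfig",
    "classify_variant",
]


class Panel(str, enum.Enum):
    """Disease panel; determines which MAF threshold applies."""

    RAS = "RAS"
    LGMD = "LGMD"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    OTHER = "other"


class CredibilityLabel(str, enum.Enum):
    CREDIBLY_PATHOGENIC = "credibly_pathogenic"
    CREDIBLY_BENIGN = "credibly_benign"
    EXCLUDED = "excluded"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Variant:
    """A single missense (or other) variant on one gene panel.

    HGVS strings are carried as opaque text; no transcript mapping is done.
    """

    variant_id: str
    gene: str
    panel: Panel
    protein_change: str
    coding_change: Optional[str] = None
    consequence: Consequence = Consequence.MISSENSE

    def __post_init__(self) -> None:
        if not isinstance(self.panel, Panel):
            object.__setattr__(self, "panel", Panel(self.panel))
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))


@dataclass(frozen=True)
class EvidenceRecord:
    """Curation evidence used by :func:`classify_variant`.

    ``max_population_maf`` is the largest minor allele frequency observed in
    any large population resource, or ``None`` when the variant is absent
    from all of them.
    """

    published_disease_associated: bool = False
    in_curated_disease_db: bool = False
    clinical_case_or_validation: bool = False
    sequenced_in_lab: bool = False
    different_aa_at_known_codon: bool = False
    n_large_population_sources: int = 0
    max_population_maf: Optional[float] = None
    dbsnp_validated: bool = False
    published_benign: bool = False

    def __post_init__(self) -> None:
        if self.n_large_population_sources < 0:
            raise ValueError(
                "n_large_population_sources must be >= 0, got "
                f"{self.n_large_population_sources}"
            )
        if self.max_population_maf is not None and not (
            0.0 <= self.max_population_maf <= 1.0
        ):
            raise ValueError(
                f"max_population_maf must be in [0, 1], got {self.max_population_maf}"
            )


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for the credibly-benign rule."""

    maf_threshold_ras: float = 0.001
    maf_threshold_lgmd: float = 0.010
    min_population_sources: int = 2

    def __post_init__(self) -> None:
        for name in ("maf_threshold_ras", "maf_threshold_lgmd"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_population_sources < 1:
            raise ValueError("min_population_sources must be >= 1")

    def maf_threshold(self, panel: Panel) -> float:
        if panel is Panel.RAS:
            return self.maf_threshold_ras
        if panel is Panel.LGMD:
            return self.maf_threshold_lgmd
        raise ValueError(f"unknown panel: {panel!r}")


def classify_variant(
    variant: Variant,
    evidence: EvidenceRecord,
    config: ClassificationConfig = ClassificationConfig(),
) -> CredibilityLabel:
    """Assign a credibility label from curation evidence.

    Rules, in order:

    * non-missense consequence -> ``EXCLUDED``;
    * the pathogenic criteria otherwise hold but the substitution produces a
      different amino acid than the one reported at that codon ->
      ``EXCLUDED`` (an internally "likely pathogenic" call without published
      verification, e.g. p.Asp106Gly where p.Asp106Ala is the known change);
    * pathogenic rule: (published as disease-associated OR in a curated
      disease database) AND seen in a clinical case or validation specimen
      AND sequenced in-house -> ``CREDIBLY_PATHOGENIC``;
    * benign rule: seen in >= ``min_population_sources`` large-population
      resources AND max MAF strictly greater than the panel threshold AND
      (dbSNP-validated OR published benign) -> ``CREDIBLY_BENIGN``;
    * both rules firing is a curation conflict -> ``UNCLASSIFIED``;
    * neither rule -> ``UNCLASSIFIED``.

    The MAF comparison is strict: a frequency exactly at the threshold does
    not qualify as credibly benign.
    """
    if variant.panel is None:
        raise ValueError(f"variant {variant.variant_id!r} has no panel")

    if variant.consequence is not Consequence.MISSENSE:
        return CredibilityLabel.EXCLUDED

    pathogenic_core = (
        (evidence.published_disease_associated or evidence.in_curated_disease_db)
        and evidence.clinical_case_or_validation
        and evidence.sequenced_in_lab
    )
    if pathogenic_core and evidence.different_aa_at_known_codon:
        return CredibilityLabel.EXCLUDED
    pathogenic = pathogenic_core and not evidence.different_aa_at_known_codon

    threshold = config.maf_threshold(variant.panel)
    benign = (
        evidence.n_large_population_sources >= config.min_population_sources
        and evidence.max_population_maf is not None
        and evidence.max_population_maf > threshold
        and (evidence.dbsnp_validated or evidence.published_benign)
    )

    if pathogenic and benign:
        return CredibilityLabel.UNCLASSIFIED
    if pathogenic:
        return CredibilityLabel.CREDIBLY_PATHOGENIC
    if benign:
        return CredibilityLabel.CREDIBLY_BENIGN
    return CredibilityLabel.UNCLASSIFIED
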