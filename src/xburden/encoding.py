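"""Variant qualification rules and boolean gene-burden collapsing.

The analysis reduces a cohort's annotated X-chromosome variant calls to a
subjects x genes matrix of {0, 1} burden indicators: a gene is set to 1 for a
subject if the subject carries at least one *qualifying* rare variant in it.
A variant qualifies for the burden when its consequence is missense, splicing
or loss-of-function and its Non-Finnish-European allele frequency is at most
1% (a missing frequency is treated as rare by default).  A stricter
*candidate* rule additionally requires a CADD deleteriousness score of at
least 12.28.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Consequence",
    "VariantRecord",
    "Subject",
    "FilterConfig",
    "SubjectClass",
    "classify_subject",
    "qualifies_for_burden",
    "qualifies_as_candidate",
    "build_boolean_matrix",
]


class Consequence(str, enum.Enum):
    """Collapsed functional-annotation classes used by the burden rule."""

    MISSENSE = "missense"
    SPLICING = "splicing"
    LOF = "LOF"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: annotation strings mapped onto the collapsed classes; "splicing" is taken
#: as the superset of donor/acceptor/region annotations.
CONSEQUENCE_ALIASES: dict[str, Consequence] = {
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "splicing": Consequence.SPLICING,
    "splice_donor_variant": Consequence.SPLICING,
    "splice_acceptor_variant": Consequence.SPLICING,
    "splice_region_variant": Consequence.SPLICING,
    "LOF": Consequence.LOF,
    "lof": Consequence.LOF,
    "stop_gained": Consequence.LOF,
    "frameshift_variant": Consequence.LOF,
    "start_lost": Consequence.LOF,
    "stop_lost": Consequence.LOF,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "other": Consequence.OTHER,
}


def normalize_consequence(label: str) -> Consequence:
    """Map a raw consequence annotation onto a collapsed class.

    Unknown labels fall back to :attr:`Consequence.OTHER`.
    """
    return CONSEQUENCE_ALIASES.get(str(label), Consequence.OTHER)


@dataclass
class VariantRecord:
    """One annotated alternate allele with its carrier set.

    Multi-allelic sites must be decomposed into one record per ALT before
    filtering.  ``functional_class`` holds an experimentally determined label
    (``LOF`` / ``HYPO`` / ``Neutral``) when available; it is never computed.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    nfe_af: float | None = None
    cadd: float | None = None
    carriers: frozenset[str] = field(default_factory=frozenset)
    variant_id: str | None = None
    functional_class: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")
        if self.nfe_af is not None and not (0.0 <= self.nfe_af <= 1.0):
            raise ValueError(f"nfe_af outside [0, 1]: {self.nfe_af}")
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", normalize_consequence(self.consequence))
        self.carriers = frozenset(self.carriers)


@dataclass
class Subject:
    """Phenotype row for one cohort participant."""

    id: str
    sex: str
    age: float
    clinical_category: int
    cohort: str = ""
    pcr_confirmed: bool = True
    ethnicity: str = ""

    def __post_init__(self) -> None:
        if self.clinical_category not in range(5):
            raise ValueError(
                f"clinical_category must be in 0..4, got {self.clinical_category}"
            )
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")


@dataclass
class FilterConfig:
    """Thresholds of the variant-qualification rules.

    ``cadd_threshold`` is applied inclusively (>= 12.28): variants scoring
    exactly at the threshold are counted as candidates.
    """

    maf_threshold: float = 0.01
    qualifying_consequences: frozenset[Consequence] = frozenset(
        {Consequence.MISSENSE, Consequence.SPLICING, Consequence.LOF}
    )
    cadd_threshold: float = 12.28
    missing_maf_is_rare: bool = True
    age_cutoff: float = 60.0

    def __post_init__(self) -> None:
        if self.maf_threshold < 0 or self.cadd_threshold < 0 or self.age_cutoff < 0:
            raise ValueError("thresholds must be non-negative")
        self.qualifying_consequences = frozenset(
            normalize_consequence(c) if not isinstance(c, Consequence) else c
            for c in self.qualifying_consequences
        )


class SubjectClass(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"


def classify_subject(subject: Subject, cfg: FilterConfig | None = None) -> SubjectClass:
    """Assign a subject to the case, control, or excluded arm.

    Cases are PCR-confirmed males under the age cutoff in clinical category 3
    (hospitalized, CPAP/BiPAP) or 4 (hospitalized, intubated); controls are
    confirmed males under the cutoff in category 0 (oligo-asymptomatic, not
    hospitalized).  Everyone else — intermediate categories 1–2, unconfirmed
    infection, age at or above the cutoff, non-male — is excluded.
    """
    cfg = cfg or FilterConfig()
    if subject.clinical_category not in range(5):
        raise ValueError(f"clinical_category out of range: {subject.clinical_category}")
    if subject.sex != "M" or not subject.pcr_confirmed or subject.age >= cfg.age_cutoff:
        return SubjectClass.EXCLUDED
    if subject.clinical_category in (3, 4):
        return SubjectClass.CASE
    if subject.clinical_category == 0:
        return SubjectClass.CONTROL
    return SubjectClass.EXCLUDED


def qualifies_for_burden(variant: VariantRecord, cfg: FilterConfig | None = None) -> bool:
    """True if the variant counts toward the boolean gene burden.

    Requires a qualifying consequence class and rarity: NFE allele frequency
    at most ``maf_threshold``, or missing when ``missing_maf_is_rare``.
    """
    cfg = cfg or FilterConfig()
    if variant.consequence not in cfg.qualifying_consequences:
        return False
    af = variant.nfe_af
    if af is None or (isinstance(af, float) and np.isnan(af)):
        return cfg.missing_maf_is_rare
    return af <= cfg.maf_threshold


def qualifies_as_candidate(variant: VariantRecord, cfg: FilterConfig | None = None) -> bool:
    """True if the variant passes the burden rule and the CADD threshold.

    A missing CADD score never qualifies; a warning is emitted because the
    variant might qualify under complete annotation.
    """
    cfg = cfg or FilterConfig()
    if not qualifies_for_burden(variant, cfg):
        return False
    cadd = variant.cadd
    if cadd is None or (isinstance(cadd, float) and np.isnan(cadd)):
        warnings.warn(
            f"variant {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} "
            "has no CADD score; treated as non-candidate",
            stacklevel=2,
        )
        return False
    return cadd >= cfg.cadd_threshold


def build_boolean_matrix(
    variants: list[VariantRecord],
    subjects: list[Subject],
    cfg: FilterConfig | None = None,
    gene_universe: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse qualifying variants into the subjects x genes {0,1} matrix.

    Entry (s, g) is 1 iff subject ``s`` carries at least one variant in gene
    ``g`` that passes :func:`qualifies_for_burden`; the collapse is idempotent
    in the number of qualifying variants.  Columns are the union of genes
    observed among qualifying variants (or ``gene_universe`` when supplied),
    in lexicographic order.  A carrier ID that does not resolve to a subject
    is a hard error.

    Returns a DataFrame indexed by subject ID with int8 entries.
    """
    cfg = cfg or FilterConfig()
    subject_ids = [s.id for s in subjects]
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject IDs are not unique")
    id_set = set(subject_ids)

    qualifying = [v for v in variants if qualifies_for_burden(v, cfg)]
    for v in qualifying:
        unknown = v.carriers - id_set
        if unknown:
            raise KeyError(
                f"carrier IDs not in subject list: {sorted(unknown)[:5]} "
                f"(variant {v.chrom}:{v.pos})"
            )

    if gene_universe is not None:
        genes = sorted(set(gene_universe))
    else:
        genes = sorted({v.gene for v in qualifying})

    mat = pd.DataFrame(
        np.zeros((len(subject_ids), len(genes)), dtype=np.int8),
        index=pd.Index(subject_ids, name="subject_id"),
        columns=genes,
    )
    for v in qualifying:
        if v.gene in mat.columns and v.carriers:
            mat.loc[sorted(v.carriers), v.gene] = 1
    return mat
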