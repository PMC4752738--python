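"""Cross-referencing family candidates against case/control cohorts.

Three operations: exact-key intersection of the family's candidate
variants with variants seen in a familial cancer case cohort; a gene-level
filter selecting rare, protein-altering, prediction-supported cohort
variants in the candidate genes whose case frequency is not below the
control frequency; and per-family segregation classification of a variant
across the cohort's families.

Family classification distinguishes three mutually exclusive categories
(per family, for one variant):

- *single carrier*: exactly one member genotyped, and that member carries;
- *segregating*: >= 2 members genotyped, >= 2 genotyped affected members,
  and every genotyped affected member carries;
- *non-segregating*: >= 2 members genotyped, at least one carrier in the
  family, and at least one genotyped affected member does not carry.

Families without any carrier are not counted.  Unaffected carriers never
demote a family: incomplete penetrance is tolerated by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    AnnotatedVariant,
    GenotypeCall,
    PROTEIN_ALTERING_CLASSES,
    Variant,
)
from .predictions import SupportPolicy, supportive_calls

__all__ = [
    "MemberCall",
    "FamilyGenotypes",
    "CohortFilterConfig",
    "intersect_candidates",
    "cohort_gene_filter",
    "classify_family_segregation",
    "distinct_gene_count",
]


@dataclass(frozen=True)
class MemberCall:
    """One cohort-family member's genotype at one variant."""

    id: str
    affection: str
    call: GenotypeCall


@dataclass(frozen=True)
class FamilyGenotypes:
    """Genotypes of one cohort family at one variant."""

    family_id: str
    members: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError(f"family {self.family_id!r} has no members")


@dataclass(frozen=True)
class CohortFilterConfig:
    """Predicates for the cohort gene-level variant filter."""

    maf_threshold: float = 0.20
    require_supportive_prediction: bool = True
    require_case_freq_ge_controls: bool = True
    kept_func_classes: frozenset = PROTEIN_ALTERING_CLASSES
    policy: SupportPolicy = SupportPolicy()

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValueError(f"maf_threshold outside [0,1]: {self.maf_threshold}")


def intersect_candidates(
    candidates: Sequence[AnnotatedVariant | Variant],
    cohort_variants: Sequence[AnnotatedVariant],
) -> list[AnnotatedVariant]:
    """Candidates whose exact (chrom, pos, ref, alt) key occurs in the
    cohort list, with the cohort's annotations attached.

    Matching is pure key membership — same position with a different
    alternate allele does not match.
    """
    by_key = {cv.key: cv for cv in cohort_variants}
    matched: list[AnnotatedVariant] = []
    for cand in candidates:
        if isinstance(cand, Variant):
            cand = AnnotatedVariant(variant=cand)
        hit = by_key.get(cand.key)
        if hit is not None:
            matched.append(cand.with_cohort(hit.cohort))
    return matched


def cohort_gene_filter(
    cohort_variants: Sequence[AnnotatedVariant],
    genes: set,
    config: CohortFilterConfig = CohortFilterConfig(),
) -> list[AnnotatedVariant]:
    """Filter cohort variants in the candidate genes.

    Keeps variants passing the conjunction of: gene in ``genes``; exonic
    protein-altering functional class; 1000G MAF <= threshold (absent MAF
    kept); >= 1 supportive in-silico prediction when required; case
    frequency >= control frequency when required (an absent control
    frequency is treated as 0, so the variant is kept; an absent case
    frequency is likewise treated as 0).
    """
    kept = []
    for record in cohort_variants:
        v = record.variant
        if v.gene not in genes:
            continue
        if v.func_class not in config.kept_func_classes:
            continue
        maf = v.maf_1000g
        if maf is not None and maf > config.maf_threshold:
            continue
        if config.require_supportive_prediction:
            profile = record.profile
            if profile is None or not supportive_calls(profile, config.policy)[1]:
                continue
        if config.require_case_freq_ge_controls:
            cohort = record.cohort
            case = (cohort.freq_98_cases if cohort else None) or 0.0
            control = (cohort.freq_249_controls if cohort else None) or 0.0
            if case < control:
                continue
        kept.append(record)
    return kept


def classify_family_segregation(
    per_family: Sequence[FamilyGenotypes], variant: Variant
) -> tuple[int, int, int]:
    """Classify each family as single-carrier / segregating /
    non-segregating for ``variant``; returns the three counts.

    See the module docstring for the category definitions.  Carrier status
    is the dominant predicate (>= 1 alternate allele); missing calls count
    as not genotyped.
    """
    c = d = e = 0
    for family in per_family:
        genotyped = [m for m in family.members if not m.call.is_missing]
        carriers = [m for m in genotyped if m.call.carries(variant.alt)]
        if not carriers:
            continue
        if len(genotyped) == 1:
            c += 1
            continue
        affected = [
            m for m in genotyped if m.affection in {"cancer", "polyps"}
        ]
        affected_noncarriers = [
            m for m in affected if not m.call.carries(variant.alt)
        ]
        if affected_noncarriers:
            e += 1
        elif len(affected) >= 2:
            d += 1
        # >= 2 genotyped but < 2 genotyped affected carriers and no affected
        # non-carrier: uninformative for segregation, not counted.
    return c, d, e


def distinct_gene_count(variants: Sequence[AnnotatedVariant | Variant]) -> int:
    """Number of distinct gene symbols across the records."""
    genes = set()
    for item in variants:
        gene = item.gene if isinstance(item, (AnnotatedVariant, Variant)) else None
        if not gene:
            raise ValueError(f"record without gene symbol: {item!r}")
        genes.add(gene)
    return len(genes)
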