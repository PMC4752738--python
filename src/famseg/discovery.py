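"""Discovery-phase filtering cascade for shared exome variants.

The cascade reduces the exome-wide variant set of the sequenced affected
relatives to a shortlist of rare, protein-altering, family-specific
candidates under a dominant model.  Four pointwise predicates are applied
in a fixed order:

1. *shared*: every discovery-sequenced individual carries >= 1 alternate
   allele (non-missing genotype required);
2. *frequency*: 1000 Genomes MAF <= threshold (strictly-greater excluded;
   variants absent from the panel are treated as novel and kept);
3. *functional*: functional class in the kept set (by default synonymous
   and non-exonic variants are dropped);
4. *background occurrence*: carried by at most ``background_max_carriers``
   samples of an unrelated background cohort sequenced alongside the
   family (occurrence-based, not frequency-based).

Because each stage is a pointwise predicate the final shortlist does not
depend on stage order; the per-stage exclusion ledger does, and the fixed
order above is what the ledger reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    GenotypeTable,
    PROTEIN_ALTERING_CLASSES,
    Variant,
    VariantKey,
)

__all__ = [
    "CascadeConfig",
    "StageRecord",
    "StageLedger",
    "shared_variants",
    "frequency_filter",
    "functional_filter",
    "cohort_occurrence_filter",
    "discovery_cascade",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds for the discovery cascade.

    ``maf_threshold``: population-frequency cut-off; variants with MAF
    strictly greater are excluded (default 0.20).
    ``kept_func_classes``: functional classes retained (default: exonic
    protein-altering classes).
    ``background_max_carriers``: maximum number of background-cohort
    carriers tolerated (default 1, i.e. "present in more than one"
    excludes).
    """

    maf_threshold: float = 0.20
    kept_func_classes: frozenset = PROTEIN_ALTERING_CLASSES
    background_max_carriers: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValueError(f"maf_threshold outside [0,1]: {self.maf_threshold}")
        if self.background_max_carriers < 0:
            raise ValueError("background_max_carriers must be >= 0")


@dataclass(frozen=True)
class StageRecord:
    """Audit record for one cascade stage."""

    name: str
    n_input: int
    excluded: tuple  # variant keys

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_excluded


@dataclass
class StageLedger:
    """Ordered stage records; consecutive counts must chain."""

    stages: list[StageRecord] = field(default_factory=list)

    def append(self, record: StageRecord) -> None:
        if self.stages and record.n_input != self.stages[-1].n_output:
            raise ValueError(
                f"ledger chain broken at stage {record.name!r}: "
                f"input {record.n_input} != previous output {self.stages[-1].n_output}"
            )
        self.stages.append(record)

    def counts(self) -> dict[str, tuple[int, int]]:
        """stage name -> (input count, excluded count)."""
        return {s.name: (s.n_input, s.n_excluded) for s in self.stages}

    def to_records(self) -> list[dict]:
        return [
            {
                "stage": s.name,
                "n_input": s.n_input,
                "n_excluded": s.n_excluded,
                "n_output": s.n_output,
                "excluded": [":".join(map(str, k)) for k in s.excluded],
            }
            for s in self.stages
        ]


def shared_variants(table: GenotypeTable, individuals: Sequence[str]) -> list[Variant]:
    """Variants where every listed individual has >= 1 alternate allele.

    A missing genotype in any listed individual removes the variant: the
    sharing criterion demands an observed carrier genotype.
    """
    if not individuals:
        raise ValueError("empty individual list: sharing criterion is ambiguous")
    unknown = [i for i in individuals if i not in table.samples]
    if unknown:
        raise KeyError(f"individuals not in table: {unknown}")
    return [
        v
        for v in table.variants
        if all(table.call(v, ind).carries(v.alt) for ind in individuals)
    ]


def frequency_filter(variants: Sequence[Variant], maf_threshold: float) -> list[Variant]:
    """Drop variants with 1000G MAF strictly above the threshold.

    Absent MAF annotation means the variant is novel and is retained.
    """
    if not (0.0 <= maf_threshold <= 1.0):
        raise ValueError(f"maf_threshold outside [0,1]: {maf_threshold}")
    return [v for v in variants if v.maf_1000g is None or v.maf_1000g <= maf_threshold]


def functional_filter(
    variants: Sequence[Variant], kept_classes: frozenset = PROTEIN_ALTERING_CLASSES
) -> list[Variant]:
    """Keep only variants whose functional class is in ``kept_classes``."""
    return [v for v in variants if v.func_class in kept_classes]


def cohort_occurrence_filter(
    variants: Sequence[Variant],
    background: Optional[GenotypeTable],
    max_carriers: int = 1,
) -> list[Variant]:
    """Drop variants carried by strictly more than ``max_carriers``
    background samples.

    Carrier status is matched on the exact (chrom, pos, ref, alt) key; a
    variant absent from the background table has zero carriers.  A ``None``
    background keeps everything.
    """
    if background is None:
        return list(variants)
    kept = []
    for v in variants:
        n = len(background.carrier_samples(v)) if background.has_variant(v.key) else 0
        if n <= max_carriers:
            kept.append(v)
    return kept


def discovery_cascade(
    table: GenotypeTable,
    discovery_ids: Sequence[str],
    background: Optional[GenotypeTable] = None,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[Variant], StageLedger]:
    """Run shared -> frequency -> functional -> background in fixed order.

    Returns the final shortlist and a :class:`StageLedger` whose chained
    counts audit each exclusion step.
    """
    ledger = StageLedger()

    def record(name: str, before: Sequence[Variant], after: Sequence[Variant]) -> None:
        after_keys = {v.key for v in after}
        excluded = tuple(v.key for v in before if v.key not in after_keys)
        ledger.append(StageRecord(name, len(before), excluded))

    current: list[Variant] = list(table.variants)
    if current and not discovery_ids:
        raise ValueError("empty discovery_ids")
    stage = shared_variants(table, discovery_ids) if current else []
    record("shared", current, stage)
    current = stage

    stage = frequency_filter(current, config.maf_threshold)
    record("frequency", current, stage)
    current = stage

    stage = functional_filter(current, config.kept_func_classes)
    record("functional", current, stage)
    current = stage

    stage = cohort_occurrence_filter(current, background, config.background_max_carriers)
    record("background", current, stage)
    return stage, ledger
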