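"""Obligate-carrier segregation filtering under a dominant model.

Given a shortlist of candidate variants and genotypes for additional
relatives, each relative assumed (from phenotype and pedigree position) to
be an obligate carrier must carry at least one alternate allele of a true
predisposing variant.  A variant failing the carrier predicate for any
assumed carrier is excluded; the exclusion is attributed to the *first*
failing carrier in the declared order, which reproduces the sequential
accounting style of a stepwise analysis ("N excluded because not shared by
X, M more because not shared by Y").  The retained set itself is
independent of carrier order — only the attribution depends on it.

Carrier-assumption scenarios extend the analysis: soft-phenotype relatives
(e.g. polyp carriers) are added cumulatively, and each step reports the
variants newly excluded by its added carriers.

Missing genotypes: the default *strict* mode raises, since obligate-carrier
filtering on an incompletely typed relative is undefined; the *permissive*
mode treats a missing call as "carrier status unknown — do not exclude" and
reports the affected cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .model import GenotypeCall, GenotypeTable, Variant, VariantKey

__all__ = [
    "MissingGenotypeError",
    "CarrierSet",
    "ExclusionLedger",
    "Scenario",
    "ScenarioStep",
    "carries_alt",
    "segregation_filter",
    "scenario_analysis",
    "order_invariance_check",
]

Strictness = Literal["strict", "permissive"]


class MissingGenotypeError(ValueError):
    """A carrier's genotype is missing and strict mode is in force."""


class CarrierSet(tuple):
    """Ordered, duplicate-free list of assumed obligate carrier ids.

    Order is the ledger attribution order; it never changes which variants
    are retained.
    """

    def __new__(cls, ids: Sequence[str] = ()):
        ids = tuple(ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate carrier ids in {ids}")
        return super().__new__(cls, ids)


@dataclass(frozen=True)
class Scenario:
    """One cumulative carrier-assumption step.

    ``added_carriers`` are assumed to be obligate carriers *in addition to*
    everything assumed so far; ``rationale`` records the soft-phenotype
    justification (e.g. "three large tubulovillous adenomas").
    """

    label: str
    added_carriers: tuple
    rationale: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "added_carriers", tuple(self.added_carriers))


@dataclass
class ExclusionLedger:
    """Partition of a shortlist into retained variants and per-carrier
    exclusion sets.

    The per-carrier excluded sets are disjoint and, together with the
    retained set, reconstitute the input shortlist exactly; this is
    asserted on construction via :meth:`validate`.
    """

    carriers: tuple
    per_carrier: dict  # carrier id -> tuple of excluded VariantKey
    retained: tuple  # VariantKey
    unknown_cells: tuple = ()  # (VariantKey, carrier id) skipped in permissive mode

    def validate(self, shortlist_keys: Sequence[VariantKey]) -> None:
        excluded: list[VariantKey] = []
        for keys in self.per_carrier.values():
            excluded.extend(keys)
        if len(set(excluded)) != len(excluded):
            raise AssertionError("per-carrier excluded sets are not disjoint")
        if set(excluded) | set(self.retained) != set(shortlist_keys) or set(
            excluded
        ) & set(self.retained):
            raise AssertionError("ledger does not partition the shortlist")

    def excluded_count(self, carrier: str) -> int:
        return len(self.per_carrier.get(carrier, ()))

    @property
    def n_excluded(self) -> int:
        return sum(len(k) for k in self.per_carrier.values())

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_record(self) -> dict:
        return {
            "carriers": list(self.carriers),
            "retained": [":".join(map(str, k)) for k in self.retained],
            "excluded_by_carrier": {
                c: [":".join(map(str, k)) for k in keys]
                for c, keys in self.per_carrier.items()
            },
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
        }


def carries_alt(
    call: GenotypeCall, alt: str, missing: Strictness = "strict"
) -> Optional[bool]:
    """Dominant-model carrier predicate: >= 1 allele equals ``alt``.

    A missing call raises :class:`MissingGenotypeError` in strict mode and
    returns ``None`` ("unknown") in permissive mode.
    """
    if call.is_missing:
        if missing == "strict":
            raise MissingGenotypeError("missing genotype under strict mode")
        return None
    return call.carries(alt)


def segregation_filter(
    shortlist: Sequence[Variant],
    table: GenotypeTable,
    carriers: Sequence[str],
    missing: Strictness = "strict",
) -> ExclusionLedger:
    """Retain variants carried by every assumed obligate carrier.

    Exclusions are attributed to the first carrier (in ``carriers`` order)
    failing the carrier predicate.  In permissive mode an unknown carrier
    status neither excludes nor attributes; the skipped cells are listed in
    ``unknown_cells``.
    """
    carriers = CarrierSet(carriers)
    unknown = [c for c in carriers if c not in table.samples]
    if unknown:
        raise KeyError(f"carrier ids not in genotype table: {unknown}")
    per_carrier: dict[str, list[VariantKey]] = {c: [] for c in carriers}
    retained: list[VariantKey] = []
    unknown_cells: list[tuple[VariantKey, str]] = []
    for variant in shortlist:
        failing = None
        for carrier in carriers:
            status = carries_alt(table.call(variant, carrier), variant.alt, missing)
            if status is None:
                unknown_cells.append((variant.key, carrier))
            elif not status:
                failing = carrier
                break
        if failing is None:
            retained.append(variant.key)
        else:
            per_carrier[failing].append(variant.key)
    ledger = ExclusionLedger(
        carriers=tuple(carriers),
        per_carrier={c: tuple(k) for c, k in per_carrier.items()},
        retained=tuple(retained),
        unknown_cells=tuple(unknown_cells),
    )
    ledger.validate([v.key for v in shortlist])
    return ledger


@dataclass(frozen=True)
class ScenarioStep:
    """Report row for one cumulative carrier-assumption step."""

    label: str
    added_carriers: tuple
    rationale: str
    newly_excluded: tuple  # VariantKey
    retained_after: tuple  # VariantKey

    def newly_excluded_genes(self, shortlist: Sequence[Variant]) -> set[str]:
        by_key = {v.key: v.gene for v in shortlist}
        return {by_key[k] for k in self.newly_excluded if k in by_key}


def scenario_analysis(
    shortlist: Sequence[Variant],
    table: GenotypeTable,
    base: Sequence[str],
    scenarios: Sequence[Scenario],
    missing: Strictness = "strict",
) -> list[ScenarioStep]:
    """Apply carrier-assumption scenarios cumulatively.

    Step k filters whatever the previous steps retained with that
    scenario's added carriers; the final retained set therefore equals a
    one-shot :func:`segregation_filter` with the base set united with every
    added carrier.
    """
    base_ledger = segregation_filter(shortlist, table, base, missing)
    current = [v for v in shortlist if v.key in set(base_ledger.retained)]
    assumed = list(base)
    steps: list[ScenarioStep] = []
    for scenario in scenarios:
        for carrier in scenario.added_carriers:
            if carrier in assumed:
                raise ValueError(f"carrier {carrier!r} already assumed")
            assumed.append(carrier)
        ledger = segregation_filter(current, table, scenario.added_carriers, missing)
        retained_keys = set(ledger.retained)
        newly_excluded = tuple(v.key for v in current if v.key not in retained_keys)
        current = [v for v in current if v.key in retained_keys]
        steps.append(
            ScenarioStep(
                label=scenario.label,
                added_carriers=scenario.added_carriers,
                rationale=scenario.rationale,
                newly_excluded=newly_excluded,
                retained_after=tuple(v.key for v in current),
            )
        )
    return steps


def order_invariance_check(
    shortlist: Sequence[Variant],
    table: GenotypeTable,
    carriers: Sequence[str],
    max_permutations: Optional[int] = None,
    missing: Strictness = "strict",
) -> bool:
    """True iff the retained set is identical under permutations of carrier
    order (ledger attribution may legitimately differ).

    All permutations are tested unless ``max_permutations`` caps the count
    (permutations are then enumerated in lexicographic order).
    """
    reference = None
    for n, perm in enumerate(itertools.permutations(carriers)):
        if max_permutations is not None and n >= max_permutations:
            break
        retained = frozenset(segregation_filter(shortlist, table, perm, missing).retained)
        if reference is None:
            reference = retained
        elif retained != reference:
            return False
    return True
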