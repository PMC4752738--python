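"""Core domain types for family-based variant prioritization.

The objects here are deliberately small and immutable: a :class:`Variant`
is one biallelic site on GRCh37 with 1-based coordinates, a
:class:`GenotypeCall` is an *unordered* allele pair for one individual at
one site (phase is never used by the dominant-model filters), and a
:class:`GenotypeTable` holds the (variant, sample) call matrix every
filtering stage consumes.

Allele strings follow the printed-table convention for indels: a pure
deletion is written with alternate allele ``"-"`` (e.g. ``GGA/-``) and a
pure insertion with reference allele ``"-"``.  VCF input instead uses the
standard anchored-base representation; :mod:`famseg.io` provides the
normalizer mapping between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "FUNC_CLASSES",
    "PROTEIN_ALTERING_CLASSES",
    "AFFECTION_STATES",
    "Variant",
    "GenotypeCall",
    "MISSING_CALL",
    "Individual",
    "Pedigree",
    "GenotypeTable",
    "PredictionProfile",
    "CohortAnnotations",
    "AnnotatedVariant",
    "VariantKey",
    "chrom_sort_key",
    "variant_sort_key",
]

#: Functional consequence classes recognised on a variant record.
FUNC_CLASSES = frozenset(
    {
        "nonsynonymous_SNV",
        "stopgain_SNV",
        "synonymous_SNV",
        "nonframeshift_deletion",
        "frameshift_deletion",
        "nonexonic",
        "other",
    }
)

#: Classes kept by the default discovery cascade: exonic, protein-altering.
#: ``other`` (e.g. in-frame insertions, which have no dedicated class) is
#: kept conservatively.
PROTEIN_ALTERING_CLASSES = frozenset(
    {
        "nonsynonymous_SNV",
        "stopgain_SNV",
        "nonframeshift_deletion",
        "frameshift_deletion",
        "other",
    }
)

AFFECTION_STATES = frozenset({"cancer", "polyps", "unaffected", "unknown"})

ROLES = frozenset({"discovery_sequenced", "validation_typed", "untyped"})

#: Hashable identity of a biallelic variant: (chrom, pos, ref, alt).
VariantKey = tuple  # (str, int, str, str)

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order 1..22, X, Y; unknown labels sort last."""
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def variant_sort_key(v: "Variant") -> tuple:
    return (*chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)


@dataclass(frozen=True, slots=True)
class Variant:
    """One biallelic variant record (GRCh37, 1-based).

    ``maf_1000g`` is the 1000 Genomes allele frequency; ``None`` means the
    variant is absent from the reference panel and is treated as novel
    (frequency 0) by the filters.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    dbsnp_id: Optional[str] = None
    func_class: str = "other"
    maf_1000g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty strings")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        if self.maf_1000g is not None and not (0.0 <= self.maf_1000g <= 1.0):
            raise ValueError(f"maf_1000g outside [0,1]: {self.maf_1000g}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """Unordered diploid allele pair, or a missing call.

    ``alleles`` is a sorted 2-tuple of allele strings, or ``None`` when the
    genotype is missing.  ``"-"`` is a valid allele string (printed-table
    indel convention), so ``GenotypeCall(("GGA", "-"))`` means heterozygous
    for a 3-bp deletion.
    """

    alleles: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if len(self.alleles) != 2:
                raise ValueError("a genotype call has exactly two alleles")
            if any(not a for a in self.alleles):
                raise ValueError("allele strings must be non-empty")
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def carries(self, allele: str) -> bool:
        """True iff at least one allele equals ``allele`` (missing -> False)."""
        return self.alleles is not None and allele in self.alleles

    def count(self, allele: str) -> int:
        if self.alleles is None:
            return 0
        return sum(a == allele for a in self.alleles)

    def __str__(self) -> str:
        return "./." if self.alleles is None else "/".join(self.alleles)

    @classmethod
    def from_string(cls, text: str) -> "GenotypeCall":
        """Parse ``"C/T"``-style genotype text; ``"./."`` or ``"."`` = missing."""
        text = text.strip()
        if text in {".", "./.", ".|.", ""}:
            return MISSING_CALL
        parts = text.replace("|", "/").split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse genotype {text!r}")
        return cls((parts[0], parts[1]))


#: Shared singleton for missing genotypes.
MISSING_CALL = GenotypeCall(None)


@dataclass(frozen=True, slots=True)
class Individual:
    """A family member with affection status and sequencing role."""

    id: str
    sex: Optional[str] = None
    affection: str = "unknown"
    phenotype_detail: str = ""
    role: str = "untyped"

    def __post_init__(self) -> None:
        if self.affection not in AFFECTION_STATES:
            raise ValueError(f"unknown affection {self.affection!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class Pedigree:
    """Family members plus optional child -> (father, mother) links.

    Links are validated to reference existing members and to be acyclic.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        parents: Optional[Mapping[str, tuple[Optional[str], Optional[str]]]] = None,
    ) -> None:
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.parents: dict[str, tuple[Optional[str], Optional[str]]] = dict(parents or {})
        for child, (father, mother) in self.parents.items():
            if child not in self.individuals:
                raise ValueError(f"parent link for unknown individual {child!r}")
            for p in (father, mother):
                if p is not None and p not in self.individuals:
                    raise ValueError(f"individual {child!r} references absent parent {p!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(node: str) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise ValueError(f"parent links contain a cycle through {node!r}")
            state[node] = 0
            for p in self.parents.get(node, (None, None)):
                if p is not None:
                    visit(p)
            state[node] = 1

        for node in self.individuals:
            visit(node)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self.individuals

    def __getitem__(self, member_id: str) -> Individual:
        return self.individuals[member_id]

    @property
    def members(self) -> list[str]:
        return list(self.individuals)

    def founders(self) -> list[str]:
        """Members with no parent links."""
        return [
            i
            for i in self.individuals
            if self.parents.get(i, (None, None)) == (None, None)
        ]

    def affected(self, states: Sequence[str] = ("cancer",)) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.affection in states]


class GenotypeTable:
    """Ordered variants x ordered samples matrix of genotype calls.

    Every (variant, sample) pair resolves to a :class:`GenotypeCall`;
    pairs absent from ``calls`` resolve to the missing call.  Variant keys
    must be unique.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        samples: Sequence[str],
        calls: Mapping[tuple[VariantKey, str], GenotypeCall],
    ) -> None:
        self.variants: list[Variant] = list(variants)
        self.samples: list[str] = list(samples)
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            seen: set[VariantKey] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate variant key {k}")
                seen.add(k)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self._keyset = set(keys)
        sampleset = set(self.samples)
        self.calls: dict[tuple[VariantKey, str], GenotypeCall] = {}
        for (vkey, sample), call in calls.items():
            if vkey not in self._keyset:
                raise ValueError(f"call for unknown variant key {vkey}")
            if sample not in sampleset:
                raise ValueError(f"call for unknown sample {sample!r}")
            self.calls[(vkey, sample)] = call

    def call(self, variant: "Variant | VariantKey", sample: str) -> GenotypeCall:
        key = variant.key if isinstance(variant, Variant) else tuple(variant)
        return self.calls.get((key, sample), MISSING_CALL)

    def has_variant(self, key: VariantKey) -> bool:
        return tuple(key) in self._keyset

    def variant_by_key(self, key: VariantKey) -> Variant:
        key = tuple(key)
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(key)

    def carrier_samples(self, variant: Variant) -> list[str]:
        """Samples with >= 1 alternate allele at ``variant`` (dominant model)."""
        return [s for s in self.samples if self.call(variant, s).carries(variant.alt)]

    def subset(self, variants: Sequence[Variant]) -> "GenotypeTable":
        keep = {v.key for v in variants}
        calls = {
            (k, s): c for (k, s), c in self.calls.items() if k in keep
        }
        return GenotypeTable(list(variants), self.samples, calls)

    def sorted(self) -> "GenotypeTable":
        return self.subset(sorted(self.variants, key=variant_sort_key))

    def __len__(self) -> int:
        return len(self.variants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            [v.key for v in self.variants] == [v.key for v in other.variants]
            and self.samples == other.samples
            and all(
                self.call(v, s) == other.call(v, s)
                for v in self.variants
                for s in self.samples
            )
        )


# --- annotation types -------------------------------------------------------

_PREDICTOR_CATEGORIES = {
    "phylop": frozenset({"C", "N"}),
    "sift": frozenset({"T", "D"}),
    "polyphen2": frozenset({"D", "P", "B"}),
    "lrt": frozenset({"N", "D"}),
    "mutation_taster": frozenset({"N", "D"}),
}

VARIANT_TYPE_FLAGS = frozenset({"inframe_indel", "frameshift", "stopgain"})


@dataclass(frozen=True, slots=True)
class PredictionProfile:
    """The five categorical in-silico predictor calls for one variant.

    Letters follow the conventional single-character encodings: PhyloP
    C(onserved)/N(ot conserved); SIFT T(olerated)/D(eleterious); PolyPhen2
    D(probably damaging)/P(ossibly damaging)/B(enign); LRT
    N(eutral)/D(eleterious); MutationTaster N(polymorphism)/D(isease
    causing).  ``None`` marks a predictor that produced no call (indels,
    uncovered sites).  ``variant_type_flags`` records protein-truncating /
    in-frame-indel status used as an independent line of evidence.  GERP++
    conservation, when available, rides along as an optional sixth score
    that default policies ignore.
    """

    phylop: Optional[str] = None
    sift: Optional[str] = None
    polyphen2: Optional[str] = None
    lrt: Optional[str] = None
    mutation_taster: Optional[str] = None
    variant_type_flags: frozenset = frozenset()
    gerp: Optional[float] = None

    def __post_init__(self) -> None:
        for name, allowed in _PREDICTOR_CATEGORIES.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValueError(
                    f"invalid category {value!r} for predictor {name} "
                    f"(allowed: {sorted(allowed)})"
                )
        bad = set(self.variant_type_flags) - VARIANT_TYPE_FLAGS
        if bad:
            raise ValueError(f"unknown variant_type_flags {sorted(bad)}")

    PREDICTORS = ("phylop", "sift", "polyphen2", "lrt", "mutation_taster")


@dataclass(frozen=True, slots=True)
class CohortAnnotations:
    """Cohort frequencies and per-family segregation counts for a variant.

    ``fam_single_carrier``: families where only one individual was
    sequenced and that individual carried the variant.
    ``fam_segregating``: families with >= 2 sequenced individuals where the
    variant co-occurred with disease.  ``fam_nonsegregating``: families
    with >= 2 sequenced individuals where it did not.
    """

    maf_1000g: Optional[float] = None
    freq_249_controls: Optional[float] = None
    freq_98_cases: Optional[float] = None
    fam_single_carrier: int = 0
    fam_segregating: int = 0
    fam_nonsegregating: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_1000g", "freq_249_controls", "freq_98_cases"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {value}")
        for name in ("fam_single_carrier", "fam_segregating", "fam_nonsegregating"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True, slots=True)
class AnnotatedVariant:
    """A variant together with whatever annotations a table supplied."""

    variant: Variant
    profile: Optional[PredictionProfile] = None
    cohort: Optional[CohortAnnotations] = None
    flags: frozenset = frozenset()

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def gene(self) -> str:
        return self.variant.gene

    def with_cohort(self, cohort: CohortAnnotations) -> "AnnotatedVariant":
        return replace(self, cohort=cohort)
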