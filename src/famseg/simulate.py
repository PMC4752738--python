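"""Synthetic pedigree-exome generator for desk-scale pipeline testing.

The generator emulates the statistical structure the filtering pipeline
assumes: a multi-generation pedigree segregating a dominant trait, one
planted novel heterozygous causal variant transmitted from a founder,
background variants with a rare-MAF spectrum drawn under Hardy–Weinberg in
founders and gene-dropped through the pedigree (independently per variant,
no linkage or recombination), incomplete penetrance, phenocopies, genotype
error and missingness, and an unrelated background cohort standing in for
the co-sequenced research samples used by the occurrence filter.

Everything is deterministic given the single integer ``seed``: each stage
draws from its own named stream derived via ``numpy`` ``SeedSequence``
spawn keys, so stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .discovery import CascadeConfig, discovery_cascade
from .model import (
    GenotypeCall,
    GenotypeTable,
    Individual,
    MISSING_CALL,
    Pedigree,
    Variant,
    VariantKey,
)
from .segregation import segregation_filter

__all__ = [
    "PedigreeSpec",
    "CausalSpec",
    "BackgroundSpec",
    "NoiseSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_cohort",
    "inject_errors",
    "recovery_benchmark",
    "RecoveryResult",
]

# named sub-streams of the master seed
_STREAM_PEDIGREE = 0
_STREAM_CAUSAL = 1
_STREAM_PHENOTYPE = 2
_STREAM_BACKGROUND = 3
_STREAM_ERRORS = 4
_STREAM_COHORT = 5
_STREAM_BENCHMARK = 10


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, *extra)))


@dataclass(frozen=True)
class PedigreeSpec:
    """Pedigree shape: ``generations`` >= 2 and offspring per couple,
    either a fixed count or an inclusive ``(low, high)`` range sampled
    uniformly per couple."""

    generations: int = 3
    offspring_per_couple: int | tuple = 2

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ValueError("need >= 2 generations")
        off = self.offspring_per_couple
        low = off if isinstance(off, int) else off[0]
        high = off if isinstance(off, int) else off[1]
        if high <= 0:
            raise ValueError("degenerate pedigree spec: no couple can have offspring")
        if low < 0 or high < low:
            raise ValueError(f"bad offspring range {off!r}")

    def draw_offspring(self, rng: np.random.Generator) -> int:
        off = self.offspring_per_couple
        if isinstance(off, int):
            return off
        return int(rng.integers(off[0], off[1] + 1))


@dataclass(frozen=True)
class CausalSpec:
    """Disease model: dominant single locus with the given penetrance and
    phenocopy rate; the causal allele enters through one founder
    (``founder_carrier`` is an id or ``"random"`` over the two
    first-generation founders)."""

    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    founder_carrier: str = "random"

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {value}")


@dataclass(frozen=True)
class BackgroundSpec:
    """Background variant landscape.

    ``maf_dist`` is ``("beta", a, b)`` for ``0.5 * Beta(a, b)`` or
    ``("uniform", low, high)`` over ``(0, 0.5]``.  ``func_class_weights``
    emulates the post-annotation mix of exonic and non-exonic calls the
    functional filter sees.
    """

    n_variants: int = 100
    maf_dist: tuple = ("beta", 0.5, 3.0)
    func_class_weights: tuple = (
        ("nonsynonymous_SNV", 0.6),
        ("synonymous_SNV", 0.25),
        ("nonexonic", 0.15),
    )

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        if self.maf_dist[0] not in {"beta", "uniform"}:
            raise ValueError(f"unknown maf distribution {self.maf_dist[0]!r}")

    def draw_mafs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind, p1, p2 = self.maf_dist
        if kind == "beta":
            mafs = 0.5 * rng.beta(p1, p2, size=n)
        else:
            mafs = rng.uniform(p1, p2, size=n)
        return np.clip(mafs, 1e-6, 0.5)


@dataclass(frozen=True)
class NoiseSpec:
    """Genotyping noise: per-cell error and missingness probabilities."""

    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("genotype_error_rate", "missing_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generator configuration; ``seed`` is mandatory."""

    seed: int
    pedigree: PedigreeSpec = PedigreeSpec()
    causal: CausalSpec = CausalSpec()
    background: BackgroundSpec = BackgroundSpec()
    noise: NoiseSpec = NoiseSpec()
    n_background_cohort: int = 30

    def __post_init__(self) -> None:
        if self.n_background_cohort < 0:
            raise ValueError("n_background_cohort must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated dataset."""

    causal_key: VariantKey
    true_carriers: tuple
    affected: tuple
    phenocopies: tuple
    perturbed_cells: tuple = ()

    def __post_init__(self) -> None:
        if not set(self.phenocopies) <= set(self.affected):
            raise ValueError("phenocopies must be affected")
        if set(self.phenocopies) & set(self.true_carriers):
            raise ValueError("phenocopies cannot be true carriers")


# --------------------------------------------------------------------------
# pedigree + disease model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _PedigreeTruth:
    pedigree: Pedigree
    carriers: tuple
    affected: tuple
    phenocopies: tuple


def _build_pedigree(config: SimulationConfig) -> _PedigreeTruth:
    """Structure, causal-carrier descent and affection — all seed-derived."""
    spec = config.pedigree
    struct_rng = _rng(config.seed, _STREAM_PEDIGREE)
    causal_rng = _rng(config.seed, _STREAM_CAUSAL)
    pheno_rng = _rng(config.seed, _STREAM_PHENOTYPE)

    individuals: list[Individual] = []
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    sexes: dict[str, str] = {}

    def add(member: str, sex: str, father: Optional[str] = None, mother: Optional[str] = None):
        individuals.append(Individual(id=member, sex=sex))
        sexes[member] = sex
        if father or mother:
            parents[member] = (father, mother)

    founder_pair = ("G1-1", "G1-2")
    add(founder_pair[0], "male")
    add(founder_pair[1], "female")
    couples = [founder_pair]
    counter = 3
    total_offspring = 0
    for gen in range(2, spec.generations + 1):
        next_couples = []
        for father, mother in couples:
            if sexes[father] == "female":  # normalise couple orientation
                father, mother = mother, father
            n_off = spec.draw_offspring(struct_rng)
            total_offspring += n_off
            for _ in range(n_off):
                sex = "male" if struct_rng.random() < 0.5 else "female"
                child = f"G{gen}-{counter}"
                counter += 1
                add(child, sex, father, mother)
                if gen < spec.generations:
                    spouse = f"G{gen}-{counter}s"
                    counter += 1
                    add(spouse, "female" if sex == "male" else "male")
                    next_couples.append((child, spouse))
        couples = next_couples
    if total_offspring == 0:
        raise ValueError("degenerate pedigree: no offspring were produced")

    # causal-allele descent (dominant, single copy entering via one founder)
    if config.causal.founder_carrier == "random":
        origin = founder_pair[int(causal_rng.integers(0, 2))]
    else:
        origin = config.causal.founder_carrier
        if origin not in sexes:
            raise ValueError(f"founder_carrier {origin!r} not in pedigree")
    carriers = {origin}
    for ind in individuals:  # construction order puts parents before children
        links = parents.get(ind.id)
        if links is None:
            continue
        carrier_parents = [p for p in links if p in carriers]
        # het parent transmits the alternate allele with probability 1/2
        if carrier_parents and any(causal_rng.random() < 0.5 for _ in carrier_parents):
            carriers.add(ind.id)

    affected: list[str] = []
    phenocopies: list[str] = []
    for ind in individuals:
        if ind.id in carriers:
            if pheno_rng.random() < config.causal.penetrance:
                affected.append(ind.id)
        elif pheno_rng.random() < config.causal.phenocopy_rate:
            affected.append(ind.id)
            phenocopies.append(ind.id)

    affected_set = set(affected)
    final = [
        Individual(
            id=i.id,
            sex=i.sex,
            affection="cancer" if i.id in affected_set else "unaffected",
        )
        for i in individuals
    ]
    return _PedigreeTruth(
        pedigree=Pedigree(final, parents),
        carriers=tuple(sorted(carriers, key=[i.id for i in individuals].index)),
        affected=tuple(affected),
        phenocopies=tuple(phenocopies),
    )


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate the pedigree with affection status assigned.

    Carriers are affected with probability ``penetrance``; non-carriers
    with probability ``phenocopy_rate``.  Deterministic given the seed.
    """
    return _build_pedigree(config).pedigree


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

_BASES = np.array(["A", "C", "G", "T"])

CAUSAL_VARIANT = Variant(
    chrom="7",
    pos=10_000_000,
    ref="A",
    alt="C",
    gene="CAUSAL1",
    func_class="nonsynonymous_SNV",
    maf_1000g=None,  # novel: absent from the reference panel
)


def _background_variants(config: SimulationConfig) -> tuple[list[Variant], np.ndarray]:
    rng = _rng(config.seed, _STREAM_BACKGROUND)
    spec = config.background
    n = spec.n_variants
    mafs = spec.draw_mafs(rng, n)
    classes, weights = zip(*spec.func_class_weights) if spec.func_class_weights else ((), ())
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum() if len(weights) else weights
    chroms = rng.integers(1, 23, size=n)
    positions = set()
    variants: list[Variant] = []
    for j in range(n):
        while True:
            pos = int(rng.integers(1_000_000, 200_000_000))
            if (int(chroms[j]), pos) not in positions:
                positions.add((int(chroms[j]), pos))
                break
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        func = str(rng.choice(np.array(classes), p=weights)) if len(weights) else "other"
        variants.append(
            Variant(
                chrom=str(int(chroms[j])),
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                gene=f"BG{j:04d}",
                func_class=func,
                maf_1000g=float(mafs[j]),  # annotation assumed accurate
            )
        )
    return variants, mafs


def _call_cache(variant: Variant) -> tuple[GenotypeCall, GenotypeCall, GenotypeCall]:
    return (
        GenotypeCall((variant.ref, variant.ref)),
        GenotypeCall((variant.ref, variant.alt)),
        GenotypeCall((variant.alt, variant.alt)),
    )


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[GenotypeTable, TruthRecord]:
    """Simulate family genotypes: causal variant heterozygous along its
    founder descent, background variants Hardy–Weinberg in founders and
    gene-dropped (one allele per parent, uniformly, independently per
    variant).

    ``pedigree`` must be the pedigree produced by :func:`simulate_pedigree`
    with the same config, so that genotypes stay consistent with the
    affection assignments.
    """
    truth = _build_pedigree(config)
    if set(pedigree.members) != set(truth.pedigree.members):
        raise ValueError("pedigree does not match the one generated by this config")

    bg_variants, mafs = _background_variants(config)
    rng = _rng(config.seed, _STREAM_BACKGROUND, 1)  # transmission sub-stream
    n = len(bg_variants)
    members = truth.pedigree.members  # parents precede children
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for member in members:
        links = truth.pedigree.parents.get(member)
        if links is None:
            hap_a = (rng.random(n) < mafs).astype(np.int8)
            hap_b = (rng.random(n) < mafs).astype(np.int8)
        else:
            transmitted = []
            for parent in links:
                pa, pb = haplotypes[parent]
                pick = rng.integers(0, 2, size=n).astype(bool)
                transmitted.append(np.where(pick, pa, pb))
            hap_a, hap_b = transmitted
        haplotypes[member] = (hap_a, hap_b)

    variants = [CAUSAL_VARIANT] + bg_variants
    calls: dict[tuple, GenotypeCall] = {}
    causal_calls = _call_cache(CAUSAL_VARIANT)
    carrier_set = set(truth.carriers)
    for member in members:
        calls[(CAUSAL_VARIANT.key, member)] = causal_calls[1 if member in carrier_set else 0]
    for j, variant in enumerate(bg_variants):
        cache = _call_cache(variant)
        for member in members:
            hap_a, hap_b = haplotypes[member]
            calls[(variant.key, member)] = cache[int(hap_a[j]) + int(hap_b[j])]

    table = GenotypeTable(variants, members, calls)
    record = TruthRecord(
        causal_key=CAUSAL_VARIANT.key,
        true_carriers=truth.carriers,
        affected=truth.affected,
        phenocopies=truth.phenocopies,
    )
    return table, record


def simulate_cohort(
    variants: Sequence[Variant], config: SimulationConfig
) -> GenotypeTable:
    """Unrelated background cohort under Hardy–Weinberg at each variant.

    Stands in for the research samples co-sequenced with the family; the
    causal variant has population frequency 0 and is never carried.
    """
    rng = _rng(config.seed, _STREAM_COHORT)
    samples = [f"BGC{i:03d}" for i in range(1, config.n_background_cohort + 1)]
    calls: dict[tuple, GenotypeCall] = {}
    for variant in variants:
        maf = variant.maf_1000g or 0.0
        cache = _call_cache(variant)
        counts = rng.binomial(2, maf, size=len(samples))
        for sample, count in zip(samples, counts):
            calls[(variant.key, sample)] = cache[int(count)]
    return GenotypeTable(list(variants), samples, calls)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def inject_errors(
    table: GenotypeTable, config: SimulationConfig
) -> tuple[GenotypeTable, list[tuple]]:
    """Perturb genotypes cell-wise: set missing with probability
    ``missing_rate``, else replace with a uniformly chosen *different*
    genotype with probability ``genotype_error_rate``.

    Returns the perturbed table and a log of
    ``(variant key, sample, old, new)`` for every changed cell.
    """
    noise = config.noise
    rng = _rng(config.seed, _STREAM_ERRORS)
    log: list[tuple] = []
    if noise.missing_rate == 0.0 and noise.genotype_error_rate == 0.0:
        return table, log
    calls = dict(table.calls)
    for variant in table.variants:
        cache = _call_cache(variant)
        for sample in table.samples:
            u = rng.random()
            old = table.call(variant, sample)
            if u < noise.missing_rate:
                new = MISSING_CALL
            elif u < noise.missing_rate + noise.genotype_error_rate:
                options = [g for g in cache if g != old]
                new = options[int(rng.integers(0, len(options)))]
            else:
                continue
            if new != old:
                calls[(variant.key, sample)] = new
                log.append((variant.key, sample, old, new))
    return GenotypeTable(table.variants, table.samples, calls), log


# --------------------------------------------------------------------------
# recovery benchmark
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryResult:
    """Monte-Carlo summary of causal-variant recovery."""

    n_reps: int
    n_retained: int
    mean_shortlist_size: float
    mean_retained_size: float

    @property
    def retention_rate(self) -> float:
        return self.n_retained / self.n_reps if self.n_reps else float("nan")


def recovery_benchmark(
    config: SimulationConfig,
    reps: int,
    assumed_carriers: Literal["true_carriers", "affected"] = "true_carriers",
    discovery_n: int = 3,
) -> RecoveryResult:
    """Simulate ``reps`` datasets and run the full pipeline on each.

    Per replicate: simulate pedigree, genotypes and background cohort,
    apply noise, run the discovery cascade with the first ``discovery_n``
    assumed carriers as the sequenced trio stand-in, then the segregation
    filter with the whole assumed carrier set (permissive missing-genotype
    handling, since noisy data may lack calls).  ``assumed_carriers``
    selects the study design being emulated: ``"true_carriers"`` assumes
    only affected true carriers (the ideal analysis), ``"affected"``
    assumes every affected individual — phenocopies included, which is the
    failure mode the benchmark quantifies.

    Reports the fraction of replicates retaining the planted causal
    variant and mean shortlist sizes.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_retained = 0
    shortlist_sizes: list[int] = []
    retained_sizes: list[int] = []
    n_used = 0
    for rep in range(reps):
        rep_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(_STREAM_BENCHMARK, rep))
            .generate_state(1)[0]
            % (2**31)
        )
        rep_config = replace(config, seed=rep_seed)
        pedigree = simulate_pedigree(rep_config)
        table, truth = simulate_genotypes(pedigree, rep_config)
        noisy, _ = inject_errors(table, rep_config)
        cohort = simulate_cohort(table.variants, rep_config)
        if assumed_carriers == "true_carriers":
            assumed = [i for i in truth.affected if i in set(truth.true_carriers)]
        else:
            assumed = list(truth.affected)
        if not assumed:
            continue  # no affected individuals: the study could not start
        n_used += 1
        discovery_ids = assumed[: max(1, discovery_n)]
        shortlist, _ledger = discovery_cascade(noisy, discovery_ids, cohort)
        ledger = segregation_filter(shortlist, noisy, assumed, missing="permissive")
        shortlist_sizes.append(len(shortlist))
        retained_sizes.append(ledger.n_retained)
        if truth.causal_key in set(ledger.retained):
            n_retained += 1
    return RecoveryResult(
        n_reps=n_used,
        n_retained=n_retained,
        mean_shortlist_size=float(np.mean(shortlist_sizes)) if shortlist_sizes else 0.0,
        mean_retained_size=float(np.mean(retained_sizes)) if retained_sizes else 0.0,
    )
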