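"""Shared fixtures: packaged tables and seeded random genotype tables.

The random-table generator and the brute-force conjunction oracle live
here so that unit tests and acceptance-level property checks exercise the
same independent reference implementation: the oracle evaluates each
filter as a pointwise predicate per variant, with none of the cascade's
staging or ledger bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pytest

from famseg import fixtures
from famseg.model import (
    FUNC_CLASSES,
    GenotypeCall,
    GenotypeTable,
    MISSING_CALL,
    Variant,
)


@pytest.fixture(scope="session")
def table1() -> GenotypeTable:
    return fixtures.load_table1()


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_table2()


@pytest.fixture(scope="session")
def table3():
    return fixtures.load_table3()


_BASES = ["A", "C", "G", "T"]
_CLASSES = sorted(FUNC_CLASSES)


def random_genotype_table(
    rng: np.random.Generator,
    max_variants: int = 50,
    max_samples: int = 10,
    missing_prob: float = 0.05,
) -> GenotypeTable:
    """A random biallelic genotype table with mixed annotations."""
    n_variants = int(rng.integers(1, max_variants + 1))
    n_samples = int(rng.integers(2, max_samples + 1))
    samples = [f"S{i}" for i in range(n_samples)]
    variants = []
    used = set()
    for _ in range(n_variants):
        while True:
            chrom = str(rng.integers(1, 23))
            pos = int(rng.integers(1, 10_000_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        maf = None if rng.random() < 0.3 else float(rng.random() * 0.5)
        variants.append(
            Variant(
                chrom=chrom,
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                gene=f"G{len(variants)}",
                func_class=_CLASSES[int(rng.integers(0, len(_CLASSES)))],
                maf_1000g=maf,
            )
        )
    calls = {}
    for v in variants:
        genotypes = (
            GenotypeCall((v.ref, v.ref)),
            GenotypeCall((v.ref, v.alt)),
            GenotypeCall((v.alt, v.alt)),
        )
        for s in samples:
            if rng.random() < missing_prob:
                calls[(v.key, s)] = MISSING_CALL
            else:
                calls[(v.key, s)] = genotypes[int(rng.integers(0, 3))]
    return GenotypeTable(variants, samples, calls)


def cascade_conjunction_oracle(table, discovery_ids, background, config):
    """Brute-force reference for the discovery cascade: per-variant
    conjunction of the four predicates, no staging."""
    kept = []
    for v in table.variants:
        if not all(table.call(v, s).carries(v.alt) for s in discovery_ids):
            continue
        if v.maf_1000g is not None and v.maf_1000g > config.maf_threshold:
            continue
        if v.func_class not in config.kept_func_classes:
            continue
        if background is not None and background.has_variant(v.key):
            n = sum(
                background.call(v, s).carries(v.alt) for s in background.samples
            )
            if n > config.background_max_carriers:
                continue
        kept.append(v.key)
    return kept


def segregation_conjunction_oracle(shortlist, table, carriers):
    """Brute-force reference for the segregation filter: a variant is
    retained iff every carrier's (non-missing) call carries the alternate
    allele."""
    retained = []
    for v in shortlist:
        if all(table.call(v, c).carries(v.alt) for c in carriers):
            retained.append(v.key)
    return retained
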