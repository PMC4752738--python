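"""Discovery cascade: per-filter behaviour, ledger accounting, and
equivalence with the pointwise conjunction oracle."""

import numpy as np
import pytest

from famseg.discovery import (
    CascadeConfig,
    cohort_occurrence_filter,
    discovery_cascade,
    frequency_filter,
    functional_filter,
    shared_variants,
)
from famseg.model import FUNC_CLASSES, GenotypeCall, GenotypeTable, MISSING_CALL, Variant

from conftest import cascade_conjunction_oracle, random_genotype_table


def build_table(rows, samples):
    """rows: list of (Variant, {sample: 'A/C' or None})."""
    variants = [v for v, _ in rows]
    calls = {}
    for v, genotypes in rows:
        for s in samples:
            g = genotypes.get(s)
            calls[(v.key, s)] = (
                MISSING_CALL if g is None else GenotypeCall.from_string(g)
            )
    return GenotypeTable(variants, samples, calls)


def _variant(i, **kw):
    kw.setdefault("func_class", "nonsynonymous_SNV")
    return Variant("1", 1000 + i, "A", "C", gene=f"G{i}", **kw)


class TestSharedVariants:
    def test_planted_shared_subset(self):
        """Brute-force check: exactly the planted tri-shared variants come
        back from a 10-variant table."""
        samples = ["a", "b", "c"]
        rng = np.random.default_rng(7)
        planted = {1, 4, 6, 9}
        rows = []
        for i in range(10):
            if i in planted:
                genotypes = {s: "A/C" for s in samples}
            else:
                spoiled = samples[int(rng.integers(0, 3))]
                genotypes = {s: ("A/A" if s == spoiled else "A/C") for s in samples}
            rows.append((_variant(i), genotypes))
        table = build_table(rows, samples)
        result = {v.pos - 1000 for v in shared_variants(table, samples)}
        assert result == planted

    def test_missing_call_breaks_sharing(self):
        samples = ["a", "b"]
        table = build_table([(_variant(0), {"a": "A/C", "b": None})], samples)
        assert shared_variants(table, samples) == []

    def test_hom_alt_counts_as_shared(self):
        samples = ["a", "b"]
        table = build_table([(_variant(0), {"a": "C/C", "b": "A/C"})], samples)
        assert len(shared_variants(table, samples)) == 1

    def test_errors(self):
        table = build_table([(_variant(0), {"a": "A/C"})], ["a"])
        with pytest.raises(ValueError):
            shared_variants(table, [])
        with pytest.raises(KeyError):
            shared_variants(table, ["nobody"])


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "maf,threshold,kept",
        [
            (0.25, 0.20, False),  # strictly above: excluded
            (0.20, 0.20, True),  # equality retained
            (0.0023, 0.20, True),
            (None, 0.20, True),  # novel: retained
        ],
    )
    def test_threshold_semantics(self, maf, threshold, kept):
        v = _variant(0, maf_1000g=maf)
        assert (v in frequency_filter([v], threshold)) is kept

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            frequency_filter([], 1.5)


class TestFunctionalFilter:
    @pytest.mark.parametrize(
        "func_class,kept",
        [
            ("synonymous_SNV", False),
            ("nonexonic", False),
            ("nonsynonymous_SNV", True),
            ("nonframeshift_deletion", True),
            ("stopgain_SNV", True),
            ("frameshift_deletion", True),
        ],
    )
    def test_default_classes(self, func_class, kept):
        v = _variant(0, func_class=func_class)
        assert (v in functional_filter([v])) is kept


class TestOccurrenceFilter:
    @pytest.mark.parametrize("n_carriers,kept", [(0, True), (1, True), (2, False)])
    def test_carrier_boundary(self, n_carriers, kept):
        v = _variant(0)
        samples = [f"bg{i}" for i in range(5)]
        genotypes = {
            s: ("A/C" if i < n_carriers else "A/A") for i, s in enumerate(samples)
        }
        background = build_table([(v, genotypes)], samples)
        assert (v in cohort_occurrence_filter([v], background, max_carriers=1)) is kept

    def test_absent_variant_has_no_carriers(self):
        v = _variant(0)
        other = _variant(1)
        background = build_table([(other, {"bg0": "A/C"})], ["bg0"])
        assert cohort_occurrence_filter([v], background, 0) == [v]


class TestCascade:
    def test_planted_stage_bookkeeping(self):
        """Each stage removes a known planted subset; the ledger reproduces
        the construction."""
        samples = ["a", "b", "c"]
        rows = [
            (_variant(0), {s: "A/C" for s in samples}),  # survives everything
            (_variant(1), {"a": "A/A", "b": "A/C", "c": "A/C"}),  # lost: not shared
            (_variant(2, maf_1000g=0.5), {s: "A/C" for s in samples}),  # lost: common
            (_variant(3, func_class="synonymous_SNV"), {s: "A/C" for s in samples}),
            (_variant(4), {s: "A/C" for s in samples}),  # lost: background
        ]
        table = build_table(rows, samples)
        bg_samples = ["bg0", "bg1"]
        background = build_table(
            [(_variant(4), {s: "A/C" for s in bg_samples})], bg_samples
        )
        shortlist, ledger = discovery_cascade(table, samples, background)
        assert [v.pos - 1000 for v in shortlist] == [0]
        assert ledger.counts() == {
            "shared": (5, 1),
            "frequency": (4, 1),
            "functional": (3, 1),
            "background": (2, 1),
        }

    def test_disabled_filters_equal_shared(self):
        rng = np.random.default_rng(3)
        table = random_genotype_table(rng, max_variants=30)
        ids = table.samples[:2]
        config = CascadeConfig(
            maf_threshold=1.0,
            kept_func_classes=frozenset(FUNC_CLASSES),
            background_max_carriers=10**9,
        )
        shortlist, _ = discovery_cascade(table, ids, None, config)
        assert [v.key for v in shortlist] == [
            v.key for v in shared_variants(table, ids)
        ]

    def test_empty_table(self):
        table = GenotypeTable([], ["a"], {})
        shortlist, ledger = discovery_cascade(table, ["a"], None)
        assert shortlist == []
        assert all(n == (0, 0) for n in ledger.counts().values())

    def test_oracle_equivalence_on_random_tables(self):
        """The staged cascade equals the pointwise predicate conjunction."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            table = random_genotype_table(rng)
            background = random_genotype_table(rng, max_variants=20)
            ids = table.samples[: int(rng.integers(1, min(4, len(table.samples)) + 1))]
            config = CascadeConfig(
                maf_threshold=float(rng.random()),
                background_max_carriers=int(rng.integers(0, 3)),
            )
            shortlist, ledger = discovery_cascade(table, ids, background, config)
            expected = cascade_conjunction_oracle(table, ids, background, config)
            assert [v.key for v in shortlist] == expected
            # anti-monotone pipeline: chained ledger counts partition the input
            assert ledger.stages[0].n_input == len(table.variants)
            assert ledger.stages[-1].n_output == len(shortlist)

    def test_monotone_in_config(self):
        """Relaxing any threshold never shrinks the shortlist."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            table = random_genotype_table(rng)
            ids = table.samples[:2]
            background = random_genotype_table(rng, max_variants=20)
            tight = CascadeConfig(
                maf_threshold=0.1,
                kept_func_classes=frozenset({"nonsynonymous_SNV"}),
                background_max_carriers=0,
            )
            loose = CascadeConfig(
                maf_threshold=0.4,
                kept_func_classes=frozenset(
                    {"nonsynonymous_SNV", "stopgain_SNV", "synonymous_SNV"}
                ),
                background_max_carriers=2,
            )
            small, _ = discovery_cascade(table, ids, background, tight)
            large, _ = discovery_cascade(table, ids, background, loose)
            assert {v.key for v in small} <= {v.key for v in large}
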