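"""Obligate-carrier segregation filter: the worked family example,
ledger partitioning, scenario chaining, and oracle equivalence."""

import itertools

import numpy as np
import pytest

from famseg import fixtures
from famseg.model import GenotypeCall, GenotypeTable, MISSING_CALL, Variant
from famseg.segregation import (
    CarrierSet,
    MissingGenotypeError,
    Scenario,
    carries_alt,
    order_invariance_check,
    scenario_analysis,
    segregation_filter,
)

from conftest import random_genotype_table, segregation_conjunction_oracle


def genes_of(table, keys):
    return sorted(table.variant_by_key(k).gene for k in keys)


class TestCarriesAlt:
    @pytest.mark.parametrize(
        "genotype,alt,expected",
        [
            ("C/T", "T", True),
            ("C/C", "T", False),
            ("GGA/-", "-", True),  # indel deletion allele
            ("T/T", "T", True),  # homozygous alternate is a carrier
        ],
    )
    def test_dominant_predicate(self, genotype, alt, expected):
        assert carries_alt(GenotypeCall.from_string(genotype), alt) is expected

    def test_missing_strict_raises(self):
        with pytest.raises(MissingGenotypeError):
            carries_alt(MISSING_CALL, "T", missing="strict")

    def test_missing_permissive_is_unknown(self):
        assert carries_alt(MISSING_CALL, "T", missing="permissive") is None


class TestFamilyExample:
    def test_five_cancer_carriers_retain_twelve(self, table1):
        ledger = segregation_filter(
            table1.variants, table1, fixtures.CANCER_CARRIERS
        )
        assert ledger.n_retained == 12
        assert ledger.excluded_count("Co-634") == 15
        assert ledger.excluded_count("Co-667") == 7
        assert ledger.n_excluded == 22
        # the sequenced trio shares everything, so nothing attributes to it
        for member in fixtures.DISCOVERY_TRIO:
            assert ledger.excluded_count(member) == 0
        assert genes_of(table1, ledger.retained) == sorted(
            [
                "DZIP1L", "PCOLCE2", "IGSF10", "SUCNR1", "OR13C8", "EPB41L4B",
                "SEC16A", "NOTCH1", "TAS2R7", "SF3A1", "GAL3ST1", "TRIOBP",
            ]
        )

    def test_empty_carrier_set_is_vacuous(self, table1):
        ledger = segregation_filter(table1.variants, table1, CarrierSet())
        assert ledger.n_retained == 34
        assert ledger.n_excluded == 0

    def test_all_eight_members_leave_four(self, table1):
        """Brute-force-checkable: requiring every typed member to carry
        leaves only the variants heterozygous across the whole family."""
        ledger = segregation_filter(table1.variants, table1, table1.samples)
        assert genes_of(table1, ledger.retained) == [
            "IGSF10", "NOTCH1", "SEC16A", "SUCNR1",
        ]

    def test_hom_alt_carrier_not_excluded(self, table1):
        """Co-771 is T/T at the X-linked COL4A5 variant and still counts as
        a carrier under the dominant predicate."""
        col4a5 = table1.variant_by_key(("X", 107844666, "G", "T"))
        ledger = segregation_filter([col4a5], table1, ("Co-441", "Co-666", "Co-771"))
        assert ledger.n_retained == 1

    def test_unknown_carrier(self, table1):
        with pytest.raises(KeyError):
            segregation_filter(table1.variants, table1, ("nobody",))

    def test_duplicate_carriers_rejected(self, table1):
        with pytest.raises(ValueError):
            CarrierSet(("Co-441", "Co-441"))


class TestScenarios:
    def test_cumulative_polyp_scenarios(self, table1):
        """Genotype-computed exclusions for the three polyp-carrier
        assumptions, applied cumulatively after the five cancer cases."""
        steps = scenario_analysis(
            table1.variants, table1, fixtures.CANCER_CARRIERS, fixtures.POLYP_SCENARIOS
        )
        by_label = {s.label: s for s in steps}
        assert by_label["tubulovillous-adenomas"].newly_excluded_genes(
            table1.variants
        ) == {"OR13C8", "EPB41L4B", "TAS2R7"}
        assert by_label["tubular-adenomas"].newly_excluded_genes(table1.variants) == {
            "DZIP1L", "PCOLCE2",
        }
        assert by_label["hyperplastic-polyps"].newly_excluded_genes(
            table1.variants
        ) == {"SF3A1", "GAL3ST1", "TRIOBP"}
        # narrated sets are a subset of what the genotypes imply
        for label, narrated in fixtures.NARRATED_SCENARIO_EXCLUSIONS.items():
            assert narrated <= by_label[label].newly_excluded_genes(table1.variants)

    def test_final_set_equals_one_shot_union(self, table1):
        steps = scenario_analysis(
            table1.variants, table1, fixtures.CANCER_CARRIERS, fixtures.POLYP_SCENARIOS
        )
        union = fixtures.CANCER_CARRIERS + ("Co-652", "Co-692", "Co-657")
        one_shot = segregation_filter(table1.variants, table1, union)
        assert set(steps[-1].retained_after) == set(one_shot.retained)

    def test_carrier_of_everything_excludes_nothing(self, table1):
        """Adding an individual who carries every variant the base set
        retained must exclude nothing: Co-441 carries all 34, so assuming
        the other seven first and then Co-441 changes nothing."""
        base = tuple(s for s in table1.samples if s != "Co-441")
        steps = scenario_analysis(
            table1.variants,
            table1,
            base,
            (Scenario("redundant", ("Co-441",)),),
        )
        assert steps[0].newly_excluded == ()


class TestInvariantsAndOracle:
    def test_ledger_partitions_shortlist(self, table1):
        ledger = segregation_filter(table1.variants, table1, fixtures.CANCER_CARRIERS)
        excluded = [k for keys in ledger.per_carrier.values() for k in keys]
        assert len(excluded) == len(set(excluded))
        assert set(excluded) | set(ledger.retained) == {v.key for v in table1.variants}

    def test_order_invariance_exhaustive_on_family(self, table1):
        assert order_invariance_check(
            table1.variants, table1, fixtures.CANCER_CARRIERS
        )

    def test_attribution_depends_on_order_but_retention_does_not(self, table1):
        reversed_order = tuple(reversed(fixtures.CANCER_CARRIERS))
        forward = segregation_filter(table1.variants, table1, fixtures.CANCER_CARRIERS)
        backward = segregation_filter(table1.variants, table1, reversed_order)
        assert set(forward.retained) == set(backward.retained)
        assert backward.excluded_count("Co-667") > forward.excluded_count("Co-667")

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            table = random_genotype_table(rng, missing_prob=0.0)
            n_carriers = int(rng.integers(1, min(5, len(table.samples)) + 1))
            carriers = list(table.samples[:n_carriers])
            ledger = segregation_filter(table.variants, table, carriers)
            assert list(ledger.retained) == segregation_conjunction_oracle(
                table.variants, table, carriers
            )

    def test_adding_carrier_never_grows_retained(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            table = random_genotype_table(rng, missing_prob=0.0)
            carriers = list(table.samples)
            smaller = segregation_filter(table.variants, table, carriers[:-1])
            larger = segregation_filter(table.variants, table, carriers)
            assert set(larger.retained) <= set(smaller.retained)

    def test_order_invariance_random_tables(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            table = random_genotype_table(rng, missing_prob=0.0, max_samples=6)
            carriers = table.samples[: min(4, len(table.samples))]
            assert order_invariance_check(table.variants, table, carriers)


class TestPermissiveMode:
    def test_missing_is_unknown_not_exclusion(self):
        v = Variant("1", 100, "A", "C", gene="G", func_class="nonsynonymous_SNV")
        table = GenotypeTable(
            [v],
            ["a", "b"],
            {(v.key, "a"): GenotypeCall(("A", "C")), (v.key, "b"): MISSING_CALL},
        )
        with pytest.raises(MissingGenotypeError):
            segregation_filter([v], table, ("a", "b"), missing="strict")
        ledger = segregation_filter([v], table, ("a", "b"), missing="permissive")
        assert ledger.n_retained == 1
        assert ledger.unknown_cells == ((v.key, "b"),)
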