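"""Synthetic-data generator: determinism, Mendelian and Hardy–Weinberg
consistency, noise calibration, and causal-variant recovery."""

import numpy as np
import pytest

from famseg.io import write_vcf
from famseg.simulate import (
    BackgroundSpec,
    CausalSpec,
    NoiseSpec,
    PedigreeSpec,
    SimulationConfig,
    inject_errors,
    recovery_benchmark,
    simulate_cohort,
    simulate_genotypes,
    simulate_pedigree,
)
from famseg.model import Variant


def config(seed=7, **kw):
    return SimulationConfig(seed=seed, **kw)


class TestPedigree:
    def test_seed_determinism(self):
        a = simulate_pedigree(config())
        b = simulate_pedigree(config())
        assert a.members == b.members
        assert a.parents == b.parents
        assert all(a[m].affection == b[m].affection for m in a.members)

    def test_different_seed_differs(self):
        a = simulate_pedigree(config(seed=1))
        b = simulate_pedigree(config(seed=2))
        assert any(a[m].affection != b[m].affection for m in a.members) or (
            a.members != b.members
        )

    def test_three_generations_present(self):
        ped = simulate_pedigree(config())
        generations = {m.split("-")[0] for m in ped.members}
        assert {"G1", "G2", "G3"} <= generations

    def test_full_penetrance_no_phenocopies(self):
        cfg = config(causal=CausalSpec(penetrance=1.0, phenocopy_rate=0.0))
        _, truth = simulate_genotypes(simulate_pedigree(cfg), cfg)
        assert set(truth.affected) == set(truth.true_carriers)
        assert truth.phenocopies == ()

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            PedigreeSpec(offspring_per_couple=0)

    def test_penetrance_binomial_calibration(self):
        """Across replicates the affected fraction among carriers tracks
        the penetrance within 3 standard errors."""
        n_carriers = n_affected_carriers = 0
        for rep in range(800):
            cfg = config(
                seed=10_000 + rep,
                causal=CausalSpec(penetrance=0.8, phenocopy_rate=0.05),
                background=BackgroundSpec(n_variants=0),
            )
            _, truth = simulate_genotypes(simulate_pedigree(cfg), cfg)
            n_carriers += len(truth.true_carriers)
            n_affected_carriers += len(
                set(truth.true_carriers) & set(truth.affected)
            )
        frac = n_affected_carriers / n_carriers
        se = np.sqrt(0.8 * 0.2 / n_carriers)
        assert abs(frac - 0.8) < 3 * se


class TestGenotypes:
    def test_mendelian_consistency_exhaustive(self):
        """Every child allele at every variant is present in the
        corresponding parent's genotype (error-free run)."""
        cfg = config(background=BackgroundSpec(n_variants=60))
        ped = simulate_pedigree(cfg)
        table, _ = simulate_genotypes(ped, cfg)
        for child, (father, mother) in ped.parents.items():
            for v in table.variants:
                child_alleles = table.call(v, child).alleles
                pat = table.call(v, father).alleles
                mat = table.call(v, mother).alleles
                # one allele traceable to each parent, in some assignment
                a, b = child_alleles
                assert (a in pat and b in mat) or (a in mat and b in pat)

    def test_causal_carriers_match_truth(self):
        cfg = config()
        ped = simulate_pedigree(cfg)
        table, truth = simulate_genotypes(ped, cfg)
        causal = table.variant_by_key(truth.causal_key)
        assert set(table.carrier_samples(causal)) == set(truth.true_carriers)
        # novel variant: no population frequency annotation
        assert causal.maf_1000g is None

    def test_causal_absent_from_unrelated_cohort(self):
        """At population frequency zero the causal allele exists only via
        the planted founder's descent, never in unrelated samples."""
        cfg = config(n_background_cohort=500)
        ped = simulate_pedigree(cfg)
        table, truth = simulate_genotypes(ped, cfg)
        cohort = simulate_cohort(table.variants, cfg)
        causal = table.variant_by_key(truth.causal_key)
        assert cohort.carrier_samples(causal) == []

    def test_hardy_weinberg_founder_frequencies(self):
        """Unrelated genotypes at MAF 0.5 hit 0.25/0.5/0.25 within 3 SE."""
        v = Variant("1", 100, "A", "C", gene="HW", func_class="nonsynonymous_SNV",
                    maf_1000g=0.5)
        cfg = config(n_background_cohort=10_000)
        cohort = simulate_cohort([v], cfg)
        counts = {0: 0, 1: 0, 2: 0}
        for s in cohort.samples:
            counts[cohort.call(v, s).count("C")] += 1
        n = len(cohort.samples)
        for dose, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(counts[dose] / n - expected) < 3 * se

    def test_vcf_output_byte_identical_under_seed(self, tmp_path):
        for name in ("a.vcf", "b.vcf"):
            cfg = config(seed=11)
            table, _ = simulate_genotypes(simulate_pedigree(cfg), cfg)
            write_vcf(table, tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_mismatched_pedigree_rejected(self):
        ped = simulate_pedigree(config(seed=1))
        with pytest.raises(ValueError):
            simulate_genotypes(ped, config(seed=99, pedigree=PedigreeSpec(generations=4)))


class TestInjectErrors:
    def test_zero_rates_identity(self):
        cfg = config()
        table, _ = simulate_genotypes(simulate_pedigree(cfg), cfg)
        perturbed, log = inject_errors(table, cfg)
        assert log == []
        assert perturbed == table

    def test_missing_rate_one_blanks_everything(self):
        cfg = config(noise=NoiseSpec(missing_rate=1.0))
        table, _ = simulate_genotypes(simulate_pedigree(cfg), cfg)
        perturbed, log = inject_errors(table, cfg)
        assert all(
            perturbed.call(v, s).is_missing
            for v in perturbed.variants
            for s in perturbed.samples
        )
        assert len(log) == len(table.variants) * len(table.samples)

    def test_error_rate_binomial_calibration(self):
        """1% errors over ~10,000 cells lands within 3 SE of 100."""
        cfg = config(
            n_background_cohort=100,
            background=BackgroundSpec(n_variants=99),
            noise=NoiseSpec(genotype_error_rate=0.01),
        )
        table, _ = simulate_genotypes(simulate_pedigree(cfg), cfg)
        cohort = simulate_cohort(table.variants, cfg)  # 100 x 100 cells
        _, log = inject_errors(cohort, cfg)
        n_cells = len(cohort.variants) * len(cohort.samples)
        expected = 0.01 * n_cells
        se = np.sqrt(n_cells * 0.01 * 0.99)
        assert abs(len(log) - expected) < 3 * se

    def test_log_records_old_and_new(self):
        cfg = config(noise=NoiseSpec(genotype_error_rate=0.2))
        table, _ = simulate_genotypes(simulate_pedigree(cfg), cfg)
        perturbed, log = inject_errors(table, cfg)
        assert log
        for key, sample, old, new in log:
            assert old != new
            assert perturbed.call(key, sample) == new


class TestRecovery:
    def test_ideal_conditions_always_retain_causal(self):
        result = recovery_benchmark(config(seed=3), reps=60)
        assert result.retention_rate == 1.0
        assert result.mean_retained_size >= 1.0

    def test_retention_nonincreasing_in_error_rate(self):
        rates = [0.0, 0.1]
        retentions = []
        for rate in rates:
            cfg = config(seed=5, noise=NoiseSpec(genotype_error_rate=rate))
            retentions.append(recovery_benchmark(cfg, reps=80).retention_rate)
        assert retentions[1] <= retentions[0] == 1.0

    def test_phenocopy_contaminated_carrier_set_hurts(self):
        clean = recovery_benchmark(config(seed=9), reps=80).retention_rate
        contaminated = recovery_benchmark(
            config(seed=9, causal=CausalSpec(penetrance=1.0, phenocopy_rate=0.3)),
            reps=80,
            assumed_carriers="affected",
        ).retention_rate
        assert contaminated < clean == 1.0

    def test_deterministic_given_seed(self):
        a = recovery_benchmark(config(seed=21), reps=20)
        b = recovery_benchmark(config(seed=21), reps=20)
        assert a == b
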