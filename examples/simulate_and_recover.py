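"""Synthetic-family recovery benchmark.

Simulates three-generation pedigrees segregating a dominant causal variant
plus a rare background variant landscape, runs the full discovery +
segregation pipeline on each replicate, and reports how often the planted
variant survives — under ideal conditions, with genotyping error, and with
phenocopies contaminating the assumed carrier set.
"""

from famseg.simulate import (
    CausalSpec,
    NoiseSpec,
    SimulationConfig,
    recovery_benchmark,
)

REPS = 200

ideal = recovery_benchmark(SimulationConfig(seed=7), reps=REPS)
print(
    f"ideal design (penetrance 1, no noise):      retention"
    f" {ideal.retention_rate:5.1%}, mean shortlist {ideal.mean_shortlist_size:.2f}"
)

noisy = recovery_benchmark(
    SimulationConfig(seed=7, noise=NoiseSpec(genotype_error_rate=0.05)), reps=REPS
)
print(
    f"5% genotype error:                          retention"
    f" {noisy.retention_rate:5.1%}, mean shortlist {noisy.mean_shortlist_size:.2f}"
)

contaminated = recovery_benchmark(
    SimulationConfig(seed=7, causal=CausalSpec(penetrance=1.0, phenocopy_rate=0.3)),
    reps=REPS,
    assumed_carriers="affected",
)
print(
    f"30% phenocopies assumed to be carriers:     retention"
    f" {contaminated.retention_rate:5.1%}, mean shortlist"
    f" {contaminated.mean_shortlist_size:.2f}"
)

print(
    "\nRetention is the fraction of replicates in which the planted causal"
    "\nvariant survives every filter: any genotyping error or phenocopy in"
    "\nthe assumed obligate-carrier set can eliminate the true variant, which"
    "\nis exactly the failure mode the deterministic carrier predicate has."
)
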