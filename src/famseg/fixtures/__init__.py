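"""Packaged desk-scale fixtures: the family-242 worked example.

Three tab-separated tables ship with the package:

- ``table1.tsv`` — the 34-variant shortlist with Sanger genotypes for 8
  family members (3 exome-sequenced, 5 typed for validation);
- ``table2.tsv`` — the 12 candidate variants surviving obligate-carrier
  segregation, with five categorical predictor calls each;
- ``table3.tsv`` — the 36 cohort-recurrent variants in the candidate
  genes, with 1000 Genomes / control / familial-case frequencies and
  per-family segregation counts.

Cells whose printed source is typographically ambiguous carry provenance
flags (``counts_ambiguous``, ``freq_ambiguous``, ``allele_as_printed``,
``prediction_string_ambiguous``); they record a curator's reading and are
not treated as exact ground truth.

The module also exports the analysis constants of the worked example: the
exome-sequenced discovery trio, the obligate-carrier order used for the
exclusion ledger, and the cumulative polyp-carrier scenarios.  For the
scenarios, both the genotype-computed exclusions and the narrated gene
sets of the source analysis are retained — they differ for two steps, and
the package always reports what the genotypes imply.
"""

from __future__ import annotations

from pathlib import Path

from ..io import read_variant_fixture
from ..model import Individual
from ..segregation import Scenario

_DIR = Path(__file__).parent

__all__ = [
    "load_table1",
    "load_table2",
    "load_table3",
    "DISCOVERY_TRIO",
    "CANCER_CARRIERS",
    "POLYP_SCENARIOS",
    "NARRATED_SCENARIO_EXCLUSIONS",
    "FAMILY242_MEMBERS",
]


def load_table1():
    """Segregation-test genotype table: 34 variants x 8 members."""
    return read_variant_fixture(_DIR / "table1.tsv", "table1")


def load_table2():
    """The 12 candidate variants with prediction profiles."""
    return read_variant_fixture(_DIR / "table2.tsv", "table2")


def load_table3():
    """The 36 cohort-recurrent variants with frequencies and family counts."""
    return read_variant_fixture(_DIR / "table3.tsv", "table3")


#: Exome-sequenced affected members (one gastric, two rectal cancers).
DISCOVERY_TRIO = ("Co-441", "Co-666", "Co-771")

#: All five cancer-affected genotyped members, in ledger attribution
#: order: the sequenced trio first, then the two Sanger-typed rectal
#: cancer cases in the order they entered the analysis.
CANCER_CARRIERS = ("Co-441", "Co-666", "Co-771", "Co-634", "Co-667")

#: Cumulative carrier-assumption scenarios using polyp findings as soft
#: affection evidence, strongest lesion first.
POLYP_SCENARIOS = (
    Scenario(
        label="tubulovillous-adenomas",
        added_carriers=("Co-652",),
        rationale="three large tubulovillous adenomas, two with high-degree dysplasia",
    ),
    Scenario(
        label="tubular-adenomas",
        added_carriers=("Co-692",),
        rationale="four small tubular adenomas and 8 hyperplastic polyps at age 75",
    ),
    Scenario(
        label="hyperplastic-polyps",
        added_carriers=("Co-657",),
        rationale="five large hyperplastic polyps at age 73",
    ),
)

#: Gene sets the source analysis narrated as excluded per scenario step.
#: The genotype-computed sets differ in two places (TAS2R7 is also lost
#: when Co-652 is assumed a carrier; PCOLCE2 also when Co-692 is), and the
#: package reports the computed sets — this mapping preserves the narrated
#: reading for comparison.
NARRATED_SCENARIO_EXCLUSIONS = {
    "tubulovillous-adenomas": frozenset({"OR13C8", "EPB41L4B"}),
    "tubular-adenomas": frozenset({"DZIP1L"}),
    "hyperplastic-polyps": frozenset({"SF3A1", "GAL3ST1", "TRIOBP"}),
}

#: The eight genotyped members with phenotype detail and sequencing role.
FAMILY242_MEMBERS = (
    Individual("Co-441", affection="cancer", phenotype_detail="gastric cancer, age 63",
               role="discovery_sequenced"),
    Individual("Co-666", affection="cancer", phenotype_detail="rectal cancer, age 50",
               role="discovery_sequenced"),
    Individual("Co-771", affection="cancer", phenotype_detail="rectal cancer, age 40",
               role="discovery_sequenced"),
    Individual("Co-634", affection="cancer", phenotype_detail="rectal cancer",
               role="validation_typed"),
    Individual("Co-667", affection="cancer", phenotype_detail="rectal cancer",
               role="validation_typed"),
    Individual("Co-652", affection="polyps",
               phenotype_detail="three large tubulovillous adenomas",
               role="validation_typed"),
    Individual("Co-692", affection="polyps",
               phenotype_detail="four tubular adenomas, 8 hyperplastic polyps",
               role="validation_typed"),
    Individual("Co-657", affection="polyps",
               phenotype_detail="five large hyperplastic polyps",
               role="validation_typed"),
)
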