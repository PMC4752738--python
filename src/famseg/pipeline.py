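"""Declarative pipeline orchestration behind the command-line interface.

A single YAML/JSON config names the inputs (VCF/PED paths, fixture tables
or TSVs in the packaged dialects), the discovery trio, the obligate-carrier
order, the carrier-assumption scenarios and every threshold.  Each stage
writes its report into the output directory, and a run log records the
config hash and package version so a run can be reproduced bit-identically
from the log alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__, fixtures
from .cohort import CohortFilterConfig, cohort_gene_filter, distinct_gene_count, intersect_candidates
from .discovery import CascadeConfig, discovery_cascade
from .io import read_variant_fixture, read_vcf, write_report
from .model import PROTEIN_ALTERING_CLASSES
from .predictions import SupportPolicy, summarize_predictions
from .segregation import Scenario, scenario_analysis, segregation_filter

__all__ = ["PipelineConfig", "run_pipeline", "load_genotype_input", "load_annotated_input"]


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are flagged in the run log."""


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration; see ``PipelineConfig.from_file``."""

    genotypes: str = "fixtures:table1"
    pedigree: Optional[str] = None
    background: Optional[str] = None
    candidates: str = "fixtures:table2"
    cohort_table: str = "fixtures:table3"
    discovery_ids: tuple = fixtures.DISCOVERY_TRIO
    carriers: tuple = fixtures.CANCER_CARRIERS
    scenarios: tuple = fixtures.POLYP_SCENARIOS
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    policy: SupportPolicy = field(default_factory=SupportPolicy)
    cohort_filter: CohortFilterConfig = field(default_factory=CohortFilterConfig)
    strict_genotypes: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        inputs = data.get("inputs", {})
        cascade_kw = dict(data.get("cascade", {}))
        if "kept_func_classes" in cascade_kw:
            cascade_kw["kept_func_classes"] = frozenset(cascade_kw["kept_func_classes"])
        policy_kw = {
            k: (frozenset(v) if isinstance(v, (list, set, tuple)) else v)
            for k, v in dict(data.get("support_policy", {})).items()
        }
        cohort_kw = dict(data.get("cohort_filter", {}))
        if "kept_func_classes" in cohort_kw:
            cohort_kw["kept_func_classes"] = frozenset(cohort_kw["kept_func_classes"])
        policy = SupportPolicy(**policy_kw)
        scenarios = tuple(
            Scenario(
                label=s["label"],
                added_carriers=tuple(s.get("add", s.get("added_carriers", ()))),
                rationale=s.get("rationale", ""),
            )
            for s in data.get("scenarios", [])
        ) or fixtures.POLYP_SCENARIOS
        return cls(
            genotypes=inputs.get("genotypes", "fixtures:table1"),
            pedigree=inputs.get("pedigree"),
            background=inputs.get("background"),
            candidates=inputs.get("candidates", "fixtures:table2"),
            cohort_table=inputs.get("cohort_table", "fixtures:table3"),
            discovery_ids=tuple(data.get("discovery_ids", fixtures.DISCOVERY_TRIO)),
            carriers=tuple(data.get("carriers", fixtures.CANCER_CARRIERS)),
            scenarios=scenarios,
            cascade=CascadeConfig(**cascade_kw),
            policy=policy,
            cohort_filter=CohortFilterConfig(policy=policy, **cohort_kw),
            strict_genotypes=bool(data.get("strict_genotypes", True)),
            raw=data,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_genotype_input(spec: str):
    """Resolve a genotype input spec: ``fixtures:table1``, a ``.vcf``
    path, or a table1-dialect TSV path."""
    if spec == "fixtures:table1":
        return fixtures.load_table1()
    path = Path(spec)
    if not path.exists():
        raise PipelineError(f"genotype input not found: {spec}")
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        return read_vcf(path)
    return read_variant_fixture(path, "table1")


def load_annotated_input(spec: str, dialect: str):
    """Resolve an annotated-table input spec (``fixtures:table2/3`` or a
    TSV path in the corresponding dialect)."""
    if spec == f"fixtures:{dialect}":
        return read_variant_fixture(fixtures._DIR / f"{dialect}.tsv", dialect)
    path = Path(spec)
    if not path.exists():
        raise PipelineError(f"{dialect} input not found: {spec}")
    return read_variant_fixture(path, dialect)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple = ("discover", "segregate", "scenarios", "annotate", "cohort"),
) -> dict[str, Any]:
    """Run the requested stages and write their reports under ``out_dir``.

    Inputs are resolved (and validated) before anything is written, so a
    missing path never leaves a partial candidate table behind.  Returns a
    summary dict mirroring the run log.
    """
    # resolve all inputs first
    table = load_genotype_input(config.genotypes)
    background = (
        load_genotype_input(config.background) if config.background else None
    )
    if config.pedigree is not None:
        from .io import read_pedigree

        pedigree = read_pedigree(config.pedigree)
        missing = [c for c in config.carriers if c not in pedigree]
        if missing:
            raise PipelineError(f"carriers absent from pedigree: {missing}")
    candidates = (
        load_annotated_input(config.candidates, "table2")
        if ("annotate" in stages or "cohort" in stages)
        else []
    )
    cohort_records = (
        load_annotated_input(config.cohort_table, "table3") if "cohort" in stages else []
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    missing_mode = "strict" if config.strict_genotypes else "permissive"
    summary: dict[str, Any] = {}

    shortlist = list(table.variants)
    if "discover" in stages:
        shortlist, ledger = discovery_cascade(
            table, config.discovery_ids, background, config.cascade
        )
        write_report(shortlist, out / "shortlist.tsv", "tsv")
        (out / "discovery_ledger.json").write_text(
            json.dumps(ledger.to_records(), indent=2) + "\n"
        )
        summary["discovery"] = {
            "n_shortlist": len(shortlist),
            "stages": ledger.counts(),
        }

    if "segregate" in stages:
        seg = segregation_filter(shortlist, table, config.carriers, missing_mode)
        retained_variants = [v for v in shortlist if v.key in set(seg.retained)]
        write_report(retained_variants, out / "candidates.tsv", "tsv")
        (out / "segregation_ledger.json").write_text(
            json.dumps(seg.to_record(), indent=2) + "\n"
        )
        summary["segregation"] = {
            "n_retained": seg.n_retained,
            "excluded_by_carrier": {
                c: seg.excluded_count(c) for c in config.carriers
            },
        }
        shortlist_for_scenarios = shortlist
        if "scenarios" in stages and config.scenarios:
            steps = scenario_analysis(
                shortlist_for_scenarios, table, config.carriers, config.scenarios,
                missing_mode,
            )
            (out / "scenarios.json").write_text(
                json.dumps(
                    [
                        {
                            "label": s.label,
                            "added_carriers": list(s.added_carriers),
                            "rationale": s.rationale,
                            "newly_excluded_genes": sorted(
                                s.newly_excluded_genes(shortlist_for_scenarios)
                            ),
                            "n_retained_after": len(s.retained_after),
                        }
                        for s in steps
                    ],
                    indent=2,
                )
                + "\n"
            )
            summary["scenarios"] = {
                s.label: len(s.newly_excluded) for s in steps
            }

    if "annotate" in stages:
        pred = summarize_predictions(candidates, config.policy)
        pred.table.to_csv(out / "predictions.tsv", sep="\t", index=False)
        summary["predictions"] = {
            "n_candidates": len(candidates),
            "n_supported": pred.n_supported,
            "n_unsupported": pred.n_unsupported,
            "unsupported_genes": pred.unsupported_genes,
        }

    if "cohort" in stages:
        matched = intersect_candidates(candidates, cohort_records)
        genes = {c.gene for c in candidates}
        filtered = cohort_gene_filter(cohort_records, genes, config.cohort_filter)
        write_report([m.variant for m in matched], out / "cohort_matches.tsv", "tsv")
        summary["cohort"] = {
            "n_candidates_in_cohort": len(matched),
            "matched_genes": sorted({m.gene for m in matched}),
            "n_cohort_variants": len(cohort_records),
            "n_cohort_genes": distinct_gene_count(cohort_records)
            if cohort_records
            else 0,
            "n_pass_gene_filter": len(filtered),
        }

    run_log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.raw,
        "stages": list(stages),
        "summary": summary,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str) + "\n")
    return summary
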