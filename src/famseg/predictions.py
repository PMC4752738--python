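"""Aggregation of categorical in-silico pathogenicity predictions.

Five predictors are consumed as categorical calls (PhyloP, SIFT,
PolyPhen2, LRT, MutationTaster); no score is ever computed here.  A
:class:`SupportPolicy` declares which category letters count as supportive
of pathogenicity, and :func:`supportive_calls` reduces a profile to a
supportive-evidence count plus a boolean "any support" flag.

Two policy knobs are deliberately explicit rather than hard-coded:
PhyloP "conserved" counts as supportive by default (conservation is the
only non-benign signal some candidates have), and protein-truncating or
in-frame-indel variant types count as one supportive line of evidence by
default (such variants typically receive no predictor letters at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import AnnotatedVariant, PredictionProfile

__all__ = ["SupportPolicy", "supportive_calls", "summarize_predictions", "PredictionSummary"]


@dataclass(frozen=True)
class SupportPolicy:
    """Which predictor categories count as supportive of pathogenicity."""

    phylop: frozenset = frozenset({"C"})
    sift: frozenset = frozenset({"D"})
    polyphen2: frozenset = frozenset({"D", "P"})
    lrt: frozenset = frozenset({"D"})
    mutation_taster: frozenset = frozenset({"D"})
    indel_supportive: bool = True

    _CATEGORY_SETS = {
        "phylop": frozenset({"C", "N"}),
        "sift": frozenset({"T", "D"}),
        "polyphen2": frozenset({"D", "P", "B"}),
        "lrt": frozenset({"N", "D"}),
        "mutation_taster": frozenset({"N", "D"}),
    }

    def __post_init__(self) -> None:
        for name, allowed in self._CATEGORY_SETS.items():
            chosen = getattr(self, name)
            if not frozenset(chosen) <= allowed:
                raise ValueError(
                    f"supportive set {sorted(chosen)} for {name} is not a subset "
                    f"of its categories {sorted(allowed)}"
                )
            object.__setattr__(self, name, frozenset(chosen))


def supportive_calls(
    profile: PredictionProfile, policy: SupportPolicy = SupportPolicy()
) -> tuple[int, bool]:
    """Count supportive predictor calls; flag = at least one.

    The count adds one when the variant type itself (in-frame indel,
    frameshift, stop-gain) is treated as supportive evidence and the policy
    enables that.
    """
    count = 0
    for name in PredictionProfile.PREDICTORS:
        value = getattr(profile, name)
        if value is not None and value in getattr(policy, name):
            count += 1
    if policy.indel_supportive and profile.variant_type_flags:
        count += 1
    return count, count >= 1


@dataclass
class PredictionSummary:
    """Per-candidate supportive-evidence counts plus totals."""

    table: pd.DataFrame
    n_supported: int
    n_unsupported: int

    @property
    def unsupported_genes(self) -> list[str]:
        return list(self.table.loc[~self.table["supported"], "gene"])


def summarize_predictions(
    candidates: Sequence[AnnotatedVariant], policy: SupportPolicy = SupportPolicy()
) -> PredictionSummary:
    """Tabulate supportive counts and flags for a candidate list."""
    rows = []
    for cand in candidates:
        profile = cand.profile or PredictionProfile()
        count, flag = supportive_calls(profile, policy)
        rows.append(
            {
                "chrom": cand.variant.chrom,
                "pos": cand.variant.pos,
                "gene": cand.variant.gene,
                "func_class": cand.variant.func_class,
                "phylop": profile.phylop or "",
                "sift": profile.sift or "",
                "polyphen2": profile.polyphen2 or "",
                "lrt": profile.lrt or "",
                "mutation_taster": profile.mutation_taster or "",
                "n_supportive": count,
                "supported": flag,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "gene", "func_class", "phylop", "sift",
            "polyphen2", "lrt", "mutation_taster", "n_supportive", "supported",
        ],
    )
    n_supported = int(table["supported"].sum()) if len(table) else 0
    return PredictionSummary(
        table=table,
        n_supported=n_supported,
        n_unsupported=len(table) - n_supported,
    )
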