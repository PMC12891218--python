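"""Two-step modified-SMQ case selection.

Step 1 includes a case if any of its reaction PTs belongs to the SMQ
"Drug abuse, dependence and withdrawal". Step 2 removes suicide-related
overdoses: a case is excluded iff every SMQ hit on the case is an
overdose-type PT (Accidental/Intentional/Prescribed overdose, Overdose,
Toxicity to various agents) AND the case also reports any suicidal-behavior
PT. Such cases are overdoses in the context of a suicide attempt, not drug
abuse. Selection is computed per case, independent of drug grouping, so a
case contributes the same outcome to every drug group it belongs to.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .faers_io import SafetyCase
from .lexicon import SmqDefinition

__all__ = [
    "SelectionOutcome",
    "FunnelCounts",
    "smq_step1",
    "smq_step2_exclude",
    "select_modified_smq",
]


@dataclass(frozen=True)
class SelectionOutcome:
    """Per-case result of the two-step selection.

    ``smq_hit_pts`` holds the canonical (SMQ-spelled) forms of the case's
    inclusion-PT hits; ``selected`` is step-1 non-empty AND not excluded.
    """

    case_id: str
    smq_hit_pts: frozenset[str]
    excluded_by_suicide_rule: bool
    selected: bool


@dataclass(frozen=True)
class FunnelCounts:
    """Aggregate counts at each selection step (the extraction funnel)."""

    total: int
    smq_hits: int
    suicide_rule_exclusions: int
    selected: int

    def __post_init__(self) -> None:
        if not (self.selected <= self.smq_hits <= self.total):
            raise ValueError("funnel counts must be monotone: selected <= smq_hits <= total")


def smq_step1(case: SafetyCase, smq: SmqDefinition) -> frozenset[str]:
    """Intersection of the case's reactions with the SMQ inclusion PTs.

    Comparison is normalized (case- and whitespace-insensitive); the returned
    PTs use the SMQ's canonical spelling.
    """
    return frozenset(
        smq.inclusion_by_key[key] for key in case.reaction_keys & set(smq.inclusion_by_key)
    )


def smq_step2_exclude(case: SafetyCase, hits: frozenset[str], smq: SmqDefinition) -> bool:
    """True iff the case is a suicide-related overdose-only case.

    Requires: at least one SMQ hit, every hit is overdose-type, and any
    suicidal-behavior PT is co-reported. A single non-overdose SMQ PT rescues
    the case ("without any other PTs" clause).
    """
    if not hits:
        return False
    hit_keys = {k for k in case.reaction_keys if k in smq.inclusion_by_key}
    if not hit_keys <= smq.overdose_keys:
        return False
    return bool(case.reaction_keys & smq.suicide_keys)


def select_modified_smq(
    cases: Iterable[SafetyCase] | Sequence[SafetyCase],
    smq: SmqDefinition,
) -> tuple[list[SelectionOutcome], FunnelCounts]:
    """Apply both selection steps to a deduplicated case list.

    Returns one outcome per case plus the aggregate funnel (total cases,
    step-1 hits, step-2 exclusions, final selected).
    """
    outcomes: list[SelectionOutcome] = []
    n_hits = n_excluded = n_selected = 0
    for case in cases:
        hits = smq_step1(case, smq)
        excluded = smq_step2_exclude(case, hits, smq)
        selected = bool(hits) and not excluded
        n_hits += bool(hits)
        n_excluded += excluded
        n_selected += selected
        outcomes.append(
            SelectionOutcome(
                case_id=case.case_id,
                smq_hit_pts=hits,
                excluded_by_suicide_rule=excluded,
                selected=selected,
            )
        )
    funnel = FunnelCounts(
        total=len(outcomes),
        smq_hits=n_hits,
        suicide_rule_exclusions=n_excluded,
        selected=n_selected,
    )
    return outcomes, funnel
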