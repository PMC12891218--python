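"""End-to-end orchestration: ingest -> dedup -> scope -> select -> signals -> report.

Thin glue used by the command-line interface; each stage is a plain function
from the corresponding module, so library users can compose them directly.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

from .case_selection import select_modified_smq
from .disproportionality import DEFAULT_COMPARISONS, SignalRow, run_analysis
from .faers_io import (
    DrugRole,
    SafetyCase,
    assemble_cases,
    deduplicate,
    read_table,
    scope_filter,
)
from .lexicon import DrugGroup, SmqDefinition, case_in_group
from .reporting import FunnelRow, funnel_table

logger = logging.getLogger(__name__)

__all__ = ["StageCounts", "ingest", "prepare_cases", "analyze_cases", "ROLE_MODES"]

#: Named role restrictions for counting a case under a drug group.
ROLE_MODES: dict[str, frozenset[DrugRole] | None] = {
    "any": None,
    "suspect": frozenset({DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT}),
    "primary_suspect": frozenset({DrugRole.PRIMARY_SUSPECT}),
}


@dataclass(frozen=True)
class StageCounts:
    reports: int
    orphan_drugs: int
    orphan_reactions: int
    after_dedup: int
    after_scope: int


def ingest(demo: str | Path, drug: str | Path, reac: str | Path) -> tuple[list[SafetyCase], StageCounts]:
    """Read the three quarterly tables and assemble per-report cases."""
    reports = read_table(demo, "DEMO")
    drugs = read_table(drug, "DRUG")
    reactions = read_table(reac, "REAC")
    assembly = assemble_cases(reports, drugs, reactions)
    logger.info(
        "ingest: %d reports, %d orphan drug / %d orphan reaction mentions",
        len(assembly.cases), assembly.orphan_drugs, assembly.orphan_reactions,
    )
    counts = StageCounts(
        reports=len(assembly.cases),
        orphan_drugs=assembly.orphan_drugs,
        orphan_reactions=assembly.orphan_reactions,
        after_dedup=0,
        after_scope=0,
    )
    return assembly.cases, counts


def prepare_cases(
    cases: Sequence[SafetyCase],
    country: str,
    window_start: dt.date,
    window_end: dt.date,
    date_field: str = "event_date",
    counts: StageCounts | None = None,
) -> tuple[list[SafetyCase], StageCounts]:
    """Deduplicate, then restrict to the study country and date window."""
    deduped = deduplicate(cases)
    scoped = scope_filter(deduped, country, window_start, window_end, date_field)
    logger.info(
        "dedup: %d -> %d cases; scope: %d kept (%d wrong country, %d outside window, %d missing dates)",
        len(cases), len(deduped), len(scoped.cases),
        scoped.excluded_country, scoped.excluded_date, scoped.excluded_missing_date,
    )
    base = counts or StageCounts(len(cases), 0, 0, 0, 0)
    out_counts = StageCounts(
        reports=base.reports,
        orphan_drugs=base.orphan_drugs,
        orphan_reactions=base.orphan_reactions,
        after_dedup=len(deduped),
        after_scope=len(scoped.cases),
    )
    return scoped.cases, out_counts


def analyze_cases(
    cases: Sequence[SafetyCase],
    groups: Sequence[DrugGroup],
    smq: SmqDefinition,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    measures: Sequence[str] = ("ROR", "PRR"),
    alpha: float = 0.05,
    pt_threshold: float = 0.01,
    roles_mode: str = "any",
    co_mention: str = "both",
) -> tuple[list[SignalRow], list[FunnelRow]]:
    """Run selection and disproportionality; returns signal rows and the
    per-group funnel for every group appearing in a comparison."""
    if roles_mode not in ROLE_MODES:
        raise ValueError(f"unknown roles mode: {roles_mode!r}")
    roles = ROLE_MODES[roles_mode]
    signal_rows = run_analysis(
        cases,
        groups,
        smq,
        comparisons=comparisons,
        measures=measures,
        alpha=alpha,
        pt_threshold=pt_threshold,
        roles=roles,
        co_mention=co_mention,
    )
    by_name = {g.name: g for g in groups}
    funnels = {}
    for name in dict.fromkeys(n for pair in comparisons for n in pair):
        member_cases = [c for c in cases if case_in_group(c, by_name[name], roles)]
        _, funnel = select_modified_smq(member_cases, smq)
        funnels[name] = funnel
    return signal_rows, funnel_table(funnels)
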