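"""Disproportionality statistics: reporting odds ratio and proportional reporting ratio.

Signals are measured against a designated reference drug group rather than the
whole database. For an index group with ``a`` event cases out of ``a + b`` and
a reference group with ``c`` out of ``c + d``:

    ROR = (a/b) / (c/d)          var(log ROR) = 1/a + 1/b + 1/c + 1/d   (Woolf)
    PRR = (a/(a+b)) / (c/(c+d))  var(log PRR) = 1/a - 1/(a+b) + 1/c - 1/(c+d)

Confidence intervals are delta-method intervals on the log scale,
``exp(log(est) ± z · se)``. A value below 1 means the event is reported less
often for the index drug than for the reference; the difference is
conventionally called non-significant when 1 lies inside the 95% CI. If any
cell is zero, the Haldane–Anscombe correction adds 0.5 to all four cells and
the result is flagged ``continuity_corrected``.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass

from scipy.stats import norm

from .case_selection import select_modified_smq
from .faers_io import DrugRole, SafetyCase
from .lexicon import DrugGroup, SmqDefinition, case_in_group

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "SignalRow",
    "UndefinedTableError",
    "OVERALL_EVENT",
    "DEFAULT_COMPARISONS",
    "make_table",
    "ror",
    "prr",
    "pt_frequency_filter",
    "run_analysis",
]

#: Event label used for the overall modified-SMQ comparison in result rows.
OVERALL_EVENT = "OVERALL_MODIFIED_SMQ"

#: The study's six overall comparisons: Schedule IV classes against the Z-drug
#: class, unscheduled drugs (and DORAs again) against trazodone.
DEFAULT_COMPARISONS = (
    ("dora", "z_drug"),
    ("benzodiazepine_any", "z_drug"),
    ("benzodiazepine_insomnia", "z_drug"),
    ("dora", "trazodone"),
    ("doxepin", "trazodone"),
    ("ramelteon", "trazodone"),
)


class UndefinedTableError(ValueError):
    """Raised when a contingency table has an empty index or reference margin."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of event reporting for an index drug vs a reference drug.

    a: index-group cases with the event; b: without. c/d likewise for the
    reference group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def index_total(self) -> int:
        return self.a + self.b

    @property
    def reference_total(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    measure: str
    estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    table: ContingencyTable
    continuity_corrected: bool


@dataclass(frozen=True)
class SignalRow:
    """One exported analysis row: a measure for one (group, reference, event)."""

    group: str
    reference: str
    event: str
    measure: str
    a: int
    b: int
    c: int
    d: int
    estimate: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool


def make_table(
    cases: Sequence[SafetyCase],
    index_group: DrugGroup,
    reference_group: DrugGroup,
    event: Callable[[SafetyCase], bool],
    roles: Iterable[DrugRole] | None = None,
    co_mention: str = "both",
) -> ContingencyTable:
    """Tally the 2x2 reporting table for an event predicate.

    Cases mentioning drugs of both groups are counted in both by default
    (``co_mention="both"``); ``co_mention="exclusive"`` drops them from both
    margins. Raises :class:`UndefinedTableError` when either margin is empty.
    """
    if index_group.name == reference_group.name:
        raise ValueError("index and reference group must differ")
    if co_mention not in ("both", "exclusive"):
        raise ValueError(f"unknown co_mention mode: {co_mention!r}")
    a = b = c = d = 0
    for case in cases:
        in_index = case_in_group(case, index_group, roles)
        in_reference = case_in_group(case, reference_group, roles)
        if in_index and in_reference and co_mention == "exclusive":
            continue
        if not (in_index or in_reference):
            continue
        has_event = event(case)
        if in_index:
            a += has_event
            b += not has_event
        if in_reference:
            c += has_event
            d += not has_event
    if a + b == 0 or c + d == 0:
        raise UndefinedTableError("empty index or reference margin")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _z_quantile(alpha: float, z_value: float | None) -> float:
    if z_value is not None:
        return z_value
    return float(norm.ppf(1 - alpha / 2))


def _corrected_cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    cells = (table.a, table.b, table.c, table.d)
    if 0 in cells:
        return tuple(x + 0.5 for x in cells) + (True,)  # type: ignore[return-value]
    return tuple(float(x) for x in cells) + (False,)  # type: ignore[return-value]


def ror(
    table: ContingencyTable, alpha: float = 0.05, z_value: float | None = None
) -> SignalResult:
    """Reporting odds ratio with its Woolf (log-scale delta-method) CI.

    ``z_value`` overrides the exact normal quantile (e.g. 1.96) for
    bit-matching legacy outputs.
    """
    a, b, c, d, corrected = _corrected_cells(table)
    estimate = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _z_quantile(alpha, z_value)
    return SignalResult(
        measure="ROR",
        estimate=estimate,
        ci_low=math.exp(math.log(estimate) - z * se),
        ci_high=math.exp(math.log(estimate) + z * se),
        alpha=alpha,
        table=table,
        continuity_corrected=corrected,
    )


def prr(
    table: ContingencyTable, alpha: float = 0.05, z_value: float | None = None
) -> SignalResult:
    """Proportional reporting ratio with its log-scale delta-method CI."""
    a, b, c, d, corrected = _corrected_cells(table)
    estimate = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = _z_quantile(alpha, z_value)
    return SignalResult(
        measure="PRR",
        estimate=estimate,
        ci_low=math.exp(math.log(estimate) - z * se),
        ci_high=math.exp(math.log(estimate) + z * se),
        alpha=alpha,
        table=table,
        continuity_corrected=corrected,
    )


_MEASURES = {"ROR": ror, "PRR": prr}


def pt_frequency_filter(
    cases_by_group: Mapping[str, Sequence[SafetyCase]],
    smq: SmqDefinition,
    threshold: float = 0.01,
) -> list[str]:
    """PTs of the modified SMQ whose case frequency reaches ``threshold`` in
    at least one group.

    Frequency is the number of selected (modified-SMQ) cases reporting the PT
    divided by the group's total case count. Returned sorted by descending
    maximum frequency, ties alphabetical.
    """
    if not cases_by_group:
        raise ValueError("at least one group of cases is required")
    max_freq: dict[str, float] = {}
    for cases in cases_by_group.values():
        total = len(cases)
        if total == 0:
            continue
        counts: dict[str, int] = {}
        outcomes, _ = select_modified_smq(cases, smq)
        for outcome in outcomes:
            if not outcome.selected:
                continue
            for pt in outcome.smq_hit_pts:
                counts[pt] = counts.get(pt, 0) + 1
        for pt, n in counts.items():
            freq = n / total
            if freq > max_freq.get(pt, -1.0):
                max_freq[pt] = freq
    kept = [pt for pt, freq in max_freq.items() if freq >= threshold]
    return sorted(kept, key=lambda pt: (-max_freq[pt], pt))


def run_analysis(
    cases: Sequence[SafetyCase],
    groups: Sequence[DrugGroup],
    smq: SmqDefinition,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    measures: Sequence[str] = ("ROR", "PRR"),
    alpha: float = 0.05,
    pt_threshold: float = 0.01,
    roles: Iterable[DrugRole] | None = None,
    co_mention: str = "both",
    z_value: float | None = None,
) -> list[SignalRow]:
    """Full disproportionality analysis on a deduplicated, scoped case list.

    For each (index, reference) comparison, emits one row per measure for the
    overall modified SMQ and for every PT passing the frequency filter among
    the compared groups. Ordering is deterministic: comparisons in the given
    order, the overall event first, then PTs in filter order, then measures in
    the given order.
    """
    by_name = {g.name: g for g in groups}
    for index_name, reference_name in comparisons:
        if index_name == reference_name:
            raise ValueError("a group cannot be compared against itself")
        for name in (index_name, reference_name):
            if name not in by_name:
                raise KeyError(f"comparison group {name!r} is not configured")
    for measure in measures:
        if measure not in _MEASURES:
            raise ValueError(f"unknown measure: {measure!r}")

    roles_t = tuple(roles) if roles is not None else None
    outcome_by_case: dict[str, bool] = {}
    hits_by_case: dict[str, frozenset[str]] = {}
    outcomes, _ = select_modified_smq(cases, smq)
    for outcome in outcomes:
        outcome_by_case[outcome.case_id] = outcome.selected
        hits_by_case[outcome.case_id] = outcome.smq_hit_pts

    membership: dict[str, list[SafetyCase]] = {}
    compared_groups = {name for pair in comparisons for name in pair}
    for name in compared_groups:
        group = by_name[name]
        membership[name] = [c for c in cases if case_in_group(c, group, roles_t)]

    rows: list[SignalRow] = []
    for index_name, reference_name in comparisons:
        pts = pt_frequency_filter(
            {name: membership[name] for name in (index_name, reference_name)},
            smq,
            threshold=pt_threshold,
        )
        events: list[tuple[str, Callable[[SafetyCase], bool]]] = [
            (OVERALL_EVENT, lambda case: outcome_by_case[case.case_id])
        ]
        for pt in pts:
            events.append(
                (
                    pt,
                    lambda case, pt=pt: outcome_by_case[case.case_id]
                    and pt in hits_by_case[case.case_id],
                )
            )
        for event_name, predicate in events:
            table = make_table(
                cases,
                by_name[index_name],
                by_name[reference_name],
                predicate,
                roles=roles_t,
                co_mention=co_mention,
            )
            for measure in measures:
                result = _MEASURES[measure](table, alpha=alpha, z_value=z_value)
                rows.append(
                    SignalRow(
                        group=index_name,
                        reference=reference_name,
                        event=event_name,
                        measure=measure,
                        a=table.a,
                        b=table.b,
                        c=table.c,
                        d=table.d,
                        estimate=result.estimate,
                        ci_low=result.ci_low,
                        ci_high=result.ci_high,
                        continuity_corrected=result.continuity_corrected,
                    )
                )
    return rows
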