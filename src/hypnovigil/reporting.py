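"""Result tables and run summaries.

Exports the descriptive funnel (total cases, SMQ cases, modified-SMQ cases and
percentage per drug group), the signal table behind the forest plots, and a
plain-language run summary listing the study-design elements transparent
pharmacovigilance reporting asks for. Serialized numbers use fixed precision:
estimates and CI bounds at 3 decimals, percentages at 1 decimal, both rounded
half-up; exports are deterministic (same inputs, byte-identical files).
"""

from __future__ import annotations

import datetime as dt
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, TypeAdapter

from .case_selection import FunnelCounts
from .disproportionality import SignalRow

__all__ = [
    "FunnelRow",
    "round_half_up",
    "funnel_table",
    "funnel_from_counts",
    "export",
    "validate_signals_json",
    "validate_funnel_json",
    "run_summary",
]


def round_half_up(value: float, digits: int) -> float:
    """Decimal round-half-up (0.0265 -> 0.027 at 3 digits), matching the
    reporting convention of the benchmark tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FunnelRow:
    """Per-group extraction funnel. ``smq_cases`` (step-1 count) may be None
    when a row is built from published totals that only report the final
    modified-SMQ count."""

    group: str
    total_cases: int
    smq_cases: int | None
    modified_smq_cases: int
    percent_modified: float

    def __post_init__(self) -> None:
        upper = self.smq_cases if self.smq_cases is not None else self.total_cases
        if not (0 <= self.modified_smq_cases <= upper <= self.total_cases):
            raise ValueError("funnel row violates monotonicity")


def _percent(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 1)


def funnel_table(funnels_by_group: Mapping[str, FunnelCounts]) -> list[FunnelRow]:
    """One row per drug group, ordered by descending total case count."""
    rows = [
        FunnelRow(
            group=name,
            total_cases=f.total,
            smq_cases=f.smq_hits,
            modified_smq_cases=f.selected,
            percent_modified=_percent(f.selected, f.total),
        )
        for name, f in funnels_by_group.items()
    ]
    rows.sort(key=lambda r: (-r.total_cases, r.group))
    return rows


def funnel_from_counts(counts: Mapping[str, tuple[int, int]]) -> list[FunnelRow]:
    """Funnel rows from (total, modified-SMQ) count pairs, e.g. the benchmark."""
    rows = [
        FunnelRow(
            group=name,
            total_cases=total,
            smq_cases=None,
            modified_smq_cases=selected,
            percent_modified=_percent(selected, total),
        )
        for name, (total, selected) in counts.items()
    ]
    rows.sort(key=lambda r: (-r.total_cases, r.group))
    return rows


class SignalRecord(BaseModel):
    """Export schema of one signal row (JSON and CSV share these columns)."""

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


class FunnelRecord(BaseModel):
    group: str
    total_cases: int
    smq_cases: int | None
    modified_smq_cases: int
    percent_modified: float


_SIGNALS_ADAPTER = TypeAdapter(list[SignalRecord])
_FUNNEL_ADAPTER = TypeAdapter(list[FunnelRecord])

_SIGNAL_COLUMNS = [
    "group", "reference", "event", "measure", "a", "b", "c", "d",
    "estimate", "ci_low", "ci_high", "continuity_corrected",
]
_FUNNEL_COLUMNS = [
    "group", "total_cases", "smq_cases", "modified_smq_cases", "percent_modified",
]


def _signal_records(rows: Sequence[SignalRow]) -> list[dict]:
    return [
        {
            "group": r.group,
            "reference": r.reference,
            "event": r.event,
            "measure": r.measure,
            "a": r.a,
            "b": r.b,
            "c": r.c,
            "d": r.d,
            "estimate": round_half_up(r.estimate, 3),
            "ci_low": round_half_up(r.ci_low, 3),
            "ci_high": round_half_up(r.ci_high, 3),
            "continuity_corrected": r.continuity_corrected,
        }
        for r in rows
    ]


def export(
    signal_rows: Sequence[SignalRow],
    funnel_rows: Sequence[FunnelRow],
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "json"),
    manifest_extra: Mapping | None = None,
) -> dict[str, str]:
    """Write signals and funnel tables plus a manifest; returns name->file map.

    Row and column order are deterministic and numbers are serialized at fixed
    precision, so identical inputs yield byte-identical files.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"csv", "json"}
    if unknown:
        raise ValueError(f"unknown export format(s): {sorted(unknown)}")
    signals = _signal_records(signal_rows)
    funnel = [
        {
            "group": r.group,
            "total_cases": r.total_cases,
            "smq_cases": r.smq_cases,
            "modified_smq_cases": r.modified_smq_cases,
            "percent_modified": r.percent_modified,
        }
        for r in funnel_rows
    ]
    written: dict[str, str] = {}
    if "csv" in formats:
        pd.DataFrame(signals, columns=_SIGNAL_COLUMNS).to_csv(
            out / "signals.csv", index=False, lineterminator="\n"
        )
        pd.DataFrame(funnel, columns=_FUNNEL_COLUMNS).to_csv(
            out / "funnel.csv", index=False, lineterminator="\n"
        )
        written["signals_csv"] = "signals.csv"
        written["funnel_csv"] = "funnel.csv"
    if "json" in formats:
        (out / "signals.json").write_text(
            json.dumps(signals, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        (out / "funnel.json").write_text(
            json.dumps(funnel, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        written["signals_json"] = "signals.json"
        written["funnel_json"] = "funnel.json"
    manifest = {"tool": "hypnovigil", "version": __version__, "files": written}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    written["manifest"] = "manifest.json"
    return written


def validate_signals_json(path: str | Path) -> list[SignalRecord]:
    """Parse and schema-validate an exported signals.json."""
    return _SIGNALS_ADAPTER.validate_json(Path(path).read_text(encoding="utf-8"))


def validate_funnel_json(path: str | Path) -> list[FunnelRecord]:
    return _FUNNEL_ADAPTER.validate_json(Path(path).read_text(encoding="utf-8"))


def run_summary(
    country: str,
    window_start: dt.date,
    window_end: dt.date,
    date_field: str,
    smq_name: str,
    n_inclusion_pts: int,
    comparisons: Sequence[tuple[str, str]],
    measures: Sequence[str],
    alpha: float,
    pt_threshold: float,
) -> str:
    """Plain-text study-design summary (data source scope, dedup rule, case
    definition, comparators, measures) for transparent reporting."""
    lines = [
        "hypnovigil run summary",
        "======================",
        f"Scope: occurrence country {country}, {date_field} within "
        f"{window_start.isoformat()}..{window_end.isoformat()} (inclusive; "
        "missing date falls back to the other date field).",
        "Deduplication: one report per case id - highest case version, ties by "
        "latest FDA receipt date, then largest primary id.",
        f"Case definition: {smq_name} ({n_inclusion_pts} inclusion PTs); "
        "step 2 excludes cases whose only SMQ terms are overdose-type PTs "
        "co-reported with a suicidal-behavior PT.",
        "Comparisons (index vs reference): "
        + "; ".join(f"{i} vs {r}" for i, r in comparisons)
        + ".",
        f"Measures: {', '.join(measures)} with {100 * (1 - alpha):g}% log-scale "
        "delta-method confidence intervals (Haldane-Anscombe +0.5 on zero cells).",
        f"PT-level analyses restricted to modified-SMQ PTs with frequency >= "
        f"{100 * pt_threshold:g}% in at least one compared group.",
    ]
    return "\n".join(lines) + "\n"
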