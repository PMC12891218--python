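"""Reading FAERS-dialect quarterly ASCII extracts and building deduplicated cases.

FAERS quarters ship one "$"-delimited text file per table; this module handles
the three tables the abuse analysis needs (DEMO, DRUG, REAC), joins them into
per-report case records, collapses multiple versions of the same case to the
authoritative one, and applies the country/date scope of a study window.

A FAERS *case* (``caseid``) can appear as several *reports* (``primaryid``)
as follow-up versions arrive; counting reports instead of cases inflates every
numerator, so deduplication keeps exactly one report per case: the highest
``caseversion``, ties broken by latest FDA receipt date, then by largest
``primaryid``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import json
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .normalize import collapse_whitespace, pt_key

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRole",
    "RawReport",
    "DrugMention",
    "ReactionMention",
    "SafetyCase",
    "AssemblyResult",
    "ScopeResult",
    "FaersFormatError",
    "parse_faers_date",
    "read_table",
    "assemble_cases",
    "deduplicate",
    "scope_filter",
    "write_cases_jsonl",
    "read_cases_jsonl",
]


class FaersFormatError(ValueError):
    """Raised when a FAERS table file is structurally unusable (e.g. bad header)."""


class DrugRole(str, enum.Enum):
    """Reported role of a drug on a case (FAERS ``role_cod``)."""

    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"


ALL_ROLES = frozenset(DrugRole)


@dataclass(frozen=True)
class RawReport:
    primary_id: str
    case_id: str
    case_version: int
    fda_receipt_date: dt.date | None
    event_date: dt.date | None
    occurrence_country: str | None


@dataclass(frozen=True)
class DrugMention:
    report_key: str
    sequence: int
    role: DrugRole
    verbatim_name: str
    active_ingredient: str | None = None


@dataclass(frozen=True)
class ReactionMention:
    report_key: str
    preferred_term: str


@dataclass(frozen=True)
class SafetyCase:
    """One adverse-event case: a report plus its drug and reaction mentions.

    ``reactions`` is a set of whitespace-collapsed PT strings, deduplicated
    case-insensitively (the first spelling seen is kept for display).
    """

    case_id: str
    report: RawReport
    drugs: tuple[DrugMention, ...]
    reactions: frozenset[str]

    @property
    def reaction_keys(self) -> frozenset[str]:
        return frozenset(pt_key(r) for r in self.reactions)


@dataclass(frozen=True)
class AssemblyResult:
    cases: list[SafetyCase]
    orphan_drugs: int
    orphan_reactions: int


@dataclass(frozen=True)
class ScopeResult:
    cases: list[SafetyCase]
    excluded_country: int
    excluded_date: int
    excluded_missing_date: int


def parse_faers_date(raw: str | None) -> dt.date | None:
    """Parse a FAERS date field (YYYYMMDD, YYYYMM or YYYY).

    Partial dates resolve to the first day of the period; blank or unparseable
    values return None.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if not text or not text.isdigit():
        return None
    try:
        if len(text) == 8:
            return dt.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
        if len(text) == 6:
            return dt.date(int(text[:4]), int(text[4:6]), 1)
        if len(text) == 4:
            return dt.date(int(text), 1, 1)
    except ValueError:
        return None
    return None


_REQUIRED_COLUMNS = {
    "DEMO": ("primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "occr_country"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "pt"),
}

_ROLE_CODES = {r.value: r for r in DrugRole}


def _read_dollar_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    kind = table_kind.upper()
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    frame = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in _REQUIRED_COLUMNS[kind] if c not in frame.columns]
    if missing:
        raise FaersFormatError(
            f"{kind} file {path} is missing required column(s): {', '.join(missing)}"
        )
    return frame


def read_table(
    path: str | Path, table_kind: str
) -> list[RawReport] | list[DrugMention] | list[ReactionMention]:
    """Read one FAERS quarterly table into typed records.

    Unknown columns are ignored; blank optional fields become None. A malformed
    header raises :class:`FaersFormatError`; an unparseable date is logged and
    set missing at record level.
    """
    kind = table_kind.upper()
    frame = _read_dollar_table(path, kind)
    if kind == "DEMO":
        return _demo_records(frame, path)
    if kind == "DRUG":
        return _drug_records(frame)
    return _reac_records(frame)


def _demo_records(frame: pd.DataFrame, path: str | Path) -> list[RawReport]:
    records: list[RawReport] = []
    for row in frame.itertuples(index=False):
        fda = parse_faers_date(row.fda_dt)
        if fda is None and str(row.fda_dt).strip():
            logger.warning("unparseable fda_dt %r on primaryid %s in %s", row.fda_dt, row.primaryid, path)
        event = parse_faers_date(row.event_dt)
        if event is None and str(row.event_dt).strip():
            logger.warning("unparseable event_dt %r on primaryid %s in %s", row.event_dt, row.primaryid, path)
        try:
            version = int(str(row.caseversion).strip() or 0)
        except ValueError:
            logger.warning("unparseable caseversion %r on primaryid %s", row.caseversion, row.primaryid)
            version = 0
        country = str(row.occr_country).strip().upper() or None
        records.append(
            RawReport(
                primary_id=str(row.primaryid).strip(),
                case_id=str(row.caseid).strip(),
                case_version=max(version, 0),
                fda_receipt_date=fda,
                event_date=event,
                occurrence_country=country,
            )
        )
    return records


def _drug_records(frame: pd.DataFrame) -> list[DrugMention]:
    records: list[DrugMention] = []
    for row in frame.itertuples(index=False):
        name = collapse_whitespace(str(row.drugname))
        if not name:
            continue
        role = _ROLE_CODES.get(str(row.role_cod).strip().upper(), DrugRole.CONCOMITANT)
        try:
            seq = int(str(row.drug_seq).strip() or 1)
        except ValueError:
            seq = 1
        ingredient = collapse_whitespace(str(row.prod_ai)) or None
        records.append(
            DrugMention(
                report_key=str(row.primaryid).strip(),
                sequence=seq,
                role=role,
                verbatim_name=name,
                active_ingredient=ingredient,
            )
        )
    return records


def _reac_records(frame: pd.DataFrame) -> list[ReactionMention]:
    records: list[ReactionMention] = []
    for row in frame.itertuples(index=False):
        term = collapse_whitespace(str(row.pt))
        if not term:
            continue
        records.append(ReactionMention(report_key=str(row.primaryid).strip(), preferred_term=term))
    return records


def assemble_cases(
    reports: Sequence[RawReport],
    drug_mentions: Iterable[DrugMention],
    reaction_mentions: Iterable[ReactionMention],
) -> AssemblyResult:
    """Group drug and reaction mentions under their report.

    Mentions whose ``report_key`` resolves to no report are counted as orphans
    and logged, never fatal: real FAERS extracts contain referential gaps.
    Duplicate PTs on one report collapse case-insensitively to a single entry.
    """
    by_key: dict[str, RawReport] = {r.primary_id: r for r in reports}
    drugs: dict[str, list[DrugMention]] = {k: [] for k in by_key}
    reactions: dict[str, dict[str, str]] = {k: {} for k in by_key}
    orphan_drugs = 0
    orphan_reactions = 0
    for mention in drug_mentions:
        bucket = drugs.get(mention.report_key)
        if bucket is None:
            orphan_drugs += 1
            continue
        bucket.append(mention)
    for mention in reaction_mentions:
        bucket = reactions.get(mention.report_key)
        if bucket is None:
            orphan_reactions += 1
            continue
        bucket.setdefault(pt_key(mention.preferred_term), mention.preferred_term)
    if orphan_drugs or orphan_reactions:
        logger.warning(
            "orphan mentions ignored: %d drug, %d reaction", orphan_drugs, orphan_reactions
        )
    cases = [
        SafetyCase(
            case_id=report.case_id,
            report=report,
            drugs=tuple(sorted(drugs[key], key=lambda m: m.sequence)),
            reactions=frozenset(reactions[key].values()),
        )
        for key, report in sorted(by_key.items())
    ]
    cases.sort(key=lambda c: (c.case_id, c.report.primary_id))
    return AssemblyResult(cases=cases, orphan_drugs=orphan_drugs, orphan_reactions=orphan_reactions)


def _dedup_rank(case: SafetyCase) -> tuple[int, dt.date, str]:
    receipt = case.report.fda_receipt_date or dt.date.min
    return (case.report.case_version, receipt, case.report.primary_id)


def deduplicate(cases: Sequence[SafetyCase]) -> list[SafetyCase]:
    """Keep one report per case id: highest version, then latest receipt, then
    lexicographically largest primaryid. Output is sorted by case id, so the
    result is independent of input order and idempotent."""
    best: dict[str, SafetyCase] = {}
    for case in cases:
        current = best.get(case.case_id)
        if current is None or _dedup_rank(case) > _dedup_rank(current):
            best[case.case_id] = case
    return [best[k] for k in sorted(best)]


def scope_filter(
    cases: Sequence[SafetyCase],
    country: str,
    window_start: dt.date,
    window_end: dt.date,
    date_field: str = "event_date",
) -> ScopeResult:
    """Restrict cases to one occurrence country and an inclusive date window.

    ``date_field`` selects the scoping date ("event_date" or
    "fda_receipt_date"); a case missing it falls back to the other field, and a
    case missing both is excluded and counted.
    """
    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    if date_field not in ("event_date", "fda_receipt_date"):
        raise ValueError(f"unknown date_field: {date_field!r}")
    other = "fda_receipt_date" if date_field == "event_date" else "event_date"
    wanted = country.strip().upper()
    kept: list[SafetyCase] = []
    excluded_country = excluded_date = excluded_missing = 0
    for case in cases:
        if (case.report.occurrence_country or "") != wanted:
            excluded_country += 1
            continue
        when = getattr(case.report, date_field) or getattr(case.report, other)
        if when is None:
            excluded_missing += 1
            continue
        if window_start <= when <= window_end:
            kept.append(case)
        else:
            excluded_date += 1
    if excluded_missing:
        logger.info("%d case(s) excluded for missing both dates", excluded_missing)
    return ScopeResult(
        cases=kept,
        excluded_country=excluded_country,
        excluded_date=excluded_date,
        excluded_missing_date=excluded_missing,
    )


def _case_to_json(case: SafetyCase) -> dict:
    payload = dataclasses.asdict(case)
    payload["drugs"] = [
        {**dataclasses.asdict(d), "role": d.role.value} for d in case.drugs
    ]
    payload["reactions"] = sorted(case.reactions)
    report = payload["report"]
    for field in ("fda_receipt_date", "event_date"):
        if report[field] is not None:
            report[field] = report[field].isoformat()
    return payload


def _case_from_json(payload: dict) -> SafetyCase:
    report = payload["report"]
    raw = RawReport(
        primary_id=report["primary_id"],
        case_id=report["case_id"],
        case_version=report["case_version"],
        fda_receipt_date=dt.date.fromisoformat(report["fda_receipt_date"])
        if report["fda_receipt_date"]
        else None,
        event_date=dt.date.fromisoformat(report["event_date"]) if report["event_date"] else None,
        occurrence_country=report["occurrence_country"],
    )
    drugs = tuple(
        DrugMention(
            report_key=d["report_key"],
            sequence=d["sequence"],
            role=DrugRole(d["role"]),
            verbatim_name=d["verbatim_name"],
            active_ingredient=d["active_ingredient"],
        )
        for d in payload["drugs"]
    )
    return SafetyCase(
        case_id=payload["case_id"],
        report=raw,
        drugs=drugs,
        reactions=frozenset(payload["reactions"]),
    )


def write_cases_jsonl(cases: Iterable[SafetyCase], path: str | Path) -> None:
    """Checkpoint a case ledger as JSON lines (one case per line)."""
    with open(path, "w", encoding="utf-8") as handle:
        for case in cases:
            handle.write(json.dumps(_case_to_json(case), sort_keys=True) + "\n")


def read_cases_jsonl(path: str | Path) -> list[SafetyCase]:
    with open(path, encoding="utf-8") as handle:
        return [_case_from_json(json.loads(line)) for line in handle if line.strip()]
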