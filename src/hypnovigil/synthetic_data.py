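"""Synthetic FAERS-dialect corpora with known ground truth.

The generator emits DEMO/DRUG/REAC tables in the quarterly "$"-delimited
dialect together with a ledger of per-case truth (group memberships, abuse
event flag, planted suicide-overdose flag, scope status), so that every
pipeline stage — parsing, deduplication, scoping, lexicon resolution, the
two-step selection and the disproportionality estimates — can be checked
against what was actually planted, without downloading anything.

Per case the model draws: a drug group, one drug mention (generic or brand
name, optionally with dose/formulation suffixes, random role), an occurrence
country, an event date uniform in the study window (optionally emitted partial
or missing) with an FDA receipt date lagging it, and a reaction bundle. With
probability ``suicide_overdose_fraction`` the case is a planted
suicide-related overdose (overdose-type SMQ PTs plus a suicidal-behavior PT —
constructed to match the step-2 exclusion exactly); otherwise it is an abuse
event with probability ``odds/(1+odds)`` from the group's configured event
odds, carrying one or more SMQ PTs. Everything else is background noise PTs.
Duplicated cases re-emit the same case id with an incremented version.

The default configuration mirrors the study conditions of the bundled
benchmark: per-group case totals and event odds are taken from the published
US 2014-01-01..2024-03-31 funnel counts (see :data:`REFERENCE_COUNTS`).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__
from .disproportionality import DEFAULT_COMPARISONS, ContingencyTable
from .lexicon import DrugGroup, SmqDefinition, load_default_lexicon, resolve_drug

__all__ = [
    "REFERENCE_COUNTS",
    "SimulationConfig",
    "CaseTruth",
    "GroundTruthLedger",
    "SyntheticCorpus",
    "simulate_corpus",
    "write_corpus",
    "simulate_event_tables",
    "reference_tables",
]

#: Benchmark per-group case counts (total retrieved, modified-SMQ selected)
#: from a published 10-year US FAERS analysis of insomnia medications
#: (2014-01-01 to 2024-03-31). These printed counts define the six overall
#: contingency tables used as exact acceptance fixtures.
REFERENCE_COUNTS: dict[str, tuple[int, int]] = {
    "benzodiazepine_any": (67584, 18690),
    "z_drug": (13495, 2063),
    "trazodone": (9965, 2261),
    "dora": (9963, 262),
    "benzodiazepine_insomnia": (2868, 659),
    "doxepin": (2358, 525),
    "ramelteon": (314, 25),
}

_DEFAULT_NOISE_PTS = (
    "Headache",
    "Nausea",
    "Dizziness",
    "Somnolence",
    "Fatigue",
    "Insomnia",
    "Fall",
    "Vomiting",
    "Dyspnoea",
    "Rash",
)

_DEFAULT_WINDOW = (dt.date(2014, 1, 1), dt.date(2024, 3, 31))


def _default_event_odds() -> dict[str, float]:
    return {g: n / (total - n) for g, (total, n) in REFERENCE_COUNTS.items()}


class SimulationConfig(BaseModel):
    """Parameters of one synthetic corpus. Defaults reproduce the benchmark
    study conditions; rates the benchmark does not pin down (duplicates,
    planted suicide-overdoses, brand-name usage, country mix) use fixed
    realistic values documented in the methods note."""

    seed: int = Field(default=0, ge=0)
    n_cases_per_group: dict[str, int] = Field(
        default_factory=lambda: {g: t for g, (t, _) in REFERENCE_COUNTS.items()}
    )
    event_odds: dict[str, float] = Field(default_factory=_default_event_odds)
    suicide_overdose_fraction: float = Field(default=0.02, ge=0.0, le=1.0)
    duplicate_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    brand_name_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    co_mention_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    dose_token_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    partial_date_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    missing_event_date_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    missing_ingredient_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    noise_pt_pool: tuple[str, ...] = _DEFAULT_NOISE_PTS
    event_pt_weights: dict[str, float] | None = None
    window_start: dt.date = _DEFAULT_WINDOW[0]
    window_end: dt.date = _DEFAULT_WINDOW[1]
    country_mix: dict[str, float] = Field(
        default_factory=lambda: {"US": 0.94, "CA": 0.02, "GB": 0.02, "FR": 0.02}
    )

    @field_validator("n_cases_per_group")
    @classmethod
    def _counts_non_negative(cls, value: dict[str, int]) -> dict[str, int]:
        if any(n < 0 for n in value.values()):
            raise ValueError("case counts must be non-negative")
        return value

    @field_validator("event_odds")
    @classmethod
    def _odds_positive(cls, value: dict[str, float]) -> dict[str, float]:
        if any(o <= 0 for o in value.values()):
            raise ValueError("event odds must be positive")
        return value

    @field_validator("country_mix")
    @classmethod
    def _mix_is_distribution(cls, value: dict[str, float]) -> dict[str, float]:
        if not value or any(p < 0 for p in value.values()):
            raise ValueError("country mix proportions must be non-negative")
        if abs(sum(value.values()) - 1.0) > 1e-9:
            raise ValueError("country mix must sum to 1")
        return value

    @model_validator(mode="after")
    def _check_consistency(self) -> "SimulationConfig":
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")
        missing = set(self.n_cases_per_group) - set(self.event_odds)
        if missing:
            raise ValueError(f"event_odds missing for group(s): {sorted(missing)}")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def true_odds_ratio(self, index_group: str, reference_group: str) -> float:
        """Configured true reporting odds ratio between two groups."""
        return self.event_odds[index_group] / self.event_odds[reference_group]


@dataclass(frozen=True)
class CaseTruth:
    case_id: str
    primary_group: str
    groups: tuple[str, ...]
    true_event: bool
    true_excluded: bool
    country: str
    scope_date: dt.date | None
    in_scope: bool
    n_versions: int


@dataclass(frozen=True)
class GroundTruthLedger:
    cases: tuple[CaseTruth, ...]
    config: SimulationConfig

    def group_cases(self, group: str, in_scope_only: bool = True) -> list[CaseTruth]:
        return [
            c
            for c in self.cases
            if group in c.groups and (c.in_scope or not in_scope_only)
        ]

    def group_total(self, group: str, in_scope_only: bool = True) -> int:
        return len(self.group_cases(group, in_scope_only))

    def group_event_count(self, group: str, in_scope_only: bool = True) -> int:
        return sum(c.true_event for c in self.group_cases(group, in_scope_only))

    def to_dict(self) -> dict:
        return {
            "config": self.config.model_dump(mode="json"),
            "cases": [
                {
                    "case_id": c.case_id,
                    "primary_group": c.primary_group,
                    "groups": list(c.groups),
                    "true_event": c.true_event,
                    "true_excluded": c.true_excluded,
                    "country": c.country,
                    "scope_date": c.scope_date.isoformat() if c.scope_date else None,
                    "in_scope": c.in_scope,
                    "n_versions": c.n_versions,
                }
                for c in self.cases
            ],
        }


@dataclass(frozen=True)
class SyntheticCorpus:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ledger: GroundTruthLedger


def _validate_pools(config: SimulationConfig, smq: SmqDefinition) -> None:
    from .normalize import pt_key

    smq_keys = {pt_key(t) for t in smq.inclusion_pts} | {pt_key(t) for t in smq.suicide_pts}
    clash = [t for t in config.noise_pt_pool if pt_key(t) in smq_keys]
    if clash:
        raise ValueError(f"noise PTs collide with SMQ/suicide terms: {clash}")
    if config.event_pt_weights is not None:
        unknown = [
            t for t in config.event_pt_weights if pt_key(t) not in {pt_key(x) for x in smq.inclusion_pts}
        ]
        if unknown:
            raise ValueError(f"event PT weights name non-SMQ terms: {unknown}")


def _sample_bundle(
    rng: np.random.Generator, pool: list[str], size: int, probs: np.ndarray | None = None
) -> list[str]:
    limit = len(pool) if probs is None else int(np.count_nonzero(probs))
    size = min(size, limit)
    idx = rng.choice(len(pool), size=size, replace=False, p=probs)
    return [pool[i] for i in np.sort(idx)]


def _emit_date(day: dt.date, partial: bool) -> str:
    if partial:
        return f"{day.year:04d}{day.month:02d}"
    return f"{day.year:04d}{day.month:02d}{day.day:02d}"


def simulate_corpus(
    config: SimulationConfig,
    groups: list[DrugGroup] | None = None,
    smq: SmqDefinition | None = None,
) -> SyntheticCorpus:
    """Generate a corpus; deterministic for a fixed config (incl. seed)."""
    if groups is None or smq is None:
        default_groups, default_smq = load_default_lexicon()
        groups = groups or default_groups
        smq = smq or default_smq
    _validate_pools(config, smq)
    by_name = {g.name: g for g in groups}
    unknown = set(config.n_cases_per_group) - set(by_name)
    if unknown:
        raise ValueError(f"n_cases_per_group names unknown group(s): {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    inclusion = sorted(smq.inclusion_pts)
    overdose = sorted(smq.overdose_exclusion_pts)
    suicide = sorted(smq.suicide_pts)
    noise = list(config.noise_pt_pool)
    pt_probs: np.ndarray | None = None
    if config.event_pt_weights is not None:
        from .normalize import pt_key

        weight_by_key = {pt_key(t): w for t, w in config.event_pt_weights.items()}
        raw = np.array([weight_by_key.get(pt_key(t), 0.0) for t in inclusion], dtype=float)
        if raw.sum() <= 0:
            raise ValueError("event PT weights must have positive total mass")
        pt_probs = raw / raw.sum()
    countries = sorted(config.country_mix)
    country_p = np.array([config.country_mix[c] for c in countries])
    span = (config.window_end - config.window_start).days
    role_pool = ["PS", "SS", "C"]
    role_p = np.array([0.70, 0.15, 0.15])

    demo_rows: list[dict] = []
    drug_rows: list[dict] = []
    reac_rows: list[dict] = []
    truths: list[CaseTruth] = []
    next_case = 10_000_000

    for group_name in sorted(config.n_cases_per_group):
        n = config.n_cases_per_group[group_name]
        if n == 0:
            continue
        group = by_name[group_name]
        odds = config.event_odds[group_name]
        p_event = odds / (1.0 + odds)
        ingredients = sorted(group.ingredients)
        brands_by_ing: dict[str, list[str]] = {}
        for brand, generic in sorted(group.synonyms.items()):
            brands_by_ing.setdefault(generic, []).append(brand)

        planted = rng.random(n) < config.suicide_overdose_fraction
        event = (~planted) & (rng.random(n) < p_event)
        country_idx = rng.choice(len(countries), size=n, p=country_p)
        event_offsets = rng.integers(0, span + 1, size=n)
        fda_lags = rng.integers(0, 61, size=n)
        dup = rng.random(n) < config.duplicate_rate
        missing_event = rng.random(n) < config.missing_event_date_rate
        partial = (~missing_event) & (rng.random(n) < config.partial_date_rate)
        use_brand = rng.random(n) < config.brand_name_rate
        add_dose = rng.random(n) < config.dose_token_rate
        co_mention = rng.random(n) < config.co_mention_rate
        missing_ing = rng.random(n) < config.missing_ingredient_rate
        roles = rng.choice(role_pool, size=n, p=role_p)
        ing_idx = rng.integers(0, len(ingredients), size=n)
        other_groups = sorted(set(config.n_cases_per_group) - {group_name})

        for i in range(n):
            case_id = str(next_case)
            next_case += 1
            country = countries[country_idx[i]]
            event_day = config.window_start + dt.timedelta(days=int(event_offsets[i]))
            fda_day = event_day + dt.timedelta(days=int(fda_lags[i]))

            # reaction bundle
            pts: list[str]
            if planted[i]:
                k_od = 1 + int(rng.random() < 0.3)
                pts = _sample_bundle(rng, overdose, k_od)
                pts.append(suicide[int(rng.integers(0, len(suicide)))])
            elif event[i]:
                k = 1 + int(rng.binomial(2, 0.3))
                pts = _sample_bundle(rng, inclusion, k, pt_probs)
            else:
                pts = []
            k_noise = int(rng.integers(0, 3)) if pts else 1 + int(rng.integers(0, 3))
            pts.extend(_sample_bundle(rng, noise, k_noise))

            # drug mentions
            generic = ingredients[int(ing_idx[i])]
            verbatim = generic
            if use_brand[i] and generic in brands_by_ing:
                options = brands_by_ing[generic]
                verbatim = options[int(rng.integers(0, len(options)))]
            if add_dose[i]:
                dose = int(rng.integers(1, 6)) * 5
                verbatim = f"{verbatim} {dose} MG TABLET"
            mentions = [(verbatim, generic, str(roles[i]))]
            member_groups = set(resolve_drug(generic, groups))
            if co_mention[i] and other_groups:
                other = other_groups[int(rng.integers(0, len(other_groups)))]
                other_ing = sorted(by_name[other].ingredients)
                pick = other_ing[int(rng.integers(0, len(other_ing)))]
                mentions.append((pick, pick, "C"))
                member_groups |= set(resolve_drug(pick, groups))

            n_versions = 2 if dup[i] else 1
            for version in range(1, n_versions + 1):
                primary_id = f"{case_id}{version}"
                fda = fda_day if version == 1 else fda_day + dt.timedelta(days=7)
                demo_rows.append(
                    {
                        "primaryid": primary_id,
                        "caseid": case_id,
                        "caseversion": str(version),
                        "fda_dt": _emit_date(fda, False),
                        "event_dt": "" if missing_event[i] else _emit_date(event_day, bool(partial[i])),
                        "occr_country": country,
                    }
                )
                for seq, (name, ing, role) in enumerate(mentions, start=1):
                    drug_rows.append(
                        {
                            "primaryid": primary_id,
                            "drug_seq": str(seq),
                            "role_cod": role,
                            "drugname": name.upper(),
                            "prod_ai": "" if missing_ing[i] else ing.upper(),
                        }
                    )
                for pt in pts:
                    reac_rows.append({"primaryid": primary_id, "pt": pt})

            # scope truth mirrors the pipeline's date rule: event date (as the
            # parser will read it, i.e. truncated if partial) with FDA-date fallback.
            if missing_event[i]:
                scope_date: dt.date | None = fda_day
            elif partial[i]:
                scope_date = dt.date(event_day.year, event_day.month, 1)
            else:
                scope_date = event_day
            in_scope = (
                country == "US"
                and scope_date is not None
                and config.window_start <= scope_date <= config.window_end
            )
            truths.append(
                CaseTruth(
                    case_id=case_id,
                    primary_group=group_name,
                    groups=tuple(sorted(member_groups)),
                    true_event=bool(event[i]),
                    true_excluded=bool(planted[i]),
                    country=country,
                    scope_date=scope_date,
                    in_scope=in_scope,
                    n_versions=n_versions,
                )
            )

    demo = pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "occr_country"])
    drug = pd.DataFrame(drug_rows, columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"])
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])
    ledger = GroundTruthLedger(cases=tuple(truths), config=config)
    return SyntheticCorpus(demo=demo, drug=drug, reac=reac, ledger=ledger)


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict:
    """Write DEMO/DRUG/REAC files, the ledger and a run manifest; returns the
    manifest. Output is byte-identical for identical configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("demo", corpus.demo), ("drug", corpus.drug), ("reac", corpus.reac)):
        path = out / f"{name}.txt"
        frame.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path.name
    ledger_path = out / "ledger.json"
    ledger_path.write_text(
        json.dumps(corpus.ledger.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    paths["ledger"] = ledger_path.name
    manifest = {
        "tool": "hypnovigil",
        "version": __version__,
        "seed": corpus.ledger.config.seed,
        "config_sha256": corpus.ledger.config.config_hash(),
        "files": paths,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    return manifest


def simulate_event_tables(
    n_index: int,
    n_reference: int,
    odds_index: float,
    odds_reference: float,
    n_reps: int,
    seed: int,
) -> list[ContingencyTable]:
    """Replicate 2x2 tables under the generator's Bernoulli event model.

    This is the corpus generator's per-case event draw run in bulk (without
    report assembly), for studying the sampling behaviour of the estimators:
    per replicate, event counts are binomial with the groups' configured event
    probabilities ``odds/(1+odds)``.
    """
    if min(odds_index, odds_reference) <= 0:
        raise ValueError("event odds must be positive")
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_index, odds_index / (1 + odds_index), size=n_reps)
    c = rng.binomial(n_reference, odds_reference / (1 + odds_reference), size=n_reps)
    return [
        ContingencyTable(a=int(ai), b=int(n_index - ai), c=int(ci), d=int(n_reference - ci))
        for ai, ci in zip(a, c)
    ]


def reference_tables() -> dict[tuple[str, str], ContingencyTable]:
    """The six overall drug-vs-reference tables from the benchmark counts.

    Each table satisfies a+b = the group's printed total and a = its printed
    modified-SMQ case count.
    """
    tables: dict[tuple[str, str], ContingencyTable] = {}
    for index_name, reference_name in DEFAULT_COMPARISONS:
        total_i, n_i = REFERENCE_COUNTS[index_name]
        total_r, n_r = REFERENCE_COUNTS[reference_name]
        tables[(index_name, reference_name)] = ContingencyTable(
            a=n_i, b=total_i - n_i, c=n_r, d=total_r - n_r
        )
    return tables
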