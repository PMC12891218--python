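"""Drug-group lexicon and the modified-SMQ term sets.

The study compares seven groups of insomnia medications: three DEA Schedule IV
classes (benzodiazepines approved for any indication, the five benzodiazepines
approved for insomnia, Z-drugs, DORAs) and three unscheduled drugs (trazodone,
doxepin, ramelteon). Verbatim FAERS drug strings (brand or generic, with dose
and formulation suffixes) are resolved to these groups by exact match after
normalization — no fuzzy matching, no substring matching.

The abuse event of interest is defined by the MedDRA SMQ "Drug abuse,
dependence and withdrawal" (v26.1) PT list, modified by an exclusion of
suicide-related overdose-only cases; the three PT sets live in packaged text
files and are exposed as an :class:`SmqDefinition`.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .faers_io import ALL_ROLES, DrugRole, SafetyCase
from .normalize import drug_name_candidates, normalize_drug_name, pt_key

__all__ = [
    "DrugGroup",
    "SmqDefinition",
    "GROUP_ORDER",
    "load_default_lexicon",
    "resolve_drug",
    "case_in_group",
]

# Deterministic presentation order: Schedule IV classes first, then unscheduled.
GROUP_ORDER = (
    "benzodiazepine_any",
    "benzodiazepine_insomnia",
    "z_drug",
    "dora",
    "trazodone",
    "doxepin",
    "ramelteon",
)


@dataclass(frozen=True)
class DrugGroup:
    """A named set of active ingredients plus brand/alias synonyms.

    ``ingredients`` and the keys/values of ``synonyms`` are stored normalized
    (uppercase, whitespace-collapsed); lookup is exact against either.
    """

    name: str
    ingredients: frozenset[str]
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValueError(f"drug group {self.name!r} has no ingredients")

    @staticmethod
    def build(name: str, ingredients: Iterable[str], synonyms: Mapping[str, str] | None = None) -> "DrugGroup":
        norm_ing = frozenset(normalize_drug_name(i) for i in ingredients)
        norm_syn = {
            normalize_drug_name(brand): normalize_drug_name(generic)
            for brand, generic in (synonyms or {}).items()
        }
        return DrugGroup(name=name, ingredients=norm_ing, synonyms=norm_syn)

    def matches(self, candidate: str) -> bool:
        return candidate in self.ingredients or candidate in self.synonyms


@dataclass(frozen=True)
class SmqDefinition:
    """PT sets of the modified SMQ: inclusion terms, the overdose-type subset
    used by the exclusion rule, and the co-reported suicidal-behavior terms."""

    name: str
    inclusion_pts: frozenset[str]
    overdose_exclusion_pts: frozenset[str]
    suicide_pts: frozenset[str]

    def __post_init__(self) -> None:
        inc = {pt_key(t) for t in self.inclusion_pts}
        if not {pt_key(t) for t in self.overdose_exclusion_pts} <= inc:
            raise ValueError("overdose exclusion PTs must be a subset of the inclusion PTs")
        if {pt_key(t) for t in self.suicide_pts} & inc:
            raise ValueError("suicidal-behavior PTs must be disjoint from the inclusion PTs")
        object.__setattr__(self, "_inclusion_by_key", {pt_key(t): t for t in self.inclusion_pts})
        object.__setattr__(self, "_overdose_keys", frozenset(pt_key(t) for t in self.overdose_exclusion_pts))
        object.__setattr__(self, "_suicide_keys", frozenset(pt_key(t) for t in self.suicide_pts))

    @property
    def inclusion_by_key(self) -> Mapping[str, str]:
        return self._inclusion_by_key  # type: ignore[attr-defined]

    @property
    def overdose_keys(self) -> frozenset[str]:
        return self._overdose_keys  # type: ignore[attr-defined]

    @property
    def suicide_keys(self) -> frozenset[str]:
        return self._suicide_keys  # type: ignore[attr-defined]


def _read_pt_file(name: str) -> frozenset[str]:
    text = resources.files("hypnovigil.data").joinpath(name).read_text(encoding="utf-8")
    terms = [line.strip() for line in text.splitlines()]
    return frozenset(t for t in terms if t and not t.startswith("#"))


def _read_group_file(name: str) -> DrugGroup:
    text = (
        resources.files("hypnovigil.data")
        .joinpath(f"groups/{name}.yaml")
        .read_text(encoding="utf-8")
    )
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict) or "ingredients" not in payload:
        raise ValueError(f"corrupt packaged drug-group file for {name!r}")
    return DrugGroup.build(name, payload["ingredients"], payload.get("synonyms"))


def load_default_lexicon(
    overrides: Mapping[str, Mapping] | str | Path | None = None,
) -> tuple[list[DrugGroup], SmqDefinition]:
    """Load the packaged study drug groups and the modified-SMQ definition.

    ``overrides`` may be a mapping (or path to a YAML file) of
    ``group name -> {ingredients: [...], synonyms: {...}}``; named groups
    replace the packaged definition, unnamed packaged groups are kept.
    """
    override_map: Mapping[str, Mapping] = {}
    if overrides is not None:
        if isinstance(overrides, (str, Path)):
            override_map = yaml.safe_load(Path(overrides).read_text(encoding="utf-8")) or {}
        else:
            override_map = overrides
    groups: list[DrugGroup] = []
    for name in GROUP_ORDER:
        if name in override_map:
            spec = override_map[name]
            groups.append(DrugGroup.build(name, spec["ingredients"], spec.get("synonyms")))
        else:
            groups.append(_read_group_file(name))
    for name, spec in override_map.items():
        if name not in GROUP_ORDER:
            groups.append(DrugGroup.build(name, spec["ingredients"], spec.get("synonyms")))
    by_name = {g.name: g for g in groups}
    if "benzodiazepine_any" in by_name and "benzodiazepine_insomnia" in by_name:
        if not by_name["benzodiazepine_insomnia"].ingredients <= by_name["benzodiazepine_any"].ingredients:
            raise ValueError(
                "benzodiazepine_insomnia ingredients must be a subset of benzodiazepine_any"
            )
    smq = SmqDefinition(
        name="Drug abuse, dependence and withdrawal (modified)",
        inclusion_pts=_read_pt_file("smq_inclusion_pts.txt"),
        overdose_exclusion_pts=_read_pt_file("smq_overdose_exclusion_pts.txt"),
        suicide_pts=_read_pt_file("smq_suicide_pts.txt"),
    )
    return groups, smq


def resolve_drug(verbatim_name: str, groups: Sequence[DrugGroup]) -> frozenset[str]:
    """Map a verbatim drug string to the set of group names it belongs to.

    Normalization (uppercase, trim, dose/formulation token stripping) is
    followed by exact lookup against every group's ingredients and synonyms;
    one name may hit several groups (temazepam belongs to both benzodiazepine
    groups) and an unknown name yields the empty set.
    """
    candidates = drug_name_candidates(verbatim_name)
    hits = {
        group.name
        for group in groups
        if any(group.matches(c) for c in candidates)
    }
    return frozenset(hits)


def case_in_group(
    case: SafetyCase,
    group: DrugGroup,
    roles: Iterable[DrugRole] | None = None,
) -> bool:
    """True iff any drug mention with an accepted role resolves into ``group``.

    The default counts a drug in any role (primary/secondary suspect,
    concomitant, interacting); pass ``roles`` to restrict, e.g. suspect-only.
    Both the verbatim name and the reported active ingredient are tried.
    """
    accepted = frozenset(roles) if roles is not None else ALL_ROLES
    for mention in case.drugs:
        if mention.role not in accepted:
            continue
        names = [mention.verbatim_name]
        if mention.active_ingredient:
            names.append(mention.active_ingredient)
        for name in names:
            if any(group.matches(c) for c in drug_name_candidates(name)):
                return True
    return False
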