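"""Text normalization shared across the pipeline.

MedDRA preferred terms and FAERS drug strings are free text: case, stray
whitespace and dose/formulation suffixes vary between reports. All comparisons
in this package go through the helpers below so that the matching rules are
defined in exactly one place.
"""

from __future__ import annotations

import re

__all__ = [
    "collapse_whitespace",
    "pt_key",
    "normalize_drug_name",
    "drug_name_candidates",
]

_WS = re.compile(r"\s+")

# Tokens stripped from verbatim drug strings before exact matching. Covers dose
# units, formulations and common salt suffixes; matching stays exact-after-strip,
# never substring, to avoid false positives inside compounded product names.
_FORM_TOKENS = frozenset(
    {
        "MG", "MCG", "G", "ML", "MG/ML", "MG/DAY", "HCL", "HYDROCHLORIDE",
        "TARTRATE", "TABLET", "TABLETS", "TAB", "TABS", "CAPSULE", "CAPSULES",
        "CAP", "CAPS", "ORAL", "SOLUTION", "SPRAY", "SUBLINGUAL", "EXTENDED",
        "RELEASE", "CR", "ER", "XR", "SL", "FILM", "COATED", "UNKNOWN",
    }
)

_DOSE_TOKEN = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML)?$")


def collapse_whitespace(text: str) -> str:
    """Trim and collapse internal runs of whitespace to single spaces."""
    return _WS.sub(" ", text.strip())


def pt_key(term: str) -> str:
    """Canonical comparison key for a MedDRA PT (whitespace-collapsed, casefolded)."""
    return collapse_whitespace(term).casefold()


def normalize_drug_name(name: str) -> str:
    """Uppercase, whitespace-collapsed form of a verbatim drug string."""
    return collapse_whitespace(name).upper()


def drug_name_candidates(name: str) -> tuple[str, ...]:
    """Candidate strings for exact lexicon lookup of a verbatim drug name.

    Returns the normalized full string and, if different, the string with
    dose/formulation tokens stripped ("TEMAZEPAM 15 MG CAPSULE" -> "TEMAZEPAM").
    """
    full = normalize_drug_name(name)
    if not full:
        return ()
    kept = [
        tok
        for tok in full.split(" ")
        if tok not in _FORM_TOKENS and not _DOSE_TOKEN.match(tok)
    ]
    stripped = " ".join(kept)
    if stripped and stripped != full:
        return (full, stripped)
    return (full,)
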