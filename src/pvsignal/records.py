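"""Core record types shared by every stage of the pipeline.

A spontaneous adverse-event report (the unit of analysis throughout) carries
minimal demographics, an ordered list of drug mentions with reporter-assigned
roles, and a set of MedDRA preferred terms (PTs) describing the reactions.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from functools import lru_cache

#: Reporter-assigned drug roles: primary suspect, secondary suspect,
#: concomitant, interacting.
ROLES = ("PS", "SS", "C", "I")

SEXES = ("M", "F", "U")


@lru_cache(maxsize=8192)
def fold(term: str) -> str:
    """Canonical string form used for all name/PT comparisons."""
    return term.strip().casefold()


@dataclass(slots=True)
class DrugEntry:
    """One drug mention on a report.

    ``normalized_name`` is filled by curation; ``unresolved`` marks verbatim
    names the synonym map could not resolve (they are kept — they still
    contribute to the comparator background).
    """

    verbatim_name: str
    role: str
    normalized_name: str | None = None
    unresolved: bool = False


@dataclass(slots=True)
class ReportRecord:
    """One spontaneous report.

    ``report_id`` is unique within a database; ``case_id`` may be shared by
    several versions of the same case. ``reactions`` is a set of MedDRA PTs;
    a structurally valid report has at least one drug and one reaction.
    """

    report_id: str
    case_id: str
    receipt_date: _dt.date | None
    age_years: float | None
    sex: str
    country: str | None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: frozenset[str] = frozenset()

    def normalized_drug_names(self) -> set[str]:
        """Set of normalized names present on the report (any role)."""
        return {e.normalized_name for e in self.drugs if e.normalized_name}

    def primary_suspect_names(self) -> set[str]:
        return {
            e.normalized_name
            for e in self.drugs
            if e.role == "PS" and e.normalized_name
        }

    def folded_reactions(self) -> frozenset[str]:
        return frozenset(fold(r) for r in self.reactions)
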