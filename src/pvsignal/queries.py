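"""Case selection: from a curated database to the 2x2 contingency table.

A :class:`DrugQuery` defines the exposed population. Two modes mirror the two
designs a suspect-role-aware analysis needs:

* ``PRIMARY_SUSPECT_ONLY`` — a report is exposed iff one of the query drugs
  is its designated primary suspect (accurate attribution for single-drug
  analyses);
* ``ANY_ROLE`` — the drug may appear in any role; with ``combination=True``
  every query drug must co-occur on the report (the sensitive, unfiltered
  design used for co-reporting analyses).

An :class:`EndpointSet` is a named set of MedDRA preferred terms; a report
matches when its reaction set intersects the endpoint terms (exact string
equality after case-folding and whitespace trimming — no hierarchy
traversal). The comparator for every query is *all other reports in the
curated database*.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import ReportRecord, fold
from .stats import ContingencyTable

__all__ = [
    "PRIMARY_SUSPECT_ONLY",
    "ANY_ROLE",
    "DrugQuery",
    "EndpointSet",
    "report_matches_query",
    "report_matches_endpoint",
    "build_contingency",
    "contingency_panel",
]

PRIMARY_SUSPECT_ONLY = "PRIMARY_SUSPECT_ONLY"
ANY_ROLE = "ANY_ROLE"


@dataclass(frozen=True)
class DrugQuery:
    """Target drug set plus the role-filter mode defining case membership.

    ``exclude`` optionally bars reports mentioning any of the listed drugs
    (in any role) from the exposed group; empty by default.
    """

    drugs: frozenset[str]
    mode: str = PRIMARY_SUSPECT_ONLY
    combination: bool = False
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(fold(d) for d in self.drugs))
        object.__setattr__(self, "exclude", frozenset(fold(d) for d in self.exclude))
        if not self.drugs:
            raise ValueError("a drug query needs at least one drug")
        if self.mode not in (PRIMARY_SUSPECT_ONLY, ANY_ROLE):
            raise ValueError(f"unknown query mode {self.mode!r}")
        if self.combination and self.mode != ANY_ROLE:
            raise ValueError("combination queries require ANY_ROLE mode")
        if self.drugs & self.exclude:
            raise ValueError("a query drug cannot also be excluded")


@dataclass(frozen=True)
class EndpointSet:
    """Named outcome: a non-empty set of MedDRA preferred terms."""

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(fold(t) for t in self.terms))
        if not self.terms or any(not t for t in self.terms):
            raise ValueError(f"endpoint {self.name!r} needs non-empty terms")


def report_matches_query(record: ReportRecord, query: DrugQuery) -> bool:
    """Is this report in the exposed group?"""
    names = record.normalized_drug_names()
    if query.exclude & names:
        return False
    if query.mode == PRIMARY_SUSPECT_ONLY:
        return bool(query.drugs & record.primary_suspect_names())
    if query.combination:
        return query.drugs <= names
    return bool(query.drugs & names)


def report_matches_endpoint(record: ReportRecord, endpoint: EndpointSet) -> bool:
    """Does any reaction PT on the report belong to the endpoint?"""
    return bool(endpoint.terms & record.folded_reactions())


def build_contingency(
    records: Sequence[ReportRecord], query: DrugQuery, endpoint: EndpointSet
) -> ContingencyTable:
    """Count every report exactly once into a/b/c/d.

    Counting is report-level: a report mentioning a query drug twice still
    counts once.
    """
    if not records:
        raise ValueError("empty database")
    a = b = c = d = 0
    for rec in records:
        q = report_matches_query(rec, query)
        e = report_matches_endpoint(rec, endpoint)
        if q and e:
            a += 1
        elif q:
            b += 1
        elif e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def contingency_panel(
    records: Sequence[ReportRecord],
    queries: Sequence[tuple[str, DrugQuery]],
    endpoints: Sequence[EndpointSet],
) -> dict[tuple[str, str], ContingencyTable]:
    """All (query, endpoint) tables in one pass over the database.

    Equivalent to calling :func:`build_contingency` per pair, but each
    predicate is evaluated once per report.
    """
    if not records:
        raise ValueError("empty database")
    n = len(records)
    q_flags = {
        label: [report_matches_query(r, q) for r in records] for label, q in queries
    }
    folded = [r.folded_reactions() for r in records]
    tables: dict[tuple[str, str], ContingencyTable] = {}
    for ep in endpoints:
        e_flags = [bool(ep.terms & fr) for fr in folded]
        n_event = sum(e_flags)
        for label, _ in queries:
            qf = q_flags[label]
            a = sum(1 for q, e in zip(qf, e_flags) if q and e)
            nq = sum(qf)
            b = nq - a
            c = n_event - a
            d = n - nq - c
            tables[(label, ep.name)] = ContingencyTable(a, b, c, d)
    return tables
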