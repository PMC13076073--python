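"""Cleaning of a raw spontaneous-report database.

Three stages, applied in order:

1. drug-name normalization against a synonym map (brand names, salt forms and
   abbreviations mapped to a canonical USAN-style lower-case name; unmapped
   names are flagged unresolved but retained, since they still belong to the
   comparator background);
2. structural validation (a usable report has at least one drug, at least one
   reaction PT, a receipt date inside the analysis window, and a non-negative
   age when an age is present);
3. case-level deduplication by matching demographic and case-level variables,
   keeping one record per duplicate group.

Every exclusion is tallied in a :class:`CurationReport`, whose counts always
satisfy n_input = n_output + n_excluded_invalid + n_removed_duplicates.
"""
from __future__ import annotations

import datetime as _dt
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import ROLES, SEXES, DrugEntry, ReportRecord, fold

__all__ = [
    "SynonymMap",
    "CurationReport",
    "ParseError",
    "read_report_tables",
    "normalize_drug_names",
    "validate_records",
    "deduplicate",
    "curate",
]


class ParseError(ValueError):
    """Malformed or inconsistent input tables; message carries file context."""


@dataclass(frozen=True)
class SynonymMap:
    """Functional mapping case-folded verbatim name -> canonical name.

    Canonical names always map to themselves (identity entries are added on
    construction if missing).
    """

    entries: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs) -> "SynonymMap":
        entries: dict[str, str] = {}
        for verbatim, canonical in pairs:
            key = fold(verbatim)
            canon = fold(canonical)
            if not canon:
                raise ParseError(f"empty canonical name for verbatim {verbatim!r}")
            if entries.get(key, canon) != canon:
                raise ParseError(
                    f"synonym map is not functional: {key!r} maps to both "
                    f"{entries[key]!r} and {canon!r}"
                )
            entries[key] = canon
        for canon in list(entries.values()):
            entries.setdefault(canon, canon)
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymMap":
        """Two-column CSV (verbatim, normalized), header row."""
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except FileNotFoundError:
            raise ParseError(f"synonym map not found: {path}") from None
        if df.shape[1] < 2:
            raise ParseError(f"synonym map {path} needs two columns, got {list(df.columns)}")
        return cls.from_pairs(df.iloc[:, :2].itertuples(index=False))

    def lookup(self, verbatim: str) -> tuple[str, bool]:
        """Return (normalized_name, resolved). A miss yields the case-folded
        verbatim itself with resolved = False."""
        key = fold(verbatim)
        if key in self.entries:
            return self.entries[key], True
        return key, False


@dataclass
class CurationReport:
    """Bookkeeping for one curation run."""

    n_input: int = 0
    n_excluded_invalid: int = 0
    n_removed_duplicates: int = 0
    n_output: int = 0
    exclusion_reasons: Counter = field(default_factory=Counter)

    def check_conservation(self) -> None:
        if self.n_input != (
            self.n_output + self.n_excluded_invalid + self.n_removed_duplicates
        ):
            raise AssertionError("curation counts do not conserve records")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_excluded_invalid": self.n_excluded_invalid,
            "n_removed_duplicates": self.n_removed_duplicates,
            "n_output": self.n_output,
            "exclusion_reasons": dict(sorted(self.exclusion_reasons.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reading the three-table layout


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParseError(msg)


def read_report_tables(path: str | Path) -> list[ReportRecord]:
    """Read demo.csv / drug.csv / reac.csv and join them on report_id.

    Reports present in demo but absent from drug/reac get empty drug or
    reaction lists (they will be excluded by validation). Records are
    returned sorted by report_id.
    """
    base = Path(path)
    frames = {}
    for name in ("demo", "drug", "reac"):
        f = base / f"{name}.csv"
        if not f.exists():
            raise ParseError(f"missing table: {f}")
        try:
            frames[name] = pd.read_csv(f, dtype=str, keep_default_na=False)
        except Exception as exc:  # malformed CSV
            raise ParseError(f"cannot parse {f}: {exc}") from exc

    demo, drug, reac = frames["demo"], frames["drug"], frames["reac"]
    _require(
        list(demo.columns)
        == ["report_id", "case_id", "receipt_date", "age_years", "sex", "country"],
        f"unexpected demo.csv columns: {list(demo.columns)}",
    )
    _require(
        list(drug.columns) == ["report_id", "verbatim_name", "role"],
        f"unexpected drug.csv columns: {list(drug.columns)}",
    )
    _require(
        list(reac.columns) == ["report_id", "preferred_term"],
        f"unexpected reac.csv columns: {list(reac.columns)}",
    )
    dupes = demo["report_id"][demo["report_id"].duplicated()]
    if not dupes.empty:
        raise ParseError(
            f"duplicate report_id in demo.csv: {dupes.iloc[0]!r} "
            f"(row {int(dupes.index[0]) + 2})"
        )
    known = set(demo["report_id"])
    for name, frame in (("drug", drug), ("reac", reac)):
        unknown = frame.loc[~frame["report_id"].isin(known), "report_id"]
        if not unknown.empty:
            raise ParseError(
                f"{name}.csv references report_id {unknown.iloc[0]!r} "
                f"absent from demo.csv (row {int(unknown.index[0]) + 2})"
            )

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for rid, verbatim, role in drug.itertuples(index=False):
        if role not in ROLES:
            raise ParseError(
                f"drug.csv, report {rid}: unknown role {role!r}; expected one of {ROLES}"
            )
        drugs_by_id.setdefault(rid, []).append(DrugEntry(verbatim, role))
    reacs_by_id: dict[str, list[str]] = {}
    for rid, term in reac.itertuples(index=False):
        reacs_by_id.setdefault(rid, []).append(term)

    records = []
    for row in demo.itertuples(index=False):
        rid = row.report_id
        try:
            date = (
                _dt.date.fromisoformat(row.receipt_date) if row.receipt_date else None
            )
        except ValueError as exc:
            raise ParseError(f"demo.csv, report {rid}: bad date {row.receipt_date!r}") from exc
        try:
            age = float(row.age_years) if row.age_years != "" else None
        except ValueError as exc:
            raise ParseError(f"demo.csv, report {rid}: bad age {row.age_years!r}") from exc
        sex = row.sex or "U"
        if sex not in SEXES:
            raise ParseError(f"demo.csv, report {rid}: sex must be one of {SEXES}, got {sex!r}")
        records.append(
            ReportRecord(
                report_id=rid,
                case_id=row.case_id,
                receipt_date=date,
                age_years=age,
                sex=sex,
                country=row.country or None,
                drugs=drugs_by_id.get(rid, []),
                reactions=frozenset(reacs_by_id.get(rid, ())),
            )
        )
    records.sort(key=lambda r: r.report_id)
    return records


# ---------------------------------------------------------------------------
# normalization


def normalize_drug_names(
    records: list[ReportRecord], synonyms: SynonymMap
) -> list[ReportRecord]:
    """Fill normalized_name on every drug entry (in place); idempotent."""
    for record in records:
        for entry in record.drugs:
            name, resolved = synonyms.lookup(entry.verbatim_name)
            entry.normalized_name = name
            entry.unresolved = not resolved
    return records


# ---------------------------------------------------------------------------
# validation

# one primary reason per excluded record, in this fixed precedence
REASON_DATE = "outside window"
REASON_DRUGS = "no drugs"
REASON_REACTIONS = "no reactions"
REASON_DEMOGRAPHICS = "negative age"


def validate_records(
    records: list[ReportRecord], window: tuple[_dt.date, _dt.date]
) -> tuple[list[ReportRecord], CurationReport]:
    """Drop structurally invalid records; the window is closed on both ends."""
    start, end = window
    kept: list[ReportRecord] = []
    report = CurationReport(n_input=len(records))
    for rec in records:
        if rec.receipt_date is None or not (start <= rec.receipt_date <= end):
            reason = REASON_DATE
        elif not rec.drugs:
            reason = REASON_DRUGS
        elif not rec.reactions:
            reason = REASON_REACTIONS
        elif rec.age_years is not None and rec.age_years < 0:
            reason = REASON_DEMOGRAPHICS
        else:
            kept.append(rec)
            continue
        report.n_excluded_invalid += 1
        report.exclusion_reasons[reason] += 1
    report.n_output = len(kept)
    report.check_conservation()
    return kept, report


# ---------------------------------------------------------------------------
# deduplication


def _duplicate_key(rec: ReportRecord) -> tuple:
    # demographic + case-level variables; age rounded to whole years to
    # tolerate unit jitter between re-submissions
    age = None if rec.age_years is None else round(rec.age_years)
    drugs = tuple(sorted({e.normalized_name or fold(e.verbatim_name) for e in rec.drugs}))
    return (rec.sex, age, rec.country, drugs, tuple(sorted(rec.reactions)))


def deduplicate(
    records: list[ReportRecord],
) -> tuple[list[ReportRecord], CurationReport]:
    """Remove duplicate cases.

    Records sharing a case_id are versions of one case and form a group;
    otherwise records grouped on the tuple (sex, rounded age, country, sorted
    normalized drug names, sorted reaction PTs) are treated as duplicate
    submissions. Each group keeps the record with the latest receipt date,
    ties broken by the lexicographically smallest report_id. The retained set
    does not depend on input order.
    """
    report = CurationReport(n_input=len(records))
    case_counts = Counter(rec.case_id for rec in records)
    groups: dict[tuple, list[ReportRecord]] = {}
    for rec in records:
        if case_counts[rec.case_id] > 1:
            key = ("case", rec.case_id)
        else:
            key = ("tuple",) + _duplicate_key(rec)
        groups.setdefault(key, []).append(rec)

    kept: list[ReportRecord] = []
    for members in groups.values():
        winner = max(
            members,
            key=lambda r: (
                r.receipt_date or _dt.date.min,
                # latest date wins; among ties the smallest report_id wins
                tuple(-ord(ch) for ch in r.report_id),
            ),
        )
        kept.append(winner)
        report.n_removed_duplicates += len(members) - 1
    kept.sort(key=lambda r: r.report_id)
    report.n_output = len(kept)
    report.check_conservation()
    return kept, report


# ---------------------------------------------------------------------------
# the full chain


def curate(
    records: list[ReportRecord],
    synonyms: SynonymMap,
    window: tuple[_dt.date, _dt.date],
) -> tuple[list[ReportRecord], CurationReport]:
    """normalize -> validate -> deduplicate, with merged bookkeeping."""
    normalize_drug_names(records, synonyms)
    valid, v_report = validate_records(records, window)
    deduped, d_report = deduplicate(valid)
    merged = CurationReport(
        n_input=v_report.n_input,
        n_excluded_invalid=v_report.n_excluded_invalid,
        n_removed_duplicates=d_report.n_removed_duplicates,
        n_output=d_report.n_output,
        exclusion_reasons=v_report.exclusion_reasons,
    )
    merged.check_conservation()
    return deduped, merged
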