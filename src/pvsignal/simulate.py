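"""Synthetic spontaneous-report database generator with known ground truth.

The generator emulates the structure of a FAERS-style spontaneous reporting
system — per-report demographics, drug mentions with reporter roles and
brand/generic name variants, MedDRA preferred-term (PT) reactions, duplicate
submissions and structurally invalid records — while planting a *known*
drug-event association structure so that every downstream stage (curation,
querying, disproportionality statistics) can be scored against the truth.

Event model
-----------
Each PT is an independent Bernoulli draw per report. A report's probability
for PT j is

    p_j = logit^{-1}( logit(baseline_j) + sum_{drug i on report} ln(theta_ij) )

so a configured odds multiplier theta for a (drug, PT) pair IS the true
reporting odds ratio between exposed and unexposed reports — which makes
parameter recovery by the downstream ROR well defined. Reports whose reaction
vector comes up empty are redrawn (a reaction-free report is structurally
invalid by definition and only ever produced as planted contamination); with
the default catalogs the probability of an empty vector is ~1.5e-3, so the
marginal PT frequencies stay within Monte-Carlo noise of their baselines.

Determinism
-----------
Generation is fully vectorised; random draws are consumed in a fixed
field-major order (documented in docs/methods.md), so a given ``SimConfig``
(including its seed) always yields byte-identical output tables.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from itertools import islice
from pathlib import Path

import numpy as np
import pandas as pd

from .records import DrugEntry, ReportRecord

__all__ = [
    "DrugSpec",
    "EventSpec",
    "Effect",
    "SimConfig",
    "GroundTruth",
    "SimConfigError",
    "generate_reports",
    "write_report_tables",
    "write_ground_truth",
]

DEFAULT_ROLE_DISTRIBUTION = {"PS": 0.45, "SS": 0.20, "C": 0.30, "I": 0.05}

DEFAULT_SEXES = ("M", "F", "U")
DEFAULT_SEX_PROBS = (0.43, 0.52, 0.05)
DEFAULT_COUNTRIES = ("US", "CA", "GB", "DE", "FR", "JP", "AU", "BR")
DEFAULT_COUNTRY_PROBS = (0.70, 0.05, 0.05, 0.04, 0.04, 0.04, 0.03, 0.05)


class SimConfigError(ValueError):
    """A SimConfig invariant is violated; the message names it."""


@dataclass(frozen=True, slots=True)
class DrugSpec:
    """One marketed drug: canonical name, verbatim aliases as they appear on
    reports, and the per-report probability of being mentioned."""

    name: str
    aliases: tuple[str, ...]
    marketing_probability: float


@dataclass(frozen=True, slots=True)
class EventSpec:
    """One MedDRA PT with its baseline per-report probability."""

    term: str
    baseline_probability: float


@dataclass(frozen=True, slots=True)
class Effect:
    """Planted association: reports carrying ``drug`` have their odds of
    ``term`` multiplied by ``theta``."""

    drug: str
    term: str
    theta: float


@dataclass(slots=True)
class SimConfig:
    """Generative parameters for one synthetic database."""

    n_reports: int
    date_start: _dt.date
    date_end: _dt.date
    drug_catalog: list[DrugSpec]
    event_catalog: list[EventSpec]
    effects: list[Effect] = field(default_factory=list)
    role_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_DISTRIBUTION)
    )
    duplicate_rate: float = 0.0
    invalid_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise SimConfigError("n_reports must be a positive integer")
        if self.date_end < self.date_start:
            raise SimConfigError("date_end must not precede date_start")
        if not self.drug_catalog:
            raise SimConfigError("drug_catalog must be non-empty")
        if not self.event_catalog:
            raise SimConfigError("event_catalog must be non-empty")
        for spec in self.drug_catalog:
            if not 0.0 <= spec.marketing_probability <= 1.0:
                raise SimConfigError(
                    f"marketing_probability for {spec.name!r} outside [0, 1]"
                )
            if not spec.aliases:
                raise SimConfigError(f"drug {spec.name!r} has no verbatim aliases")
        for spec in self.event_catalog:
            if not 0.0 <= spec.baseline_probability <= 1.0:
                raise SimConfigError(
                    f"baseline_probability for {spec.term!r} outside [0, 1]"
                )
        drug_names = {s.name for s in self.drug_catalog}
        event_terms = {s.term for s in self.event_catalog}
        for eff in self.effects:
            if eff.drug not in drug_names:
                raise SimConfigError(f"effect references unknown drug {eff.drug!r}")
            if eff.term not in event_terms:
                raise SimConfigError(f"effect references unknown PT {eff.term!r}")
            if not eff.theta > 0:
                raise SimConfigError(
                    f"odds multiplier for ({eff.drug!r}, {eff.term!r}) must be > 0"
                )
        if set(self.role_distribution) != {"PS", "SS", "C", "I"}:
            raise SimConfigError("role_distribution must cover exactly PS, SS, C, I")
        if any(p < 0 for p in self.role_distribution.values()):
            raise SimConfigError("role_distribution probabilities must be >= 0")
        if abs(sum(self.role_distribution.values()) - 1.0) > 1e-9:
            raise SimConfigError("role_distribution must sum to 1")
        if sum(self.role_distribution[r] for r in ("SS", "C", "I")) <= 0:
            raise SimConfigError("role_distribution must give non-PS roles some mass")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise SimConfigError("duplicate_rate must lie in [0, 1)")
        if not 0.0 <= self.invalid_rate < 1.0:
            raise SimConfigError("invalid_rate must lie in [0, 1)")
        if self.duplicate_rate + self.invalid_rate >= 1.0:
            raise SimConfigError("duplicate_rate + invalid_rate must be < 1")


@dataclass(slots=True)
class GroundTruth:
    """What the generator actually did, for scoring downstream stages."""

    effects: dict[tuple[str, str], float]
    duplicate_of: dict[str, str]  # clone report_id -> source report_id
    invalid_ids: set[str]
    report_ids: list[str]

    def theta(self, drug: str, term: str) -> float:
        return self.effects.get((drug, term), 1.0)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def generate_reports(config: SimConfig) -> tuple[list[ReportRecord], GroundTruth]:
    """Generate a synthetic database.

    Returns the reports (primaries, then duplicate clones, then invalid
    records) and the ground truth covering every one of them. Deterministic
    for a given config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    n_drugs = len(config.drug_catalog)
    n_events = len(config.event_catalog)

    # --- field-major draws, fixed order -----------------------------------
    span = (config.date_end - config.date_start).days
    day_offsets = rng.integers(0, span + 1, size=n)
    ages = np.clip(np.rint(rng.normal(52.0, 17.0, size=n)), 18, 90)
    sexes = rng.choice(DEFAULT_SEXES, size=n, p=DEFAULT_SEX_PROBS)
    countries = rng.choice(DEFAULT_COUNTRIES, size=n, p=DEFAULT_COUNTRY_PROBS)

    probs = np.array([s.marketing_probability for s in config.drug_catalog])
    drug_mask = rng.random((n, n_drugs)) < probs  # column j = drug j present
    # a spontaneous report exists to implicate a drug: redraw empty drug sets
    # (does not alter event odds, which are conditional on the drugs present)
    no_drug = ~drug_mask.any(axis=1)
    while no_drug.any():
        idx = np.flatnonzero(no_drug)
        drug_mask[idx] = rng.random((len(idx), n_drugs)) < probs
        no_drug[idx] = ~drug_mask[idx].any(axis=1)

    # verbatim alias per mention, drawn column-wise in catalog order
    alias_idx = np.zeros((n, n_drugs), dtype=np.int64)
    for j, spec in enumerate(config.drug_catalog):
        col = drug_mask[:, j]
        alias_idx[col, j] = rng.integers(0, len(spec.aliases), size=int(col.sum()))

    # exactly one primary suspect per report with any drug: uniform pick
    # among the drugs present; remaining mentions draw SS/C/I from the
    # renormalised role distribution
    counts = drug_mask.sum(axis=1)
    ps_pick = np.floor(rng.random(n) * np.maximum(counts, 1)).astype(np.int64)
    other_roles_u = rng.random((n, n_drugs))
    non_ps = np.array([config.role_distribution[r] for r in ("SS", "C", "I")])
    non_ps = non_ps / non_ps.sum()
    role_edges = np.cumsum(non_ps)[:-1]
    role_codes = np.digitize(other_roles_u, role_edges)  # 0->SS, 1->C, 2->I

    # reaction matrix: additive log-odds of planted effects
    base = np.array([s.baseline_probability for s in config.event_catalog])
    log_theta = np.zeros((n_drugs, n_events))
    drug_index = {s.name: j for j, s in enumerate(config.drug_catalog)}
    event_index = {s.term: j for j, s in enumerate(config.event_catalog)}
    for eff in config.effects:
        log_theta[drug_index[eff.drug], event_index[eff.term]] += np.log(eff.theta)
    eta = _logit(np.clip(base, 1e-12, 1 - 1e-12)) + drug_mask @ log_theta
    p_event = 1.0 / (1.0 + np.exp(-eta))
    event_mask = rng.random((n, n_events)) < p_event
    # redraw empty reaction vectors (structurally invalid by definition)
    empty = ~event_mask.any(axis=1)
    while empty.any():
        idx = np.flatnonzero(empty)
        event_mask[idx] = rng.random((len(idx), n_events)) < p_event[idx]
        empty[idx] = ~event_mask[idx].any(axis=1)

    # --- materialise primary reports --------------------------------------
    epoch = config.date_start.toordinal()
    from_ordinal = _dt.date.fromordinal
    dates = [from_ordinal(epoch + o) for o in day_offsets.tolist()]
    aliases = [s.aliases for s in config.drug_catalog]
    terms = [s.term for s in config.event_catalog]

    # flatten the two sparse matrices to mention-level lists (row-major),
    # resolve roles vectorised (the PS slot by position within the report),
    # then regroup per report with islice
    drug_rows, drug_cols = np.nonzero(drug_mask)
    mention_counts = drug_mask.sum(axis=1)
    offsets = np.concatenate(([0], np.cumsum(mention_counts)[:-1]))
    positions = np.arange(len(drug_rows)) - offsets[drug_rows]
    role_code_flat = np.where(
        positions == ps_pick[drug_rows], 3, role_codes[drug_rows, drug_cols]
    )
    role_names = ("SS", "C", "I", "PS")
    roles_l = [role_names[cd] for cd in role_code_flat.tolist()]
    verbatims = [
        aliases[j][k]
        for j, k in zip(drug_cols.tolist(), alias_idx[drug_rows, drug_cols].tolist())
    ]
    entries_flat = list(map(DrugEntry, verbatims, roles_l))
    eit = iter(entries_flat)
    drugs_per = [list(islice(eit, int(k))) for k in mention_counts.tolist()]

    ev_counts = event_mask.sum(axis=1).tolist()
    rit = map(terms.__getitem__, np.nonzero(event_mask)[1].tolist())
    reactions_per = [frozenset(islice(rit, m)) for m in ev_counts]

    records = list(
        map(
            ReportRecord,
            ["R%08d" % i for i in range(n)],
            ["C%08d" % i for i in range(n)],
            dates,
            ages.tolist(),
            sexes.tolist(),
            countries.tolist(),
            drugs_per,
            reactions_per,
        )
    )

    # --- contamination: exact counts --------------------------------------
    n_dup = round(config.duplicate_rate * n)
    n_inv = round(config.invalid_rate * n)
    duplicate_of: dict[str, str] = {}
    invalid_ids: set[str] = set()
    next_id = n

    if n_dup:
        dup_sources = rng.choice(n, size=n_dup, replace=False)
        shifts = rng.integers(1, 31, size=n_dup)
        for src, shift in zip(dup_sources, shifts):
            source = records[src]
            shifted = source.receipt_date + _dt.timedelta(days=int(shift))
            if shifted > config.date_end:
                shifted = source.receipt_date - _dt.timedelta(days=int(shift))
                if shifted < config.date_start:
                    shifted = source.receipt_date
            rid = f"R{next_id:08d}"
            clone = ReportRecord(
                report_id=rid,
                case_id=f"C{next_id:08d}",
                receipt_date=shifted,
                age_years=source.age_years,
                sex=source.sex,
                country=source.country,
                drugs=[DrugEntry(e.verbatim_name, e.role) for e in source.drugs],
                reactions=source.reactions,
            )
            duplicate_of[rid] = source.report_id
            records.append(clone)
            next_id += 1

    if n_inv:
        inv_sources = rng.choice(n, size=n_inv, replace=False)
        modes = rng.integers(0, 3, size=n_inv)  # 0=no drugs, 1=no reactions, 2=bad age
        for src, mode in zip(inv_sources, modes):
            source = records[src]
            rid = f"R{next_id:08d}"
            broken = ReportRecord(
                report_id=rid,
                case_id=f"C{next_id:08d}",
                receipt_date=source.receipt_date,
                age_years=-1.0 if mode == 2 else source.age_years,
                sex=source.sex,
                country=source.country,
                drugs=[]
                if mode == 0
                else [DrugEntry(e.verbatim_name, e.role) for e in source.drugs],
                reactions=frozenset() if mode == 1 else source.reactions,
            )
            invalid_ids.add(rid)
            records.append(broken)
            next_id += 1

    truth = GroundTruth(
        effects={(e.drug, e.term): e.theta for e in config.effects},
        duplicate_of=duplicate_of,
        invalid_ids=invalid_ids,
        report_ids=[r.report_id for r in records],
    )
    return records, truth


# ---------------------------------------------------------------------------
# three-table CSV layout


def write_report_tables(reports: list[ReportRecord], path: str | Path) -> None:
    """Write demo.csv / drug.csv / reac.csv (UTF-8, header row, RFC-4180).

    Reactions are written sorted so that identical databases yield
    byte-identical files.
    """
    if not reports:
        raise ValueError("no reports to write")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    def _age(a: float | None) -> str:
        return "" if a is None else format(a, "g")

    demo = pd.DataFrame(
        {
            "report_id": [r.report_id for r in reports],
            "case_id": [r.case_id for r in reports],
            "receipt_date": [
                "" if r.receipt_date is None else r.receipt_date.isoformat()
                for r in reports
            ],
            "age_years": [_age(r.age_years) for r in reports],
            "sex": [r.sex for r in reports],
            "country": [r.country or "" for r in reports],
        }
    )
    drug_rows = [
        (r.report_id, e.verbatim_name, e.role) for r in reports for e in r.drugs
    ]
    reac_rows = [
        (r.report_id, term) for r in reports for term in sorted(r.reactions)
    ]
    demo.to_csv(out / "demo.csv", index=False, lineterminator="\n")
    pd.DataFrame(drug_rows, columns=["report_id", "verbatim_name", "role"]).to_csv(
        out / "drug.csv", index=False, lineterminator="\n"
    )
    pd.DataFrame(reac_rows, columns=["report_id", "preferred_term"]).to_csv(
        out / "reac.csv", index=False, lineterminator="\n"
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "effects": [
            {"drug": d, "term": t, "theta": th}
            for (d, t), th in sorted(truth.effects.items())
        ],
        "duplicate_of": dict(sorted(truth.duplicate_of.items())),
        "invalid_ids": sorted(truth.invalid_ids),
        "n_reports": len(truth.report_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
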