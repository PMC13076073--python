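"""Default study configuration: a worked renal-safety example.

This module ships the configuration the package uses as its running example:
a synthetic spontaneous-report database in which a mood stabiliser (lithium)
carries strongly elevated reporting odds for five renal preferred terms, a
GLP-1 receptor agonist (semaglutide) carries reduced odds for four of them,
and the two are analysed singly (primary-suspect filter) and as an
unfiltered co-reporting query.

Everything here is a fixture choice, not an estimate of any real database:
marketing probabilities and PT baselines were set by a design power
calculation (see docs/methods.md) so that planted odds multipliers are
recoverable at moderate database sizes, and the background PT catalog
carries enough mass that reaction-free draws are vanishingly rare.
"""
from __future__ import annotations

import datetime as _dt

from .curation import SynonymMap
from .queries import ANY_ROLE, PRIMARY_SUSPECT_ONLY, DrugQuery, EndpointSet
from .simulate import DrugSpec, Effect, EventSpec, SimConfig

__all__ = [
    "RENAL_TERMS",
    "WINDOW",
    "default_drug_catalog",
    "default_event_catalog",
    "default_synonym_map",
    "default_endpoints",
    "study_queries",
    "study_effects",
    "default_sim_config",
]

#: The five renal MedDRA preferred terms used as endpoints.
RENAL_TERMS = (
    "Renal impairment",
    "Renal failure",
    "Chronic kidney disease",
    "End stage renal disease",
    "Acute kidney injury",
)

#: Default analysis window (closed on both ends).
WINDOW = (_dt.date(2003, 12, 1), _dt.date(2024, 12, 31))

_DRUGS: list[tuple[str, tuple[str, ...], float]] = [
    ("lithium", ("lithium", "Lithium Carbonate", "LITHIUM", "Lithobid", "Eskalith", "lithium citrate"), 0.04),
    ("semaglutide", ("semaglutide", "Ozempic", "OZEMPIC", "Wegovy", "Rybelsus"), 0.03),
    ("metformin", ("metformin", "Glucophage", "METFORMIN HCL"), 0.20),
    ("atorvastatin", ("atorvastatin", "Lipitor"), 0.18),
    ("lisinopril", ("lisinopril", "Zestril", "Prinivil"), 0.15),
    ("ibuprofen", ("ibuprofen", "Advil", "Motrin"), 0.15),
    ("omeprazole", ("omeprazole", "Prilosec"), 0.12),
    ("sertraline", ("sertraline", "Zoloft"), 0.10),
    ("quetiapine", ("quetiapine", "Seroquel"), 0.08),
    ("insulin glargine", ("insulin glargine", "Lantus"), 0.06),
]

_RENAL_BASELINES = {
    "Acute kidney injury": 0.008,
    "Renal failure": 0.006,
    "Renal impairment": 0.005,
    "Chronic kidney disease": 0.004,
    "End stage renal disease": 0.002,
}

# Background symptom PTs. Their combined mass keeps the probability of an
# empty reaction vector near 1.5e-3, so rejection resampling barely perturbs
# the per-PT marginals.
_BACKGROUND_EVENTS = [
    ("Nausea", 0.45), ("Fatigue", 0.40), ("Headache", 0.38), ("Diarrhoea", 0.35),
    ("Dizziness", 0.32), ("Vomiting", 0.30), ("Dyspnoea", 0.28), ("Rash", 0.26),
    ("Pruritus", 0.24), ("Arthralgia", 0.22), ("Pain", 0.20), ("Insomnia", 0.20),
    ("Constipation", 0.18), ("Anxiety", 0.18), ("Oedema peripheral", 0.16),
    ("Weight decreased", 0.16), ("Tremor", 0.14), ("Hypertension", 0.14),
    ("Abdominal pain", 0.12), ("Malaise", 0.12), ("Cough", 0.10), ("Myalgia", 0.10),
    ("Back pain", 0.10), ("Pyrexia", 0.08), ("Somnolence", 0.08),
    ("Decreased appetite", 0.08), ("Dry mouth", 0.06), ("Palpitations", 0.06),
    ("Hyperhidrosis", 0.05), ("Alopecia", 0.05),
]


def default_drug_catalog() -> list[DrugSpec]:
    return [DrugSpec(name, aliases, p) for name, aliases, p in _DRUGS]


def default_event_catalog() -> list[EventSpec]:
    renal = [EventSpec(term, _RENAL_BASELINES[term]) for term in RENAL_TERMS]
    background = [EventSpec(t, p) for t, p in _BACKGROUND_EVENTS]
    return renal + background


def default_synonym_map() -> SynonymMap:
    pairs = [(alias, name) for name, aliases, _ in _DRUGS for alias in aliases]
    return SynonymMap.from_pairs(pairs)


def default_endpoints() -> list[EndpointSet]:
    """One endpoint per renal PT, keyed by a short outcome label."""
    labels = {
        "Renal impairment": "renal impairment",
        "Renal failure": "renal failure",
        "Chronic kidney disease": "CKD",
        "End stage renal disease": "ESRD",
        "Acute kidney injury": "AKI",
    }
    return [EndpointSet(labels[t], frozenset({t})) for t in RENAL_TERMS]


def study_queries() -> list[tuple[str, DrugQuery]]:
    """The three study queries: each drug as primary suspect, and their
    unfiltered co-reporting."""
    return [
        ("lithium", DrugQuery(frozenset({"lithium"}), PRIMARY_SUSPECT_ONLY)),
        ("semaglutide", DrugQuery(frozenset({"semaglutide"}), PRIMARY_SUSPECT_ONLY)),
        (
            "lithium+semaglutide",
            DrugQuery(frozenset({"lithium", "semaglutide"}), ANY_ROLE, combination=True),
        ),
    ]


def study_effects() -> list[Effect]:
    """Planted associations mirroring the example's qualitative pattern:
    strongly elevated renal reporting for lithium (theta = 8 on every renal
    PT), reduced reporting for semaglutide on four PTs and neutral on acute
    kidney injury."""
    effects = [Effect("lithium", term, 8.0) for term in RENAL_TERMS]
    for term in RENAL_TERMS:
        if term != "Acute kidney injury":
            effects.append(Effect("semaglutide", term, 0.5))
    return effects


def write_synonym_csv(path) -> None:
    """Two-column verbatim->canonical CSV for the default catalog."""
    import csv
    from pathlib import Path

    with open(Path(path), "w", newline="", encoding="utf-8") as f:
        w = csv.writer(f)
        w.writerow(["verbatim", "normalized"])
        for name, aliases, _ in _DRUGS:
            for alias in aliases:
                w.writerow([alias, name])


def write_endpoints_json(path) -> None:
    """Endpoint definition file for the five renal outcomes."""
    import json
    from pathlib import Path

    payload = [
        {"name": ep.name, "terms": sorted(ep.terms)} for ep in default_endpoints()
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_study_inputs(
    directory,
    n_reports: int = 100_000,
    seed: int = 0,
    effects=None,
    duplicate_rate: float = 0.05,
    invalid_rate: float = 0.02,
):
    """Materialise a complete study on disk: raw tables, ground truth,
    synonym map and endpoint definitions. Returns the input directory."""
    from pathlib import Path

    from .simulate import generate_reports, write_ground_truth, write_report_tables

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = default_sim_config(
        n_reports=n_reports, seed=seed, effects=effects,
        duplicate_rate=duplicate_rate, invalid_rate=invalid_rate,
    )
    reports, truth = generate_reports(config)
    write_report_tables(reports, directory)
    write_ground_truth(truth, directory / "ground_truth.json")
    write_synonym_csv(directory / "synonyms.csv")
    write_endpoints_json(directory / "endpoints.json")
    return directory


def default_sim_config(
    n_reports: int = 100_000,
    seed: int = 0,
    effects: list[Effect] | None = None,
    duplicate_rate: float = 0.05,
    invalid_rate: float = 0.02,
) -> SimConfig:
    """Study-shaped generator config; pass ``effects=[]`` for a null database."""
    return SimConfig(
        n_reports=n_reports,
        date_start=WINDOW[0],
        date_end=WINDOW[1],
        drug_catalog=default_drug_catalog(),
        event_catalog=default_event_catalog(),
        effects=study_effects() if effects is None else effects,
        duplicate_rate=duplicate_rate,
        invalid_rate=invalid_rate,
        seed=seed,
    )
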