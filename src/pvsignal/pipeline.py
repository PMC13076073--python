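"""Orchestration: curation -> queries -> statistics -> study-shaped outputs.

``run_pipeline`` reads a raw three-table database, curates it once (all
queries share the same curated denominator), evaluates every configured
(query, endpoint) pair and writes:

* ``results.csv`` — one row per pair with counts and the full metric panel
  (rows with no cases are kept, flagged ``NE``, never dropped: the absence
  of estimable disproportionality is itself a result);
* ``forest.csv`` (and optionally ``forest.svg``) — plot-ready ROR/CI records
  on a log axis with a reference line at ROR = 1;
* ``curation_report.json`` and ``run_metadata.json``.

No multiplicity adjustment is applied across the pairs; the metadata echoes
this choice.

Output rendering is fixed-format (ratios at 2 decimals, p-values in
scientific notation below 1e-4, Unix newlines), so identical inputs produce
byte-identical files.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .curation import SynonymMap, curate, read_report_tables
from .queries import DrugQuery, EndpointSet, contingency_panel
from .records import ReportRecord
from .stats import SignalStats, StatsOptions, compute_signal_stats

__all__ = [
    "RunConfig",
    "ResultsRow",
    "PipelineError",
    "analyze_records",
    "run_pipeline",
    "export_results_csv",
    "export_forest_data",
    "render_forest_svg",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass(frozen=True)
class ResultsRow:
    """One (query, endpoint) result: the 2x2 cells plus every statistic."""

    label: str
    endpoint: str
    a: int
    b: int
    c: int
    d: int
    stats: SignalStats


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_dir: Path
    synonyms_path: Path
    window: tuple[_dt.date, _dt.date]
    endpoints_path: Path
    queries: list[tuple[str, DrugQuery]]
    out_dir: Path
    ic_mode: str = "quantile"
    continuity: bool = False
    evans_metric: str = "ror"
    forest_svg: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.queries]
        if len(labels) != len(set(labels)):
            raise ValueError("query labels must be unique")
        if not self.queries:
            raise ValueError("at least one query is required")

    @property
    def stats_options(self) -> StatsOptions:
        return StatsOptions(
            ic_mode=self.ic_mode,
            continuity=self.continuity,
            evans_metric=self.evans_metric,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON run config.

        Expected keys: input_dir, synonyms, window {start, end}, endpoints,
        queries [{label, drugs, mode, combination?, exclude?}], out_dir, and
        optional stats options (ic_mode, continuity, evans_metric,
        forest_svg, seed). Relative paths are resolved against the config
        file's directory.
        """
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        base = path.parent

        def _p(key: str) -> Path:
            try:
                return (base / raw[key]).resolve()
            except KeyError:
                raise PipelineError(f"config: missing required key {key!r}") from None

        try:
            window = (
                _dt.date.fromisoformat(raw["window"]["start"]),
                _dt.date.fromisoformat(raw["window"]["end"]),
            )
            queries = [
                (
                    q["label"],
                    DrugQuery(
                        drugs=frozenset(q["drugs"]),
                        mode=q.get("mode", "PRIMARY_SUSPECT_ONLY"),
                        combination=bool(q.get("combination", False)),
                        exclude=frozenset(q.get("exclude", ())),
                    ),
                )
                for q in raw["queries"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise PipelineError(f"config: {exc}") from exc
        return cls(
            input_dir=_p("input_dir"),
            synonyms_path=_p("synonyms"),
            window=window,
            endpoints_path=_p("endpoints"),
            queries=queries,
            out_dir=_p("out_dir"),
            ic_mode=raw.get("ic_mode", "quantile"),
            continuity=bool(raw.get("continuity", False)),
            evans_metric=raw.get("evans_metric", "ror"),
            forest_svg=bool(raw.get("forest_svg", False)),
            seed=int(raw.get("seed", 0)),
        )


def load_endpoints(path: str | Path) -> list[EndpointSet]:
    """Endpoint definitions: JSON list of {name, terms: [...]}."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not raw:
        raise PipelineError("endpoints: the endpoint list is empty")
    try:
        return [EndpointSet(e["name"], frozenset(e["terms"])) for e in raw]
    except (KeyError, TypeError, ValueError) as exc:
        raise PipelineError(f"endpoints: {exc}") from exc


def analyze_records(
    records: Sequence[ReportRecord],
    queries: Sequence[tuple[str, DrugQuery]],
    endpoints: Sequence[EndpointSet],
    options: StatsOptions = StatsOptions(),
) -> list[ResultsRow]:
    """Evaluate every (query, endpoint) pair on an already-curated database.

    Rows come out in query-major, endpoint-minor configuration order.
    """
    tables = contingency_panel(records, queries, endpoints)
    rows = []
    for label, _ in queries:
        for ep in endpoints:
            t = tables[(label, ep.name)]
            rows.append(
                ResultsRow(label, ep.name, t.a, t.b, t.c, t.d, compute_signal_stats(t, options))
            )
    return rows


def run_pipeline(config: RunConfig) -> list[ResultsRow]:
    """Execute the full study: read, curate, analyse, export."""
    try:
        records = read_report_tables(config.input_dir)
    except Exception as exc:
        raise PipelineError(f"read stage: {exc}") from exc
    try:
        synonyms = SynonymMap.from_csv(config.synonyms_path)
        curated, curation_report = curate(records, synonyms, config.window)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"curation stage: {exc}") from exc
    endpoints = load_endpoints(config.endpoints_path)
    try:
        rows = analyze_records(curated, config.queries, endpoints, config.stats_options)
    except Exception as exc:
        raise PipelineError(f"analysis stage: {exc}") from exc

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_results_csv(rows, out / "results.csv")
    export_forest_data(rows, out / "forest.csv")
    if config.forest_svg:
        render_forest_svg(rows, out / "forest.svg")
    curation_report.to_json(out / "curation_report.json")
    metadata = {
        "pvsignal_version": __version__,
        "input_dir": str(config.input_dir),
        "window": [config.window[0].isoformat(), config.window[1].isoformat()],
        "queries": [label for label, _ in config.queries],
        "endpoints": [ep.name for ep in endpoints],
        "ic_mode": config.ic_mode,
        "continuity": config.continuity,
        "evans_metric": config.evans_metric,
        "seed": config.seed,
        "multiplicity_adjustment": "none (per-pair tests are reported unadjusted)",
    }
    (out / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2) + "\n", encoding="utf-8"
    )
    return rows


# ---------------------------------------------------------------------------
# exports

RESULTS_COLUMNS = [
    "label", "endpoint", "a", "b", "c", "d",
    "ror", "ror_ci_low", "ror_ci_high", "p_value",
    "prr", "rrr", "chi2", "ic", "ic025", "evans", "classification",
]


def _fmt_ratio(v: float | None) -> str:
    return "NE" if v is None else f"{v:.2f}"


def _fmt_p(p: float) -> str:
    return f"{p:.2e}" if p < 1e-4 else f"{p:.4f}"


def export_results_csv(rows: Sequence[ResultsRow], path: str | Path) -> None:
    """Fixed-order, fixed-format results table; NE marks not-estimable."""
    if not rows:
        raise ValueError("no result rows to export")
    lines = [",".join(RESULTS_COLUMNS)]
    for r in rows:
        s = r.stats
        lines.append(
            ",".join(
                [
                    r.label, r.endpoint,
                    str(r.a), str(r.b), str(r.c), str(r.d),
                    _fmt_ratio(s.ror), _fmt_ratio(s.ror_ci_low), _fmt_ratio(s.ror_ci_high),
                    _fmt_p(s.p_value), _fmt_ratio(s.prr), _fmt_ratio(s.rrr),
                    _fmt_ratio(s.chi2), f"{s.ic:.2f}", f"{s.ic025:.2f}",
                    str(s.evans_met).lower(), s.classification,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_forest_data(rows: Sequence[ResultsRow], path: str | Path) -> None:
    """Plot-ready forest records; NE rows carry an annotation, no interval.

    The header comment records the axis convention: RORs are drawn on a
    log-scaled axis with a reference line at ROR = 1.
    """
    if not rows:
        raise ValueError("no result rows to export")
    lines = [
        "# axis: log-scaled ROR; reference line at ROR=1",
        "label,endpoint,ror,ci_low,ci_high,estimable,annotation",
    ]
    for r in rows:
        s = r.stats
        if s.ror is None:
            lines.append(f"{r.label},{r.endpoint},,,,false,NE (n={s.n_cases})")
        else:
            lines.append(
                f"{r.label},{r.endpoint},{s.ror:.4f},{s.ror_ci_low:.4f},"
                f"{s.ror_ci_high:.4f},true,"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def render_forest_svg(rows: Sequence[ResultsRow], path: str | Path) -> None:
    """Render a grouped forest plot (one panel row per query label)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(dict.fromkeys(r.label for r in rows))
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(rows) + 1.2))
    y, ticks, ticklabels = 0, [], []
    for label in labels:
        for r in [row for row in rows if row.label == label]:
            s = r.stats
            ticks.append(y)
            ticklabels.append(f"{label} / {r.endpoint}")
            if s.ror is not None:
                ax.errorbar(
                    [s.ror], [y],
                    xerr=[[s.ror - s.ror_ci_low], [s.ror_ci_high - s.ror]],
                    fmt="s", color="black", capsize=3, markersize=4,
                )
            else:
                ax.annotate("NE", xy=(1.0, y), fontsize=8, va="center", color="grey")
            y -= 1
        y -= 0.5
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xscale("log")
    ax.set_yticks(ticks)
    ax.set_yticklabels(ticklabels, fontsize=8)
    ax.set_xlabel("Reporting odds ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
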