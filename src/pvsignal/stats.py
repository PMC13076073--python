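"""Disproportionality statistics for one 2x2 contingency table.

The table follows the standard pharmacovigilance convention::

                     endpoint    not endpoint
    query drug(s)        a            b
    all other reports    c            d

with N = a + b + c + d, the size of the curated database. On this table the
module computes the reporting odds ratio (ROR) with a Woolf (log-normal) 95%
confidence interval, the proportional reporting ratio (PRR), the relative
reporting ratio (RRR, observed/expected), a Yates-corrected chi-square, a
two-sided Fisher exact p-value by full hypergeometric enumeration, and the
Bayesian information component

    IC    = log2((a + 1/2) / (E + 1/2)),        E = (a+b)(a+c)/N,
    IC025 = log2(q_gamma(0.025; a + 1/2) / (E + 1/2)),

where q_gamma is the lower 2.5% quantile of a Gamma(shape = a + 1/2, rate = 1)
posterior for the observed count — the shrinkage that stabilises small-count
cells. The widely used closed-form approximation
IC - 3.3 (a+1/2)^(-1/2) - 2 (a+1/2)^(-3/2) is available as an alternative mode.

A metric that is undefined for the observed table (a zero cell for the ROR, a
zero margin for PRR/RRR/chi-square) is *not estimable* and is represented by
``None``; this is a value, not an error, because reporting "no estimable ROR"
for zero-count drug-event combinations is itself a study outcome.

The ratio statistics are computed as a single float division of
exactly-representable integer products, so for integer cells the returned
float is the correctly rounded value of the underlying rational number.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy import special

__all__ = [
    "ContingencyTable",
    "StatsOptions",
    "SignalStats",
    "ror_with_ci",
    "prr",
    "rrr",
    "chi2_yates",
    "association_p",
    "ic_with_ic025",
    "evans_criteria",
    "classify_signal",
    "compute_signal_stats",
    "batch_from_csv",
    "SIGNAL",
    "NO_SIGNAL",
    "NOT_ESTIMABLE",
]

Z95 = 1.96  # normal quantile used by the Woolf interval

SIGNAL = "SIGNAL"
NO_SIGNAL = "NO_SIGNAL"
NOT_ESTIMABLE = "NOT_ESTIMABLE"


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 cell counts; all cells are non-negative integers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under independence of the margins."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True, slots=True)
class StatsOptions:
    """Knobs for the statistics layer.

    ic_mode: "quantile" (gamma-posterior quantile, default) or "approx"
        (closed-form IC025 approximation).
    continuity: when True, add 0.5 to every cell (Haldane-Anscombe) before
        computing ROR/PRR if, and only if, the table has a zero cell. Off by
        default: zero-cell tables are reported not estimable.
    evans_metric: ratio compared against 2 in the Evans screen — "ror"
        (default) or "prr" (the classical variant).
    """

    ic_mode: str = "quantile"
    continuity: bool = False
    evans_metric: str = "ror"

    def __post_init__(self) -> None:
        if self.ic_mode not in ("quantile", "approx"):
            raise ValueError(f"ic_mode must be 'quantile' or 'approx', got {self.ic_mode!r}")
        if self.evans_metric not in ("ror", "prr"):
            raise ValueError(f"evans_metric must be 'ror' or 'prr', got {self.evans_metric!r}")


@dataclass(frozen=True, slots=True)
class SignalStats:
    """All disproportionality metrics for one (query, endpoint) table.

    ``None`` marks a not-estimable metric. ``classification`` is SIGNAL iff
    p < 0.05 and IC025 > 0 (strict), NOT_ESTIMABLE when the ROR is not
    estimable and a = 0, otherwise NO_SIGNAL.
    """

    ror: float | None
    ror_ci_low: float | None
    ror_ci_high: float | None
    p_value: float
    chi2: float | None
    prr: float | None
    rrr: float | None
    expected: float
    ic: float
    ic025: float
    n_cases: int
    evans_met: bool
    classification: str


# ---------------------------------------------------------------------------
# individual metrics


def _haldane(t: ContingencyTable) -> tuple[float, float, float, float]:
    return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)


def ror_with_ci(
    t: ContingencyTable, continuity: bool = False
) -> tuple[float | None, float | None, float | None]:
    """Reporting odds ratio (a*d)/(b*c) with Woolf 95% CI.

    Any zero cell makes the estimate (or its variance) undefined; the triple
    (None, None, None) is returned unless ``continuity`` is set, in which case
    0.5 is added to every cell of a zero-cell table first.
    """
    a, b, c, d = t.cells()
    if min(a, b, c, d) == 0:
        if not continuity:
            return (None, None, None)
        a, b, c, d = _haldane(t)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return (ror, math.exp(log_ror - Z95 * se), math.exp(log_ror + Z95 * se))


def prr(t: ContingencyTable, continuity: bool = False) -> float | None:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)]."""
    a, b, c, d = t.cells()
    if continuity and min(a, b, c, d) == 0:
        a, b, c, d = _haldane(t)
    if a + b == 0 or c == 0:
        return None
    return (a * (c + d)) / (c * (a + b))


def rrr(t: ContingencyTable) -> float | None:
    """Relative reporting ratio a/E = a*N / ((a+b)(a+c)); observed/expected."""
    a, b, c, d = t.cells()
    if a + b == 0 or a + c == 0:
        return None
    return (a * t.n) / ((a + b) * (a + c))


def chi2_yates(t: ContingencyTable) -> float | None:
    """Continuity-corrected chi-square; None when any margin is zero.

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), floored at 0 when
    |ad - bc| <= N/2.
    """
    a, b, c, d = t.cells()
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None
    num = abs(a * d - b * c) - n / 2
    if num <= 0:
        return 0.0
    return n * num * num / denom


# -- Fisher exact p ----------------------------------------------------------

_LOG_FACT = np.zeros(1)


def _log_factorials(n: int) -> np.ndarray:
    """Cached table of log(k!) for k = 0..n."""
    global _LOG_FACT
    if len(_LOG_FACT) <= n:
        _LOG_FACT = special.gammaln(np.arange(max(n + 1, 1024), dtype=np.float64) + 1.0)
    return _LOG_FACT


def association_p(t: ContingencyTable, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Conditional on the observed margins, every table with point probability
    at most (1 + rel_tol) times that of the observed table contributes to p
    (the minimum-likelihood two-sided rule; the tolerance absorbs floating
    ties). Deterministic; defined for any margins (a degenerate margin gives
    p = 1).
    """
    a, b, c, d = t.cells()
    n = t.n
    if n == 0:
        return 1.0
    m1, k = a + b, a + c
    lf = _log_factorials(n)
    lo, hi = max(0, m1 + k - n), min(m1, k)
    xs = np.arange(lo, hi + 1)
    logpmf = (
        lf[m1] - lf[xs] - lf[m1 - xs]
        + lf[n - m1] - lf[k - xs] - lf[n - m1 - k + xs]
        - (lf[n] - lf[k] - lf[n - k])
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + rel_tol)].sum()))


# -- information component ---------------------------------------------------


def ic_with_ic025(t: ContingencyTable, mode: str = "quantile") -> tuple[float, float]:
    """Shrunk information component and its 95% credibility lower bound.

    Defined for every table with N > 0, including a = 0 (the +1/2 shrinkage
    keeps both quantities finite).
    """
    if t.n == 0:
        raise ValueError("information component undefined for an empty table")
    a = t.a
    e_shrunk = t.expected + 0.5
    ic = math.log2((a + 0.5) / e_shrunk)
    if mode == "quantile":
        q = float(special.gammaincinv(a + 0.5, 0.025))
        ic025 = math.log2(q / e_shrunk)
    elif mode == "approx":
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    else:
        raise ValueError(f"unknown ic mode {mode!r}")
    return (ic, ic025)


def evans_criteria(
    t: ContingencyTable,
    ratio: float | None,
    chi2: float | None,
) -> bool:
    """Evans screen: a > 2 and chi2 > 4 and ratio > 2 (strict inequalities).

    ``ratio`` is the ROR by default (PRR in the classical variant); a
    not-estimable ratio or chi-square fails the screen.
    """
    if ratio is None or chi2 is None:
        return False
    return t.a > 2 and chi2 > 4 and ratio > 2


def classify_signal(stats: SignalStats) -> str:
    """SIGNAL iff p < 0.05 and IC025 > 0; NOT_ESTIMABLE when the ROR is not
    estimable and there are no cases at all; otherwise NO_SIGNAL."""
    if stats.ror is None and stats.n_cases == 0:
        return NOT_ESTIMABLE
    if stats.p_value < 0.05 and stats.ic025 > 0:
        return SIGNAL
    return NO_SIGNAL


def compute_signal_stats(
    t: ContingencyTable, options: StatsOptions = StatsOptions()
) -> SignalStats:
    """Evaluate the full metric panel for one table."""
    if t.n == 0:
        raise ValueError("empty contingency table")
    ror_v, lo, hi = ror_with_ci(t, continuity=options.continuity)
    prr_v = prr(t, continuity=options.continuity)
    rrr_v = rrr(t)
    chi2_v = chi2_yates(t)
    p = association_p(t)
    ic, ic025 = ic_with_ic025(t, mode=options.ic_mode)
    ratio = ror_v if options.evans_metric == "ror" else prr_v
    evans = evans_criteria(t, ratio, chi2_v)
    stats = SignalStats(
        ror=ror_v,
        ror_ci_low=lo,
        ror_ci_high=hi,
        p_value=p,
        chi2=chi2_v,
        prr=prr_v,
        rrr=rrr_v,
        expected=t.expected,
        ic=ic,
        ic025=ic025,
        n_cases=t.a,
        evans_met=evans,
        classification=NO_SIGNAL,
    )
    return replace(stats, classification=classify_signal(stats))


# ---------------------------------------------------------------------------
# vectorised forms (used by sweeps and the batch calculator)


def ror_array(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ROR with Woolf CI; NaN where any cell is zero."""
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    a_, b_, c_, d_ = (np.where(ok, x, np.nan) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a_ * d_) / (b_ * c_)
        se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
        log_ror = np.log(ror)
        return ror, np.exp(log_ror - Z95 * se), np.exp(log_ror + Z95 * se)


def prr_array(a, b, c, d) -> np.ndarray:
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    ok = (a + b > 0) & (c > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, (a * (c + d)) / (c * (a + b)), np.nan)


def rrr_array(a, b, c, d) -> np.ndarray:
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    ok = (a + b > 0) & (a + c > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, (a * n) / ((a + b) * (a + c)), np.nan)


def chi2_yates_array(a, b, c, d) -> np.ndarray:
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = np.maximum(np.abs(a * d - b * c) - n / 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, n * num * num / denom, np.nan)


def ic_array(a, b, c, d, mode: str = "quantile") -> tuple[np.ndarray, np.ndarray]:
    """Vectorised IC / IC025. Gamma quantiles are evaluated once per distinct
    case count, which makes full-grid sweeps cheap."""
    a = np.asarray(a, dtype=np.int64)
    bf, cf, df = (np.asarray(x, dtype=np.float64) for x in (b, c, d))
    n = a + bf + cf + df
    e_shrunk = (a + bf) * (a + cf) / n + 0.5
    ic = np.log2((a + 0.5) / e_shrunk)
    if mode == "quantile":
        uniq, inv = np.unique(a, return_inverse=True)
        q = special.gammaincinv(uniq + 0.5, 0.025)
        ic025 = np.log2(q[inv].reshape(a.shape) / e_shrunk)
    else:
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


# ---------------------------------------------------------------------------
# standalone batch calculator


def batch_from_csv(
    in_path: str | Path,
    out_path: str | Path,
    options: StatsOptions = StatsOptions(),
) -> int:
    """Read rows of (label, a, b, c, d) and write the full metric panel.

    Returns the number of rows processed. Not-estimable metrics are written
    as the literal ``NE``; numbers are written at full precision (this entry
    point is a calculator, not a report).
    """
    n_rows = 0
    with open(in_path, newline="", encoding="utf-8") as fin, open(
        out_path, "w", newline="", encoding="utf-8"
    ) as fout:
        reader = csv.reader(fin)
        writer = csv.writer(fout)
        header = next(reader)
        if [h.strip().lower() for h in header[:5]] != ["label", "a", "b", "c", "d"]:
            raise ValueError(
                f"expected header label,a,b,c,d in {in_path}, got {header!r}"
            )
        writer.writerow(
            [
                "label", "a", "b", "c", "d",
                "ror", "ror_ci_low", "ror_ci_high", "p_value",
                "prr", "rrr", "chi2", "expected", "ic", "ic025",
                "evans_met", "classification",
            ]
        )
        for row in reader:
            if not row:
                continue
            label = row[0]
            t = ContingencyTable(*(int(x) for x in row[1:5]))
            s = compute_signal_stats(t, options)
            fmt = lambda v: "NE" if v is None else repr(float(v))
            writer.writerow(
                [
                    label, t.a, t.b, t.c, t.d,
                    fmt(s.ror), fmt(s.ror_ci_low), fmt(s.ror_ci_high),
                    repr(s.p_value), fmt(s.prr), fmt(s.rrr), fmt(s.chi2),
                    repr(s.expected), repr(s.ic), repr(s.ic025),
                    str(s.evans_met).lower(), s.classification,
                ]
            )
            n_rows += 1
    return n_rows
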