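"""Descriptive and paired-comparison statistics for crossover sessions.

Recreates the study-style analysis: per participant x scenario x arm, the
scenario-level mean heart rate (bpm) and final cumulative energy (kcal) form
twelve variables named ``Hrate{P1|P2|P3}{UAS|CIS}`` and
``Gcalorico{1|2|3}{UAS|CIS}``; each UAS-CIS pair is compared with a paired
t-test. Because published reports often print only the summary columns
(mean difference, SD of differences, n), the test is computable from either
raw paired vectors or those three numbers — the two routes agree exactly.

Conventions: skewness and excess kurtosis use the bias-corrected
(sample-adjusted) estimators; the kurtosis standard error uses the classical
small-sample closed form, which depends only on n.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import SessionLog

__all__ = [
    "VariableSeries",
    "DescriptiveSummary",
    "PairedSummary",
    "PairedTestResult",
    "describe",
    "skew_se",
    "kurtosis_se",
    "paired_t_from_raw",
    "paired_t_from_summary",
    "summarize_paired",
    "build_variables",
    "render_tables",
]

_NAME_RE = re.compile(r"^(Hrate|Gcal(?:orico)?)P?([123])(UAS|CIS)$")


@dataclass(frozen=True)
class VariableSeries:
    """One named per-participant measurement vector (e.g. ``HrateP2UAS``)."""

    name: str
    values: tuple

    def __post_init__(self) -> None:
        if self.parse_name() is None:
            raise ValueError(f"unparseable variable name {self.name!r}")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"{self.name}: values must be finite")

    def parse_name(self) -> tuple | None:
        m = _NAME_RE.match(self.name)
        if m is None:
            return None
        measure = "Hrate" if m.group(1) == "Hrate" else "Gcalorico"
        return measure, int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class DescriptiveSummary:
    """Moment summary of one variable; fields that need more data are None."""

    n: int
    mean: float
    sd: float | None
    variance: float | None
    asymmetry: float | None  # bias-corrected skewness
    kurtosis: float | None  # bias-corrected excess kurtosis
    kurtosis_se: float | None
    interval: float  # range, max - min


@dataclass(frozen=True)
class PairedSummary:
    """The printed columns of a paired test: mean and SD of differences, n."""

    mean_diff: float
    sd_diff: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("paired summary needs n >= 2")
        if self.sd_diff < 0:
            raise ValueError("sd_diff must be non-negative")


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float  # two-tailed
    se: float
    ci_lower: float
    ci_upper: float


def skew_se(n: int) -> float:
    """Standard error of the sample skewness (classical closed form)."""
    if n < 3:
        raise ValueError("skewness SE needs n >= 3")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def kurtosis_se(n: int) -> float:
    """Standard error of the sample excess kurtosis; depends only on n."""
    if n < 4:
        raise ValueError("kurtosis SE needs n >= 4")
    return 2.0 * skew_se(n) * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))


def describe(series: VariableSeries | Sequence[float]) -> DescriptiveSummary:
    """Moment-based descriptive summary of one variable.

    Uses sample (n−1) variance and the bias-corrected skewness/kurtosis
    estimators. Statistics whose minimum sample size is not met are reported
    as None rather than fabricated.
    """
    values = series.values if isinstance(series, VariableSeries) else tuple(series)
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("describe needs at least one value")
    mean = float(x.mean())
    interval = float(x.max() - x.min())
    sd = variance = asym = kurt = k_se = None
    if n >= 2:
        variance = float(x.var(ddof=1))
        sd = math.sqrt(variance)
    if n >= 3 and sd and sd > 0:
        asym = float(sps.skew(x, bias=False))
    if n >= 4 and sd and sd > 0:
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    if n >= 4:
        k_se = kurtosis_se(n)
    return DescriptiveSummary(n, mean, sd, variance, asym, kurt, k_se, interval)


def summarize_paired(
    x_first: Sequence[float], x_second: Sequence[float]
) -> PairedSummary:
    """Reduce two paired vectors to (mean difference, SD of differences, n)."""
    a = np.asarray(x_first, dtype=float)
    b = np.asarray(x_second, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("paired test needs n >= 2")
    d = a - b
    return PairedSummary(float(d.mean()), float(d.std(ddof=1)), int(d.size))


def paired_t_from_summary(s: PairedSummary, conf: float = 0.95) -> PairedTestResult:
    """Paired t-test from the printed (mean diff, SD diff, n) columns.

    t = mean / (sd/sqrt(n)), df = n−1, two-tailed p, and the
    ``conf``-level CI mean ± t_crit * se. A zero SD with nonzero mean yields
    an infinite t (flagged by the inf value) with p = 0.
    """
    df = s.n - 1
    se = s.sd_diff / math.sqrt(s.n)
    if se == 0.0:
        t = 0.0 if s.mean_diff == 0.0 else math.copysign(math.inf, s.mean_diff)
        p = 1.0 if s.mean_diff == 0.0 else 0.0
        return PairedTestResult(t, df, p, se, s.mean_diff, s.mean_diff)
    t = s.mean_diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    crit = float(sps.t.ppf(0.5 + conf / 2.0, df))
    half = crit * se
    return PairedTestResult(t, df, p, se, s.mean_diff - half, s.mean_diff + half)


def paired_t_from_raw(
    x_uas: Sequence[float], x_cis: Sequence[float], conf: float = 0.95
) -> PairedTestResult:
    """Paired t-test on raw per-participant vectors (UAS − CIS differences)."""
    return paired_t_from_summary(summarize_paired(x_uas, x_cis), conf)


def _scenario_measures(log: SessionLog) -> dict:
    """Per-scenario (mean calibrated HR, final cumulative kcal) of one log."""
    out: dict = {}
    by_scenario: dict = {}
    for row in log.rows:
        by_scenario.setdefault(row.scenario, []).append(row)
    for scenario, rows in by_scenario.items():
        hr_mean = float(np.mean([r.hr_cal for r in rows]))
        out[scenario] = (hr_mean, rows[-1].kcal)
    return out


def build_variables(
    logs: Iterable[SessionLog],
    scenarios: Sequence = (1, 2, 3),
) -> tuple[dict, list[str]]:
    """Aggregate session logs into the twelve named variables.

    Participants missing an arm or a scenario segment are excluded; the
    second return value lists each exclusion with its reason.
    """
    per_participant: dict = {}
    for log in logs:
        per_participant.setdefault(log.participant, {})[log.arm] = _scenario_measures(log)
    exclusions: list[str] = []
    values: dict = {}
    for pid in sorted(per_participant):
        arms = per_participant[pid]
        missing = {"UAS", "CIS"} - set(arms)
        if missing:
            exclusions.append(f"{pid}: missing arm(s) {sorted(missing)}")
            continue
        if any(s not in arms[a] for a in ("UAS", "CIS") for s in scenarios):
            exclusions.append(f"{pid}: incomplete scenario coverage")
            continue
        for arm in ("UAS", "CIS"):
            for s in scenarios:
                hr_mean, kcal = arms[arm][s]
                values.setdefault(f"HrateP{s}{arm}", []).append(hr_mean)
                values.setdefault(f"Gcalorico{s}{arm}", []).append(kcal)
    series = {name: VariableSeries(name, tuple(vals)) for name, vals in values.items()}
    return series, exclusions


def render_tables(
    variables: dict | None = None,
    out_dir: str | Path | None = None,
    conf: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """Render the descriptive and paired-test tables of a crossover analysis.

    Returns (and optionally writes as CSV) two frames: ``descriptives`` —
    one column per variable with the moment summary rows — and ``paired`` —
    one row per UAS-CIS pair with mean/SD of differences, SE, CI, t, df and
    the two-tailed p. No multiple-testing correction is applied.
    """
    variables = variables or {}
    desc = pd.DataFrame(
        {
            name: {
                "N": (d := describe(v)).n,
                "Mean": d.mean,
                "Std. Dev": d.sd,
                "Variance": d.variance,
                "Kurtosis": d.kurtosis,
                "K. Std. Err.": d.kurtosis_se,
                "Asymmetry": d.asymmetry,
                "Interval": d.interval,
            }
            for name, v in variables.items()
        }
    )
    paired_rows = []
    for name, v in variables.items():
        parsed = v.parse_name()
        if parsed is None or parsed[2] != "UAS":
            continue
        measure, scenario, _ = parsed
        cis_name = f"{measure}{'P' if measure == 'Hrate' else ''}{scenario}CIS"
        if cis_name not in variables:
            continue
        res = paired_t_from_raw(v.values, variables[cis_name].values, conf)
        s = summarize_paired(v.values, variables[cis_name].values)
        paired_rows.append(
            {
                "pair": f"{name}-{cis_name}",
                "mean_diff": s.mean_diff,
                "sd_diff": s.sd_diff,
                "se": res.se,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    paired = pd.DataFrame(
        paired_rows,
        columns=["pair", "mean_diff", "sd_diff", "se", "ci_lower", "ci_upper", "t", "df", "p"],
    )
    tables = {"descriptives": desc, "paired": paired}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        desc.to_csv(out_dir / "descriptives.csv")
        paired.to_csv(out_dir / "paired_tests.csv", index=False)
        (out_dir / "report.md").write_text(_markdown_report(desc, paired, conf))
    return tables


def _markdown_table(df: pd.DataFrame, index: bool) -> str:
    frame = df.reset_index() if index else df
    cols = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in frame.iterrows():
        cells = [
            f"{v:.2f}" if isinstance(v, float) else ("" if v is None else str(v))
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def _markdown_report(desc: pd.DataFrame, paired: pd.DataFrame, conf: float) -> str:
    parts = ["# Crossover evaluation report", ""]
    if not desc.empty:
        parts += ["## Descriptive statistics", "", _markdown_table(desc, index=True), ""]
    if not paired.empty:
        parts += [
            f"## Paired t-tests (UAS − CIS, {conf:.0%} CI)",
            "",
            _markdown_table(paired, index=False),
            "",
        ]
    parts.append("No multiple-testing correction applied.")
    return "\n".join(parts) + "\n"
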