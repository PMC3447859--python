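"""Assay arithmetic and statistics.

Implements the quantitative definitions used throughout the study layer:
four-parameter logistic (4PL) dose-response fitting with closed-form GI50
inversion, LDH percent cytotoxicity, caliper tumor volume, percent
inhibition / percent of control, the unpaired two-tailed Student t-test with
the conventional significance stars, and group summaries (mean, SD, SEM).

The 4PL model is written in the concentration form

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x) ** hill)

so that a *negative* Hill slope describes an inhibition curve: y(0) = top
(the untreated control level) and y(inf) = bottom.  GI50 is the
concentration at which the fitted curve crosses half of the untreated
control mean, obtained by inverting the model analytically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FourPLFit",
    "FitError",
    "GroupStats",
    "GroupSummary",
    "fourpl",
    "fit_4pl",
    "gi50",
    "percent_cytotoxicity",
    "percent_inhibition",
    "percent_of_control",
    "tumor_volume",
    "ttest_unpaired",
    "stars_for_p",
    "summarize_groups",
    "growth_curve_summary",
]


class FitError(RuntimeError):
    """Raised when a dose-response fit is infeasible or unidentifiable."""


@dataclass
class FourPLFit:
    """Parameters of a four-parameter logistic dose-response curve.

    Attributes
    ----------
    bottom, top : float
        Lower/upper response asymptotes (``top >= bottom`` after
        canonicalization).
    ec50 : float
        Concentration of half-maximal effect, in the dose units of the fit
        (µM throughout this package); strictly positive.
    hill : float
        Hill slope; negative for inhibition curves (response falls with
        dose), positive for stimulation.
    residual_sse : float
        Sum of squared residuals of the fit (0 for hand-built curves).
    converged : bool
        False when the optimizer hit an iteration limit or the slope ran to
        a boundary (e.g. step-like data); such fits should not be trusted.
    note : str
        Free-text diagnostic (empty when clean).
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    residual_sse: float = 0.0
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.bottom > self.top:
            # same curve with asymptotes swapped and slope negated
            self.bottom, self.top = self.top, self.bottom
            self.hill = -self.hill

    def predict(self, x) -> np.ndarray:
        return fourpl(x, self.bottom, self.top, self.ec50, self.hill)


def fourpl(x, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the 4PL curve; dose 0 is handled as the analytic limit."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, ec50 / x, np.inf)
        term = ratio**hill  # inf**hill -> 0 when hill<0, inf when hill>0
    y = bottom + (top - bottom) / (1.0 + term)
    return float(y[0]) if scalar else y


_HILL_BOUNDARY = 25.0


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit of responses vs doses.

    Requires at least four distinct doses including dose 0 (the untreated
    control, which anchors the top asymptote of an inhibition curve).
    Initialization: top = mean response at dose 0, bottom = mean response at
    the maximal dose, ec50 = geometric mid-dose, hill = -1.  ec50 is
    optimized in log-space to keep it positive.

    Raises
    ------
    FitError
        For flat (unidentifiable) responses or fewer than 4 distinct doses.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("doses and responses must be non-negative")
    distinct = np.unique(x)
    if distinct.size < 4:
        raise FitError(f"need >= 4 distinct doses, got {distinct.size}")
    if 0.0 not in distinct:
        raise FitError("a dose-0 (untreated control) row is required")
    span = float(np.ptp(y))
    if span <= 1e-12 * max(1.0, float(np.max(y))):
        raise FitError("responses are flat; ec50 is unidentifiable")

    top0 = float(np.mean(y[x == 0]))
    bottom0 = float(np.mean(y[x == x.max()]))
    pos = distinct[distinct > 0]
    ec50_0 = float(np.exp(np.mean(np.log(pos))))  # geometric mid-dose
    p0 = np.array([bottom0, top0, math.log(ec50_0), -1.0])

    def residuals(p):
        b, t, log_e, h = p
        return fourpl(x, b, t, math.exp(log_e), h) - y

    sol = optimize.least_squares(
        residuals, p0, method="lm", ftol=1e-12, xtol=1e-12, gtol=1e-12,
        max_nfev=5000,
    )
    b, t, log_e, h = sol.x
    sse = float(np.sum(sol.fun**2))
    converged = bool(sol.success)
    note = ""
    if abs(h) > _HILL_BOUNDARY:
        converged = False
        note = "hill slope at boundary (step-like data?)"
        logger.warning("4PL fit: %s (hill=%.3g)", note, h)
    return FourPLFit(
        bottom=float(b), top=float(t), ec50=float(math.exp(log_e)),
        hill=float(h), residual_sse=sse, converged=converged, note=note,
    )


def gi50(fit: FourPLFit, control_mean: float, max_dose: float | None = None) -> float:
    """Concentration inhibiting 50% of growth relative to the untreated mean.

    Solves ``fit.predict(x) == control_mean / 2`` in closed form.  Fails
    with :class:`FitError` ("GI50 not reached") when the target response is
    not strictly between the asymptotes, or — if ``max_dose`` is given —
    when the solution lies beyond 10x the observed dose range (mirroring
    assay reports that quote "no GI50 up to the maximal tested dose").
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    target = control_mean / 2.0
    if not (fit.bottom < target < fit.top):
        raise FitError(
            f"GI50 not reached: half-control response {target:g} outside the "
            f"fitted asymptotes [{fit.bottom:g}, {fit.top:g}]"
        )
    # (ec50/x)^hill = (top-target)/(target-bottom) => closed-form inversion
    r = (target - fit.bottom) / (fit.top - target)
    x = fit.ec50 * r ** (1.0 / fit.hill)
    if max_dose is not None and x > 10.0 * max_dose:
        raise FitError(
            f"GI50 not reached within 10x the tested dose range "
            f"(solution {x:g} µM > {10 * max_dose:g} µM)"
        )
    return float(x)


def percent_cytotoxicity(released: float, total: float) -> float:
    """LDH released into the medium as percent of total lysate LDH."""
    if total <= 0:
        raise ValueError("total LDH signal must be positive")
    if released < 0:
        raise ValueError("released LDH signal must be non-negative")
    return 100.0 * released / total


def tumor_volume(r1: float, r2: float) -> float:
    """Caliper tumor volume V = 4/3*pi*R1^2*R2 (mm^3), with R1 <= R2.

    Inputs arriving in the wrong order are sorted (calipers do not guarantee
    which axis is minor); a debug message is logged when a swap occurs.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if r1 > r2:
        logger.debug("tumor_volume: swapping radii (%g, %g) to enforce R1<=R2", r1, r2)
        r1, r2 = r2, r1
    return 4.0 / 3.0 * math.pi * r1**2 * r2


def percent_inhibition(treated_mean: float, control_mean: float) -> float:
    """100*(1 - treated/control); negative values indicate stimulation."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return 100.0 * (1.0 - treated_mean / control_mean)


def percent_of_control(value: float, control: float) -> float:
    """Express a readout as percent of the untreated-control readout."""
    if control <= 0:
        raise ValueError("control must be positive")
    return 100.0 * value / control


def stars_for_p(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_unpaired(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> tuple[float, float, str]:
    """Unpaired two-tailed t-test between two groups.

    Student's pooled-variance t by default (``welch=True`` switches to
    Welch's unequal-variance form).  Degenerate case: zero variance in both
    groups with equal means yields (0.0, 1.0, "ns") instead of NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, "ns"
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0, "***"
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), stars_for_p(float(p))


@dataclass
class GroupStats:
    """Per-group descriptive statistics (SD with ddof=1, SEM = SD/sqrt(n))."""

    n: int
    mean: float
    sd: float
    sem: float

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need n >= 2 values per group (SEM undefined)")
        sd = float(np.std(v, ddof=1))
        return cls(n=int(v.size), mean=float(np.mean(v)), sd=sd,
                   sem=sd / math.sqrt(v.size))


@dataclass
class GroupSummary:
    """Two-group comparison: descriptives, percent change, t-test, stars."""

    control: GroupStats
    treated: GroupStats
    percent_change: float
    t_statistic: float
    p_value: float
    stars: str
    label: str = ""


def summarize_groups(
    control: Sequence[float],
    treated: Sequence[float],
    label: str = "",
    welch: bool = False,
) -> GroupSummary:
    """Mean/SD/SEM per group plus percent inhibition and the unpaired t-test."""
    cs = GroupStats.from_values(control)
    ts = GroupStats.from_values(treated)
    t, p, stars = ttest_unpaired(control, treated, welch=welch)
    return GroupSummary(
        control=cs, treated=ts,
        percent_change=percent_inhibition(ts.mean, cs.mean),
        t_statistic=t, p_value=p, stars=stars, label=label,
    )


def growth_curve_summary(
    calipers: pd.DataFrame, control_group: str = "control", welch: bool = False
) -> tuple[pd.DataFrame, GroupSummary]:
    """Per-group tumor-volume time series and endpoint comparison.

    Parameters
    ----------
    calipers : DataFrame
        Columns ``group, mouse, day, R1_mm, R2_mm`` (the schema written by
        the synthetic caliper generator).  Radii are canonicalized per row.

    Returns
    -------
    series : DataFrame
        ``group, day, n, mean_mm3, sd_mm3, sem_mm3`` per group and day.
    endpoint : GroupSummary
        Control-vs-treated comparison of per-mouse volumes at the last
        common day, including percent inhibition and the unpaired t-test.
    """
    required = {"group", "mouse", "day", "R1_mm", "R2_mm"}
    missing = required - set(calipers.columns)
    if missing:
        raise ValueError(f"caliper table missing columns: {sorted(missing)}")
    df = calipers.copy()
    df["volume_mm3"] = [tumor_volume(a, b) for a, b in zip(df.R1_mm, df.R2_mm)]

    grp = df.groupby(["group", "day"])["volume_mm3"]
    series = grp.agg(n="count", mean_mm3="mean", sd_mm3=lambda v: v.std(ddof=1))
    series["sem_mm3"] = series["sd_mm3"] / np.sqrt(series["n"])
    series = series.reset_index()

    groups = sorted(df["group"].unique())
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent from table")
    others = [g for g in groups if g != control_group]
    if not others:
        raise ValueError("no treated group in table")
    treated_group = others[0]
    endpoint_day = min(df[df.group == g]["day"].max() for g in (control_group, treated_group))
    at_end = df[df.day == endpoint_day]
    ctrl = at_end[at_end.group == control_group]["volume_mm3"].to_numpy()
    trt = at_end[at_end.group == treated_group]["volume_mm3"].to_numpy()
    if ctrl.size < 2 or trt.size < 2:
        raise ValueError("need >= 2 mice per group at the endpoint")
    summary = summarize_groups(ctrl, trt, label=f"day {endpoint_day:g} volume",
                               welch=welch)
    return series, summary
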