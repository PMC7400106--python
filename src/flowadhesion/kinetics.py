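"""Two-phase adhesion kinetics and rate comparison.

Adhered-cell density versus time in initial-adhesion assays typically rises
linearly and then, after several minutes, continues at a visibly lower
slope.  This module fits that behaviour with two independent ordinary
least-squares lines split at a breakpoint chosen by grid search over the
observation times inside a configurable window (default 5-9 min), reports
both slopes in cells/(cm^2*min) and the percent rate reduction
``(1 - s2/s1) * 100``, and compares replicate slopes across conditions with
a one-way ANOVA plus Tukey's HSD post-hoc test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "AdhesionTimeSeries",
    "TwoPhaseFit",
    "RateComparison",
    "fit_two_phase",
    "rate_reduction",
    "compare_rates",
]

#: Default breakpoint search window, seconds (5 to 9 minutes).
DEFAULT_WINDOW_S = (300.0, 540.0)


@dataclass(frozen=True)
class AdhesionTimeSeries:
    """Adhered-cell surface density (cells/cm^2) versus time (s)."""

    times_s: np.ndarray
    densities: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ParameterError("times_s and densities must be 1D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ParameterError("times_s must be strictly increasing")
        if np.any(d < 0):
            raise ParameterError("densities must be >= 0")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "densities", d)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class TwoPhaseFit:
    """Result of a two-segment linear fit.

    Slopes are in cells/(cm^2*min); intercepts in cells/cm^2 at t=0 of each
    segment's own line.  ``reduction_pct`` is ``(1 - s2/s1)*100`` (NaN when
    the initial slope is zero).
    """

    breakpoint_s: float
    slope1: float
    slope2: float
    intercept1: float
    intercept2: float
    r2_1: float
    r2_2: float
    sse: float
    n1: int
    n2: int

    @property
    def reduction_pct(self) -> float:
        if self.slope1 == 0:
            return float("nan")
        return (1.0 - self.slope2 / self.slope1) * 100.0


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, SSE and R^2 of an ordinary least-squares line."""
    tm, ym = t.mean(), y.mean()
    stt = float(np.sum((t - tm) ** 2))
    if stt == 0:
        raise ParameterError("degenerate segment: all times equal")
    slope = float(np.sum((t - tm) * (y - ym)) / stt)
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return slope, intercept, sse, r2


def fit_two_phase(
    series: AdhesionTimeSeries,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    min_points: int = 3,
) -> TwoPhaseFit:
    """Fit two independent OLS lines split at an SSE-minimising breakpoint.

    Candidate breakpoints are the observation times falling inside
    ``window_s``; for each, the first segment takes points with
    ``t <= t_b`` and the second ``t > t_b``, both fitted independently (the
    lines need not meet at the breakpoint).  The candidate with the smallest
    total SSE wins; ties go to the latest breakpoint, which maximises the
    initial segment and recovers the true kink exactly on noiseless
    piecewise-linear data (where the kink observation lies on both lines).
    Each segment must keep at least ``min_points`` observations.
    """
    t = series.times_s
    y = series.densities
    if t.size < 2 * min_points:
        raise ParameterError(f"need at least {2 * min_points} points for a two-phase fit")
    lo, hi = window_s
    if lo > hi:
        raise ParameterError("window_s must satisfy t_min <= t_max")
    candidates = t[(t >= lo) & (t <= hi)]
    best: TwoPhaseFit | None = None
    for tb in candidates:
        left = t <= tb
        right = ~left
        if left.sum() < min_points or right.sum() < min_points:
            continue
        s1, b1, sse1, r21 = _ols(t[left], y[left])
        s2, b2, sse2, r22 = _ols(t[right], y[right])
        fit = TwoPhaseFit(
            breakpoint_s=float(tb),
            slope1=s1 * 60.0,
            slope2=s2 * 60.0,
            intercept1=b1,
            intercept2=b2,
            r2_1=r21,
            r2_2=r22,
            sse=sse1 + sse2,
            n1=int(left.sum()),
            n2=int(right.sum()),
        )
        if best is None or fit.sse <= best.sse:
            best = fit
    if best is None:
        raise ParameterError(
            "no valid breakpoint: every candidate in the window leaves fewer than "
            f"{min_points} points in one segment"
        )
    return best


def rate_reduction(fit: TwoPhaseFit) -> float:
    """Percent decrease from the initial to the final adhesion rate.

    ``(1 - s2/s1) * 100``; negative when the second slope exceeds the first.
    """
    if fit.slope1 == 0:
        raise ParameterError("rate reduction undefined: initial slope is zero")
    return (1.0 - fit.slope2 / fit.slope1) * 100.0


@dataclass(frozen=True)
class RateComparison:
    """One-way ANOVA across conditions plus Tukey HSD pairwise results."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # columns: group1, group2, diff, q, p, significant
    alpha: float = 0.05


def compare_rates(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> RateComparison:
    """Compare replicate adhesion rates across conditions.

    One-way ANOVA F statistic from between/within sums of squares, with
    Tukey's honest-significant-difference test for all pairs:
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` referred to the
    studentized-range distribution with k groups and N-k error degrees of
    freedom.  Pairs with p < ``alpha`` are flagged significant.
    """
    names = list(groups)
    if len(names) < 2:
        raise ParameterError("compare_rates requires at least 2 groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ParameterError(f"group '{k}' needs at least 2 replicates")
    k = len(names)
    ns = np.array([data[g].size for g in names])
    means = np.array([data[g].mean() for g in names])
    n_total = int(ns.sum())
    grand = float(np.concatenate([data[g] for g in names]).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((data[g] - data[g].mean()) ** 2) for g in names))
    df_b, df_w = k - 1, n_total - k
    msb = ss_between / df_b
    msw = ss_within / df_w
    if msw == 0:
        f_stat = np.inf if msb > 0 else 0.0
        p_anova = 0.0 if msb > 0 else 1.0
    else:
        f_stat = msb / msw
        p_anova = float(stats.f.sf(f_stat, df_b, df_w))

    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(names), 2):
        diff = means[i] - means[j]
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "group1": gi,
                "group2": gj,
                "diff": diff,
                "q": q,
                "p": p,
                "significant": p < alpha,
            }
        )
    return RateComparison(
        f_statistic=f_stat,
        p_value=p_anova,
        df_between=df_b,
        df_within=df_w,
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )
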