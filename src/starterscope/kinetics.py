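"""Dough-rise kinetics: pixel-to-mm normalization, collapse truncation,
logistic growth fitting, and cross-inoculum ANOVA on rise rates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

DEFAULT_TUBE_MM = 103.0

__all__ = [
    "RiseSeries",
    "LogisticFit",
    "normalize_heights",
    "truncate_after_fall",
    "fit_logistic",
    "logistic_curve",
    "rise_rate_anova",
]


@dataclass
class RiseSeries:
    """One tube's normalized rise trajectory in mm."""

    tube: str
    inoculum: str
    replicate: int
    times: np.ndarray  # hours, strictly increasing
    heights_mm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        if self.times.shape != self.heights_mm.shape:
            raise ValueError("times and heights must align")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class LogisticFit:
    r: float
    K: float
    N0: float
    residual_ss: float
    gof_p: float
    accepted: bool
    n_points: int
    diagnostic: str | None = None


def normalize_heights(
    tube: str,
    inoculum: str,
    replicate: int,
    times,
    pixels,
    x0: float | None = None,
    tube_height_px: float = 1.0,
    tube_mm: float = DEFAULT_TUBE_MM,
) -> RiseSeries:
    """Convert a tracked pixel series to physical rise in mm.

    delta = (X - X0) / Th scaled by the physical tube height; X0 defaults
    to the first tracked value so the series starts at 0.
    """
    if tube_height_px <= 0:
        raise ValueError(f"tube height in pixels must be positive, got {tube_height_px}")
    pixels = np.asarray(pixels, dtype=float)
    if x0 is None:
        x0 = float(pixels[0])
    heights = (pixels - x0) / tube_height_px * tube_mm
    return RiseSeries(tube, inoculum, replicate, times, heights)


def truncate_after_fall(series: RiseSeries, frac: float = 0.05) -> RiseSeries:
    """Drop everything from the first collapse onward.

    A collapse is a height strictly more than ``frac`` below the running
    maximum; all points from that sample on are removed, so the output is
    always a prefix of the input.
    """
    h = series.heights_mm
    run_max = np.maximum.accumulate(h)
    fallen = h < (1 - frac) * run_max
    cut = int(np.argmax(fallen)) if fallen.any() else len(h)
    return RiseSeries(
        series.tube, series.inoculum, series.replicate,
        series.times[:cut], h[:cut],
    )


def logistic_curve(t, K, N0, r):
    t = np.asarray(t, dtype=float)
    return K / (1 + ((K - N0) / N0) * np.exp(-r * t))


def fit_logistic(series: RiseSeries, gof_alpha: float = 0.01) -> LogisticFit:
    """Least-squares logistic fit N(t) = K / (1 + ((K-N0)/N0) e^{-rt}).

    Initial guesses: K = max height, N0 = first positive height,
    r = 4 * max_slope / K. The goodness-of-fit p compares the logistic
    model against the constant-mean model with a nested F-test; fits are
    accepted when gof_p <= ``gof_alpha`` (i.e. the curve explains the
    data significantly better than a flat line).
    """
    n = len(series)
    if n < 5:
        raise ValueError(f"need at least 5 points after truncation, got {n}")
    t, y = series.times, series.heights_mm

    def rejected(msg: str) -> LogisticFit:
        resid0 = float(((y - y.mean()) ** 2).sum())
        return LogisticFit(np.nan, np.nan, np.nan, resid0, 1.0, False, n, msg)

    positive = y[y > 0]
    if positive.size == 0 or y.max() <= 0:
        return rejected("no positive heights; nothing to fit")
    k0 = float(y.max())
    n0 = float(positive[0])
    slopes = np.diff(y) / np.diff(t)
    slope_max = float(slopes.max()) if slopes.size else 0.0
    r0 = max(4 * slope_max / k0, 1e-3)

    try:
        popt, _ = optimize.curve_fit(
            logistic_curve, t, y,
            p0=(k0, min(n0, 0.9 * k0), r0),
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        return rejected(f"optimizer failed: {exc}")

    K, N0, r = (float(v) for v in popt)
    resid = y - logistic_curve(t, K, N0, r)
    ss1 = float((resid**2).sum())
    ss0 = float(((y - y.mean()) ** 2).sum())
    df1, df0 = n - 3, n - 1
    if ss1 <= 0:
        gof_p = 0.0
    elif ss0 <= ss1 or df1 <= 0:
        gof_p = 1.0
    else:
        f = ((ss0 - ss1) / (df0 - df1)) / (ss1 / df1)
        gof_p = float(stats.f.sf(f, df0 - df1, df1))
    accepted = gof_p <= gof_alpha
    return LogisticFit(r, K, N0, ss1, gof_p, accepted, n)


@dataclass
class RiseAnova:
    adj_r2: float
    r2: float
    f: float
    p: float
    n: int
    k: int
    group_means: dict = field(default_factory=dict)


def rise_rate_anova(rates, inoculum) -> RiseAnova:
    """One-way fixed-effects ANOVA of rise rates on inoculum identity.

    Reports adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k). Degenerate data
    (zero total variance) yields NaN statistics.
    """
    rates = np.asarray(rates, dtype=float)
    inoculum = np.asarray(inoculum, dtype=object)
    levels = sorted(set(inoculum.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 inocula")
    groups = [rates[inoculum == lv] for lv in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every inoculum needs at least 2 replicates")
    n, k = rates.size, len(levels)
    grand = rates.mean()
    ss_total = float(((rates - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    means = {lv: float(g.mean()) for lv, g in zip(levels, groups)}
    if ss_total == 0:
        return RiseAnova(np.nan, np.nan, np.nan, np.nan, n, k, means)
    r2 = ss_between / ss_total
    adj = 1 - (1 - r2) * (n - 1) / (n - k)
    if ss_within == 0:
        return RiseAnova(adj, r2, np.inf, 0.0, n, k, means)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return RiseAnova(adj, r2, float(f), p, n, k, means)
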