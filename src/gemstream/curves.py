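"""Growth-curve and degradation-curve phenotyping.

The estimators are deliberately non-parametric: the specific growth rate
μmax (h⁻¹) is the slope of ln(OD) against time over the sliding window with
the best linear fit, the lag time is where that tangent line crosses the
initial ln(OD), and the maximum degradation rate is the steepest downhill
least-squares slope of a concentration series. No sigmoid model is fitted,
so the estimators make no assumption about the functional form that produced
the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from scipy.stats import linregress


@dataclass
class GrowthCurve:
    """An OD600 time series; times in hours, strictly increasing, >= 4 points."""

    times: np.ndarray
    od600: np.ndarray
    replicate_id: Optional[str] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 must have equal length")
        if len(self.times) < 4:
            raise ValueError("a growth curve needs at least 4 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 values must be non-negative")


class ConcentrationCurve(GrowthCurve):
    """A substrate-concentration time series (mM); same structural rules."""

    @property
    def concentration(self) -> np.ndarray:
        return self.od600


@dataclass
class GrowthPhenotypes:
    mu_max: float          # h^-1
    lag_hours: float
    od_max: float
    fit_window: tuple[int, int]
    r_squared: float


def fit_growth_rate(
    curve: GrowthCurve, min_window: int = 4, r2_tolerance: float = 1e-3
) -> tuple[float, tuple[int, int], float]:
    """Specific growth rate by sliding-window regression on ln(OD).

    Every contiguous window of at least ``min_window`` positive-OD points is
    fitted by ordinary least squares on ln(OD) vs time. Among the windows
    whose R² is within ``r2_tolerance`` of the best, the steepest-slope
    window wins (this resolves the near-ties a smooth sigmoid produces
    between its quasi-linear stretches in favour of the inflection region,
    where the tangent slope is the maximum specific rate); remaining ties go
    to longer, then earlier, windows. μ = max(slope, 0). Zero-variance
    (flat) windows are scored R² = 0 — a constant segment carries no growth
    signal. Returns (mu, (start, stop) index window, R²).
    """
    if min_window < 2:
        raise ValueError("min_window must be >= 2")
    positive = curve.od600 > 0
    if positive.sum() < min_window:
        raise ValueError(
            f"need at least {min_window} positive OD readings, "
            f"have {int(positive.sum())}")
    t = curve.times
    y = np.where(positive, np.log(np.where(positive, curve.od600, 1.0)), 0.0)
    n = len(t)
    # prefix sums give O(1) slope and R^2 per window
    bad = np.concatenate([[0], np.cumsum(~positive)])
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    candidates = []  # (slope, length, -start, window, r2)
    for start in range(n):
        for stop in range(start + min_window, n + 1):
            if bad[stop] - bad[start] > 0:
                continue
            m = stop - start
            st = ct[stop] - ct[start]
            sy = cy[stop] - cy[start]
            stt = ctt[stop] - ctt[start]
            sty = cty[stop] - cty[start]
            syy = cyy[stop] - cyy[start]
            var_t = stt - st * st / m
            var_y = syy - sy * sy / m
            cov = sty - st * sy / m
            slope = cov / var_t
            if var_y <= max(1e-24, 1e-15 * abs(syy)):
                r2, slope = 0.0, 0.0  # flat segment: no growth signal
            else:
                r2 = min(max(cov * cov / (var_t * var_y), 0.0), 1.0)
            candidates.append((slope, m, -start, (start, stop), r2))
    if not candidates:
        raise ValueError("no contiguous window of positive OD readings")
    best_r2 = max(c[4] for c in candidates)
    top = [c for c in candidates if c[4] >= best_r2 - r2_tolerance]
    slope, _, _, window, r2 = max(
        top, key=lambda c: (round(c[0], 10), c[1], c[2]))
    return max(float(slope), 0.0), window, float(r2)


def extract_phenotypes(
    curve: GrowthCurve, min_window: int = 4, smooth_od_max: bool = True
) -> GrowthPhenotypes:
    """μmax, lag time, and maximum OD from one growth curve.

    The lag is where the tangent to ln(OD) over the best-fit exponential
    window intersects the initial ln(OD) level — the classical geometric lag
    construction. od_max is the maximum of the median-of-3 smoothed series
    (single-point spikes are discounted), or of the raw series when smoothing
    is disabled.
    """
    mu, window, r2 = fit_growth_rate(curve, min_window=min_window)
    start, stop = window
    t = curve.times
    seg = slice(start, stop)
    log_seg = np.log(curve.od600[seg])
    res = linregress(t[seg], log_seg)
    initial = curve.od600[curve.od600 > 0][0]
    if res.slope > 1e-12:
        lag = (np.log(initial) - res.intercept) / res.slope
    else:
        lag = 0.0
    lag = float(np.clip(lag, 0.0, t[-1]))
    if smooth_od_max and len(curve.od600) >= 3:
        od_max = float(np.max(medfilt(curve.od600, kernel_size=3)))
    else:
        od_max = float(np.max(curve.od600))
    return GrowthPhenotypes(mu_max=mu, lag_hours=lag, od_max=od_max,
                            fit_window=window, r_squared=r2)


def max_degradation_rate(curve: ConcentrationCurve, window: int = 3) -> float:
    """Maximum substrate removal rate (mM·h⁻¹): the steepest negative
    least-squares slope over sliding windows; 0 when the concentration never
    decreases."""
    t, conc = curve.times, curve.concentration
    n = len(t)
    best = 0.0
    for start in range(n - window + 1):
        seg = slice(start, start + window)
        slope = linregress(t[seg], conc[seg]).slope
        best = max(best, -slope)
    return float(best)


def compare_phenotypes(
    a: GrowthPhenotypes, b: GrowthPhenotypes,
    rate_a: Optional[float] = None, rate_b: Optional[float] = None,
) -> dict:
    """Pairwise phenotype comparison (a = reference strain, b = derived).

    Fold increases follow the (new/old − 1) convention: an od_max going from
    1.0 to 1.7 is a 0.7-fold increase.
    """
    if a.mu_max <= 0 or a.od_max <= 0:
        raise ValueError("reference phenotypes must have positive mu_max and od_max")
    out = {
        "lag_reduction_hours": a.lag_hours - b.lag_hours,
        "mu_ratio": b.mu_max / a.mu_max,
        "od_max_fold_increase": b.od_max / a.od_max - 1.0,
        "rate_fold_increase": None,
    }
    if rate_a is not None and rate_b is not None:
        if rate_a <= 0:
            raise ValueError("reference degradation rate must be positive")
        out["rate_fold_increase"] = rate_b / rate_a - 1.0
    return out


# ---------------------------------------------------------------------------
# Curve files (long-format TSV: time_h, value, series_id)
# ---------------------------------------------------------------------------

def read_curves(path: Union[str, Path],
                kind: str = "growth") -> dict[str, GrowthCurve]:
    """Read a long-format curve TSV into one curve per series_id."""
    path = Path(path)
    cls = GrowthCurve if kind == "growth" else ConcentrationCurve
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"time_h", "value", "series_id"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: curve TSV needs columns {sorted(required)}, "
            f"found {list(frame.columns)}")
    out: dict[str, GrowthCurve] = {}
    for series_id, grp in frame.groupby("series_id", sort=True):
        grp = grp.sort_values("time_h")
        out[str(series_id)] = cls(
            times=grp["time_h"].to_numpy(),
            od600=grp["value"].to_numpy(),
            replicate_id=str(series_id))
    return out


def write_curves(curves: dict[str, GrowthCurve], path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["time_h\tvalue\tseries_id"]
    for series_id in sorted(curves):
        c = curves[series_id]
        for t, v in zip(c.times, c.od600):
            lines.append(f"{float(t)!r}\t{float(v)!r}\t{series_id}")
    path.write_text("\n".join(lines) + "\n")
    return path
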