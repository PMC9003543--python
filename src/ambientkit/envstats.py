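"""Environmental-sensor summaries and paired-sensor agreement.

Ambient-light logs are summarized per named period (clear day, night,
cloudy day, ...) by order statistics of illuminance.  A fast 1 Hz sensor is
validated against a slow reference by averaging the fast samples over the
10 minutes preceding each slow reading, then comparing the aligned pairs
with RMSE, an ordinary-least-squares fit with r-squared, and Bland-Altman
limits of agreement (mean difference +- 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PeriodSchedule:
    """Named, non-overlapping (start s, end s) periods plus optional
    excluded windows (e.g. a nightly data-upload hour)."""

    periods: dict[str, tuple[float, float]]
    excluded: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        spans = sorted(self.periods.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("periods overlap")


def period_stats(
    timestamps, values, schedule: PeriodSchedule
) -> dict[str, dict[str, float]]:
    """Min / median / max of ``values`` within each named period.

    Samples inside any excluded window are dropped from every period.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.ones(len(t), dtype=bool)
    for s, e in schedule.excluded:
        keep &= ~((t >= s) & (t < e))
    out = {}
    for name, (s, e) in schedule.periods.items():
        sel = keep & (t >= s) & (t < e)
        if not sel.any():
            raise ValueError(f"period {name!r} contains no samples")
        pv = v[sel]
        out[name] = {
            "min": float(pv.min()),
            "median": float(np.median(pv)),
            "max": float(pv.max()),
        }
    return out


def align_windows(fast: np.ndarray, slow: np.ndarray, window: float = 600.0):
    """Mean of fast samples in the half-open window (t_slow - window, t_slow]
    for each slow timestamp.

    Returns ``(aligned, slow_values, n_missing)``; slow readings whose
    window holds no fast sample are dropped and counted in ``n_missing``.
    """
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    aligned, slow_vals = [], []
    n_missing = 0
    for ts, val in slow:
        sel = (fast[:, 0] > ts - window) & (fast[:, 0] <= ts)
        if not sel.any():
            n_missing += 1
            continue
        aligned.append(fast[sel, 1].mean())
        slow_vals.append(val)
    return np.array(aligned), np.array(slow_vals), n_missing


@dataclass(frozen=True)
class AgreementReport:
    rmse: float
    r_squared: float
    slope: float
    intercept: float
    mean_difference: float
    loa_lower: float  # mean difference - 1.96 SD
    loa_upper: float  # mean difference + 1.96 SD
    frac_within_loa: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "mean_difference": self.mean_difference,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "frac_within_loa": self.frac_within_loa,
            "n": self.n,
        }


def agreement(aligned, slow) -> AgreementReport:
    """Agreement statistics between aligned fast means and slow readings.

    Differences are fast-derived minus reference (a fast sensor reading low
    gives a negative mean difference).  The limits-of-agreement SD uses the
    n-1 denominator.  A zero-variance reference makes r-squared undefined.
    """
    a = np.asarray(aligned, dtype=float)
    s = np.asarray(slow, dtype=float)
    if a.shape != s.shape or a.ndim != 1:
        raise ValueError("aligned and slow must be equal-length 1-D arrays")
    if len(a) < 3:
        raise ValueError("need at least three paired points")
    if np.ptp(s) == 0:
        raise ValueError("reference series has zero variance; r^2 undefined")
    rmse = float(np.sqrt(np.mean((a - s) ** 2)))
    fit = stats.linregress(s, a)
    d = a - s
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = md - 1.96 * sd, md + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi))) if sd > 0 else 1.0
    return AgreementReport(
        rmse=rmse,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        mean_difference=md,
        loa_lower=float(lo),
        loa_upper=float(hi),
        frac_within_loa=within,
        n=len(a),
    )


def validate_pair(fast, slow, window: float = 600.0) -> AgreementReport:
    """align_windows followed by agreement, the full validation recipe."""
    aligned, slow_vals, _ = align_windows(fast, slow, window)
    return agreement(aligned, slow_vals)


def light_log_frame(timestamps, r, g, b, lux, color_temp) -> pd.DataFrame:
    """Assemble and validate a 1 Hz ambient-light log."""
    df = pd.DataFrame(
        {
            "timestamp": np.asarray(timestamps, dtype=float),
            "R": r, "G": g, "B": b,
            "lux": np.asarray(lux, dtype=float),
            "color_temp_k": np.asarray(color_temp, dtype=float),
        }
    )
    for c in "RGB":
        if ((df[c] < 0) | (df[c] > 255)).any():
            raise ValueError(f"{c} channel outside RGB888 range")
    if (df["lux"] < 0).any():
        raise ValueError("negative illuminance")
    return df
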