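"""Window summaries, the 63 %-criterion time constant, and the Friedman test.

These are the analysis stages applied to inspired-gas traces around a
reservoir-bag disconnection: descriptive statistics over the 10-minute
windows before, during and after the disconnection; a nonparametric
before/during/after comparison (Friedman rank test over paired readings);
and the classical single-exponential time constant read off a transient
as the time to cover 63 % of its total change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import GASES
from .scenario import GasTrace

WINDOW_NAMES = ("before", "during", "after")
#: Length of each analysis window (min) and the cadence of the recorded
#: readings feeding the descriptive statistics (one per minute, 10 per
#: window per run).
WINDOW_MINUTES = 10
#: 63 % criterion: fraction of the total change used as the threshold.
TAU_CRITERION = 0.632


class ConstantSignalError(ValueError):
    """The signal has no net change in the window; tau is undefined."""


class ThresholdNotCrossedError(RuntimeError):
    """The 63 % threshold was not reached inside the analysis window."""


@dataclass(frozen=True)
class WindowSummary:
    """Order statistics of inspired-gas readings in one analysis window.

    Values are in % (vol% for sevoflurane).
    """

    gas: str
    window: str
    median: float
    q25: float
    q75: float
    vmin: float
    vmax: float
    n: int

    def __post_init__(self) -> None:
        if not (self.vmin <= self.q25 <= self.median <= self.q75 <= self.vmax):
            raise ValueError("order statistics out of order")

    @classmethod
    def from_values(cls, values, gas: str = "o2", window: str = "during"):
        """Summarize raw readings with type-7 (linear) percentiles."""
        v = np.asarray(values, float)
        if v.size == 0:
            raise ValueError("no readings in window")
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        return cls(
            gas=gas,
            window=window,
            median=float(med),
            q25=float(q25),
            q75=float(q75),
            vmin=float(v.min()),
            vmax=float(v.max()),
            n=int(v.size),
        )


@dataclass(frozen=True)
class TimeConstantEstimate:
    """63 %-criterion time constant of a monotone transient.

    ``f_initial``/``f_final`` in % of the analyzed gas; ``direction`` is
    ``"falling"`` or ``"rising"``; ``tau`` in minutes from window start.
    """

    tau: float
    f_initial: float
    f_final: float
    direction: str

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n_blocks: int
    k_treatments: int

    def __post_init__(self) -> None:
        if self.statistic < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValueError("invalid Friedman result")
        if self.df != self.k_treatments - 1:
            raise ValueError("df must equal k_treatments - 1")


# ---------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------

def disconnect_time(trace: GasTrace) -> float:
    """Start time (min) of the bag-disconnection phase in a trace."""
    mask = trace.phases == "disconnected"
    if not mask.any():
        raise ValueError("trace has no 'disconnected' phase labels")
    return float(trace.times[mask][0])


def window_bounds(window: str, t_disconnect: float) -> tuple[float, float]:
    """[start, end] of a named 10-min analysis window.

    ``before`` is the last 10 min of maintenance, ``during`` the 10 min
    of disconnection, ``after`` the first 10 min after reconnection (the
    reconnected phase itself lasts longer).
    """
    if window not in WINDOW_NAMES:
        raise ValueError(f"unknown window {window!r}; expected one of {WINDOW_NAMES}")
    offset = {"before": -WINDOW_MINUTES, "during": 0, "after": WINDOW_MINUTES}[window]
    t0 = t_disconnect + offset
    return t0, t0 + WINDOW_MINUTES


def per_minute_readings(
    trace: GasTrace, gas: str, window: str, t_disconnect: float | None = None
) -> np.ndarray:
    """The 10 once-a-minute recorded readings of a window, in %.

    Readings are taken at whole minutes from the window start (offsets
    0..9 min), mirroring a per-minute record of a 10-min window.
    """
    if t_disconnect is None:
        t_disconnect = disconnect_time(trace)
    t0, _ = window_bounds(window, t_disconnect)
    col = trace.column(gas)
    try:
        idx = [trace.index_at(t0 + k) for k in range(WINDOW_MINUTES)]
    except ValueError as exc:
        raise ValueError(f"trace does not cover the {window!r} window") from exc
    return col[idx] * 100.0


def window_summary(
    trace: GasTrace, gas: str, window: str, t_disconnect: float | None = None
) -> WindowSummary:
    """Summary statistics of the per-minute readings in one window."""
    vals = per_minute_readings(trace, gas, window, t_disconnect)
    return WindowSummary.from_values(vals, gas=gas, window=window)


# ---------------------------------------------------------------------
# 63 %-criterion time constant
# ---------------------------------------------------------------------

def estimate_tau_63(
    trace: GasTrace, gas: str, window: tuple[float, float]
) -> TimeConstantEstimate:
    """Time constant of the transient of ``gas`` inside ``window``.

    The initial value is the reading at the window start; the final value
    is the window extremum (minimum for a falling signal, maximum for a
    rising one, direction taken from the sign of the net change).  tau is
    the first time, linearly interpolated between samples, at which the
    signal crosses ``f_initial + 0.632 * (f_final - f_initial)``, measured
    from the window start.  Affine rescalings of the signal leave tau
    unchanged.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("window must have positive length")
    sub = trace.window(t_start, t_end)
    times = sub.times
    vals = sub.column(gas) * 100.0
    f_initial = float(vals[0])
    net = float(vals[-1]) - f_initial
    if np.ptp(vals) == 0.0:
        raise ConstantSignalError(
            f"{gas} signal is constant in [{t_start}, {t_end}] min; "
            "time constant undefined"
        )
    if net == 0.0:
        # No net change but not constant: use the larger excursion.
        net = (
            float(vals.max()) - f_initial
            if vals.max() - f_initial > f_initial - vals.min()
            else float(vals.min()) - f_initial
        )
    if net < 0:
        direction, f_final = "falling", float(vals.min())
    else:
        direction, f_final = "rising", float(vals.max())
    if f_final == f_initial:
        raise ConstantSignalError(
            f"{gas} signal shows no excursion from its initial value"
        )
    threshold = f_initial + TAU_CRITERION * (f_final - f_initial)
    crossed = vals <= threshold if direction == "falling" else vals >= threshold
    hits = np.nonzero(crossed[1:])[0]
    if hits.size == 0:
        raise ThresholdNotCrossedError(
            f"63 % threshold not crossed within the window; transient "
            f"censored at {t_end - t_start:.2f} min"
        )
    i = int(hits[0]) + 1
    v0, v1 = vals[i - 1], vals[i]
    if v1 == v0:
        t_cross = float(times[i])
    else:
        t_cross = float(times[i - 1] + (threshold - v0) / (v1 - v0) * (times[i] - times[i - 1]))
    return TimeConstantEstimate(
        tau=max(t_cross - float(times[0]), 0.0),
        f_initial=f_initial,
        f_final=f_final,
        direction=direction,
    )


# ---------------------------------------------------------------------
# Friedman rank test
# ---------------------------------------------------------------------

def friedman_test(values) -> FriedmanResult:
    """Friedman rank test over an (n_blocks x k_treatments) matrix.

    Ranks are assigned within each block (average ranks for ties); the
    statistic is Q = [12/(n k (k+1))] * sum_j R_j^2 - 3 n (k+1), divided
    by the standard tie-correction factor
    1 - sum(t^3 - t) / (n k (k^2 - 1)); the p-value comes from the
    chi-square distribution with k-1 degrees of freedom.  Fully tied data
    yield Q = 0, p = 1.
    """
    x = np.asarray(values, float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D matrix (blocks x treatments)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if not np.isfinite(x).all():
        raise ValueError("missing or non-finite cells are not allowed")
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    q0 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0.0:
        statistic, p = 0.0, 1.0
    else:
        statistic = max(q0 / correction, 0.0)
        p = float(stats.chi2.sf(statistic, k - 1))
    return FriedmanResult(
        statistic=float(statistic),
        df=k - 1,
        p_value=p,
        n_blocks=n,
        k_treatments=k,
    )
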