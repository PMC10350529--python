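"""Session-level protocol summaries and group statistics.

Covers the three experiment designs run on the fitted (CBVF, SO2) series:

* rotarod: 60 s rest, 180 s forced running, 120 s rest; responses expressed
  as percent change from the first-10-second reference average,
* hypercapnia: 60 s baseline, CO2 challenge from 60 s to 300 s, recovery to
  360 s; maximum CBVF rise and minimum SO2 drop as percent change from the
  baseline average, plus the time for CBVF to return to its baseline band
  after CO2 release,
* free-moving behavior: per-label (grooming/resting/walking/...) means.

Only samples with quality "ok" enter any summary. Group comparisons use a
two-tailed unpaired Student t-test (pooled variance by default, Welch
optional) with mean +/- s.e.m. reported per group.

All windows are closed intervals [t0, t1] in seconds from session start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from .fitting import HemodynamicTimeSeries

__all__ = [
    "ProtocolWindows",
    "SessionSummary",
    "BehaviorSummary",
    "GroupComparison",
    "InsufficientDataError",
    "ProtocolError",
    "percent_change",
    "summarize_rotarod",
    "summarize_hypercapnia",
    "summarize_behavior",
    "compare_groups",
]

BEHAVIOR_LABELS = ("grooming", "resting", "walking", "running", "unknown")


class InsufficientDataError(ValueError):
    """A required window holds no usable (quality ok) samples."""


class ProtocolError(ValueError):
    """The session does not cover the protocol's required windows."""


@dataclass(frozen=True)
class ProtocolWindows:
    """Named time intervals (closed, seconds from session start)."""

    reference: Tuple[float, float] = (0.0, 10.0)
    baseline: Tuple[float, float] = (0.0, 60.0)
    challenge: Tuple[float, float] = (60.0, 300.0)
    session_end_s: float = 360.0

    def __post_init__(self) -> None:
        for name in ("reference", "baseline", "challenge"):
            t0, t1 = getattr(self, name)
            if not t0 < t1:
                raise ValueError(f"{name} window must be a nonempty interval")
            if t1 > self.session_end_s:
                raise ValueError(f"{name} window extends past the session end")

    @classmethod
    def rotarod(cls) -> "ProtocolWindows":
        return cls(reference=(0.0, 10.0), baseline=(0.0, 60.0),
                   challenge=(60.0, 240.0), session_end_s=360.0)

    @classmethod
    def hypercapnia(cls) -> "ProtocolWindows":
        return cls(reference=(0.0, 10.0), baseline=(0.0, 60.0),
                   challenge=(60.0, 300.0), session_end_s=360.0)


@dataclass
class SessionSummary:
    """Endpoint metrics for one session (percent changes are vs the stated
    reference average; fields unused by a protocol stay None)."""

    baseline_mean_cbvf_pct: float
    baseline_mean_so2: float
    baseline_cbvf_change_pct: Optional[float] = None
    baseline_so2_change_pct: Optional[float] = None
    max_cbvf_change_pct: Optional[float] = None
    max_so2_change_pct: Optional[float] = None
    min_so2_change_pct: Optional[float] = None
    time_to_baseline_s: Optional[float] = None
    time_to_baseline_censored: bool = False
    n_ok: int = 0
    n_total: int = 0


@dataclass
class BehaviorSummary:
    """Per-behavior-label means of the fitted series."""

    labels: Dict[str, Dict[str, float]]  # label -> {mean_cbvf_pct, mean_so2, n}


@dataclass
class GroupComparison:
    """Two-group unpaired t-test with per-group mean +/- s.e.m."""

    t: float
    p: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    equal_var: bool = True


def _window_values(
    series: HemodynamicTimeSeries, values: NDArray[np.float64],
    window: Tuple[float, float]
) -> NDArray[np.float64]:
    t0, t1 = window
    sel = (series.timestamps_s >= t0) & (series.timestamps_s <= t1) & series.ok
    return values[sel]


def percent_change(
    series: HemodynamicTimeSeries,
    window: Tuple[float, float],
    reference_window: Tuple[float, float],
    field: str = "cbvf_percent",
    statistic: str = "max",
    smooth: int = 1,
) -> float:
    """Percent change of a window statistic relative to a reference average.

    ``100 * (stat_over_window - mean_over_reference) / mean_over_reference``
    where ``statistic`` is "max", "min" or "mean", computed over quality-ok
    samples. ``smooth`` > 1 applies a centered running median of that many
    samples before taking the extremum (off by default).
    """
    values = np.asarray(getattr(series, field), dtype=float)
    ref = _window_values(series, values, reference_window)
    if ref.size == 0:
        raise InsufficientDataError("reference window holds no usable samples")
    if smooth > 1:
        import pandas as pd

        values = (
            pd.Series(values).rolling(smooth, center=True, min_periods=1)
            .median().to_numpy()
        )
    win = _window_values(series, values, window)
    if win.size == 0:
        raise InsufficientDataError("analysis window holds no usable samples")
    ref_mean = float(ref.mean())
    stat = {"max": np.max, "min": np.min, "mean": np.mean}[statistic](win)
    return 100.0 * (float(stat) - ref_mean) / ref_mean


def _require_coverage(series: HemodynamicTimeSeries, windows: ProtocolWindows) -> None:
    if series.timestamps_s[-1] < windows.challenge[1]:
        raise ProtocolError(
            f"session ends at {series.timestamps_s[-1]:g} s but the protocol "
            f"challenge runs to {windows.challenge[1]:g} s"
        )


def _base_summary(series: HemodynamicTimeSeries, windows: ProtocolWindows) -> SessionSummary:
    base_cbvf = _window_values(series, series.cbvf_percent, windows.baseline)
    base_so2 = _window_values(series, series.so2_fraction, windows.baseline)
    if base_cbvf.size == 0:
        raise InsufficientDataError("baseline window holds no usable samples")
    return SessionSummary(
        baseline_mean_cbvf_pct=float(base_cbvf.mean()),
        baseline_mean_so2=float(base_so2.mean()),
        n_ok=int(series.ok.sum()),
        n_total=len(series.timestamps_s),
    )


def summarize_rotarod(
    series: HemodynamicTimeSeries,
    windows: Optional[ProtocolWindows] = None,
    smooth: int = 5,
) -> SessionSummary:
    """Rotarod session summary.

    Baseline change: average over the first-60-s rest vs the first-10-s
    reference average. Running response: maximum over the running window vs
    the same reference, for both CBVF and SO2. Extrema are taken after a
    centered ``smooth``-sample running median (default 5): the raw max of a
    noisy 1 Hz series is a systematically upward-biased estimate of the
    underlying peak (set ``smooth=1`` for raw extrema).
    """
    windows = windows or ProtocolWindows.rotarod()
    _require_coverage(series, windows)
    out = _base_summary(series, windows)
    ref = windows.reference
    out.baseline_cbvf_change_pct = percent_change(
        series, windows.baseline, ref, "cbvf_percent", "mean")
    out.baseline_so2_change_pct = percent_change(
        series, windows.baseline, ref, "so2_fraction", "mean")
    out.max_cbvf_change_pct = percent_change(
        series, windows.challenge, ref, "cbvf_percent", "max", smooth)
    out.max_so2_change_pct = percent_change(
        series, windows.challenge, ref, "so2_fraction", "max", smooth)
    return out


def summarize_hypercapnia(
    series: HemodynamicTimeSeries,
    windows: Optional[ProtocolWindows] = None,
    reference: str = "baseline",
    smooth: int = 5,
    band_sd: float = 2.0,
    dwell_s: float = 5.0,
) -> SessionSummary:
    """Hypercapnia session summary.

    Maximum CBVF and minimum SO2 over the CO2 window as percent change from
    the baseline average (set ``reference="reference"`` to use the first-10-s
    average instead). ``time_to_baseline_s`` is the first post-release time at
    which the median-smoothed CBVF re-enters the baseline band (mean +/-
    ``band_sd`` baseline SDs) and stays there for at least ``dwell_s``
    seconds, reported as seconds since CO2 release; censored at session end
    (flagged) if it never recovers.
    """
    windows = windows or ProtocolWindows.hypercapnia()
    _require_coverage(series, windows)
    out = _base_summary(series, windows)
    ref_win = windows.baseline if reference == "baseline" else windows.reference
    out.max_cbvf_change_pct = percent_change(
        series, windows.challenge, ref_win, "cbvf_percent", "max", smooth)
    out.min_so2_change_pct = percent_change(
        series, windows.challenge, ref_win, "so2_fraction", "min", smooth)

    # time to baseline after CO2 release
    import pandas as pd

    release = windows.challenge[1]
    base = _window_values(series, series.cbvf_percent, windows.baseline)
    lo = base.mean() - band_sd * base.std(ddof=0)
    hi = base.mean() + band_sd * base.std(ddof=0)
    smoothed = (
        pd.Series(series.cbvf_percent).rolling(5, center=True, min_periods=1)
        .median().to_numpy()
    )
    post = (series.timestamps_s >= release) & series.ok
    t_post = series.timestamps_s[post]
    v_post = smoothed[post]
    inside = (v_post >= lo) & (v_post <= hi)
    out.time_to_baseline_s = float(series.timestamps_s[-1] - release)
    out.time_to_baseline_censored = True
    for i in range(len(t_post)):
        if not inside[i]:
            continue
        # samples covering [t_i, t_i + dwell]; a censored tail counts as staying
        j = int(np.searchsorted(t_post, t_post[i] + dwell_s, side="right"))
        long_enough = j == len(t_post) or t_post[j - 1] - t_post[i] >= dwell_s
        if inside[i:j].all() and long_enough:
            out.time_to_baseline_s = float(t_post[i] - release)
            out.time_to_baseline_censored = False
            break
    return out


def summarize_behavior(
    series: HemodynamicTimeSeries, track: Sequence[str]
) -> BehaviorSummary:
    """Mean CBVF (percent) and SO2 per behavior label over quality-ok samples."""
    track = np.asarray(track, dtype=object)
    if len(track) != len(series.timestamps_s):
        raise ValueError("behavior track is not aligned to the series")
    out: Dict[str, Dict[str, float]] = {}
    for label in dict.fromkeys(track):  # preserve first-seen order
        sel = (track == label) & series.ok
        n = int(sel.sum())
        if n == 0:
            out[str(label)] = {"mean_cbvf_pct": np.nan, "mean_so2": np.nan, "n": 0}
            continue
        out[str(label)] = {
            "mean_cbvf_pct": float(series.cbvf_percent[sel].mean()),
            "mean_so2": float(series.so2_fraction[sel].mean()),
            "n": n,
        }
    return BehaviorSummary(labels=out)


def compare_groups(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> GroupComparison:
    """Two-tailed unpaired t-test between two groups of session metrics."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 sessions")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        t=float(t),
        p=float(p),
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)),
        n_b=int(b.size),
        equal_var=equal_var,
    )
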