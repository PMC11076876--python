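"""Steady-state detection: flag windows where tracked broth concentrations
are stable relative to their mean over a span of several residence times.

A window [t_i, t_j] qualifies when (a) it spans at least ``window_span``
hydraulic retention times, (b) it holds >= 3 samples, and (c) the coefficient
of variation of every tracked compound over the window is at most ``max_cv``.
Samples covered by any qualifying window are flagged steady; qualifying
windows that share samples merge into maximal intervals, so plateaus
separated by a jump stay apart.  The criterion is scale-invariant
by construction (CV is unitless) and tightening ``max_cv`` can only shrink
the steady set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import hydraulic_retention_time
from .timeseries import ReactorTimeSeries

__all__ = ["SteadyStateCriteria", "detect_steady_state", "steady_flags"]

DEFAULT_TRACKED = (
    "n-caproate",
    "n-butyrate",
    "acetate",
    "ethanol",
    "n-hexanol",
    "n-butanol",
)

#: Concentrations below this (mCmol/L) are treated as zero when forming CVs,
#: so an absent compound cannot veto steadiness through a 0/0 ratio.
_NEAR_ZERO = 1e-9


@dataclass(frozen=True)
class SteadyStateCriteria:
    """Tunable steady-state rule: span (in HRTs), CV cap, tracked compounds."""

    window_span: float = 3.0  # multiples of HRT
    max_cv: float = 0.10
    tracked: tuple[str, ...] = DEFAULT_TRACKED

    def __post_init__(self) -> None:
        if self.window_span <= 0:
            raise ValueError("window_span must be > 0")
        if not 0.0 < self.max_cv < 1.0:
            raise ValueError("max_cv must lie in (0, 1)")


def _window_is_steady(
    values: np.ndarray, max_cv: float
) -> bool:
    """CV test for one compound over one window (population SD)."""
    mean = values.mean()
    sd = values.std()
    if abs(mean) < _NEAR_ZERO:
        return sd < _NEAR_ZERO
    return sd / abs(mean) <= max_cv


def _qualifying_windows(
    ts: ReactorTimeSeries, criteria: SteadyStateCriteria
) -> list[tuple[int, int]]:
    """All sample-index windows [i, j] passing the span and CV tests."""
    times = ts.times
    n = len(times)
    if n < 3:
        return []
    flows = [
        s.feed_flow + s.base_flow for s in ts.samples if s.feed_flow + s.base_flow > 0
    ]
    if not flows:
        raise ValueError("no liquid flow recorded; HRT (and steadiness) undefined")
    hrt_days = hydraulic_retention_time(ts.volume, float(np.mean(flows))) / 24.0
    span_days = criteria.window_span * hrt_days
    broth = ts.broth_frame()
    tracked = [c for c in criteria.tracked if c in broth.columns]
    values = broth[tracked].to_numpy() if tracked else np.zeros((n, 0))
    windows = []
    for i in range(n):
        for j in range(i + 2, n):
            if times[j] - times[i] < span_days:
                continue
            window = values[i : j + 1]
            if all(
                _window_is_steady(window[:, k], criteria.max_cv)
                for k in range(window.shape[1])
            ):
                windows.append((i, j))
    return windows


def steady_flags(
    ts: ReactorTimeSeries, criteria: SteadyStateCriteria | None = None
) -> np.ndarray:
    """Boolean flag per sample: covered by at least one qualifying window."""
    criteria = criteria or SteadyStateCriteria()
    flags = np.zeros(len(ts.samples), dtype=bool)
    for i, j in _qualifying_windows(ts, criteria):
        flags[i : j + 1] = True
    return flags


def detect_steady_state(
    ts: ReactorTimeSeries, criteria: SteadyStateCriteria | None = None
) -> list[tuple[float, float]]:
    """Maximal steady intervals as (t_start, t_end) day pairs.

    Qualifying windows are merged only when they share a sample, so two
    steady plateaus separated by a jump stay separate intervals even though
    both sides individually pass.
    """
    criteria = criteria or SteadyStateCriteria()
    windows = sorted(_qualifying_windows(ts, criteria))
    times = ts.times
    merged: list[list[int]] = []
    for i, j in windows:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [(float(times[i]), float(times[j])) for i, j in merged]
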