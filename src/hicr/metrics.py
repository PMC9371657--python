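"""Per-cell burst statistics from cytosolic and ER indicator traces.

All statistics are frame-wise ratios relative to the pre-stimulus
baseline ``F0 = F_before - I_back``; no smoothing is applied anywhere.
Windows are closed on both ends, with frame timestamps compared at
half-frame tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import (
    BackgroundEstimates,
    BaselineStats,
    BurstMetrics,
    FluorescenceTrace,
    HeatPulseProtocol,
)

__all__ = [
    "baseline",
    "scatter_correct",
    "dfmax",
    "spontaneous_dfmax",
    "dfmin_cepia",
    "normalize_by_store",
    "correlate_er_cytosol",
]


def baseline(
    trace: FluorescenceTrace,
    protocol: HeatPulseProtocol,
    bg: BackgroundEstimates,
) -> BaselineStats:
    """F_before (single frame at/just before pulse onset) and F0.

    No smoothing: F_before is the one designated frame's value.
    """
    idx = trace.baseline_index(protocol.t_start)
    f_before = float(trace.intensity[idx])
    f0 = f_before - bg.i_back
    if f0 <= 0:
        raise ValueError(
            f"cell {trace.cell_id!r}: F_before ({f_before:g}) <= I_back ({bg.i_back:g})")
    return BaselineStats(f_before=f_before, f0=f0)


def scatter_correct(
    trace: FluorescenceTrace,
    bg: BackgroundEstimates,
) -> FluorescenceTrace:
    """Remove the IR-laser scatter from laser-on frames.

    The scatter excess (``bg.i_laser - bg.i_back``, i.e. the laser-on
    background above the always-present dark level) is subtracted from
    laser-on frames only; all other frames are untouched.  A zero
    excess is a no-op.
    """
    excess = bg.scatter
    if excess == 0 or not trace.laser_on.any():
        return trace.with_intensity(trace.intensity)
    return trace.with_intensity(trace.intensity - excess * trace.laser_on)


def _require_window(trace: FluorescenceTrace, t_lo: float, t_hi: float) -> np.ndarray:
    tol = 0.5 * trace.frame_interval
    if trace.time_s[0] > t_lo + tol or trace.time_s[-1] < t_hi - tol:
        raise ValueError(
            f"cell {trace.cell_id!r}: trace [{trace.time_s[0]:g}, {trace.time_s[-1]:g}] s "
            f"does not cover the window [{t_lo:g}, {t_hi:g}] s")
    mask = trace.window_mask(t_lo, t_hi)
    if not mask.any():
        raise ValueError(f"cell {trace.cell_id!r}: no frames in [{t_lo:g}, {t_hi:g}] s")
    return mask


def dfmax(
    trace: FluorescenceTrace,
    protocol: HeatPulseProtocol,
    bg: BackgroundEstimates,
    window_s: float = 20.0,
) -> BurstMetrics:
    """Peak dF/F0 within ``window_s`` seconds after heating initiation.

    ``dF = F - F_before``; the maximum of dF/F0 over the closed window
    [t_start, t_start + window_s] and the time of the peak are returned.
    The trace should already be scatter-corrected.
    """
    bl = baseline(trace, protocol, bg)
    mask = _require_window(trace, protocol.t_start, protocol.t_start + window_s)
    ratio = (trace.intensity[mask] - bl.f_before) / bl.f0
    i_pk = int(np.argmax(ratio))
    return BurstMetrics(
        cell_id=trace.cell_id,
        channel=trace.channel,
        dfmax=float(ratio[i_pk]),
        t_peak_s=float(trace.time_s[mask][i_pk]),
    )


def spontaneous_dfmax(
    trace: FluorescenceTrace,
    bg: BackgroundEstimates,
    t_before_s: float = 10.0,
    window: tuple[float, float] = (10.0, 30.0),
) -> float:
    """Spontaneous-fluctuation (F_max - F_before)/(F_before - I_back).

    For unheated control cells: F_before is the intensity ``t_before_s``
    seconds after the start of the observation and F_max the maximum
    over the closed window (default 10-30 s), mirroring the exposure
    timing of the heating experiments.
    """
    idx = trace.index_at_or_before(t_before_s)
    f_before = float(trace.intensity[idx])
    f0 = f_before - bg.i_back
    if f0 <= 0:
        raise ValueError(f"cell {trace.cell_id!r}: dead baseline at {t_before_s:g} s")
    mask = _require_window(trace, *window)
    return float((trace.intensity[mask].max() - f_before) / f0)


def dfmin_cepia(
    trace: FluorescenceTrace,
    protocol: HeatPulseProtocol,
    bg: BackgroundEstimates,
    window: tuple[float, float] = (2.4, 10.0),
) -> BurstMetrics:
    """ER-store depletion: minimum dF/F0 in the post-pulse window.

    The window is given in seconds after heating initiation (default
    2.4-10 s, excluding the thermal-quench epoch of the pulse itself).
    The trace is expected to be scatter- and bleach-corrected.  The
    depletion magnitude is reported as ``minus_dfmin = -dfmin``.
    """
    bl = baseline(trace, protocol, bg)
    t_lo = protocol.t_start + window[0]
    t_hi = protocol.t_start + window[1]
    mask = _require_window(trace, t_lo, t_hi)
    ratio = (trace.intensity[mask] - bl.f_before) / bl.f0
    i_min = int(np.argmin(ratio))
    val = float(ratio[i_min])
    return BurstMetrics(
        cell_id=trace.cell_id,
        channel=trace.channel,
        dfmin=val,
        minus_dfmin=-val,
        t_peak_s=float(trace.time_s[mask][i_min]),
    )


def normalize_by_store(dfmax_value: float, resting_store_rel: float) -> float:
    """Burst magnitude normalised by the line's relative resting ER Ca2+."""
    if resting_store_rel <= 0:
        raise ValueError("resting_store_rel must be positive")
    return dfmax_value / resting_store_rel


def correlate_er_cytosol(group_means_dfmin, group_means_dfmax):
    """Pearson correlation of ER-depletion vs cytosolic-burst group means.

    Returns (r, two-sided p).  Used across cell lines to test whether
    larger cytosolic bursts accompany deeper store depletion.
    """
    a = np.asarray(group_means_dfmin, dtype=float)
    b = np.asarray(group_means_dfmax, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D lists")
    if a.size < 3:
        raise ValueError("need at least 3 paired group means")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
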