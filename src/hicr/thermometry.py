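"""Luminescence thermometry: Eu-TTA quench ratios to deltaT.

The thermometer dye's intensity drops linearly with temperature at a
calibrated slope (fractional change per degC, negative).  The analysis
chain is: photobleach correction (single-exponential fit to the
pre-stimulus segment), quench ratio
``dF/F0 = (F_heating - I_laser)/(F_before - I_back) - 1``, and
conversion ``deltaT = ratio / slope(T0)``.  A sheet of measurements at
several distances yields a monotone radial profile from which each
cell's deltaT is assigned by interpolation in log-distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.isotonic import IsotonicRegression

from .datatypes import (
    BackgroundEstimates,
    CalibrationCurve,
    FluorescenceTrace,
    HeatPulseProtocol,
    TemperatureProfile,
)

log = logging.getLogger(__name__)

__all__ = [
    "BleachFit",
    "correct_photobleaching",
    "quench_ratio",
    "to_delta_T",
    "estimate_backgrounds",
    "profile_from_sheet",
]


@dataclass
class BleachFit:
    """Result of the single-exponential photobleach fit."""

    rate_per_s: float
    amplitude: float
    corrected: bool  # False when the fitted rate was <= 0 (no correction)


def correct_photobleaching(
    trace: FluorescenceTrace,
    fit_window: tuple[float, float],
) -> tuple[FluorescenceTrace, BleachFit]:
    """Divide out a single-exponential bleach fitted on ``fit_window``.

    The model ``F(t) = A exp(-k t)`` is fitted by least squares on the
    window (log-linear solution polished by nonlinear least squares);
    the trace is divided by ``exp(-k t)``, which has unit value at
    t = 0.  If the fitted rate is non-positive the trace is returned
    unchanged with ``corrected=False``.
    """
    t_lo, t_hi = fit_window
    mask = trace.window_mask(t_lo, t_hi)
    if mask.sum() < 5:
        raise ValueError(
            f"bleach-fit window [{t_lo:g}, {t_hi:g}] s holds {int(mask.sum())} frames; need >= 5")
    tw = trace.time_s[mask]
    yw = trace.intensity[mask]
    if not np.all(np.isfinite(yw)):
        raise ValueError("non-finite intensities in the bleach-fit window")
    if np.any(yw <= 0):
        raise ValueError("bleach fit requires positive intensities in the window")

    # log-linear least squares gives the exact answer on noise-free
    # exponentials and a good start otherwise
    b, log_a = np.polyfit(tw, np.log(yw), 1)
    k0, a0 = -b, float(np.exp(log_a))
    try:
        with warnings.catch_warnings():
            # perfect (noise-free) fits make the covariance singular
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(lambda t, a, k: a * np.exp(-k * t), tw, yw,
                                p0=(a0, k0), maxfev=2000)
        a_fit, k_fit = float(popt[0]), float(popt[1])
    except RuntimeError:  # pragma: no cover - pathological windows
        a_fit, k_fit = a0, k0

    if k_fit <= 0:
        return trace.with_intensity(trace.intensity), BleachFit(k_fit, a_fit, False)
    corrected = trace.intensity / np.exp(-k_fit * trace.time_s)
    return trace.with_intensity(corrected), BleachFit(k_fit, a_fit, True)


def _f_heating(trace: FluorescenceTrace, protocol: HeatPulseProtocol) -> float:
    """Intensity at the end of the heating period.

    Mean of the final two laser-on frames (robust to single-frame
    noise); falls back to the last one if only one frame was acquired
    during the pulse.
    """
    idx = np.flatnonzero(trace.laser_on)
    if idx.size == 0:
        # laser flags absent: use timestamps
        mask = trace.window_mask(protocol.t_start, protocol.t_end - trace.frame_interval)
        idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"trace {trace.cell_id!r} has no laser-on frames")
    take = idx[-2:] if idx.size >= 2 else idx[-1:]
    return float(trace.intensity[take].mean())


def quench_ratio(
    trace: FluorescenceTrace,
    protocol: HeatPulseProtocol,
    bg: BackgroundEstimates,
) -> float:
    """Relative quench dF/F0 = (F_heating - I_laser)/(F_before - I_back) - 1.

    F_before is the frame at (or immediately before) the pulse onset;
    F_heating the intensity just before the laser is shut off.
    """
    i_before = trace.baseline_index(protocol.t_start)
    f_before = float(trace.intensity[i_before])
    denom = f_before - bg.i_back
    if denom <= 0:
        raise ValueError(
            f"dead baseline in {trace.cell_id!r}: F_before - I_back = {denom:g} <= 0")
    f_heat = _f_heating(trace, protocol)
    return (f_heat - bg.i_laser) / denom - 1.0


def to_delta_T(ratio: float, t0_c: float, cal: CalibrationCurve) -> float:
    """Convert a quench ratio to a temperature rise via the slope at T0."""
    return ratio / cal.slope(t0_c)


def estimate_backgrounds(
    bg_trace: FluorescenceTrace,
    i_back: float,
) -> BackgroundEstimates:
    """Backgrounds from a cell-free ROI: I_laser = mean over laser-on frames."""
    on = bg_trace.laser_on
    if not on.any():
        return BackgroundEstimates(i_back=i_back, i_laser=i_back)
    return BackgroundEstimates(i_back=i_back,
                               i_laser=float(bg_trace.intensity[on].mean()))


def profile_from_sheet(
    sheet_traces: list[FluorescenceTrace],
    protocol: HeatPulseProtocol,
    bg: BackgroundEstimates,
    cal: CalibrationCurve | None = None,
    *,
    bleach_correct: bool = True,
) -> TemperatureProfile:
    """Radial deltaT profile from thermometer traces at several distances.

    Per distance: subtract the backgrounds, bleach-correct the dye
    signal on the pre-stimulus segment, form the quench ratio and
    convert to deltaT.  Duplicated distances are averaged; the profile
    is regularised to be non-increasing in distance (isotonic fit).
    """
    cal = cal or CalibrationCurve()
    if len({round(tr.distance_um, 9) for tr in sheet_traces}) < 3:
        raise ValueError("need >= 3 distinct distances for a radial profile")

    dists = []
    dts = []
    for tr in sheet_traces:
        dye = tr.intensity - bg.i_back - bg.scatter * tr.laser_on
        dye_tr = tr.with_intensity(dye)
        if bleach_correct:
            dye_tr, _ = correct_photobleaching(dye_tr, (0.0, protocol.t_start))
        # re-add the backgrounds so the exposed quench formula applies as printed
        full = dye_tr.with_intensity(
            dye_tr.intensity + bg.i_back + bg.scatter * tr.laser_on)
        ratio = quench_ratio(full, protocol, bg)
        dts.append(to_delta_T(ratio, protocol.t0_c, cal))
        dists.append(tr.distance_um)

    dists = np.asarray(dists)
    dts = np.asarray(dts)
    order = np.argsort(dists)
    r_sorted, dt_sorted = dists[order], dts[order]
    # average duplicated distances
    r_uniq, inv = np.unique(np.round(r_sorted, 9), return_inverse=True)
    dt_uniq = np.bincount(inv, weights=dt_sorted) / np.bincount(inv)

    if np.allclose(dt_uniq, 0.0):
        warnings.warn("all-zero deltaT profile (no detectable heating)")
        dt_mono = np.zeros_like(dt_uniq)
    else:
        iso = IsotonicRegression(increasing=False)
        dt_mono = iso.fit_transform(r_uniq, dt_uniq)
    dt_mono = np.clip(dt_mono, 0.0, None)
    log.info("thermometry profile: %d distances, deltaT %.3g..%.3g degC",
             r_uniq.size, dt_mono.min(), dt_mono.max())
    return TemperatureProfile(r_uniq, np.array([protocol.t_end]),
                              dt_mono[:, None])
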