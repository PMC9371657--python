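"""Core data containers for the heat-pulse Ca2+ imaging analysis.

Units throughout the package: time in seconds from the start of the
observation, distances in micrometres, temperatures in degrees Celsius
(``deltaT`` is always a rise above the base temperature T0, never an
absolute temperature), intensities in arbitrary camera units (a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "HeatPulseProtocol",
    "CalibrationCurve",
    "BackgroundEstimates",
    "TemperatureProfile",
    "BaselineStats",
    "BurstMetrics",
    "FluctuationModel",
    "ResponseCurve",
]


@dataclass
class HeatPulseProtocol:
    """Timing and conditions of a single IR-laser heat pulse.

    Parameters
    ----------
    t_start : float
        Pulse onset, seconds after the start of the observation.  The
        frame at (or immediately before) ``t_start`` defines F_before.
    duration : float
        Pulse length in seconds.
    laser_power_mw : float
        IR laser power in mW (drives the amplitude of the local heating).
    t0_c : float
        Base (incubator) temperature in degrees C.
    observation_start : float
        Time origin of the recording (kept at 0 by convention).
    """

    t_start: float = 10.0
    duration: float = 2.0
    laser_power_mw: float = 25.6
    t0_c: float = 36.0
    observation_start: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.t_start < 0:
            raise ValueError("t_start must be non-negative")

    @property
    def t_end(self) -> float:
        """Time at which the laser is shut off."""
        return self.t_start + self.duration


@dataclass
class FluorescenceTrace:
    """One cell's (or ROI's) intensity time series.

    ``laser_on`` flags the frames acquired while the IR laser was on;
    ``distance_um`` is the distance from the ROI centre to the heat
    source (NaN for unheated control cells).
    """

    cell_id: str
    channel: str
    time_s: np.ndarray
    intensity: np.ndarray
    distance_um: float = float("nan")
    laser_on: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.intensity.shape:
            raise ValueError("time_s and intensity must be 1-D arrays of equal length")
        if self.time_s.size == 0:
            raise ValueError(f"trace {self.cell_id!r} is empty")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError(f"trace {self.cell_id!r}: time must be strictly increasing")
        if self.laser_on is None:
            self.laser_on = np.zeros(self.time_s.size, dtype=bool)
        else:
            self.laser_on = np.asarray(self.laser_on, dtype=bool)
            if self.laser_on.shape != self.time_s.shape:
                raise ValueError("laser_on must match the time axis")

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def with_intensity(self, intensity: np.ndarray) -> "FluorescenceTrace":
        """Copy of the trace with a replaced intensity vector."""
        return FluorescenceTrace(
            cell_id=self.cell_id,
            channel=self.channel,
            time_s=self.time_s.copy(),
            intensity=np.asarray(intensity, dtype=float),
            distance_um=self.distance_um,
            laser_on=self.laser_on.copy(),
        )

    def index_at_or_before(self, t: float) -> int:
        """Index of the frame at ``t`` (within half a frame) or just before."""
        tol = 0.5 * self.frame_interval
        idx = np.searchsorted(self.time_s, t + tol) - 1
        if idx < 0:
            raise ValueError(
                f"trace {self.cell_id!r} starts at {self.time_s[0]:g} s, after t={t:g} s"
            )
        return int(idx)

    def baseline_index(self, t: float) -> int:
        """Frame index defining F_before: at/just before ``t``, pre-laser.

        The designated frame is the one at (or immediately before) the
        pulse onset; if that frame was already acquired with the laser
        on, the last preceding laser-off frame is used instead, so the
        baseline reads the intensity just before heating was initiated.
        """
        idx = self.index_at_or_before(t)
        while idx > 0 and self.laser_on[idx]:
            idx -= 1
        if self.laser_on[idx]:
            raise ValueError(f"trace {self.cell_id!r} has no pre-laser baseline frame")
        return idx

    def window_mask(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Boolean mask for frames in the closed window [t_lo, t_hi].

        Frame timestamps are compared with half-frame tolerance so that
        a window boundary falling on a frame always includes it.
        """
        tol = 0.5 * self.frame_interval
        return (self.time_s >= t_lo - tol) & (self.time_s <= t_hi + tol)


# Published thermal-quenching slopes of the Eu-TTA thermometer sheet:
# fractional intensity change per degree C at the two supported base
# temperatures.
EU_TTA_SLOPES: Mapping[float, float] = {24.0: -0.027, 36.0: -0.041}


@dataclass
class CalibrationCurve:
    """Eu-TTA thermal-quenching calibration: slope (1/degC) per base T0.

    Slopes are fractional intensity changes per degree of heating and
    are negative (the dye is quenched as temperature rises).  Lookup of
    an unsupported base temperature fails loudly; no extrapolation is
    performed.  User-supplied slopes may be passed for other base
    temperatures (e.g. 23 degC muscle experiments mapped to the 24 degC
    slope by the caller).
    """

    slopes: Mapping[float, float] = field(default_factory=lambda: dict(EU_TTA_SLOPES))

    def __post_init__(self) -> None:
        self.slopes = {float(k): float(v) for k, v in self.slopes.items()}
        if not self.slopes:
            raise ValueError("calibration requires at least one slope")
        for t0, s in self.slopes.items():
            if s >= 0:
                raise ValueError(f"quenching slope at T0={t0:g} must be negative, got {s:g}")

    def slope(self, t0_c: float) -> float:
        try:
            return self.slopes[float(t0_c)]
        except KeyError:
            supported = ", ".join(f"{t:g}" for t in sorted(self.slopes))
            raise KeyError(
                f"no calibration slope for T0={t0_c:g} degC; supported: {supported} degC"
            ) from None


@dataclass
class BackgroundEstimates:
    """Background intensity levels used by the dF/F0 formulas.

    ``i_back`` is the excitation-off (dark) background, present in every
    frame.  ``i_laser`` is the *total* background during laser-on frames
    (dark level plus IR-scatter), i.e. what a cell-free ROI reads while
    the heating laser is on.  With this convention the quench-ratio
    formula (F_heating - I_laser)/(F_before - I_back) - 1 isolates the
    dye signal exactly.
    """

    i_back: float = 0.0
    i_laser: float = 0.0

    def __post_init__(self) -> None:
        if self.i_back < 0 or self.i_laser < 0:
            raise ValueError("background intensities must be non-negative")

    @property
    def scatter(self) -> float:
        """IR-scatter excess above the dark background during laser-on."""
        return self.i_laser - self.i_back


@dataclass
class TemperatureProfile:
    """Temperature rise deltaT(r, t) on a grid of distances and times.

    ``delta_t`` has shape (n_distances, n_times).  A measured profile
    from a thermometer sheet typically has a single time column (the
    end-of-pulse plateau).  Per-cell assignment interpolates the plateau
    in log-distance.
    """

    distances_um: np.ndarray
    times_s: np.ndarray
    delta_t: np.ndarray

    def __post_init__(self) -> None:
        self.distances_um = np.atleast_1d(np.asarray(self.distances_um, dtype=float))
        self.times_s = np.atleast_1d(np.asarray(self.times_s, dtype=float))
        self.delta_t = np.atleast_2d(np.asarray(self.delta_t, dtype=float))
        if self.delta_t.shape != (self.distances_um.size, self.times_s.size):
            raise ValueError("delta_t must have shape (n_distances, n_times)")
        if np.any(self.distances_um <= 0):
            raise ValueError("distances must be positive")
        if not np.all(np.isfinite(self.delta_t)):
            raise ValueError("deltaT must be finite")
        if np.any(self.delta_t < -0.5):
            raise ValueError("deltaT below -0.5 degC: not a heating profile")

    def plateau(self, protocol: HeatPulseProtocol | None = None) -> np.ndarray:
        """Per-distance deltaT at the end of the pulse (last time <= t_end)."""
        if self.times_s.size == 1:
            return self.delta_t[:, 0]
        if protocol is None:
            return self.delta_t.max(axis=1)
        idx = int(np.searchsorted(self.times_s, protocol.t_end, side="right") - 1)
        idx = max(idx, 0)
        return self.delta_t[:, idx]

    def assign(self, distances_um, protocol: HeatPulseProtocol | None = None) -> np.ndarray:
        """deltaT at arbitrary distances by linear interpolation in log r.

        Distances outside the measured range are clamped to the nearest
        measured value.
        """
        r = np.atleast_1d(np.asarray(distances_um, dtype=float))
        if np.any(r <= 0):
            raise ValueError("distances must be positive")
        plateau = self.plateau(protocol)
        order = np.argsort(self.distances_um)
        return np.interp(
            np.log(r), np.log(self.distances_um[order]), plateau[order]
        )


@dataclass
class BaselineStats:
    """Pre-stimulus baseline: F_before and F0 = F_before - I_back."""

    f_before: float
    f0: float

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("dead baseline: F_before - I_back must be positive")


@dataclass
class BurstMetrics:
    """Per-cell burst statistics.

    ``dfmax`` is the maximum dF/F0 in the post-onset analysis window
    (cytosolic channels); ``dfmin`` the minimum dF/F0 in the ER-channel
    window, with ``minus_dfmin = -dfmin`` the depletion magnitude.
    """

    cell_id: str
    channel: str
    dfmax: float = float("nan")
    t_peak_s: float = float("nan")
    dfmin: float = float("nan")
    minus_dfmin: float = float("nan")
    responder: bool | None = None
    store_normalized_dfmax: float = float("nan")


@dataclass
class FluctuationModel:
    """Gaussian fitted to spontaneous dF_max/F0 fluctuations.

    ``df_th = mu + 1.96 sigma`` is the responder threshold: a heat-pulse
    dF_max/F0 strictly above it is called a significant response.
    """

    mu: float
    sigma: float
    n_cells: int
    fit_rss: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def df_th(self) -> float:
        return self.mu + 1.96 * self.sigma


@dataclass
class ResponseCurve:
    """Binned dose-response data and the fitted 50% threshold.

    ``bins`` is a DataFrame with columns deltaT_mid, n, k, p.  ``dtth``
    is the deltaT at which the fitted response probability crosses 50%;
    ``method`` records whether it came from the logistic MLE or from the
    isotonic-interpolation fallback.
    """

    bins: "object"  # pandas.DataFrame
    dtth: float = float("nan")
    logistic_width: float = float("nan")
    spont_floor: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    method: str = "none"
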