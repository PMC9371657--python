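"""Ground-truthed synthetic microheating experiments.

This module emulates the optical heat-pulse experiment end to end: a
radially decaying temperature field with sub-100-ms rise, Eu-TTA
thermometer traces quenched at the published slopes, cytosolic Ca2+
indicator traces (fluo-4 / Cal-520) with Bernoulli bursts whose
probability is logistic in deltaT around a line-specific threshold, a
SERCA-uptake dip during heating, ER-store (G-CEPIA1er) traces with a
post-pulse depletion minimum ~5 s after the laser is shut off,
photobleaching, laser-scatter background, and shot noise.

The generated datasets carry their ground truth (per-cell deltaT, burst
occurrence and amplitude) so that the analysis pipeline can be validated
by parameter recovery.

Temperature field
-----------------
The field is separable, ``deltaT(r, t) = A(r) g(t)`` with an
inverse-distance amplitude ``A(r) = a P / (r + r0)`` (``P`` laser power
in mW, ``r0`` a softening radius) and first-order rise/fall kinetics
``g(t)`` gated by the pulse.  Defaults are calibrated so that 25.6 mW
produces a 10 degC rise at r = 10 um, matching the measured gradients.

Randomness
----------
Every cell draws from its own counter-derived substream
(``default_rng([seed, cell_index])``), so datasets are bit-reproducible
and enlarging ``n_cells`` never reshuffles earlier cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CalibrationCurve,
    FluorescenceTrace,
    HeatPulseProtocol,
    TemperatureProfile,
)

__all__ = [
    "FieldModel",
    "MutantParams",
    "SimConfig",
    "CohortData",
    "MUTANT_PRESETS",
    "mutant_preset",
    "burst_probability",
    "simulate_temperature_field",
    "simulate_eutta_trace",
    "simulate_cell_trace",
    "simulate_sheet",
    "simulate_cohort",
    "render_image_stack",
]

CYTOSOLIC_CHANNELS = ("fluo4", "cal520")
ER_CHANNEL = "cepia"
EUTTA_CHANNEL = "eutta"

# G-CEPIA1er thermal quench during the pulse (fractional per degC) and
# the kinetics of the post-pulse store-depletion dip.
CEPIA_QUENCH_PER_C = -0.02
ER_DIP_DELAY_S = 5.0       # minimum ~5 s after pulse cessation
ER_DIP_WIDTH_S = 1.5
ER_DIP_COEFF = 0.10        # depth = coeff * burst amplitude / resting store

# Spontaneous activity (small non-thermal Ca2+ fluctuations): every
# cytosolic cell shows recurring mini-transients -- one per block, with
# a per-cell amplitude -- so the across-cell distribution of spontaneous
# dF_max/F0 is approximately Gaussian, the shape the fluctuation
# threshold procedure assumes.  Rare extra events come from the line's
# Poisson rate.
# amplitude well above the frame-noise floor so the across-cell
# distribution is not left-censored by noise maxima
SPONT_AMP_MEAN = 0.08
SPONT_AMP_SD = 0.025
SPONT_RISE_S = 0.4
SPONT_DECAY_S = 1.0
SPONT_BLOCK_S = 15.0

# Burst decay time constant (s); bursts decline over several seconds.
BURST_DECAY_S = 4.0

# Resting cytosolic Ca2+ (nM) used by the optional indicator-Kd
# saturation factor.
RESTING_CA_NM = 65.0


@dataclass
class FieldModel:
    """Radial heating field deltaT(r, t) = A(r) g(t).

    ``A(r) = amp_coeff * P / (r + r0)``; ``g`` is a first-order
    rise/fall gated by the pulse, with rise constant bounded by the
    observed <100 ms onset.
    """

    amp_coeff: float = 7.8125  # degC*um/mW; 25.6 mW -> 10 degC at r=10 um
    r0_um: float = 10.0
    tau_rise_s: float = 0.05
    tau_fall_s: float = 0.05

    def __post_init__(self) -> None:
        if self.tau_rise_s > 0.1:
            raise ValueError("tau_rise_s must be <= 0.1 s (sub-100-ms onset)")
        if self.amp_coeff < 0 or self.r0_um <= 0:
            raise ValueError("amp_coeff must be >= 0 and r0_um > 0")

    def amplitude(self, power_mw: float, r_um) -> np.ndarray:
        r = np.asarray(r_um, dtype=float)
        return self.amp_coeff * power_mw / (r + self.r0_um)

    def distance_for(self, power_mw: float, delta_t_c) -> np.ndarray:
        """Invert A(r): distance producing a given plateau deltaT."""
        dt = np.asarray(delta_t_c, dtype=float)
        if np.any(dt <= 0):
            raise ValueError("plateau deltaT must be positive to invert")
        return self.amp_coeff * power_mw / dt - self.r0_um

    def gate(self, times_s, protocol: HeatPulseProtocol) -> np.ndarray:
        """First-order rise during the pulse, first-order decay after."""
        t = np.asarray(times_s, dtype=float)
        g = np.zeros_like(t)
        on = (t >= protocol.t_start) & (t < protocol.t_end)
        g[on] = 1.0 - np.exp(-(t[on] - protocol.t_start) / self.tau_rise_s)
        after = t >= protocol.t_end
        g_end = 1.0 - np.exp(-protocol.duration / self.tau_rise_s)
        g[after] = g_end * np.exp(-(t[after] - protocol.t_end) / self.tau_fall_s)
        return g


@dataclass
class MutantParams:
    """Generative phenotype of one cell line.

    ``dtth_true_c`` is the deltaT at which half the cells fire a burst
    (the generative 50% point); ``resp_slope_c`` the width of the
    logistic dose-response; ``burst_latency_mode`` distinguishes lines
    that fire during heating from those that fire after recooling
    starts; ``serca_dip_frac`` the fractional intensity drop during the
    pulse from heat-accelerated store re-uptake; ``resting_store_rel``
    the resting ER Ca2+ level relative to wild type.
    """

    name: str
    dtth_true_c: float
    resp_slope_c: float = 1.0
    burst_amp_mean: float = 2.0
    burst_amp_sd: float = 0.5
    burst_latency_mode: str = "post_recooling"  # or "during_heating"
    burst_rise_s: float = 0.4
    serca_dip_frac: float = 0.05
    resting_store_rel: float = 1.0
    spont_rate_per_s: float = 0.002

    def __post_init__(self) -> None:
        if self.dtth_true_c <= 0 or self.resp_slope_c <= 0:
            raise ValueError("dtth_true_c and resp_slope_c must be positive")
        if not (0 <= self.serca_dip_frac < 1):
            raise ValueError("serca_dip_frac must be in [0, 1)")
        if self.resting_store_rel <= 0:
            raise ValueError("resting_store_rel must be positive")
        if self.burst_amp_mean < 0:
            raise ValueError("burst_amp_mean must be non-negative")
        if self.burst_latency_mode not in ("during_heating", "post_recooling"):
            raise ValueError(f"unknown burst_latency_mode {self.burst_latency_mode!r}")


def _presets() -> dict:
    # 50% points are the published per-line thresholds at each base
    # temperature; burst amplitudes and store levels are chosen so that
    # leakier lines have more depleted stores and smaller bursts, and
    # the relative ER-depletion depth (amp/store) preserves a positive
    # across-line correlation with burst size.
    p = {}
    p[("WT", 36.0)] = MutantParams(
        "WT", 5.8, burst_amp_mean=2.5, burst_latency_mode="post_recooling",
        serca_dip_frac=0.05, resting_store_rel=1.0)
    p[("Q156K", 36.0)] = MutantParams(
        "Q156K", 4.9, burst_amp_mean=2.2, burst_latency_mode="during_heating",
        serca_dip_frac=0.10, resting_store_rel=0.95)
    p[("R164C", 36.0)] = MutantParams(
        "R164C", 1.4, burst_amp_mean=1.6, burst_latency_mode="during_heating",
        serca_dip_frac=0.02, resting_store_rel=0.80)
    p[("R164L", 36.0)] = MutantParams(
        "R164L", 1.4, burst_amp_mean=1.6, burst_latency_mode="during_heating",
        serca_dip_frac=0.02, resting_store_rel=0.80)
    p[("Y523S", 36.0)] = MutantParams(
        "Y523S", 4.3, burst_amp_mean=1.2, burst_latency_mode="post_recooling",
        serca_dip_frac=0.10, resting_store_rel=0.65)
    p[("WT", 24.0)] = replace(p[("WT", 36.0)], dtth_true_c=11.5)
    p[("Q156K", 24.0)] = replace(p[("Q156K", 36.0)], dtth_true_c=7.9,
                                 burst_latency_mode="post_recooling")
    p[("R164C", 24.0)] = replace(p[("R164C", 36.0)], dtth_true_c=1.8)
    p[("R164L", 24.0)] = replace(p[("R164L", 36.0)], dtth_true_c=1.4)
    p[("Y523S", 24.0)] = replace(p[("Y523S", 36.0)], dtth_true_c=3.8)
    # Store depleted pharmacologically; essentially no release left.
    p[("WT+thapsigargin", 36.0)] = MutantParams(
        "WT+thapsigargin", 5.8, burst_amp_mean=0.05, burst_amp_sd=0.02,
        resting_store_rel=0.10, serca_dip_frac=0.0)
    return p


MUTANT_PRESETS = _presets()


def mutant_preset(name: str, t0_c: float = 36.0) -> MutantParams:
    """Look up the generative parameters of a cell line at a base T0."""
    try:
        return replace(MUTANT_PRESETS[(name, float(t0_c))])
    except KeyError:
        known = sorted({f"{n}@{t:g}" for n, t in MUTANT_PRESETS})
        raise KeyError(f"no preset {name!r} at T0={t0_c:g}; known: {known}") from None


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    ``distances_um`` fixes per-cell distances explicitly; alternatively
    ``deltaT_range_c`` draws each heated cell's plateau deltaT uniformly
    and places the cell at the distance producing it under the field
    model.  ``n_unheated`` control cells (no laser) are generated for
    fluctuation modelling, plus one cell-free background ROI.
    """

    seed: int = 0
    n_cells: int = 300
    n_unheated: int = 100
    distances_um: Sequence[float] | None = None
    deltaT_range_c: tuple[float, float] | None = (0.0, 15.0)
    frame_interval_s: float = 0.2
    total_duration_s: float = 35.0
    protocol: HeatPulseProtocol = field(default_factory=HeatPulseProtocol)
    mutant: MutantParams = field(default_factory=lambda: mutant_preset("WT", 36.0))
    channel: str = "fluo4"
    field_model: FieldModel = field(default_factory=FieldModel)
    noise_sd: float = 1.0
    bleach_rate_per_s: float = 0.001
    i_back: float = 10.0
    i_laser_peak: float = 3.0
    f_baseline_mean: float = 100.0
    f_baseline_sd: float = 10.0
    indicator_kd_22c_nm: float = 520.0
    indicator_kd_37c_nm: float = 190.0
    use_kd_modulation: bool = False
    sheet_n_distances: int = 40
    # a thermometer-sheet ROI averages this many pixels, so its shot
    # noise is reduced by sqrt(n) relative to a single pixel
    sheet_roi_npix: int = 16

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.total_duration_s <= self.protocol.t_start + 20.0:
            raise ValueError("total_duration_s must exceed pulse onset + 20 s")
        for name in ("noise_sd", "i_back", "i_laser_peak", "f_baseline_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.indicator_kd_22c_nm <= 0 or self.indicator_kd_37c_nm <= 0:
            raise ValueError("indicator Kd values must be positive")

    def times(self) -> np.ndarray:
        n = int(round(self.total_duration_s / self.frame_interval_s))
        return np.arange(n) * self.frame_interval_s

    def laser_mask(self, times: np.ndarray) -> np.ndarray:
        p = self.protocol
        return (times >= p.t_start) & (times < p.t_end)


@dataclass
class CohortData:
    """A simulated experiment: traces plus ROI and ground-truth tables."""

    traces: list
    rois: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def traces_frame(self) -> pd.DataFrame:
        """Long-format trace table (cell_id, channel, time_s, ...)."""
        parts = []
        for tr in self.traces:
            parts.append(pd.DataFrame({
                "cell_id": tr.cell_id,
                "channel": tr.channel,
                "time_s": tr.time_s,
                "intensity_au": tr.intensity,
                "distance_um": tr.distance_um,
                "laser_on": tr.laser_on.astype(int),
            }))
        return pd.concat(parts, ignore_index=True)


def burst_probability(delta_t_c, mutant: MutantParams) -> np.ndarray:
    """Probability of a heat-induced burst: logistic in deltaT.

    p = 1 / (1 + exp(-(deltaT - dtth_true) / resp_slope)); the 50% point
    sits at the line's generative threshold.
    """
    z = (np.asarray(delta_t_c, dtype=float) - mutant.dtth_true_c) / mutant.resp_slope_c
    return 1.0 / (1.0 + np.exp(-z))


def _kd_nm(t_c: float, cfg: SimConfig) -> float:
    # linear interpolation between the published 22 and 37 degC values
    frac = (t_c - 22.0) / 15.0
    return cfg.indicator_kd_22c_nm + frac * (cfg.indicator_kd_37c_nm - cfg.indicator_kd_22c_nm)


def _shot_noise(rng: np.random.Generator, clean: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Gaussian approximation of shot noise, sd scaling as sqrt(signal)."""
    if cfg.noise_sd == 0:
        return np.zeros_like(clean)
    rel = np.sqrt(np.clip(clean, 0.0, None) / cfg.f_baseline_mean)
    return rng.normal(0.0, 1.0, clean.size) * cfg.noise_sd * rel


def simulate_temperature_field(
    fieldm: FieldModel,
    power_mw: float,
    distances_um,
    times_s,
    protocol: HeatPulseProtocol,
) -> TemperatureProfile:
    """Evaluate the separable field deltaT(r, t) = A(r) g(t) on a grid."""
    if power_mw < 0:
        raise ValueError("laser power must be non-negative")
    r = np.atleast_1d(np.asarray(distances_um, dtype=float))
    t = np.atleast_1d(np.asarray(times_s, dtype=float))
    if r.size == 0 or t.size == 0:
        raise ValueError("distance and time grids must be non-empty")
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    amp = fieldm.amplitude(power_mw, r)
    gate = fieldm.gate(t, protocol)
    return TemperatureProfile(r, t, np.outer(amp, gate))


def _bleach(times: np.ndarray, rate: float) -> np.ndarray:
    return np.exp(-rate * times) if rate > 0 else np.ones_like(times)


def simulate_eutta_trace(
    profile: TemperatureProfile,
    r_um: float,
    cal: CalibrationCurve,
    cfg: SimConfig,
    *,
    cell_id: str = "sheet",
    rng: np.random.Generator | None = None,
) -> FluorescenceTrace:
    """Thermometer-sheet trace at one distance.

    intensity(t) = f_baseline (1 + slope * deltaT(r, t)) bleach(t)
                   + i_back + scatter(t) + noise
    """
    slope = cal.slope(cfg.protocol.t0_c)  # raises for unsupported T0
    rng = rng or np.random.default_rng([cfg.seed, 10_000])
    times = profile.times_s
    i_row = int(np.argmin(np.abs(profile.distances_um - r_um)))
    if not np.isclose(profile.distances_um[i_row], r_um):
        raise ValueError(f"distance {r_um:g} um not on the profile grid")
    delta_t = profile.delta_t[i_row]
    laser = cfg.laser_mask(times)
    dye = cfg.f_baseline_mean * (1.0 + slope * delta_t) * _bleach(times, cfg.bleach_rate_per_s)
    clean = dye + cfg.i_back + cfg.i_laser_peak * laser
    noise = _shot_noise(rng, clean, cfg) / np.sqrt(max(cfg.sheet_roi_npix, 1))
    return FluorescenceTrace(cell_id, EUTTA_CHANNEL, times, clean + noise, r_um, laser)


def _transient(times: np.ndarray, t_on_target: float, rise_s: float,
               decay_s: float, dt: float) -> np.ndarray:
    """Unit-peak transient: linear ramp to 1, then exponential decay.

    The peak is snapped to the frame grid so that a noise-free burst of
    amplitude ``a`` yields dF_max/F0 exactly ``a``.
    """
    i_on = int(np.searchsorted(times, t_on_target - 1e-9))
    if i_on >= times.size:
        return np.zeros_like(times)
    t_on = times[i_on]
    n_rise = max(1, int(np.ceil(rise_s / dt)))
    i_pk = min(i_on + n_rise, times.size - 1)
    t_pk = times[i_pk]
    s = np.zeros_like(times)
    ramp = slice(i_on, i_pk + 1)
    if t_pk > t_on:
        s[ramp] = (times[ramp] - t_on) / (t_pk - t_on)
    else:
        s[i_pk] = 1.0
    after = times > t_pk
    s[after] = np.exp(-(times[after] - t_pk) / decay_s)
    return s


def simulate_cell_trace(
    delta_t_at_cell: float,
    mutant: MutantParams,
    cfg: SimConfig,
    channel: str,
    seed: int,
    *,
    distance_um: float = float("nan"),
    heated: bool = True,
) -> tuple[FluorescenceTrace, dict]:
    """One cell's indicator trace plus its ground-truth record.

    Cytosolic channels (fluo4/cal520): a burst occurs with probability
    logistic((deltaT - dtth_true)/resp_slope); its amplitude is a
    truncated normal, its onset set by the line's latency mode, and a
    multiplicative SERCA dip applies during the pulse.  The ER channel
    (cepia) shows thermal quench during the pulse and a store-depletion
    dip with minimum ~5 s after pulse cessation, depth proportional to
    the burst amplitude and inversely to the resting store level.
    """
    if channel not in CYTOSOLIC_CHANNELS + (ER_CHANNEL,):
        raise ValueError(f"unknown channel {channel!r}")
    if delta_t_at_cell < 0:
        raise ValueError("deltaT at the cell must be non-negative")
    rng = np.random.default_rng([cfg.seed, seed])
    times = cfg.times()
    dt = cfg.frame_interval_s
    p = cfg.protocol
    laser = cfg.laser_mask(times) if heated else np.zeros(times.size, dtype=bool)

    f_b = max(rng.normal(cfg.f_baseline_mean, cfg.f_baseline_sd), 1.0)

    burst = False
    amp = 0.0
    if heated:
        burst = bool(rng.random() < burst_probability(delta_t_at_cell, mutant))
        if burst:
            amp = max(rng.normal(mutant.burst_amp_mean, mutant.burst_amp_sd), 0.0)

    rel = np.zeros_like(times)  # relative dye modulation, 0 = resting
    if channel in CYTOSOLIC_CHANNELS:
        if burst and amp > 0:
            if mutant.burst_latency_mode == "during_heating":
                t_on = p.t_start + 0.3
            else:
                t_on = p.t_end + 0.3
            rel += amp * _transient(times, t_on, mutant.burst_rise_s, BURST_DECAY_S, dt)
        # spontaneous activity (also in unheated controls): one
        # mini-transient per block with a per-cell amplitude; events are
        # kept >= 3 s apart so their tails do not stack.  A zero rate
        # disables spontaneous activity altogether.
        if mutant.spont_rate_per_s > 0:
            a_cell = abs(rng.normal(SPONT_AMP_MEAN, SPONT_AMP_SD))
            n_blocks = int(np.ceil(cfg.total_duration_s / SPONT_BLOCK_S))
            for k in range(n_blocks):
                t_sp = k * SPONT_BLOCK_S + rng.uniform(0.0, SPONT_BLOCK_S - 3.0)
                rel += a_cell * _transient(times, t_sp, SPONT_RISE_S, SPONT_DECAY_S, dt)
            # rare extra events on top
            n_sp = rng.poisson(mutant.spont_rate_per_s * cfg.total_duration_s)
            for _ in range(n_sp):
                t_sp = rng.uniform(0.0, cfg.total_duration_s)
                rel += a_cell * _transient(times, t_sp, SPONT_RISE_S, SPONT_DECAY_S, dt)
        dye = f_b * (1.0 + rel)
        if heated and mutant.serca_dip_frac > 0:
            dye = dye * (1.0 - mutant.serca_dip_frac * laser)
        if cfg.use_kd_modulation and heated:
            kd0 = _kd_nm(p.t0_c, cfg)
            kd_t = _kd_nm(p.t0_c + delta_t_at_cell, cfg)
            sat0 = RESTING_CA_NM / (RESTING_CA_NM + kd0)
            sat_t = RESTING_CA_NM / (RESTING_CA_NM + kd_t)
            dye = dye * np.where(laser, sat_t / sat0, 1.0)
    else:  # ER store channel
        if heated:
            rel += CEPIA_QUENCH_PER_C * delta_t_at_cell * laser
            if burst and amp > 0:
                depth = ER_DIP_COEFF * amp / mutant.resting_store_rel
                t_min_target = p.t_end + ER_DIP_DELAY_S
                i_min = int(np.searchsorted(times, t_min_target - 1e-9))
                i_min = min(i_min, times.size - 1)
                rel -= depth * np.exp(-((times - times[i_min]) ** 2)
                                      / (2.0 * ER_DIP_WIDTH_S ** 2))
        dye = f_b * (1.0 + rel)

    dye = np.clip(dye, 0.0, None) * _bleach(times, cfg.bleach_rate_per_s)
    clean = dye + cfg.i_back + cfg.i_laser_peak * laser
    intensity = clean + _shot_noise(rng, clean, cfg)

    trace = FluorescenceTrace(f"cell{seed:04d}", channel, times, intensity,
                              distance_um, laser)
    truth = {
        "cell_id": trace.cell_id,
        "deltaT_true_C": float(delta_t_at_cell) if heated else 0.0,
        "burst": int(burst),
        "amp_true": float(amp),
        "f_baseline": float(f_b),
    }
    return trace, truth


def simulate_sheet(
    cfg: SimConfig,
    distances_um: np.ndarray,
    cal: CalibrationCurve | None = None,
) -> list:
    """Eu-TTA thermometer traces at a set of distances (cell-free dish)."""
    cal = cal or CalibrationCurve()
    times = cfg.times()
    profile = simulate_temperature_field(
        cfg.field_model, cfg.protocol.laser_power_mw, distances_um, times, cfg.protocol)
    traces = []
    for j, r in enumerate(np.asarray(distances_um, dtype=float)):
        rng = np.random.default_rng([cfg.seed, 20_000 + j])
        tr = simulate_eutta_trace(profile, r, cal, cfg,
                                  cell_id=f"sheet{j:03d}", rng=rng)
        traces.append(tr)
    return traces


def _background_roi(cfg: SimConfig, *, cell_id: str = "bg000") -> FluorescenceTrace:
    rng = np.random.default_rng([cfg.seed, 30_000])
    times = cfg.times()
    laser = cfg.laser_mask(times)
    clean = cfg.i_back + cfg.i_laser_peak * laser.astype(float)
    intensity = clean + _shot_noise(rng, clean, cfg)
    return FluorescenceTrace(cell_id, cfg.channel, times, intensity,
                             float("nan"), laser)


def simulate_cohort(cfg: SimConfig) -> CohortData:
    """Generate a full synthetic experiment.

    Heated cells at distances taken from ``cfg.distances_um`` or drawn
    via ``cfg.deltaT_range_c``; unheated control cells for fluctuation
    modelling; one cell-free background ROI; and a thermometer sheet
    covering the cells' distance range.  Fully reproducible from
    ``cfg.seed``.
    """
    if cfg.n_cells <= 0:
        raise ValueError("n_cells must be positive")
    fieldm = cfg.field_model
    power = cfg.protocol.laser_power_mw

    # per-cell distances / ground-truth plateau deltaT
    if cfg.distances_um is not None:
        distances = np.asarray(list(cfg.distances_um), dtype=float)
        if distances.size != cfg.n_cells:
            raise ValueError("distances_um must list one distance per cell")
        if np.any(distances <= 0):
            raise ValueError("distances must be positive")
        delta_ts = fieldm.amplitude(power, distances)
    else:
        lo, hi = cfg.deltaT_range_c
        draws = np.empty(cfg.n_cells)
        for i in range(cfg.n_cells):
            draws[i] = np.random.default_rng([cfg.seed, 40_000 + i]).uniform(lo, hi)
        delta_ts = draws
        distances = fieldm.distance_for(power, np.clip(draws, 0.02, None))

    traces: list = []
    truth_rows = []
    roi_rows = []
    # image-mode geometry: heat source at the frame centre, cells on a
    # spiral of angles; only meaningful for small rendered cohorts
    px_per_um = 1.0
    cx = cy = 128.0

    for i in range(cfg.n_cells):
        tr, rec = simulate_cell_trace(
            float(delta_ts[i]), cfg.mutant, cfg, cfg.channel, seed=i,
            distance_um=float(distances[i]), heated=True)
        tr.cell_id = f"c{i:04d}"
        rec["cell_id"] = tr.cell_id
        rec["group"] = "heated"
        traces.append(tr)
        truth_rows.append(rec)
        ang = 2.0 * np.pi * ((i * 0.618034) % 1.0)
        roi_rows.append({
            "cell_id": tr.cell_id,
            "x_px": cx + distances[i] * px_per_um * np.cos(ang),
            "y_px": cy + distances[i] * px_per_um * np.sin(ang),
            "radius_px": 6.0,
            "distance_um": float(distances[i]),
            "role": "heated",
        })

    for i in range(cfg.n_unheated):
        tr, rec = simulate_cell_trace(
            0.0, cfg.mutant, cfg, cfg.channel, seed=50_000 + i,
            distance_um=float("nan"), heated=False)
        tr.cell_id = f"u{i:04d}"
        rec["cell_id"] = tr.cell_id
        rec["group"] = "unheated"
        traces.append(tr)
        truth_rows.append(rec)
        roi_rows.append({"cell_id": tr.cell_id, "x_px": np.nan, "y_px": np.nan,
                         "radius_px": 6.0, "distance_um": np.nan,
                         "role": "unheated"})

    bg = _background_roi(cfg)
    traces.append(bg)
    roi_rows.append({"cell_id": bg.cell_id, "x_px": 20.0, "y_px": 20.0,
                     "radius_px": 6.0, "distance_um": np.nan,
                     "role": "background"})

    # thermometer sheet spanning the heated cells' distances
    r_lo = max(distances.min() * 0.8, 0.5)
    r_hi = distances.max() * 1.25
    sheet_r = np.geomspace(r_lo, r_hi, cfg.sheet_n_distances)
    for tr in simulate_sheet(cfg, sheet_r):
        traces.append(tr)
        roi_rows.append({"cell_id": tr.cell_id, "x_px": np.nan, "y_px": np.nan,
                         "radius_px": 4.0, "distance_um": tr.distance_um,
                         "role": "sheet"})

    truth = pd.DataFrame(truth_rows)
    rois = pd.DataFrame(roi_rows)
    return CohortData(traces=traces, rois=rois, truth=truth, config=cfg)


def render_image_stack(dataset: CohortData, shape=(256, 256), tiff_path=None,
                       roi_csv_path=None):
    """Render a cohort as a 16-bit multi-page TIFF plus an ROI table.

    Cells are drawn as uniform disks at their stated centres on a
    background of i_back (+ scatter during laser-on frames); per-frame
    pixel means inside each ROI reproduce the trace intensities up to
    uint16 rounding.  Only ROIs with finite in-frame centres are
    rendered.
    """
    from skimage.draw import disk as sk_disk
    import tifffile

    cfg = dataset.config
    times = cfg.times()
    if times.size == 0:
        raise ValueError("cannot render a stack with zero frames")
    laser = cfg.laser_mask(times)
    h, w = shape
    rois = dataset.rois
    by_id = {tr.cell_id: tr for tr in dataset.traces}

    rendered = []
    masks = []
    occupancy = np.zeros(shape, dtype=bool)
    for _, row in rois.iterrows():
        if not (np.isfinite(row.x_px) and np.isfinite(row.y_px)):
            continue
        if not (0 <= row.x_px < w and 0 <= row.y_px < h):
            continue
        rr, cc = sk_disk((row.y_px, row.x_px), row.radius_px, shape=shape)
        if np.any(occupancy[rr, cc]):
            warnings.warn(f"ROI {row.cell_id} overlaps a previous ROI")
        occupancy[rr, cc] = True
        rendered.append(row.cell_id)
        masks.append((rr, cc))

    stack = np.empty((times.size, h, w), dtype=np.uint16)
    base = cfg.i_back + cfg.i_laser_peak * laser.astype(float)
    for k in range(times.size):
        frame = np.full(shape, base[k])
        for cid, (rr, cc) in zip(rendered, masks):
            frame[rr, cc] = by_id[cid].intensity[k]
        stack[k] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)

    roi_table = rois[rois.cell_id.isin(rendered)].reset_index(drop=True)
    if tiff_path is not None:
        tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    if roi_csv_path is not None:
        roi_table.to_csv(roi_csv_path, index=False)
    return stack, roi_table
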