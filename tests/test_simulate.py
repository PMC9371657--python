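"""Generator behaviour: temperature field, trace composition, cohorts."""

import dataclasses

import numpy as np
import pytest

from hicr.datatypes import CalibrationCurve, HeatPulseProtocol
from hicr.metrics import dfmax
from hicr.simulate import (
    FieldModel,
    burst_probability,
    mutant_preset,
    render_image_stack,
    simulate_cell_trace,
    simulate_cohort,
    simulate_eutta_trace,
    simulate_temperature_field,
)
from hicr.thermometry import quench_ratio

from conftest import noise_free_config


class TestTemperatureField:
    def test_zero_power_gives_zero_field(self, protocol):
        prof = simulate_temperature_field(
            FieldModel(), 0.0, [10.0, 40.0], np.arange(0, 30, 0.2), protocol)
        assert np.all(prof.delta_t == 0.0)

    def test_zero_before_pulse_onset(self, protocol):
        times = np.arange(0, 30, 0.2)
        prof = simulate_temperature_field(FieldModel(), 25.6, [10.0], times, protocol)
        assert np.all(prof.delta_t[0, times < protocol.t_start] == 0.0)

    def test_plateau_ratio_matches_inverse_distance_form(self, protocol):
        # closed form: A(r) = a P/(r + r0), so the plateau ratio between
        # 10 and 40 um is (40 + r0)/(10 + r0)
        fm = FieldModel()
        times = np.arange(0, 30, 0.2)
        prof = simulate_temperature_field(fm, 25.6, [10.0, 40.0], times, protocol)
        plateau = prof.delta_t[:, np.argmin(np.abs(times - (protocol.t_end - 0.2)))]
        assert plateau[0] > plateau[1]
        expected = (40.0 + fm.r0_um) / (10.0 + fm.r0_um)
        assert plateau[0] / plateau[1] == pytest.approx(expected, rel=1e-9)

    def test_strictly_decreasing_in_distance_during_plateau(self, protocol):
        times = np.arange(0, 30, 0.2)
        prof = simulate_temperature_field(
            FieldModel(), 25.6, np.linspace(5, 100, 20), times, protocol)
        during = (times > protocol.t_start + 1.0) & (times < protocol.t_end)
        assert np.all(np.diff(prof.delta_t[:, during], axis=0) < 0)

    def test_default_calibration_ten_degrees_at_ten_microns(self):
        # 25.6 mW produces a ~10 degC rise at r = 10 um by construction
        assert FieldModel().amplitude(25.6, 10.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("bad", [[-5.0], [0.0]])
    def test_nonpositive_distance_rejected(self, protocol, bad):
        with pytest.raises(ValueError):
            simulate_temperature_field(FieldModel(), 25.6, bad, [0.0, 1.0], protocol)

    def test_empty_time_grid_rejected(self, protocol):
        with pytest.raises(ValueError):
            simulate_temperature_field(FieldModel(), 25.6, [10.0], [], protocol)


class TestEuttaTrace:
    def _profile(self, cfg, r):
        return simulate_temperature_field(
            cfg.field_model, cfg.protocol.laser_power_mw, [r], cfg.times(),
            cfg.protocol)

    def test_quench_ratio_equals_published_slope_at_one_degree(self):
        # a 1.0 degC plateau at T0=24 quenches the dye by exactly 2.7%
        cfg = noise_free_config(protocol=HeatPulseProtocol(t0_c=24.0))
        r = float(cfg.field_model.distance_for(25.6, 1.0))
        prof = self._profile(cfg, r)
        tr = simulate_eutta_trace(prof, r, CalibrationCurve(), cfg)
        from hicr.datatypes import BackgroundEstimates
        bg = BackgroundEstimates(i_back=cfg.i_back,
                                 i_laser=cfg.i_back + cfg.i_laser_peak)
        assert quench_ratio(tr, cfg.protocol, bg) == pytest.approx(-0.027, abs=1e-9)

    def test_flat_without_heating(self):
        cfg = noise_free_config(i_laser_peak=0.0)
        prof = simulate_temperature_field(
            cfg.field_model, 0.0, [10.0], cfg.times(), cfg.protocol)
        tr = simulate_eutta_trace(prof, 10.0, CalibrationCurve(), cfg)
        assert np.allclose(tr.intensity, cfg.f_baseline_mean + cfg.i_back)

    def test_bleach_decay_reaches_e_minus_one(self):
        cfg = noise_free_config(total_duration_s=120.0, bleach_rate_per_s=0.01,
                                i_back=0.0, i_laser_peak=0.0)
        prof = simulate_temperature_field(
            cfg.field_model, 0.0, [10.0], cfg.times(), cfg.protocol)
        tr = simulate_eutta_trace(prof, 10.0, CalibrationCurve(), cfg)
        i100 = tr.index_at_or_before(100.0)
        assert tr.intensity[i100] / tr.intensity[0] == pytest.approx(np.exp(-1), rel=1e-6)

    def test_unsupported_base_temperature_fails(self):
        cfg = noise_free_config(protocol=HeatPulseProtocol(t0_c=30.0))
        prof = self._profile(cfg, 10.0)
        with pytest.raises(KeyError, match="30"):
            simulate_eutta_trace(prof, 10.0, CalibrationCurve(), cfg)


class TestCellTrace:
    def test_no_stimulus_no_spont_gives_flat_dfmax_zero(self, bg_zero):
        cfg = noise_free_config(i_back=0.0, i_laser_peak=0.0)
        tr, truth = simulate_cell_trace(0.0, cfg.mutant, cfg, "fluo4", seed=0)
        assert truth["burst"] == 0
        m = dfmax(tr, cfg.protocol, bg_zero)
        assert m.dfmax == pytest.approx(0.0, abs=1e-12)

    def test_burst_fraction_near_half_at_generative_midpoint(self):
        # Monte-Carlo oracle: at deltaT = dtth_true the logistic midpoint
        # puts the burst fraction at 1/2
        cfg = noise_free_config(total_duration_s=31.0, frame_interval_s=1.0)
        mut = cfg.mutant
        n = 4000
        hits = sum(
            simulate_cell_trace(mut.dtth_true_c, mut, cfg, "fluo4", seed=s)[1]["burst"]
            for s in range(n))
        assert hits / n == pytest.approx(0.5, abs=0.03)

    def test_serca_dip_scales_pulse_intensity(self):
        import dataclasses as dc
        cfg = noise_free_config(i_back=0.0, i_laser_peak=0.0)
        mut = dc.replace(cfg.mutant, serca_dip_frac=0.1,
                         dtth_true_c=100.0)  # far above any deltaT: no burst
        tr, truth = simulate_cell_trace(1.0, mut, cfg, "fluo4", seed=3)
        assert truth["burst"] == 0
        during = tr.laser_on
        before = tr.time_s < cfg.protocol.t_start
        assert np.mean(tr.intensity[during]) == pytest.approx(
            0.9 * np.mean(tr.intensity[before]), rel=1e-9)

    def test_unknown_channel_rejected(self):
        cfg = noise_free_config()
        with pytest.raises(ValueError, match="channel"):
            simulate_cell_trace(1.0, cfg.mutant, cfg, "gcamp", seed=0)

    def test_cepia_minimum_five_seconds_after_pulse_end(self, bg_zero):
        cfg = noise_free_config(i_back=0.0, i_laser_peak=0.0)
        mut = dataclasses.replace(cfg.mutant, dtth_true_c=1e-6, resp_slope_c=1e-6)
        tr, truth = simulate_cell_trace(5.0, mut, cfg, "cepia", seed=1)
        assert truth["burst"] == 1
        after = tr.time_s >= cfg.protocol.t_end + 1.0
        t_min = tr.time_s[after][np.argmin(tr.intensity[after])]
        assert t_min == pytest.approx(cfg.protocol.t_end + 5.0, abs=0.3)


class TestCohort:
    def test_same_seed_bitwise_identical(self):
        cfg = noise_free_config(n_cells=8, n_unheated=4, noise_sd=1.0)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.traces_frame().to_csv(index=False) == b.traces_frame().to_csv(index=False)
        assert a.truth.to_csv(index=False) == b.truth.to_csv(index=False)

    def test_prefix_stability_when_growing_cohort(self):
        small = simulate_cohort(noise_free_config(n_cells=5, noise_sd=1.0))
        large = simulate_cohort(noise_free_config(n_cells=9, noise_sd=1.0))
        for tr_s, tr_l in zip(small.traces[:5], large.traces[:5]):
            assert tr_s.cell_id == tr_l.cell_id
            np.testing.assert_array_equal(tr_s.intensity, tr_l.intensity)

    def test_equal_distances_give_equal_ground_truth(self):
        cfg = noise_free_config(n_cells=6, distances_um=[20.0] * 6,
                                deltaT_range_c=None)
        data = simulate_cohort(cfg)
        heated = data.truth[data.truth.group == "heated"]
        assert heated.deltaT_true_C.nunique() == 1

    def test_lower_threshold_line_has_more_responders(self):
        # same deltaT range, same seeds: the more heat-sensitive line
        # must produce strictly more ground-truth bursts
        import dataclasses as dc
        base = noise_free_config(n_cells=150, noise_sd=1.0,
                                 deltaT_range_c=(0.0, 10.0))
        lo = simulate_cohort(dc.replace(base, mutant=dc.replace(base.mutant, dtth_true_c=2.0)))
        hi = simulate_cohort(dc.replace(base, mutant=dc.replace(base.mutant, dtth_true_c=8.0)))
        assert lo.truth.burst.sum() > hi.truth.burst.sum()

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(noise_free_config(n_cells=0))


class TestBurstProbability:
    def test_logistic_midpoint_and_monotonicity(self):
        mut = mutant_preset("WT", 36.0)
        assert burst_probability(mut.dtth_true_c, mut) == pytest.approx(0.5)
        p = burst_probability(np.linspace(0, 15, 50), mut)
        assert np.all(np.diff(p) > 0)


class TestRenderExtract:
    def _small_cohort(self):
        return simulate_cohort(noise_free_config(
            n_cells=3, n_unheated=0, distances_um=[15.0, 25.0, 40.0],
            deltaT_range_c=None, noise_sd=0.0, sheet_n_distances=3))

    def test_constant_trace_renders_identical_roi_pixels(self):
        data = self._small_cohort()
        # replace first cell's trace with a constant
        data.traces[0].intensity[:] = 500.0
        data.traces[0].laser_on[:] = False
        stack, rois = render_image_stack(data, shape=(256, 256))
        row = rois[rois.cell_id == data.traces[0].cell_id].iloc[0]
        y, x = int(row.y_px), int(row.x_px)
        assert np.all(stack[:, y, x] == stack[0, y, x])

    def test_roi_mean_round_trip_within_quantization(self, tmp_path):
        from hicr.io import extract_rois

        data = self._small_cohort()
        tiff = tmp_path / "stack.tiff"
        roic = tmp_path / "rois.csv"
        stack, rois = render_image_stack(data, shape=(256, 256),
                                         tiff_path=tiff, roi_csv_path=roic)
        assert stack.shape[0] == data.traces[0].n_frames
        out = extract_rois(tiff, roic, frame_interval_s=data.config.frame_interval_s,
                           protocol=data.config.protocol)
        by_id = {tr.cell_id: tr for tr in data.traces}
        for tr in out:
            np.testing.assert_allclose(tr.intensity, by_id[tr.cell_id].intensity,
                                       atol=1.0)  # one uint16 quantization step

    def test_zero_frames_rejected(self):
        data = self._small_cohort()
        data.config.total_duration_s = 0.0  # bypasses validation deliberately
        with pytest.raises(ValueError, match="zero frames"):
            render_image_stack(data)
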