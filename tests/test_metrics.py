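"""Per-cell burst metrics: baselines, dF_max/F0, ER depletion, correlations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicr.datatypes import BackgroundEstimates
from hicr.metrics import (
    baseline,
    correlate_er_cytosol,
    dfmax,
    dfmin_cepia,
    normalize_by_store,
    scatter_correct,
    spontaneous_dfmax,
)
from hicr.simulate import simulate_cell_trace

from conftest import make_trace, noise_free_config


class TestBaseline:
    def test_constant_trace(self, protocol):
        tr = make_trace(np.full(150, 100.0), protocol=protocol)
        bl = baseline(tr, protocol, BackgroundEstimates(i_back=5.0, i_laser=5.0))
        assert bl.f_before == 100.0
        assert bl.f0 == 95.0

    def test_onset_before_first_frame_rejected(self, protocol):
        tr = make_trace(np.full(150, 100.0), protocol=protocol)
        tr.time_s = tr.time_s + 50.0  # trace starts after the pulse
        with pytest.raises(ValueError):
            baseline(tr, protocol, BackgroundEstimates())

    def test_single_designated_frame_no_smoothing(self, protocol):
        y = np.full(150, 100.0)
        tr = make_trace(y, protocol=protocol)
        idx = tr.baseline_index(protocol.t_start)
        tr.intensity[idx] = 113.0  # noisy designated frame
        bl = baseline(tr, protocol, BackgroundEstimates())
        assert bl.f_before == 113.0


class TestScatterCorrect:
    def test_zero_scatter_is_identity(self, protocol):
        tr = make_trace(np.full(150, 100.0), protocol=protocol)
        out = scatter_correct(tr, BackgroundEstimates(i_back=0.0, i_laser=0.0))
        np.testing.assert_array_equal(out.intensity, tr.intensity)

    def test_subtracts_scatter_during_pulse_only(self, protocol):
        tr = make_trace(np.full(150, 100.0), protocol=protocol)
        out = scatter_correct(tr, BackgroundEstimates(i_back=0.0, i_laser=3.0))
        assert np.all(out.intensity[tr.laser_on] == 97.0)
        assert np.all(out.intensity[~tr.laser_on] == 100.0)

    def test_matches_scatter_free_twin_from_generator(self):
        # generator round trip: removing the known scatter reproduces a
        # twin simulated without scatter
        cfg_on = noise_free_config(i_laser_peak=3.0)
        cfg_off = noise_free_config(i_laser_peak=0.0)
        tr_on, _ = simulate_cell_trace(2.0, cfg_on.mutant, cfg_on, "fluo4", seed=7)
        tr_off, _ = simulate_cell_trace(2.0, cfg_off.mutant, cfg_off, "fluo4", seed=7)
        bg = BackgroundEstimates(i_back=cfg_on.i_back,
                                 i_laser=cfg_on.i_back + cfg_on.i_laser_peak)
        out = scatter_correct(tr_on, bg)
        np.testing.assert_allclose(out.intensity, tr_off.intensity, rtol=1e-12)


class TestDfmax:
    def test_constant_trace_zero(self, protocol, bg_zero):
        tr = make_trace(np.full(160, 100.0), protocol=protocol)
        assert dfmax(tr, protocol, bg_zero).dfmax == 0.0

    def test_simple_peak_arithmetic(self, protocol, bg_zero):
        tr = make_trace(np.full(160, 100.0), protocol=protocol)
        i = tr.index_at_or_before(protocol.t_start + 5.0)
        tr.intensity[i] = 150.0
        m = dfmax(tr, protocol, bg_zero)
        assert m.dfmax == pytest.approx(0.5)
        assert m.t_peak_s == pytest.approx(protocol.t_start + 5.0)

    def test_peak_outside_window_excluded(self, protocol, bg_zero):
        tr = make_trace(np.full(200, 100.0), protocol=protocol)
        late = tr.index_at_or_before(protocol.t_start + 25.0)
        tr.intensity[late] = 400.0
        inwin = tr.index_at_or_before(protocol.t_start + 3.0)
        tr.intensity[inwin] = 120.0
        assert dfmax(tr, protocol, bg_zero).dfmax == pytest.approx(0.2)

    def test_incomplete_window_names_span(self, protocol, bg_zero):
        tr = make_trace(np.full(100, 100.0), protocol=protocol)  # ends at 20 s
        with pytest.raises(ValueError, match="does not cover"):
            dfmax(tr, protocol, bg_zero)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        # multiplying trace and i_back consistently leaves dF/F0 unchanged
        from hicr.datatypes import HeatPulseProtocol

        protocol = HeatPulseProtocol()
        rng = np.random.default_rng(42)
        y = 100.0 + 10.0 * rng.random(160) + 5.0
        tr1 = make_trace(y, protocol=protocol)
        tr2 = make_trace(y * scale, protocol=protocol)
        m1 = dfmax(tr1, protocol, BackgroundEstimates(i_back=5.0, i_laser=5.0))
        m2 = dfmax(tr2, protocol,
                   BackgroundEstimates(i_back=5.0 * scale, i_laser=5.0 * scale))
        assert m1.dfmax == pytest.approx(m2.dfmax, rel=1e-9)

    def test_max_property_dominates_every_frame(self, protocol, bg_zero):
        rng = np.random.default_rng(3)
        tr = make_trace(100.0 + rng.random(160) * 20, protocol=protocol)
        m = dfmax(tr, protocol, bg_zero)
        bl = baseline(tr, protocol, bg_zero)
        mask = tr.window_mask(protocol.t_start, protocol.t_start + 20.0)
        assert np.all(m.dfmax >= (tr.intensity[mask] - bl.f_before) / bl.f0 - 1e-12)

    def test_noise_free_burst_amplitude_recovered_exactly(self, bg_zero):
        # generator contract: known amplitude, no dip -> dfmax == amplitude
        cfg = noise_free_config(i_back=0.0, i_laser_peak=0.0)
        mut = dataclasses.replace(cfg.mutant, dtth_true_c=1e-9, resp_slope_c=1e-9,
                                  serca_dip_frac=0.0, burst_amp_sd=0.0,
                                  burst_amp_mean=1.7)
        tr, truth = simulate_cell_trace(5.0, mut, cfg, "fluo4", seed=2)
        assert truth["burst"] == 1
        assert dfmax(tr, cfg.protocol, bg_zero).dfmax == pytest.approx(1.7, abs=1e-12)


class TestSpontaneous:
    def test_constant_trace_zero(self, bg_zero):
        tr = make_trace(np.full(160, 100.0))
        assert spontaneous_dfmax(tr, bg_zero) == 0.0

    def test_arithmetic(self, bg_zero):
        tr = make_trace(np.full(160, 100.0))
        tr.intensity[tr.index_at_or_before(20.0)] = 120.0
        assert spontaneous_dfmax(tr, bg_zero) == pytest.approx(0.2)

    def test_window_closed_at_thirty_seconds(self, bg_zero):
        tr = make_trace(np.full(160, 100.0))
        tr.intensity[tr.index_at_or_before(30.0)] = 130.0
        assert spontaneous_dfmax(tr, bg_zero) == pytest.approx(0.3)


class TestDfminCepia:
    def test_constant_trace_zero(self, protocol, bg_zero):
        tr = make_trace(np.full(160, 100.0), protocol=protocol, channel="cepia")
        m = dfmin_cepia(tr, protocol, bg_zero)
        assert m.dfmin == 0.0 and m.minus_dfmin == 0.0

    def test_arithmetic(self, protocol, bg_zero):
        tr = make_trace(np.full(160, 100.0), protocol=protocol, channel="cepia")
        tr.intensity[tr.index_at_or_before(protocol.t_start + 6.0)] = 80.0
        m = dfmin_cepia(tr, protocol, bg_zero)
        assert m.dfmin == pytest.approx(-0.2)
        assert m.minus_dfmin == pytest.approx(0.2)

    def test_quench_epoch_excluded(self, protocol, bg_zero):
        # a deep minimum during the pulse (thermal quench) is ignored
        tr = make_trace(np.full(160, 100.0), protocol=protocol, channel="cepia")
        tr.intensity[tr.index_at_or_before(protocol.t_start + 1.0)] = 20.0
        tr.intensity[tr.index_at_or_before(protocol.t_start + 5.0)] = 90.0
        assert dfmin_cepia(tr, protocol, bg_zero).minus_dfmin == pytest.approx(0.1)

    def test_depth_monotone_in_burst_amplitude(self, bg_zero):
        # generator ER traces: larger bursts deplete the store more
        cfg = noise_free_config(i_back=0.0, i_laser_peak=0.0)
        depths = []
        for amp in (0.5, 1.5, 3.0):
            mut = dataclasses.replace(cfg.mutant, dtth_true_c=1e-9,
                                      resp_slope_c=1e-9, burst_amp_sd=0.0,
                                      burst_amp_mean=amp)
            tr, _ = simulate_cell_trace(5.0, mut, cfg, "cepia", seed=4)
            depths.append(dfmin_cepia(tr, cfg.protocol, bg_zero).minus_dfmin)
        assert depths[0] < depths[1] < depths[2]


class TestStoreNormalization:
    @pytest.mark.parametrize("value, store, expected",
                             [(2.0, 1.0, 2.0), (2.0, 0.5, 4.0)])
    def test_normalization(self, value, store, expected):
        assert normalize_by_store(value, store) == pytest.approx(expected)

    def test_zero_store_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_store(2.0, 0.0)


class TestCorrelation:
    def test_collinear(self):
        r, p = correlate_er_cytosol([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_anticollinear(self):
        r, _ = correlate_er_cytosol([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            correlate_er_cytosol([1, 2], [3, 4])

    def test_generator_coupling_gives_strong_positive_r(self):
        # simulation oracle: five lines whose ER-dip depth is coupled to
        # burst amplitude give R > 0.9 across line means (median of seeds)
        from hicr.simulate import mutant_preset

        lines = ["WT", "Q156K", "R164C", "Y523S"]
        presets = {n: mutant_preset(n, 36.0) for n in lines}
        presets["Thap"] = mutant_preset("WT+thapsigargin", 36.0)
        rs = []
        for seed in range(7):
            means_min, means_max = [], []
            for name, mut in presets.items():
                mut = dataclasses.replace(mut, dtth_true_c=1e-6, resp_slope_c=1e-6)
                cfg = noise_free_config(seed=seed, noise_sd=1.0)
                bg = BackgroundEstimates(i_back=cfg.i_back,
                                         i_laser=cfg.i_back + cfg.i_laser_peak)
                vmin, vmax = [], []
                for i in range(12):
                    trc, _ = simulate_cell_trace(10.0, mut, cfg, "cepia", seed=600 + i)
                    trf, _ = simulate_cell_trace(10.0, mut, cfg, "fluo4", seed=600 + i)
                    vmin.append(dfmin_cepia(scatter_correct(trc, bg), cfg.protocol,
                                            bg).minus_dfmin)
                    vmax.append(dfmax(scatter_correct(trf, bg), cfg.protocol,
                                      bg).dfmax)
                means_min.append(np.mean(vmin))
                means_max.append(np.mean(vmax))
            r, _ = correlate_er_cytosol(means_min, means_max)
            rs.append(r)
        assert np.median(rs) > 0.9
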