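import dataclasses
import math

import numpy as np
import pytest

from dsmcell.errors import BracketError, ConfigurationError
from dsmcell.features import (
    conductance_sweep,
    extract_features,
    knockout_experiment,
    threshold_search,
)
from dsmcell.fixtures import toy_spike_trace
from dsmcell.simulator import SimulationResult
from dsmcell.stimuli import PulseStimulus


def flat_trace(v=-52.0, t_stop=800.0, dt=0.04):
    t = np.arange(int(round(t_stop / dt)) + 1) * dt
    return SimulationResult(
        t_ms=t, v_mv=np.full_like(t, v), cai_mm=np.full_like(t, 1.5e-4), dt_ms=dt
    )


class TestExtractFeatures:
    def test_flat_trace_has_no_spike(self):
        f = extract_features(flat_trace(), settle_ms=500.0)
        assert not f.spike_detected
        assert f.rmp_mv == pytest.approx(-52.0, abs=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ConfigurationError, match="settle"):
            extract_features(flat_trace(t_stop=100.0), settle_ms=500.0)

    def test_toy_spike_threshold_within_one_sample(self):
        toy = toy_spike_trace(rmp_mv=-52.0, threshold_mv=-38.5, onset_ms=200.0)
        f = extract_features(toy, stim_onset_ms=200.0, settle_ms=200.0)
        assert f.spike_detected
        # slope jumps 1 -> 25 mV/ms exactly at the constructed threshold
        assert f.threshold_v_mv == pytest.approx(-38.5, abs=0.1)
        assert f.peak_v_mv == pytest.approx(10.0, abs=0.5)
        assert f.ahp_depth_mv == pytest.approx(8.0, abs=0.1)

    def test_time_shift_invariance(self):
        a = toy_spike_trace(onset_ms=200.0, t_stop_ms=500.0)
        b = toy_spike_trace(onset_ms=280.0, t_stop_ms=580.0)
        fa = extract_features(a, stim_onset_ms=200.0, settle_ms=200.0)
        fb = extract_features(b, stim_onset_ms=280.0, settle_ms=280.0)
        for name in ("rmp_mv", "threshold_v_mv", "peak_v_mv", "ahp_depth_mv"):
            assert getattr(fa, name) == pytest.approx(getattr(fb, name), abs=1e-6)
        assert fa.ap_duration_ms == pytest.approx(fb.ap_duration_ms, abs=0.1)


class TestThresholdSearch:
    # leaky-integrator oracle: a 10-ms pulse of amplitude A onto an RC
    # cell (G, C) peaks at A/G * (1 - exp(-T/tau)); it "spikes" when the
    # peak clears dv_th, so the rheobase is known in closed form.
    G_NS, C_PF, T_MS, DV_TH = 2.0, 37.7, 10.0, 13.5

    def rheobase(self):
        tau = self.C_PF / self.G_NS
        return (self.DV_TH * self.G_NS * 1e-3) / (1.0 - math.exp(-self.T_MS / tau))

    def spike(self, amp):
        tau = self.C_PF / self.G_NS
        peak = amp / (self.G_NS * 1e-3) * (1.0 - math.exp(-self.T_MS / tau))
        return peak > self.DV_TH

    def test_recovers_analytic_rheobase_to_grid(self):
        res = 0.001
        found = threshold_search(None, None, 0.001, 0.2, res, spike=self.spike)
        exact = self.rheobase()
        assert found == pytest.approx(math.ceil(exact / res) * res, abs=1e-12)
        assert self.spike(found) and not self.spike(found - res)

    def test_independent_of_bracket(self):
        a = threshold_search(None, None, 0.001, 0.2, 0.001, spike=self.spike)
        b = threshold_search(None, None, 0.02, 1.0, 0.001, spike=self.spike)
        assert a == b

    def test_invalid_brackets_raise(self):
        with pytest.raises(BracketError):
            threshold_search(None, None, 0.001, 0.01, 0.001, spike=self.spike)  # no spike at hi
        with pytest.raises(BracketError):
            threshold_search(None, None, 0.1, 0.2, 0.001, spike=self.spike)  # spike at lo
        with pytest.raises(BracketError):
            threshold_search(None, None, 0.5, 0.1, 0.001, spike=self.spike)  # lo >= hi


class TestSweepAndKnockout:
    def test_factor_one_row_normalizes_to_unity(self, model, cfg):
        stim = PulseStimulus(amplitude=0.8, onset_ms=150.0, duration_ms=10.0,
                             unit_na=cfg["stimulus"]["unit_na"])
        sw = conductance_sweep(model, "trpm4", [0.9, 1.0, 1.1], stim,
                               t_stop_ms=700.0)
        k = sw.factors.index(1.0)
        for name, col in sw.normalized.items():
            assert col[k] == pytest.approx(1.0, rel=1e-12), name

    def test_sweep_requires_unit_factor(self, model, cfg):
        stim = PulseStimulus(amplitude=0.8, onset_ms=150.0, duration_ms=10.0)
        with pytest.raises(ConfigurationError, match="1.0"):
            conductance_sweep(model, "trpm4", [0.7, 0.9], stim)

    def test_unknown_channel_rejected(self, model, cfg):
        stim = PulseStimulus(amplitude=0.56, onset_ms=150.0, duration_ms=10.0,
                             unit_na=cfg["stimulus"]["unit_na"])
        with pytest.raises(ConfigurationError, match="unknown channel"):
            knockout_experiment(model, "nonexistent", None, stim)

    def test_muting_leak_keeps_the_cell_resting(self, model, cfg):
        stim = PulseStimulus(amplitude=0.0, onset_ms=150.0, duration_ms=10.0,
                             unit_na=cfg["stimulus"]["unit_na"])
        (res_m, f_m), (_, f_c) = knockout_experiment(model, "leak", None, stim,
                                                     t_stop_ms=400.0)
        assert not f_m.spike_detected and not f_c.spike_detected
        assert abs(res_m.v_mv[-1] - res_m.v_mv[0]) < 5.0
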