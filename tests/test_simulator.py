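import dataclasses
import math

import numpy as np
import pytest

from dsmcell.bk import BKParams
from dsmcell.calcium import CaPoolParams
from dsmcell.errors import IntegrationError
from dsmcell.gating import HHChannelSpec
from dsmcell.geometry import CellGeometry, PassiveProperties, lateral_area
from dsmcell.simulator import (
    CellModel,
    initial_state,
    resting_state,
    run,
    scale_gmax,
    step,
    total_membrane_current,
    with_gmax,
)
from dsmcell.stimuli import PulseStimulus
from dsmcell.trpm4 import TRPM4Params

from helpers import leak_only_model

# frozen checkpoints of the default model under a 0.8-unit, 10-ms pulse
# at 150 ms (t_ms, v_mv, cai_mm); regression tolerance 1e-9 mV
GOLDEN = (
    (0.0, -52.0, 0.00015),
    (16.64, -52.040726416765104, 0.00015206787436167159),
    (50.0, -52.01848423690493, 0.00015338295030829598),
    (100.0, -52.00775972567272, 0.0001536801453846219),
    (150.0, -52.0038967825118, 0.00015370986649462792),
    (166.64000000000001, -27.756631697433264, 0.00040900334233593896),
    (183.32, -29.191808107091923, 0.0005319876723610834),
    (200.0, -32.88753565494788, 0.0005350013791399554),
    (216.64000000000001, -56.27656744809758, 0.0003909012410103858),
    (233.32, -52.23510743382518, 0.00025568149469896713),
    (250.0, -52.00848585108003, 0.00019744273943368373),
)


class TestMembraneEquation:
    def test_zero_conductance_means_zero_dvdt(self):
        m = leak_only_model(gmax=0.0)
        st = initial_state(m, v0_mv=-30.0)
        assert total_membrane_current(m, st, 0.0, None) == 0.0
        res = run(m, initial=st, t_stop_ms=50.0)
        assert np.all(res.v_mv == -30.0)

    def test_resting_fixed_point_has_zero_dvdt(self, model):
        st = resting_state(model)
        assert abs(total_membrane_current(model, st, 0.0, None)) < 1e-6

    def test_channel_removal_is_additive(self, model):
        """Zeroing one channel changes dV/dt by exactly that channel's
        current over the capacitance."""
        st = resting_state(model)
        base = total_membrane_current(model, st, 0.0, None)
        cm = model.passive.cm_uf_per_cm2
        for name in ("kdr", "trpm4", "cat"):
            reduced = with_gmax(model, name, 0.0)
            if name == "trpm4":
                g = model.trpm4.gmax_s_cm2
                e = model.trpm4.e_rev_mv
                mgate = st.gates["trpm4"][0] ** model.trpm4.power
            else:
                spec = model.channel(name)
                g, e = spec.gmax_s_cm2, spec.e_rev_mv
                mg, hg = st.gates[name]
                mgate = (mg if mg is not None else 1.0) ** (
                    spec.activation.power if spec.activation else 1
                )
                if spec.inactivation is not None:
                    mgate *= hg ** spec.inactivation.power
            i_chan = g * mgate * (st.v_mv - e) * 1e3
            got = total_membrane_current(reduced, st, 0.0, None)
            assert got - base == pytest.approx(i_chan / cm, rel=1e-9, abs=1e-12)


class TestStep:
    def test_fixed_point_is_invariant(self, model):
        st = resting_state(model)
        out = step(model, st, None, dt=0.04)
        assert out.v_mv == pytest.approx(st.v_mv, abs=1e-9)
        assert out.cai_mm == pytest.approx(st.cai_mm, rel=1e-9)

    def test_passive_rc_charging_matches_closed_form(self):
        m = leak_only_model(e_leak=0.0)
        st = initial_state(m, v0_mv=0.0)
        amp_na = 0.01
        pulse = PulseStimulus(amplitude=amp_na, onset_ms=0.0, duration_ms=400.0)
        res = run(m, initial=st, stimulus=pulse, t_stop_ms=300.0, dt_ms=0.02)
        area = lateral_area(m.geometry)
        r_gohm = 1.0 / (m.hh_channels[0].gmax_s_cm2 * area) * 1e-9
        tau = m.passive.rm_kohm_cm2  # ms (Rm * Cm with Cm = 1 uF/cm2)
        v_inf_mv = amp_na * r_gohm * 1e3  # nA * GOhm = V, times 1e3 -> mV
        analytic = v_inf_mv * (1.0 - np.exp(-res.t_ms / tau))
        err = np.abs(res.v_mv - analytic) / v_inf_mv
        assert err.max() < 1e-4

    def test_divergence_raises_named_error(self):
        m = leak_only_model(e_leak=500.0)
        st = initial_state(m, v0_mv=0.0)
        with pytest.raises(IntegrationError, match="diverged"):
            run(m, initial=st, t_stop_ms=500.0)


class TestRun:
    def test_deterministic_and_prefix_consistent(self, model, equilibrated):
        stim = PulseStimulus(amplitude=0.3, onset_ms=100.0, duration_ms=10.0,
                             unit_na=0.4988)
        a = run(model, initial=equilibrated, stimulus=stim, t_stop_ms=250.0,
                record_currents=False)
        b = run(model, initial=equilibrated, stimulus=stim, t_stop_ms=500.0,
                record_currents=False)
        n = len(a.v_mv)
        assert np.array_equal(a.v_mv, b.v_mv[:n])
        c = run(model, initial=equilibrated, stimulus=stim, t_stop_ms=250.0,
                record_currents=False)
        assert np.array_equal(a.v_mv, c.v_mv)

    def test_self_convergence_under_subthreshold_pulse(self, model, equilibrated):
        stim = PulseStimulus(amplitude=0.3, onset_ms=100.0, duration_ms=10.0,
                             unit_na=0.4988)
        coarse = run(model, initial=equilibrated, stimulus=stim, t_stop_ms=400.0,
                     dt_ms=0.04, record_currents=False)
        fine = run(model, initial=equilibrated, stimulus=stim, t_stop_ms=400.0,
                   dt_ms=0.01, record_currents=False)
        diff = np.abs(coarse.v_mv - fine.v_mv[::4]).max()
        assert diff < 0.5

    def test_golden_trace_regression(self, model, cfg, equilibrated):
        stim = PulseStimulus(
            amplitude=0.8,
            onset_ms=cfg["stimulus"]["onset_ms"],
            duration_ms=cfg["stimulus"]["duration_ms"],
            unit_na=cfg["stimulus"]["unit_na"],
        )
        res = run(model, initial=equilibrated, stimulus=stim, t_stop_ms=250.0,
                  record_currents=False)
        for t, v, cai in GOLDEN:
            k = int(round(t / res.dt_ms))
            assert res.v_mv[k] == pytest.approx(v, abs=1e-9), t
            assert res.cai_mm[k] == pytest.approx(cai, rel=1e-9), t

    def test_trpm4_gmax_raises_resting_potential(self, model):
        """More TRPM4 conductance depolarizes the resting potential,
        monotonically over the -30%..+20% range."""
        rmps = [
            resting_state(scale_gmax(model, {"trpm4": f})).v_mv
            for f in (0.7, 0.85, 1.0, 1.1, 1.2)
        ]
        assert all(b > a for a, b in zip(rmps, rmps[1:]))
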