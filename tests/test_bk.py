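import numpy as np
import pytest
import scipy.linalg

from dsmcell.bk import (
    STATE_NAMES,
    BKParams,
    BKState,
    bk_current,
    bk_steady_state,
    bk_step,
    build_rate_matrix,
)
from dsmcell.errors import ConfigurationError


def hand_built_rates(p: BKParams, v: float, cai: float):
    """Independent construction of the transition-rate table, written
    out term by term from the scheme definition."""
    a = np.exp(v / p.a_efold_mv)
    b = np.exp(-v / p.b_efold_mv)
    r = {}
    # Ca-binding ladders (closed and open rows)
    r[("C0", "C1")] = 3 * p.k_on * cai
    r[("C1", "C2")] = 4 * p.k_on * cai
    r[("C2", "C3")] = 3 * p.k_on * cai
    r[("C3", "C4")] = p.k_on * cai
    r[("C4", "C3")] = 3 * p.k_coff * cai
    r[("C3", "C2")] = 4 * p.k_coff * cai
    r[("C2", "C1")] = 3 * p.k_coff * cai
    r[("C1", "C0")] = p.k_coff * cai
    r[("O0", "O1")] = 3 * p.k_on * cai
    r[("O1", "O2")] = 4 * p.k_on * cai
    r[("O2", "O3")] = 3 * p.k_on * cai
    r[("O3", "O4")] = p.k_on * cai
    r[("O4", "O3")] = 3 * p.k_ooff * cai
    r[("O3", "O2")] = 4 * p.k_ooff * cai
    r[("O2", "O1")] = 3 * p.k_ooff * cai
    r[("O1", "O0")] = p.k_ooff * cai
    # voltage-dependent vertical transitions
    for i in range(5):
        r[(f"C{i}", f"O{i}")] = p.co_rates[i] * a
    for i in range(4):
        r[(f"O{i}", f"C{i}")] = p.oc_rates[i] * b
    r[("O4", "C4")] = p.oc_rates[4] * b * cai
    return r


class TestRateMatrix:
    @pytest.mark.parametrize("v,cai", [(-52.0, 2.5e-4), (-20.0, 1e-3), (0.0, 5e-3)])
    def test_matches_hand_built_table(self, v, cai):
        p = BKParams()
        Q = build_rate_matrix(p, v, cai)
        table = hand_built_rates(p, v, cai)
        for i, si in enumerate(STATE_NAMES):
            for j, sj in enumerate(STATE_NAMES):
                if i == j:
                    continue
                assert Q[i, j] == pytest.approx(
                    table.get((si, sj), 0.0), rel=1e-12, abs=1e-15
                ), (si, sj)

    def test_rows_sum_to_zero(self):
        Q = build_rate_matrix(BKParams(), -30.0, 4e-4)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_zero_calcium_decouples_the_ladders(self):
        Q = build_rate_matrix(BKParams(), -40.0, 0.0)
        # only the vertical C<->O transitions survive
        off = Q - np.diag(np.diag(Q))
        nz = {(i, j) for i, j in zip(*np.nonzero(off))}
        assert nz == {(i, i + 5) for i in range(5)} | {(i + 5, i) for i in range(4)}

    def test_negative_calcium_rejected(self):
        with pytest.raises(ConfigurationError):
            build_rate_matrix(BKParams(), -40.0, -1e-4)


class TestStepper:
    def test_steady_state_is_fixed_point(self):
        p = BKParams()
        ss = bk_steady_state(p, -52.0, 3e-4)
        out = bk_step(ss, p, -52.0, 3e-4, dt=0.04)
        assert np.abs(out.as_array() - ss.as_array()).max() < 1e-12

    def test_probability_conserved_over_1e5_steps(self):
        p = BKParams()
        state = bk_steady_state(p, -52.0, 3e-4)
        arr = state.as_array()
        # drive with a sinusoidal voltage so the dynamics are nontrivial
        for k in range(100_000):
            v = -52.0 + 30.0 * np.sin(2 * np.pi * k / 5000.0)
            state = bk_step(state, p, v, 3e-4, dt=0.04)
        assert abs(sum(state.occupancy) - 1.0) <= 1e-9

    @pytest.mark.parametrize("v", [-60.0, -52.0, -30.0, 0.0])
    @pytest.mark.parametrize("cai", [1e-4, 5e-4, 2e-3])
    def test_matches_matrix_exponential_oracle(self, v, cai):
        """One 0.04-ms backward-Euler step, started at the steady state
        of a slightly different voltage (small fast-mode content, as in
        a running simulation), agrees with the dense matrix exponential
        to 1e-6."""
        p = BKParams()
        start = bk_steady_state(p, v - 0.25, cai).as_array()
        Q = build_rate_matrix(p, v, cai)
        expected = scipy.linalg.expm(0.04 * Q.T) @ start
        got = bk_step(BKState(tuple(start)), p, v, cai, dt=0.04).as_array()
        assert np.abs(got - expected).max() < 1e-6

    def test_cold_start_error_versus_expm_is_first_order_in_dt(self):
        """From a cold start (all occupancy in C0) the backward-Euler
        trajectory converges to the matrix-exponential solution at first
        order: quartering dt cuts the 1-ms error by about four."""
        p = BKParams()
        v, cai = -52.0, 1e-4
        Q = build_rate_matrix(p, v, cai)
        expected = scipy.linalg.expm(1.0 * Q.T) @ np.eye(10)[0]
        errs = []
        for dt in (0.04, 0.01):
            state = BKState((1.0,) + (0.0,) * 9)
            for _ in range(int(round(1.0 / dt))):
                state = bk_step(state, p, v, cai, dt)
            errs.append(np.abs(state.as_array() - expected).max())
        assert 3.0 < errs[0] / errs[1] < 5.0


class TestSteadyState:
    def test_zero_calcium_is_an_error(self):
        with pytest.raises(ConfigurationError):
            bk_steady_state(BKParams(), -52.0, 0.0)

    def test_matches_long_run_simulation(self):
        p = BKParams()
        v, cai = -35.0, 5e-4
        ss = bk_steady_state(p, v, cai).as_array()
        state = BKState((1.0,) + (0.0,) * 9)
        for _ in range(10_000):  # 10^4 ms at dt = 1 ms
            state = bk_step(state, p, v, cai, dt=1.0)
        assert np.abs(state.as_array() - ss).max() < 1e-6

    def test_conducting_probability_decreases_with_calcium(self):
        """With every unbinding rate proportional to cai, as the scheme
        is written, the ladder equilibria are cai-independent and the
        lone cai-dependent closing rate (O4->C4) makes the stationary
        conducting probability strictly *decreasing* in cai."""
        p = BKParams()
        for v in (-52.0, -20.0, 0.0):
            probs = []
            for cai in (1e-5, 1e-4, 1e-3, 1e-2):
                occ = bk_steady_state(p, v, cai).as_array()
                probs.append(occ[list(p.conducting_index)].sum())
            assert all(b < a for a, b in zip(probs, probs[1:])), (v, probs)

    def test_conducting_probability_increases_with_voltage(self):
        p = BKParams()
        probs = [
            bk_steady_state(p, v, 3e-4).as_array()[list(p.conducting_index)].sum()
            for v in (-80.0, -52.0, -20.0, 0.0)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestCurrent:
    def test_closed_states_carry_nothing(self):
        p = BKParams()
        closed = BKState((0.2, 0.2, 0.2, 0.2, 0.2, 0, 0, 0, 0, 0))
        assert bk_current(p, closed, -20.0) == 0.0

    def test_zero_at_reversal(self):
        p = BKParams()
        open_ = BKState((0, 0, 0, 0, 0, 0.0, 0.25, 0.25, 0.25, 0.25))
        assert bk_current(p, open_, p.e_k_mv) == 0.0

    def test_direct_product_and_o0_excluded(self):
        # gmax 0.0008, conducting sum 0.25, driving +60 -> 12.0 uA/cm2
        p = BKParams(e_k_mv=-75.0)
        state = BKState((0.5, 0, 0, 0, 0, 0.25, 0.0625, 0.0625, 0.0625, 0.0625))
        assert bk_current(p, state, -15.0) == pytest.approx(12.0, rel=1e-12)

    def test_conducting_states_switch(self):
        p4 = BKParams(conducting_states=("O4",))
        state = BKState((0, 0, 0, 0, 0, 0.2, 0.2, 0.2, 0.2, 0.2))
        full = BKParams()
        assert bk_current(p4, state, 0.0) == pytest.approx(
            bk_current(full, state, 0.0) / 4.0, rel=1e-12
        )
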