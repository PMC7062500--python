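"""Equation-level mechanism fidelity: NCX, K[Ca], calcium pool, HH gates."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ca1sim._kernel import F_FARADAY, R_GAS
from ca1sim.mechanisms import (CaPoolParams, IonConditions, KCaParams,
                               KCaState, NCXParams, ca_pool_step,
                               hh_channel_current, kca_current, kca_m_inf,
                               kca_m_step, kca_tau, na_rates,
                               ncx_allosteric_factor, ncx_current_and_fluxes,
                               ncx_delta_e, ncx_reversal_potential,
                               HHChannelSpec, cal_steady)

IONS = IonConditions()          # the printed concentration set, 307.15 K
NCX = NCXParams()
KCA = KCaParams()
POOL = CaPoolParams()


class TestNCXAllostery:
    def test_half_saturation(self):
        assert ncx_allosteric_factor(NCX.Km_Ca_act, NCX) == pytest.approx(0.5)

    def test_saturation_limit(self):
        assert ncx_allosteric_factor(1e6 * NCX.Km_Ca_act, NCX) == \
            pytest.approx(1.0, abs=1e-10)

    def test_direct_evaluation_at_resting_ca(self):
        # one-line independent evaluation of the Hill form
        ca = 5e-5
        expected = 1.0 / (1.0 + (NCX.Km_Ca_act / ca) ** NCX.n_Hill)
        assert ncx_allosteric_factor(ca, NCX) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_strictly_increasing_and_bounded(self):
        cas = np.logspace(-7, -1, 200)
        allo = ncx_allosteric_factor(cas, NCX)
        assert np.all(np.diff(allo) > 0)
        assert np.all((allo > 0) & (allo < 1))

    def test_nonpositive_ca_raises(self):
        with pytest.raises(ValueError):
            ncx_allosteric_factor(0.0, NCX)


class TestNCXDeltaE:
    def test_zero_exactly_at_reversal(self):
        v_rev = ncx_reversal_potential(IONS)
        assert abs(ncx_delta_e(v_rev, IONS, NCX)) < 1e-15

    def test_reversal_near_minus_71mV_for_printed_ions(self):
        # bisection root of the electrochemical factor vs the closed form
        root = brentq(lambda v: ncx_delta_e(v, IONS, NCX), -120.0, 0.0,
                      xtol=1e-6)
        assert root == pytest.approx(-71.0, abs=0.5)
        assert root == pytest.approx(ncx_reversal_potential(IONS), abs=0.01)

    def test_sign_about_reversal(self):
        v_rev = ncx_reversal_potential(IONS)
        assert ncx_delta_e(v_rev + 50.0, IONS, NCX) > 0  # reverse, outward
        assert ncx_delta_e(v_rev - 50.0, IONS, NCX) < 0  # forward, inward

    def test_monotone_in_voltage(self):
        v = np.linspace(-100.0, 60.0, 400)
        de = ncx_delta_e(v, IONS, NCX)
        assert np.all(np.diff(de) > 0)

    def test_overflow_guard(self):
        with pytest.raises(ValueError):
            ncx_delta_e(2000.0, IONS, NCX)


class TestNCXFluxes:
    def test_all_zero_at_reversal(self):
        v_rev = ncx_reversal_potential(IONS)
        fx = ncx_current_and_fluxes(v_rev, IONS.Ca_i, IONS, NCX)
        assert fx.i_total == pytest.approx(0.0, abs=1e-18)
        for val in (fx.i_Ca, fx.i_Na, fx.j_Ca):
            assert val == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("v, ca", [(-80.0, 5e-5), (-30.0, 1e-4),
                                       (10.0, 1e-3), (40.0, 5e-3)])
    def test_stoichiometry_exact(self, v, ca):
        fx = ncx_current_and_fluxes(v, ca, IONS, NCX)
        assert fx.i_Na / fx.i_Ca == pytest.approx(-1.5, rel=1e-12)
        assert fx.i_Na + fx.i_Ca == pytest.approx(fx.i_total, rel=1e-12)

    def test_reverse_mode_calcium_entry_on_depolarization(self):
        # strong depolarization at resting Ca: exchanger admits Ca
        fx = ncx_current_and_fluxes(30.0, 5e-5, IONS, NCX)
        assert fx.i_total > 0           # net outward
        assert fx.j_Ca > 0              # molar Ca flux inward

    def test_forward_mode_clearance_below_reversal(self):
        fx = ncx_current_and_fluxes(-90.0, 1e-3, IONS, NCX)
        assert fx.i_total < 0
        assert fx.j_Ca < 0


class TestKCa:
    def test_m_inf_zero_at_zero_ca(self):
        assert kca_m_inf(0.0, KCA) == 0.0

    def test_half_activation(self):
        ca_half = math.sqrt(KCA.beta / KCA.alpha)
        assert kca_m_inf(ca_half, KCA) == pytest.approx(0.5, rel=1e-12)

    def test_tau_limit_and_monotone(self):
        assert kca_tau(0.0, KCA) == pytest.approx(1.0 / KCA.beta)
        cas = np.logspace(-6, -2, 100)
        taus = kca_tau(cas, KCA)
        assert np.all(np.diff(taus) <= 0)

    def test_minf_over_tau_identity(self):
        # m_inf / tau == alpha * Ca^n wherever the tau floor is inactive
        for ca in np.logspace(-6, -3.2, 40):
            tau = kca_tau(ca, KCA)
            if tau > KCA.tau_min:
                lhs = kca_m_inf(ca, KCA) / tau
                assert lhs == pytest.approx(KCA.alpha * ca ** KCA.n,
                                            rel=1e-12)

    def test_current_zeros(self):
        assert kca_current(-20.0, KCaState(0.0), KCA) == 0.0
        assert kca_current(KCA.E_K, KCaState(0.7), KCA) == 0.0

    def test_clamped_relaxation_matches_closed_form(self):
        ca, dt = 2e-4, 0.025
        m_inf, tau = kca_m_inf(ca, KCA), kca_tau(ca, KCA)
        state = KCaState(0.0)
        t = 0.0
        for _ in range(2000):
            state = kca_m_step(state, ca, KCA, dt)
            t += dt
            expected = m_inf + (0.0 - m_inf) * math.exp(-t / tau)
            assert state.m == pytest.approx(expected, abs=1e-3 * m_inf)

    def test_gate_stays_in_unit_interval(self, rng):
        state = KCaState(0.5)
        for _ in range(500):
            ca = float(rng.uniform(0, 5e-3))
            state = kca_m_step(state, ca, KCA, 0.025)
            assert 0.0 <= state.m <= 1.0


class TestCaPool:
    def test_equilibrium(self):
        assert ca_pool_step(POOL.Ca_rest, 0.0, POOL, 0.025) == \
            pytest.approx(POOL.Ca_rest, rel=1e-12)

    def test_decay_matches_closed_form(self):
        ca = 1e-3
        t = 0.0
        for _ in range(4000):
            ca = ca_pool_step(ca, 0.0, POOL, 0.025)
            t += 0.025
        expected = POOL.Ca_rest + (1e-3 - POOL.Ca_rest) * math.exp(
            -t / POOL.tau_decay)
        assert ca == pytest.approx(expected, rel=1e-3)

    def test_constant_influx_matches_ode_integral(self):
        # d[Ca]/dt = S - (Ca-rest)/tau with S from a constant inward current
        i_ca = -1e-3  # mA/cm², inward
        depth_cm = POOL.shell_depth * 1e-4
        S = -i_ca / (2 * F_FARADAY * depth_cm)
        ca, t = POOL.Ca_rest, 0.0
        for _ in range(400):
            ca = ca_pool_step(ca, i_ca, POOL, 0.025)
            t += 0.025
        expected = POOL.Ca_rest + S * POOL.tau_decay * (
            1.0 - math.exp(-t / POOL.tau_decay))
        assert ca == pytest.approx(expected, rel=1e-3)

    def test_inward_current_raises_ca(self):
        assert ca_pool_step(POOL.Ca_rest, -1e-3, POOL, 0.025) > POOL.Ca_rest
        assert ca_pool_step(POOL.Ca_rest, +1e-3, POOL, 0.025) >= POOL.Ca_min


class TestHHChannel:
    SPEC = HHChannelSpec(
        name="cal", gbar=1e-4, E_rev=120.0,
        gates=(("m", 2, cal_steady),))

    def test_closed_gates_no_current(self):
        i, _ = hh_channel_current(-65.0, {"m": 0.0}, self.SPEC, 0.0)
        assert i == pytest.approx(0.0, abs=1e-30)

    def test_zero_current_at_reversal(self):
        i, _ = hh_channel_current(120.0, {"m": 0.5}, self.SPEC, 0.025)
        assert i == pytest.approx(0.0, abs=1e-12)

    def test_gate_relaxes_toward_inf(self):
        gates = {"m": 0.0}
        for _ in range(2000):
            _, gates = hh_channel_current(0.0, gates, self.SPEC, 0.025)
        m_inf, _ = cal_steady(0.0)
        assert gates["m"] == pytest.approx(m_inf, rel=1e-6)

    def test_na_rates_finite_at_singularity(self):
        am, bm, ah, bh = na_rates(-40.0)   # removable singularity of alpha_m
        assert np.isfinite([am, bm, ah, bh]).all()
        assert am == pytest.approx(1.0, rel=1e-5)
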