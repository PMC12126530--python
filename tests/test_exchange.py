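"""Exchange forward models: propagator, closed forms, induced shifts."""

import numpy as np
import pytest
import scipy.linalg

from nmrbind.binding import ExchangeParams, TitrationCondition, binding_state
from nmrbind.exchange import (
    CpmgSchedule,
    SpinParams,
    carver_richards_r2eff,
    cpmg_r2eff,
    cpmg_r2eff_profile,
    delta_ex,
    delta_ex_rads,
    lineshape_shift,
    luz_meiboom_r2eff,
    ppm_to_rads,
    rads_to_ppm,
    snap_nu_cpmg,
)

T_RELAX = 0.04
NU = snap_nu_cpmg(np.linspace(25.0, 1000.0, 12), T_RELAX)


def reference_propagator_r2eff(dw, r2a, r2b, kab, kba, nu, t_relax):
    """Independent oracle: scipy.linalg.expm and an explicit python loop."""
    L = np.array([[-r2a - kab, kba], [kab, -r2b - kba + 1j * dw]])
    kex = kab + kba
    p_b = kab / kex if kex > 0 else 0.0
    m = np.array([1.0 - p_b, p_b], dtype=complex)
    n_units = int(round(2 * t_relax * nu))
    P = scipy.linalg.expm(L / (4.0 * nu))
    for _ in range(n_units):
        m = P @ np.conj(P @ m)
    return -np.log(abs(m[0]) / (1.0 - p_b)) / t_relax


class TestPropagator:
    def test_flat_without_ligand(self):
        # no exchange partner: dispersion profile is the bare R2A everywhere
        r2 = cpmg_r2eff_profile(800.0, 12.0, 60.0, 0.0, 580.0, NU, T_RELAX)
        assert np.all(np.abs(r2 - 12.0) < 1e-10)

    def test_matches_independent_expm_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            dw = rng.uniform(50, 2000)
            r2a = rng.uniform(5, 30)
            kex = rng.uniform(50, 20000)
            pb = rng.uniform(0.01, 0.5)
            kab, kba = kex * pb, kex * (1 - pb)
            nu = float(snap_nu_cpmg(rng.uniform(25, 1000), T_RELAX))
            got = float(cpmg_r2eff_profile(dw, r2a, 5 * r2a, kab, kba, nu, T_RELAX))
            want = reference_propagator_r2eff(dw, r2a, 5 * r2a, kab, kba, nu, T_RELAX)
            assert got == pytest.approx(want, abs=1e-8)

    def test_fast_pulsing_reaches_population_average(self):
        # nu -> inf: exchange fully refocused, R2 -> pA R2A + pB R2B
        kex, pb = 6000.0, 0.05
        kab, kba = kex * pb, kex * (1 - pb)
        nu_hi = float(snap_nu_cpmg(12000.0, T_RELAX))
        r2 = float(cpmg_r2eff_profile(300.0, 10.0, 50.0, kab, kba, nu_hi, T_RELAX))
        assert r2 == pytest.approx((1 - pb) * 10.0 + pb * 50.0, abs=0.05)

    def test_luz_meiboom_fast_exchange_oracle(self):
        kex, pb = 6000.0, 0.05
        kab, kba = kex * pb, kex * (1 - pb)
        prop = cpmg_r2eff_profile(300.0, 10.0, 10.0, kab, kba, NU, T_RELAX)
        lm = luz_meiboom_r2eff(300.0, 10.0, 10.0, kab, kba, NU)
        assert np.max(np.abs(prop - lm)) < 0.05

    def test_dispersion_amplitude_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            dw = rng.uniform(0, 2000)
            r2a = rng.uniform(5, 30)
            kex = rng.uniform(50, 30000)
            pb = rng.uniform(0.0, 0.5)
            kab, kba = kex * pb, kex * (1 - pb)
            prof = cpmg_r2eff_profile(dw, r2a, 5 * r2a, kab, kba, NU, T_RELAX)
            rex = prof[0] - prof[-1]
            assert rex >= -1e-8
            if dw == 0.0 or pb == 0.0:
                assert abs(rex) < 1e-9

    def test_field_scaling_of_fast_limit_rex(self):
        # dw fixed in ppm: low-nu Rex scales as the square of the field
        cond = TitrationCondition.from_uM(200.0, 20.0)
        st = binding_state(cond, ExchangeParams.from_kd(380e-6, 5000.0))
        nu_lo = float(NU[0])
        vals = {}
        for f in (600.0, 800.0):
            dw = float(ppm_to_rads(1.0, f))
            r2 = cpmg_r2eff_profile(dw, 12.0, 12.0, st.k_on_app, st.k_off,
                                    np.array([nu_lo, NU[-1] * 8]), T_RELAX)
            vals[f] = r2[0] - r2[1]
        assert vals[800.0] / vals[600.0] == pytest.approx((800 / 600) ** 2, rel=0.03)

    def test_spin_params_interface(self, jdgf_state):
        spin = SpinParams(residue_id=5, delta_omega=2.0,
                          r2_apo={600.0: 12.0}, r2_bound_scale=5.0)
        scalar = cpmg_r2eff(spin, jdgf_state, 600.0, float(NU[0]), T_RELAX)
        arr = cpmg_r2eff(spin, jdgf_state, 600.0, NU, T_RELAX)
        assert scalar == pytest.approx(arr[0])
        assert arr[0] > arr[-1]  # dispersion present under binding


class TestClosedForm:
    def test_exact_closed_form_vs_propagator_regime_grid(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(120):
            ratio = 10 ** rng.uniform(-1, np.log10(20))
            pb = rng.uniform(0.01, 0.5)
            dw = rng.uniform(100, 2000)
            kex = ratio * dw
            kab, kba = kex * pb, kex * (1 - pb)
            r2a = rng.uniform(5, 30)
            prop = cpmg_r2eff_profile(dw, r2a, 5 * r2a, kab, kba, NU, T_RELAX)
            cf = carver_richards_r2eff(dw, r2a, 5 * r2a, kab, kba, NU, T_RELAX)
            worst = max(worst, float(np.max(np.abs(prop - cf))))
        assert worst < 0.1  # in practice ~1e-12

    def test_classic_asymptote_at_moderate_echoes(self):
        # the large-N formula converges to the propagator as nu grows
        kex, pb = 2000.0, 0.03
        kab, kba = kex * pb, kex * (1 - pb)
        nu = snap_nu_cpmg(np.array([500.0, 1000.0]), T_RELAX)
        prop = cpmg_r2eff_profile(800.0, 12.0, 60.0, kab, kba, nu, T_RELAX)
        classic = carver_richards_r2eff(800.0, 12.0, 60.0, kab, kba, nu, exact=False)
        assert np.max(np.abs(prop - classic)) < 0.15

    def test_no_ligand_and_no_shift_limits(self):
        assert carver_richards_r2eff(800.0, 12.0, 60.0, 0.0, 0.0, NU)[0] == 12.0
        # dw = 0: no dispersion -- the profile is exactly flat at any kex,
        # and its level reaches the population average once kex >> R2B - R2A
        kex, pb = 1000.0, 0.1
        flat = carver_richards_r2eff(0.0, 12.0, 60.0, kex * pb, kex * (1 - pb),
                                     NU, T_RELAX)
        assert np.ptp(flat) < 1e-9
        kex = 50000.0
        fast = carver_richards_r2eff(0.0, 12.0, 60.0, kex * pb, kex * (1 - pb),
                                     NU, T_RELAX)
        assert np.all(np.abs(fast - (0.9 * 12.0 + 0.1 * 60.0)) < 0.01)


class TestDeltaEx:
    def test_zero_population_gives_zero(self):
        assert delta_ex_rads(800.0, 12.0, 60.0, 0.0, 580.0) == 0.0

    def test_fast_limit_population_weighted(self):
        kex, pb = 100000.0, 0.05
        d = delta_ex_rads(300.0, 10.0, 50.0, kex * pb, kex * (1 - pb))
        assert d == pytest.approx(pb * 300.0, rel=0.01)

    def test_sign_follows_shift_difference(self):
        kex, pb = 50000.0, 0.05
        dpos = delta_ex_rads(300.0, 10.0, 50.0, kex * pb, kex * (1 - pb))
        dneg = delta_ex_rads(-300.0, 10.0, 50.0, kex * pb, kex * (1 - pb))
        assert dpos > 0 > dneg
        assert dneg == pytest.approx(-dpos, rel=1e-10)

    def test_monotonic_approach_to_fast_limit(self):
        # |delta_ex| grows toward pB*dw as exchange accelerates
        dw, pb = 500.0, 0.04
        vals = []
        for kex in [2000.0, 5000.0, 20000.0, 100000.0]:
            vals.append(abs(delta_ex_rads(dw, 10.0, 50.0, kex * pb, kex * (1 - pb))))
        assert all(np.diff(vals) > 0)
        assert all(v <= pb * dw * (1 + 1e-9) for v in vals)

    def test_intermediate_exchange_vs_lineshape_oracle(self, jdgf_state):
        # kex ~ 600 s^-1, dw = 2 ppm 15N at 600 MHz, p_B ~ 0.034
        dw = float(ppm_to_rads(2.0, 600.0))
        d_eig = delta_ex_rads(dw, 12.0, 60.0, jdgf_state.k_on_app, jdgf_state.k_off)
        d_fid = lineshape_shift(dw, 12.0, 60.0, jdgf_state.k_on_app, jdgf_state.k_off)
        assert 0.0 < d_eig < jdgf_state.p_bound * dw
        assert d_fid == pytest.approx(d_eig, rel=0.005)

    def test_ppm_interface(self, jdgf_state):
        spin = SpinParams(residue_id=1, delta_omega=2.0, r2_apo={600.0: 12.0})
        d_ppm = delta_ex(spin, jdgf_state, 600.0)
        want = rads_to_ppm(
            delta_ex_rads(float(ppm_to_rads(2.0, 600.0)), 12.0, 60.0,
                          jdgf_state.k_on_app, jdgf_state.k_off), 600.0)
        assert d_ppm == pytest.approx(float(want), rel=1e-12)


class TestSchedule:
    def test_snapping_yields_even_echo_counts(self):
        nu = snap_nu_cpmg(np.linspace(25, 1000, 12), 0.04)
        n = 2 * 0.04 * nu
        assert np.allclose(n, np.rint(n))
        assert np.all(np.rint(n) % 2 == 0)

    def test_incompatible_schedule_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="compatible"):
            CpmgSchedule(field_mhz=600.0, t_relax=0.04, nu_cpmg=(33.0,))
        CpmgSchedule(field_mhz=600.0, t_relax=0.04, nu_cpmg=(25.0, 50.0))

    def test_ppm_rads_round_trip(self):
        assert float(rads_to_ppm(ppm_to_rads(2.5, 800.0), 800.0)) == pytest.approx(2.5)
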