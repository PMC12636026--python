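"""Unit and property tests for the relaxivity forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from gdcoil.constants import GAMMA_H, HBAR, MU_B
from gdcoil.relaxation import (ElectronSpinParams, NMRDProfile,
                               OuterSphereParams, SecondSphereParams,
                               angular_frequencies,
                               electron_relaxation_rates, freed_j,
                               lipari_szabo_j, outer_sphere_r1,
                               second_sphere_r1, total_r1_profile)
from gdcoil.relaxation import outer_sphere_constant

ANG = 1e-10


class TestAngularFrequencies:
    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            angular_frequencies(0.0)
        with pytest.raises(ValueError):
            angular_frequencies(-5.0)

    def test_proton_scaling(self):
        w_i, _ = angular_frequencies(10.0)
        assert w_i == pytest.approx(2 * np.pi * 1e7, rel=1e-12)

    def test_electron_proton_ratio_is_frequency_independent(self):
        expected = 2.0 * MU_B / HBAR / GAMMA_H
        for nu in (0.01, 10.0, 60.0):
            w_i, w_s = angular_frequencies(nu)
            assert w_s / w_i == pytest.approx(expected, rel=1e-14)


class TestLipariSzabo:
    def test_zero_frequency_closed_form(self):
        val = lipari_szabo_j(0.0, 7e-9, 3.18e-10, 0.4)
        assert val == pytest.approx(2.9908e-9, rel=1e-10)

    def test_s2_one_is_single_lorentzian(self):
        w = 2 * np.pi * 42e6
        assert lipari_szabo_j(w, 7e-9, 1e-12, 1.0) == pytest.approx(
            7e-9 / (1 + (w * 7e-9) ** 2), rel=1e-14)

    def test_rejects_s2_outside_unit_interval(self):
        with pytest.raises(ValueError):
            lipari_szabo_j(0.0, 1e-9, 1e-10, 1.2)

    def test_matches_high_precision_oracle_at_60mhz(self):
        w = 2 * np.pi * 60e6
        ref = float(oracle.lipari_szabo(w, 7e-9, 318e-12, 0.5))
        assert lipari_szabo_j(w, 7e-9, 318e-12, 0.5) == pytest.approx(
            ref, rel=1e-12)

    @given(st.floats(0, 1e12), st.floats(1e-12, 1e-7),
           st.floats(1e-13, 1e-9), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_nonincreasing(self, w, tg, tl, s2):
        j0 = lipari_szabo_j(w, tg, tl, s2)
        j1 = lipari_szabo_j(2 * w + 1.0, tg, tl, s2)
        assert j0 >= 0
        assert j1 <= j0 + 1e-30


class TestElectronRates:
    def test_zero_frequency_closed_form(self):
        el = ElectronSpinParams(delta2=1.0e19, tau_v=2.0e-11)
        r1e, _ = electron_relaxation_rates(0.0, el)
        assert r1e == pytest.approx(12 * 1.0e19 * 2.0e-11, rel=1e-12)
        assert r1e == pytest.approx(2.4e9, rel=1e-12)

    def test_matches_term_by_term_oracle_at_60mhz(self):
        el = ElectronSpinParams()
        _, w_s = angular_frequencies(60.0)
        ref = oracle.electron_rates(w_s, el.delta2, el.tau_v)
        r1e, r2e = electron_relaxation_rates(w_s, el)
        assert r1e == pytest.approx(float(ref[0]), rel=1e-12)
        assert r2e == pytest.approx(float(ref[1]), rel=1e-12)

    @given(st.floats(0, 1e13), st.floats(1e17, 1e20),
           st.floats(1e-12, 1e-10))
    @settings(max_examples=100, deadline=None)
    def test_rates_nonincreasing_in_frequency(self, w, d2, tv):
        el = ElectronSpinParams(delta2=d2, tau_v=tv)
        lo = electron_relaxation_rates(w, el)
        hi = electron_relaxation_rates(2 * w + 1.0, el)
        assert lo[0] >= hi[0] >= 0
        assert lo[1] >= hi[1] >= 0


class TestSecondSphere:
    def test_linear_in_q_ss(self, kh2_model):
        ss = kh2_model.second_sphere
        el = kh2_model.electron
        base = second_sphere_r1(20.0, ss, el)
        from dataclasses import replace
        doubled = second_sphere_r1(20.0, replace(ss, q_ss=2 * ss.q_ss), el)
        zero = second_sphere_r1(20.0, replace(ss, q_ss=0.0), el)
        assert doubled == pytest.approx(2 * base, rel=1e-12)
        assert zero == 0.0

    def test_dipolar_prefactor_r6_scaling(self, kh2_model):
        # isolate the r^-6 prefactor: T1m scales as r^6, so in the
        # T1m >> tau_M regime r1 scales as r^-6
        from dataclasses import replace
        ss = replace(kh2_model.second_sphere, tau_m_ss=1e-12)
        el = kh2_model.electron
        r1_a = second_sphere_r1(20.0, replace(ss, r_ss_A=3.6), el)
        r1_b = second_sphere_r1(20.0, replace(ss, r_ss_A=7.2), el)
        assert r1_a / r1_b == pytest.approx(2 ** 6, rel=1e-6)

    def test_matches_chained_oracle_at_20mhz(self, kh2_model):
        ss, el = kh2_model.second_sphere, kh2_model.electron
        ref = float(oracle.second_sphere(
            20.0, ss.q_ss, ss.r_ss_A, ss.tau_m_ss, ss.tau_rg, ss.tau_rl,
            ss.s2, el.delta2, el.tau_v))
        assert second_sphere_r1(20.0, ss, el) == pytest.approx(ref,
                                                               rel=1e-12)

    def test_rejects_zero_distance(self):
        with pytest.raises(ValueError):
            SecondSphereParams(r_ss_A=0.0)


class TestFreed:
    def test_zero_argument_is_one(self):
        assert freed_j(0.0, 1e-9) == pytest.approx(1.0, rel=1e-14)

    def test_high_frequency_limit_vanishes(self):
        assert freed_j(1e18, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_matches_complex_arithmetic_oracle(self):
        tau_d, t_je = 1e-9, 1e-8  # omega*tau_d = 1, tau_d/T_je = 0.1
        ref = float(oracle.freed(1e9, tau_d, t_je))
        assert freed_j(1e9, tau_d, t_je) == pytest.approx(ref, rel=1e-10)

    @given(st.floats(0, 1e14), st.floats(1e-11, 1e-7),
           st.floats(1e-11, 1e-5))
    @settings(max_examples=150, deadline=None)
    def test_bounded_in_unit_interval(self, w, tau_d, t_je):
        val = freed_j(w, tau_d, t_je)
        assert 0.0 < val <= 1.0 + 1e-12


class TestOuterSphere:
    def test_inverse_ad_scaling_at_zero_frequency(self):
        # halving both a and D multiplies the omega->0, T_je->inf value
        # by 4 (pure 1/(a*D) scaling; freed_j = 1 regardless of tau_D)
        el = ElectronSpinParams(delta2=0.0, tau_v=1e-12)  # no e-relax
        lo = outer_sphere_r1(1e-10, OuterSphereParams(a_A=4.0, d=2.3e-10), el)
        hi = outer_sphere_r1(1e-10, OuterSphereParams(a_A=2.0, d=1.15e-10), el)
        assert hi / lo == pytest.approx(4.0, rel=1e-4)

    def test_zero_frequency_closed_form(self):
        el = ElectronSpinParams(delta2=0.0, tau_v=1e-12)
        os_ = OuterSphereParams(a_A=4.0, d=2.3e-10)
        expected = 10.0 * outer_sphere_constant(el) / (4.0 * ANG * 2.3e-10)
        assert outer_sphere_r1(1e-10, os_, el) == pytest.approx(expected,
                                                               rel=1e-4)

    def test_matches_chained_oracle_at_20mhz(self, kh2_model):
        os_, el = kh2_model.outer_sphere, kh2_model.electron
        ref = float(oracle.outer_sphere(20.0, os_.a_A, os_.d, el.delta2,
                                        el.tau_v))
        assert outer_sphere_r1(20.0, os_, el) == pytest.approx(ref,
                                                               rel=1e-12)

    def test_vanishes_for_fast_diffusion(self, kh2_model):
        el = kh2_model.electron
        val = outer_sphere_r1(20.0, OuterSphereParams(a_A=4.0, d=1.0), el)
        assert val < 1e-6


class TestTotalProfile:
    def test_additivity(self, kh2_model):
        freqs = np.geomspace(0.01, 70, 12)
        prof = total_r1_profile(freqs, kh2_model)
        ss = second_sphere_r1(freqs, kh2_model.second_sphere,
                              kh2_model.electron)
        os_ = outer_sphere_r1(freqs, kh2_model.outer_sphere,
                              kh2_model.electron)
        np.testing.assert_allclose(prof.r1, ss + os_, rtol=1e-14)

    def test_qss_zero_reduces_to_outer_sphere(self, kh2_model):
        freqs = np.geomspace(0.01, 70, 12)
        model = kh2_model.replace(q_ss=0.0)
        prof = total_r1_profile(freqs, model)
        os_ = outer_sphere_r1(freqs, model.outer_sphere, model.electron)
        np.testing.assert_allclose(prof.r1, os_, rtol=1e-14)

    def test_oracle_equivalence_random_models(self):
        from conftest import random_model
        rng = np.random.default_rng(42)
        freqs = [0.05, 1.0, 20.0, 60.0]
        for _ in range(10):
            m = random_model(rng)
            prof = total_r1_profile(freqs, m)
            for k, nu in enumerate(freqs):
                ss, el, os_ = m.second_sphere, m.electron, m.outer_sphere
                ref = float(oracle.total_r1(
                    nu, ss.q_ss, ss.r_ss_A, ss.tau_m_ss, ss.tau_rg,
                    ss.tau_rl, ss.s2, os_.a_A, os_.d, el.delta2, el.tau_v))
                assert prof.r1[k] == pytest.approx(ref, rel=1e-10)

    def test_rejects_unsorted_frequencies(self, kh2_model):
        with pytest.raises(ValueError):
            total_r1_profile([10.0, 5.0], kh2_model)


class TestNMRDProfileInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            NMRDProfile(frequencies=[1.0, 2.0], r1=[5.0])

    def test_rejects_nonpositive_r1(self):
        with pytest.raises(ValueError):
            NMRDProfile(frequencies=[1.0, 2.0], r1=[5.0, -1.0])
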