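"""Forward model: kernels, transfer functions, predicted spectra."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.optimize import brentq

from nfdcm import (InstabilityError, ModelParams, SpatialParams,
                   SynapticParams, check_stability, coupling_matrix,
                   input_spectrum, kernel_transfer, lead_field_weight,
                   mass_limit_spectrum, noise_spectrum, predict_spectrum,
                   sigmoid, sigmoid_gain, transfer_pyramidal,
                   transfer_vector)
from nfdcm.model_core import SingularKernelError


class TestSigmoid:
    def test_inflection_and_saturation(self):
        assert sigmoid(3.0, 2.0, 3.0) == pytest.approx(0.5)
        assert sigmoid(0.0, 0.54, 0.0) == pytest.approx(0.5)
        assert sigmoid(1e3, 0.54, 0.0) == pytest.approx(1.0)
        assert sigmoid(-1e3, 0.54, 0.0) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(v=st.floats(-20, 20), dv=st.floats(1e-3, 5),
           r=st.floats(0.01, 0.6), eta=st.floats(-5, 5))
    def test_increasing_and_bounded(self, v, dv, r, eta):
        lo, hi = sigmoid(v, r, eta), sigmoid(v + dv, r, eta)
        assert 0.0 < lo <= hi < 1.0
        if r * (abs(v - eta) + dv) < 30:  # away from float saturation
            assert lo < hi

    def test_gain_is_slope_at_origin(self):
        h = 1e-6
        for r, eta in [(1.0, 1.0), (0.54, 0.0), (2.0, -3.0)]:
            fd = (sigmoid(h, r, eta) - sigmoid(-h, r, eta)) / (2 * h)
            assert sigmoid_gain(r, eta) == pytest.approx(fd, abs=1e-8)

    def test_gain_at_prior_values(self):
        # printed value of the prior gain
        assert sigmoid_gain(0.54, 0.0) == pytest.approx(0.135, abs=5e-4)

    def test_gain_vanishes_when_saturated(self):
        assert sigmoid_gain(0.54, 1e3) == pytest.approx(0.0, abs=1e-12)


class TestKernelTransfer:
    def test_closed_form_points(self):
        assert kernel_transfer(1, 1, 0, 0, 5.0) == pytest.approx(1.0)
        assert kernel_transfer(1, 1, 0, 1, 0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha,c,upsilon", [
        (1.0, 1.0, 0.0), (2.0, 0.5, 0.3), (0.5, 16.0, 0.0167),
        (3.0, 2.0, 0.05)])
    @pytest.mark.parametrize("k,omega", [
        (0.0, 10.0), (1.2, 10.0), (np.pi, 60 * 2 * np.pi), (10.0, 1.0)])
    def test_matches_quadrature_of_delayed_kernel(self, alpha, c, upsilon,
                                                  k, omega):
        # direct Fourier integral of (alpha/2) e^{-c|x|} delta(t - ups|x|)
        xmax = np.log(1e12) / c

        def integrand(x, part):
            val = alpha * np.exp(-c * x) * np.exp(-1j * omega * upsilon * x) \
                * np.cos(k * x)
            return val.real if part == "re" else val.imag

        re, _ = integrate.quad(integrand, 0, xmax, args=("re",), limit=400)
        im, _ = integrate.quad(integrand, 0, xmax, args=("im",), limit=400)
        expect = re + 1j * im
        got = kernel_transfer(alpha, c, upsilon, k, omega)
        assert abs(got - expect) <= 1e-6 * abs(expect)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(alpha=st.floats(0.1, 10), c=st.floats(0.1, 20),
           upsilon=st.floats(0, 0.5), k=st.floats(-20, 20),
           omega=st.floats(-400, 400))
    def test_symmetries(self, alpha, c, upsilon, k, omega):
        d = kernel_transfer(alpha, c, upsilon, k, omega)
        assert kernel_transfer(alpha, c, upsilon, k, -omega) == pytest.approx(
            np.conj(d))
        assert kernel_transfer(alpha, c, upsilon, -k, omega) == pytest.approx(d)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(SingularKernelError):
            kernel_transfer(1.0, 0.0, 0.0, 0.0, 10.0)


class TestCouplingMatrix:
    def test_sparsity_and_inhibitory_sign(self, prior_params):
        j = coupling_matrix(np.pi, 2 * np.pi * 10, prior_params)
        zeros = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)]
        for idx in zeros:
            assert j[idx] == 0
        assert j[2, 1].real < 0  # pyramidal <- interneuron is inhibitory
        assert j[0, 2] != 0 and j[1, 2] != 0 and j[2, 0] != 0

    def test_vanishing_gain_zeroes_coupling(self, prior_params):
        # gamma -> 0 scales every entry to zero relative to the prior J
        p = ModelParams(synaptic=SynapticParams(r=1e-14))
        j = coupling_matrix(np.pi, 10.0, p)
        scale = np.abs(coupling_matrix(np.pi, 10.0, prior_params)).max()
        assert np.abs(j).max() < 1e-13 * scale

    def test_elementwise_assembly(self, prior_params):
        # independent reassembly from scalar pieces
        k, omega = np.pi, 2 * np.pi * 10.0
        syn, sp = prior_params.synaptic, prior_params.spatial
        gam = sigmoid_gain(syn.r, syn.eta)
        ab = np.diag([syn.m_e * syn.kappa_e, syn.m_i * syn.kappa_i,
                      syn.m_e * syn.kappa_e])
        d = np.zeros((3, 3), dtype=complex)
        d[0, 2] = kernel_transfer(sp.alpha_13, sp.c_13, sp.upsilon, k, omega)
        d[1, 2] = kernel_transfer(sp.alpha_23, sp.c_23, sp.upsilon, k, omega)
        d[2, 0] = kernel_transfer(sp.alpha_31, sp.c_31, sp.upsilon, k, omega)
        d[2, 1] = -kernel_transfer(sp.alpha_32, sp.c_32, sp.upsilon, k, omega)
        expected = ab @ d * gam
        got = coupling_matrix(k, omega, prior_params)
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)


def _random_stable_params(rng, base=None):
    base = base or ModelParams()
    while True:
        syn = replace(base.synaptic,
                      m_e=base.synaptic.m_e * np.exp(rng.normal(0, 0.25)),
                      m_i=base.synaptic.m_i * np.exp(rng.normal(0, 0.25)),
                      kappa_e=base.synaptic.kappa_e * np.exp(rng.normal(0, 0.25)),
                      kappa_i=base.synaptic.kappa_i * np.exp(rng.normal(0, 0.25)),
                      r=base.synaptic.r * np.exp(rng.normal(0, 0.25)))
        sp = replace(base.spatial,
                     alpha_13=base.spatial.alpha_13 * np.exp(rng.normal(0, 0.25)),
                     alpha_23=base.spatial.alpha_23 * np.exp(rng.normal(0, 0.25)),
                     alpha_31=base.spatial.alpha_31 * np.exp(rng.normal(0, 0.25)),
                     alpha_32=base.spatial.alpha_32 * np.exp(rng.normal(0, 0.25)),
                     c_13=base.spatial.c_13 * np.exp(rng.normal(0, 0.25)),
                     c_23=base.spatial.c_23 * np.exp(rng.normal(0, 0.25)),
                     c_31=base.spatial.c_31 * np.exp(rng.normal(0, 0.25)),
                     upsilon=base.spatial.upsilon * np.exp(rng.normal(0, 0.25)))
        params = replace(base, synaptic=syn, spatial=sp)
        if check_stability(params, np.arange(1.0, 60.5, 0.5))[0]:
            return params


class TestTransferVector:
    def test_uncoupled_limit_is_input_filter(self):
        # gamma -> 0: input drives only the stellate population, T = B^-2 G
        p = ModelParams(synaptic=SynapticParams(r=1e-14))
        t = transfer_vector(0.0, 0.0, p)
        expect = np.array([p.synaptic.m_e / p.synaptic.kappa_e, 0, 0])
        np.testing.assert_allclose(t.value, expect, rtol=1e-10, atol=1e-12)

    def test_conjugate_symmetry(self, prior_params):
        for k, f in [(np.pi, 7.0), (3 * np.pi, 41.5)]:
            w = 2 * np.pi * f
            tp = transfer_vector(k, w, prior_params).value
            tm = transfer_vector(k, -w, prior_params).value
            np.testing.assert_allclose(tm, np.conj(tp), rtol=1e-12)

    def test_closed_form_matches_linear_solve(self, rng):
        # pyramidal component: cofactor closed form vs generic 3x3 solve
        for _ in range(100):
            params = _random_stable_params(rng)
            k = rng.uniform(0, 32 * np.pi)
            w = 2 * np.pi * rng.uniform(1.0, 60.0)
            direct = transfer_vector(k, w, params).value[2]
            closed = transfer_pyramidal(k, w, params)
            assert abs(closed - direct) <= 1e-9 * abs(direct)


class TestLeadField:
    def test_peak_and_ideal_sensor(self):
        assert lead_field_weight(0.0, 2.5, 0.01) == 2.5
        ks = np.linspace(-30, 30, 7)
        np.testing.assert_allclose(lead_field_weight(ks, 1.3, 0.0),
                                   np.full(7, 1.3))
        np.testing.assert_allclose(lead_field_weight(ks, 1.0, 0.02),
                                   lead_field_weight(-ks, 1.0, 0.02))

    def test_gaussian_value(self):
        assert lead_field_weight(10.0, 1.0, 0.01) == pytest.approx(
            np.exp(-np.pi ** 2))


class TestInputNoiseSpectra:
    def test_white_pink_mixture(self):
        w = np.array([0.5, 1.0, 2.0])
        np.testing.assert_allclose(input_spectrum(w, 3.0, 0.0), 3.0)
        np.testing.assert_allclose(input_spectrum(w, 0.0, 1.0),
                                   [2.0, 1.0, 0.5])
        assert input_spectrum(1.0, 1.0, 1.0) == pytest.approx(2.0)
        np.testing.assert_allclose(noise_spectrum(w, 0.5, 1.0),
                                   0.5 + 1.0 / w)

    def test_zero_frequency_with_pink_term_rejected(self):
        with pytest.raises(ValueError):
            input_spectrum(0.0, 1.0, 1.0)


class TestPredictSpectrum:
    def test_zero_lead_field_or_input(self, prior_params, freqs):
        p = replace(prior_params,
                    observation=replace(prior_params.observation, phi_1=0.0))
        np.testing.assert_array_equal(predict_spectrum(p, freqs), 0.0)
        p = replace(prior_params,
                    observation=replace(prior_params.observation,
                                        alpha_U=0.0, beta_U=0.0))
        np.testing.assert_array_equal(predict_spectrum(p, freqs), 0.0)

    def test_real_and_nonnegative(self, prior_params, freqs):
        g = predict_spectrum(prior_params, freqs)
        assert g.dtype.kind == "f"
        assert np.all(g > 0)

    def test_matches_independent_double_loop(self, prior_params, freqs):
        g = predict_spectrum(prior_params, freqs)
        obs = prior_params.observation
        expect = np.zeros_like(freqs)
        for j in range(1, prior_params.n_modes + 1):
            k = j * np.pi / prior_params.spatial.ell
            lw = lead_field_weight(k / (2 * np.pi), obs.phi_1, obs.phi_2)
            for i, f in enumerate(freqs):
                w = 2 * np.pi * f
                t3 = transfer_vector(k, w, prior_params).value[2]
                gu = input_spectrum(w, obs.alpha_U, obs.beta_U)
                contrib = np.pi / prior_params.spatial.ell * \
                    lw * t3 * gu * np.conj(t3) * lw
                assert abs(contrib.imag) < 1e-12 * abs(contrib.real)
                expect[i] += contrib.real
        np.testing.assert_allclose(g, expect, rtol=1e-10)

    def test_mode_sum_converged_at_32(self, prior_params, freqs):
        g32 = predict_spectrum(prior_params, freqs)
        g64 = predict_spectrum(replace(prior_params, n_modes=64), freqs)
        assert abs(g64.sum() - g32.sum()) < 0.01 * g32.sum()

    def test_instability_raises_with_mode(self, freqs):
        bad = ModelParams(spatial=SpatialParams(alpha_13=2000 * 20,
                                                alpha_31=2000 * 20))
        with pytest.raises(InstabilityError) as err:
            predict_spectrum(bad, freqs)
        assert err.value.mode is not None


class TestMassLimit:
    def test_nesting_is_bit_identical(self, prior_params, freqs):
        p0 = replace(prior_params,
                     spatial=replace(prior_params.spatial, upsilon=0.0))
        np.testing.assert_array_equal(predict_spectrum(p0, freqs),
                                      mass_limit_spectrum(prior_params, freqs))
        np.testing.assert_array_equal(mass_limit_spectrum(p0, freqs),
                                      predict_spectrum(p0, freqs))

    def test_continuity_at_zero_transit_time(self, prior_params, freqs):
        tiny = replace(prior_params, spatial=replace(
            prior_params.spatial,
            upsilon=1e-6 * prior_params.spatial.upsilon))
        g_tiny = predict_spectrum(tiny, freqs)
        g_zero = mass_limit_spectrum(prior_params, freqs)
        assert np.max(np.abs(g_tiny - g_zero)) < 1e-3 * g_zero.max()

    def test_field_and_mass_shapes_differ_at_priors(self, prior_params,
                                                    freqs):
        g_f = predict_spectrum(prior_params, freqs)
        g_m = mass_limit_spectrum(prior_params, freqs)
        nf, nm = g_f / np.linalg.norm(g_f), g_m / np.linalg.norm(g_m)
        assert np.linalg.norm(nf - nm) > 0.1


class TestStability:
    def test_priors_and_uncoupled_system_stable(self, prior_params, freqs):
        assert check_stability(prior_params, freqs)[0]
        uncoupled = ModelParams(synaptic=SynapticParams(r=1e-14))
        assert check_stability(uncoupled, freqs)[0]

    def test_excitatory_bifurcation_point(self, freqs):
        # bisection on the flag vs an independent root of the DC determinant
        def stable_at(scale):
            sp = SpatialParams(alpha_13=2000 * scale, alpha_31=2000 * scale)
            return check_stability(ModelParams(spatial=sp), freqs)[0]

        lo, hi = 1.0, 50.0
        assert stable_at(lo) and not stable_at(hi)
        for _ in range(45):
            mid = 0.5 * (lo + hi)
            if stable_at(mid):
                lo = mid
            else:
                hi = mid

        syn = ModelParams().synaptic
        gam = sigmoid_gain(syn.r, syn.eta)
        k1 = np.pi  # the widest mode destabilizes first

        def det_dc(scale):
            sp = SpatialParams(alpha_13=2000 * scale, alpha_31=2000 * scale)
            d = {key: getattr(sp, f"alpha_{key}") * getattr(sp, f"c_{key}")
                 / (getattr(sp, f"c_{key}") ** 2 + k1 ** 2)
                 for key in ("13", "23", "31", "32")}
            ke, ki = syn.kappa_e, syn.kappa_i
            return (ke ** 4 * ki ** 2
                    + ke ** 3 * ki * syn.m_e * syn.m_i * d["23"] * d["32"]
                    * gam ** 2
                    - ki ** 2 * ke ** 2 * syn.m_e ** 2 * d["13"] * d["31"]
                    * gam ** 2)

        root = brentq(det_dc, 1.0, 50.0, xtol=1e-10)
        assert lo == pytest.approx(root, abs=1e-6)
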