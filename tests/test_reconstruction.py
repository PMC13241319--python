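"""Spectrum recovery: exact invertibility, regularized projection behaviour,
noise linearity, denoising, dispersion correction and re-registration."""

import numpy as np
import pytest

from convspec.device_model import (
    CascadeDesign,
    WavenumberGrid,
    system_response,
)
from convspec.exceptions import (
    AmbiguousRegistrationError,
    UnrecoverableError,
    WindowMismatchError,
)
from convspec.measurement import (
    DispersionModel,
    MeasurementTrace,
    Spectrum,
    apply_dispersion,
    simulate_trace,
)
from convspec.modulation import phase_schedule
from convspec.reconstruction import (
    dispersion_correct,
    dual_peak_resolved,
    lowpass_filter,
    recover_dispersed,
    recover_spectrum,
    relative_error,
    robust_noise_floor,
    shift_register_correct,
)
from convspec.spectra_fixtures import PeakSpec, gaussian_peaks, random_broadband


def _bandlimited(grid, k_limit, seed=0):
    """Random nonnegative spectrum with DFT support inside |k| <= k_limit."""
    rng = np.random.default_rng(seed)
    n = grid.n_points
    spec = np.zeros(n, dtype=complex)
    spec[0] = rng.uniform(5, 10) * n / 10
    for k in range(1, k_limit + 1):
        c = rng.normal(scale=0.3) + 1j * rng.normal(scale=0.3)
        spec[k] = c * n / 10
        spec[n - k] = np.conj(spec[k])
    x = np.fft.ifft(spec).real
    x -= min(x.min(), 0.0)  # keep nonnegative, stays band-limited plus DC
    return Spectrum(grid, x / x.max())


class TestRoundtrip:
    def test_noiseless_bandlimited_exact(self, ternary4, ternary4_response, grid):
        """When the input's DFT support lies inside the response's support,
        noiseless recovery is exact to machine precision."""
        x = _bandlimited(grid, 40, seed=3)
        trace = simulate_trace(x, ternary4_response)
        res = recover_spectrum(trace, ternary4_response, x_ref=x)
        assert res.epsilon <= 1e-9
        assert res.k_used == 40
        assert not res.flagged

    def test_suppressed_component_projects_to_zero(self, ternary4_response, grid):
        """Input living only at a suppressed bin recovers as zero (projection
        behaviour of the pseudo-inverse): epsilon = 1."""
        n = grid.n_points
        k = 60  # outside the ternary-4 support (k_max = 40)
        # nonnegative input whose only AC content sits at the dead bin
        x = Spectrum(grid, 1.0 + np.cos(2 * np.pi * k * np.arange(n) / n))
        trace = simulate_trace(x, ternary4_response)
        res = recover_spectrum(trace, ternary4_response)
        # DC survives, the k=60 cosine is annihilated
        np.testing.assert_allclose(
            res.spectrum_hat.intensities, np.ones(n), atol=1e-9
        )
        ref = Spectrum(grid, np.cos(2 * np.pi * k * np.arange(n) / n) + 0.0)
        pure = Spectrum(grid, x.intensities - 1.0)
        err = relative_error(
            Spectrum(grid, res.spectrum_hat.intensities - 1.0), pure
        )
        assert err == pytest.approx(1.0, abs=1e-9)
        assert k in res.suppressed_bins or res.lowpass_k < k

    def test_circulant_pseudoinverse_oracle(self):
        """Recovery equals solving the full N x N circulant system by SVD
        pseudo-inverse with the same relative cutoff, N = 16."""
        n = 16
        g = WavenumberGrid.from_span(1000.0, 160.0, n)
        design = CascadeDesign.from_ratios([1, 3], 160.0, rho=0.42)
        resp = system_response(design, g)
        rng = np.random.default_rng(21)
        x = Spectrum(g, rng.uniform(0, 1, n))
        trace = simulate_trace(x, resp)
        reg_tau = 1e-3
        res = recover_spectrum(trace, resp, reg_tau=reg_tau, lowpass_k=None)
        idx = (np.arange(n)[None, :] - np.arange(n)[:, None]) % n
        a_mat = g.delta_nu * resp.values[idx]
        x_pinv = np.linalg.pinv(a_mat, rcond=reg_tau) @ trace.values
        np.testing.assert_allclose(
            res.spectrum_hat.intensities, x_pinv, atol=1e-8
        )
        # suppression pattern matches the numerical-rank pattern
        mag = np.abs(resp.dft)
        expected_suppressed = set(np.nonzero(mag <= reg_tau * mag.max())[0])
        assert set(res.suppressed_bins.tolist()) == expected_suppressed

    def test_all_suppressed_unrecoverable(self, grid):
        # a dead (all-zero) response has no divisor support anywhere
        from convspec.device_model import SystemResponse

        dead = SystemResponse(grid, np.zeros(grid.n_points))
        trace = MeasurementTrace(np.zeros(grid.n_points), grid)
        with pytest.raises(UnrecoverableError):
            recover_spectrum(trace, dead, lowpass_k=None)

    def test_length_mismatch_rejected(self, ternary4_response):
        other = WavenumberGrid.from_span(6250.0, 420.0, 100)
        trace = MeasurementTrace(np.zeros(100), other)
        with pytest.raises(WindowMismatchError):
            recover_spectrum(trace, ternary4_response)

    def test_noiseless_dynamic_range_linearity(self, ternary4_response, grid):
        """A 1e-6 secondary feature is recovered exactly in noiseless
        conditions: detectability limits come only from noise."""
        tiny = 1e-6
        x = _bandlimited(grid, 30, seed=9)
        vals = x.intensities + tiny * np.roll(x.intensities, 50)
        x2 = Spectrum(grid, vals)
        trace = simulate_trace(x2, ternary4_response)
        res = recover_spectrum(trace, ternary4_response, x_ref=x2)
        assert res.epsilon <= 1e-9


class TestRelativeError:
    def test_trivial_values(self, grid):
        x = random_broadband(grid, seed=1)
        zero = Spectrum(grid, np.zeros(grid.n_points))
        twice = Spectrum(grid, 2 * x.intensities)
        assert relative_error(x, x) == 0.0
        assert relative_error(zero, x) == pytest.approx(1.0)
        assert relative_error(twice, x) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            relative_error(x, zero)


class TestLowpass:
    def test_identity_and_mean(self, rng):
        v = rng.normal(size=200)
        np.testing.assert_allclose(lowpass_filter(v, 100), v, atol=1e-10)
        np.testing.assert_allclose(
            lowpass_filter(v, 0), np.full(200, v.mean()), atol=1e-10
        )

    def test_white_noise_variance_ratio(self):
        """Parseval: an ideal low-pass at k keeps (2k+1)/N of white-noise
        variance (k = 78, N = 200)."""
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(30):
            v = rng.normal(size=200)
            f = lowpass_filter(v - v.mean(), 78)
            ratios.append(np.var(f) / np.var(v - v.mean()))
        assert np.mean(ratios) == pytest.approx((2 * 78 + 1) / 200, rel=0.05)


class TestNoiseLinearity:
    def test_epsilon_proportional_to_sigma(self, ternary4_response, grid):
        """Median recovery error scales linearly with the injected noise
        level across sigma in {0.25%, 0.5%, 1%} within 15%."""
        x = random_broadband(grid, seed=6)
        rng = np.random.default_rng(0)
        seeds = rng.integers(0, 2**31 - 1, size=50)
        ratios = []
        for sigma in (0.0025, 0.005, 0.01):
            eps = [
                recover_spectrum(
                    simulate_trace(x, ternary4_response, noise_sigma=sigma,
                                   seed=int(s)),
                    ternary4_response,
                    x_ref=x,
                ).epsilon
                for s in seeds
            ]
            ratios.append(np.median(eps) / sigma)
        assert max(ratios) / min(ratios) <= 1.15


class TestDispersionCorrection:
    MODEL = DispersionModel(n_g0=2.0, slope=2.0 * 1e-2 / 420.0, anchor_nu=6460.0)

    def test_zero_slope_identity(self, ternary4_response):
        model = DispersionModel(n_g0=2.0, slope=0.0, anchor_nu=6460.0)
        out = dispersion_correct(ternary4_response, model)
        np.testing.assert_allclose(out.values, ternary4_response.values, atol=1e-9)

    def test_roundtrip_small_slope(self, ternary4_response):
        """apply_dispersion then dispersion_correct recovers the
        dispersionless response within 1% relative RMS for
        |slope * span / n_g0| <= 1e-2."""
        dispersed = apply_dispersion(ternary4_response, self.MODEL)
        corrected = dispersion_correct(dispersed, self.MODEL)
        rms = np.sqrt(np.mean((corrected.values - ternary4_response.values) ** 2))
        scale = np.sqrt(np.mean(ternary4_response.values**2))
        assert rms / scale <= 0.01

    def test_correction_improves_recovery(self, ternary4, ternary4_response, grid):
        """On a fixed broadband fixture, recovery through a dispersed system
        is strictly worse without the correction pipeline."""
        x = random_broadband(grid, seed=13)
        sched = phase_schedule(ternary4, grid.n_points)
        trace = simulate_trace(
            x, ternary4_response, schedule=sched, dispersion=self.MODEL
        )
        dispersed_static = apply_dispersion(ternary4_response, self.MODEL)
        naive = recover_spectrum(trace, ternary4_response, x_ref=x)
        corrected = recover_dispersed(
            trace, dispersed_static, self.MODEL, x_ref=x
        )
        assert corrected.epsilon < naive.epsilon


class TestShiftRegistration:
    def test_known_offset_recovered(self, ternary4, ternary4_response, grid):
        x = random_broadband(grid, seed=17)
        reference = simulate_trace(x, ternary4_response)
        drifted = simulate_trace(
            x, ternary4_response, schedule=phase_schedule(ternary4, 200, t0=17)
        )
        corrected, offset = shift_register_correct(drifted, reference)
        assert offset == 17
        np.testing.assert_allclose(corrected.values, reference.values, rtol=1e-9)

    def test_zero_offset_identity(self, ternary4_response, grid):
        x = random_broadband(grid, seed=18)
        t = simulate_trace(x, ternary4_response)
        corrected, offset = shift_register_correct(t, t)
        assert offset == 0
        np.testing.assert_array_equal(corrected.values, t.values)

    def test_scale_invariance(self, ternary4_response, grid):
        x = random_broadband(grid, seed=19)
        ref = simulate_trace(x, ternary4_response)
        drift = MeasurementTrace(np.roll(ref.values, 23) * 7.5, grid)
        _, offset = shift_register_correct(drift, ref)
        assert offset == 23

    def test_flat_trace_ambiguous(self, grid):
        flat = MeasurementTrace(np.ones(grid.n_points), grid)
        with pytest.raises(AmbiguousRegistrationError):
            shift_register_correct(flat, flat)


class TestPeakRules:
    def test_dual_peak_resolved_on_clean_dip(self):
        v = np.zeros(50)
        v[10] = 1.0
        v[11] = 0.5
        v[12] = 0.95
        assert dual_peak_resolved(v)
        v[11] = 0.9  # dip too shallow: 0.9 > 0.85 * 0.95
        assert not dual_peak_resolved(v)

    def test_single_peak_not_resolved(self):
        v = np.exp(-0.5 * ((np.arange(100) - 50) / 3.0) ** 2)
        assert not dual_peak_resolved(v)

    def test_noise_floor_scale(self, rng):
        resid = rng.normal(0, 0.01, size=5000)
        assert robust_noise_floor(resid) == pytest.approx(0.01, rel=0.1)
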