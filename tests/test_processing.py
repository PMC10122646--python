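"""Quantum-mimic transform chain and supporting signal processing."""

import numpy as np
import pytest

from qmoct import (
    AScan,
    Layer,
    LayeredObject,
    SpectralGrid,
    Spectrum,
    analytic_signal,
    assemble_scan,
    autocorrelate,
    depth_axis,
    fft_stack,
    fragment,
    remove_autocorrelation_peak,
    resample_to_k,
    standard_ascan,
    synthesize_spectrum,
)
from qmoct.processing import NonUniformGridError, peak_pixels


def brute_force_autocorrelation(x):
    """c[m] = sum_k x[k] conj(x[k-m]), the double-loop reference."""
    n = len(x)
    out = np.zeros(2 * n - 1, dtype=complex)
    for m in range(-(n - 1), n):
        acc = 0.0 + 0.0j
        for k in range(n):
            if 0 <= k - m < n:
                acc += x[k] * np.conj(x[k - m])
        out[m + n - 1] = acc
    return out


class TestAnalyticSignal:
    def test_constant_spectrum_maps_to_zero(self, grid):
        spec = Spectrum(k=grid.k, intensity=np.full(1024, 3.7), grid=grid)
        assert np.allclose(analytic_signal(spec), 0.0)

    def test_cosine_becomes_complex_exponential(self, grid):
        tau = 400.0
        spec = Spectrum(k=grid.k, intensity=np.cos(tau * grid.k), grid=grid)
        sig = analytic_signal(spec)
        expected = np.exp(1j * tau * grid.k)
        # compare away from the window edges where the Hilbert pair degrades
        core = slice(100, -100)
        err = np.abs(sig[core] - expected[core] * np.exp(
            -1j * np.angle(expected[core][0] / sig[core][0])
        ))
        assert np.median(err) < 0.05

    def test_real_part_identity(self, grid, single_reflector_spectrum):
        spec = single_reflector_spectrum
        sig = analytic_signal(spec)
        recon = sig.real + spec.intensity.mean()
        scale = np.max(np.abs(spec.intensity))
        assert np.max(np.abs(recon - spec.intensity)) / scale < 1e-10

    def test_nonuniform_grid_rejected(self):
        k = np.array([1.0, 2.0, 4.0, 8.0])
        spec = Spectrum(k=k, intensity=np.ones(4))
        with pytest.raises(NonUniformGridError, match="resample"):
            analytic_signal(spec)


class TestFragment:
    def test_default_split_of_1024(self):
        frags = fragment(np.arange(1024), 50)
        assert len(frags) == 50
        assert all(len(f) == 20 for f in frags)

    def test_exact_division(self):
        frags = fragment(np.arange(100), 50)
        assert all(len(f) == 2 for f in frags)

    def test_partition_covers_prefix(self):
        sig = np.random.default_rng(0).normal(size=1024)
        frags = fragment(sig, 50)
        assert np.array_equal(np.concatenate(frags), sig[:1000])

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            fragment(np.arange(10), 0)
        with pytest.raises(ValueError):
            fragment(np.arange(10), 11)


class TestAutocorrelate:
    def test_singleton(self):
        assert np.array_equal(autocorrelate(np.array([1.0])), [1.0])

    def test_two_ones(self):
        assert np.array_equal(autocorrelate(np.array([1.0, 1.0])), [1.0, 2.0, 1.0])

    def test_matches_brute_force_on_complex_fragment(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20) + 1j * rng.normal(size=20)
        fast = autocorrelate(x)
        slow = brute_force_autocorrelation(x)
        assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-12

    def test_zero_lag_is_energy(self):
        x = np.array([1.0, -2.0, 3.0])
        assert autocorrelate(x)[2] == pytest.approx(np.sum(x * x))


class TestFftStack:
    def test_default_geometry(self, grid, single_reflector_spectrum):
        st = fft_stack(single_reflector_spectrum)
        assert st.values.shape == (50, 1024)
        assert np.all(st.values >= 0)
        assert np.all(np.isfinite(st.values))

    def test_all_zero_spectrum(self, grid):
        spec = Spectrum(k=grid.k, intensity=np.zeros(1024), grid=grid)
        assert np.allclose(fft_stack(spec).values, 0.0)

    def test_dc_offset_invariance(self, grid, single_reflector_spectrum):
        spec = single_reflector_spectrum
        shifted = Spectrum(k=spec.k, intensity=spec.intensity + 123.0, grid=grid)
        a, b = fft_stack(spec).values, fft_stack(shifted).values
        assert np.max(np.abs(a - b)) / np.max(a) < 1e-10

    def test_dispersionless_rows_peak_at_same_column(self, grid,
                                                     single_reflector_spectrum):
        st = fft_stack(single_reflector_spectrum)
        pk = peak_pixels(st, min_relative_energy=0.02)
        pk = pk[pk >= 0]
        assert pk.max() - pk.min() <= 1

    def test_strong_dispersion_drifts_monotonically(self, grid):
        """The back-surface artefact walks across fragments with slope sign
        following the layer GVD sign — the signature the regressor reads."""
        for g, sign in ((5000.0, 1), (-5000.0, -1)):
            obj = LayeredObject(
                150.0, layers=(Layer(300.0, g, 1.0),), front_reflectivity=0.15
            )
            st = fft_stack(synthesize_spectrum(obj, grid))
            pk = peak_pixels(st, min_relative_energy=0.02)
            rows = np.nonzero(pk >= 0)[0]
            slope = np.polyfit(rows, pk[rows], 1)[0]
            assert sign * slope > 1.0
            # smoothed trajectory is monotone
            smooth = np.convolve(pk[rows], np.ones(5) / 5, mode="valid")
            assert np.all(sign * np.diff(smooth) > -1.0)

    def test_pad_too_short(self, single_reflector_spectrum):
        with pytest.raises(ValueError):
            fft_stack(single_reflector_spectrum, pad_length=16)


class TestDepthAxis:
    def test_origin_and_calibration(self, grid):
        pitch, axis = depth_axis(grid)
        assert axis[0] == 0.0
        assert axis.size == 1024
        assert axis[200] == pytest.approx(218.0, abs=1.0)
        assert axis[280] - axis[200] == pytest.approx(87.0, abs=1.0)
        assert axis[600] - axis[320] == pytest.approx(306.0, abs=1.0)

    def test_pitch_formula(self, grid):
        pitch, _ = depth_axis(grid, pad_length=2048)
        assert pitch == pytest.approx(0.5 * 2 * np.pi / (2048 * grid.delta_k))


class TestStandardAscan:
    def test_envelope_only_has_no_deep_peak(self, grid):
        obj = LayeredObject(100.0, front_reflectivity=0.0)
        a = standard_ascan(synthesize_spectrum(obj, grid))
        assert np.argmax(a.magnitude) < 8

    def test_single_interface_argmax(self, grid, single_reflector_spectrum):
        a = standard_ascan(single_reflector_spectrum)
        peak = np.argmax(a.magnitude[8:]) + 8
        assert peak == round(218.0 / a.depth_pitch_um)

    def test_two_interfaces_heights_follow_reflectivities(self, grid):
        obj = LayeredObject(
            150.0, layers=(Layer(300.0, 0.0, 0.9),), front_reflectivity=0.3
        )
        a = standard_ascan(synthesize_spectrum(obj, grid))
        p1 = round(150.0 / a.depth_pitch_um)
        p2 = round(450.0 / a.depth_pitch_um)
        h1 = a.magnitude[p1 - 5: p1 + 5].max()
        h2 = a.magnitude[p2 - 5: p2 + 5].max()
        assert h2 > h1


class TestResampleToK:
    def test_idempotent_on_uniform_k_input(self, grid, single_reflector_spectrum):
        spec = single_reflector_spectrum
        lam_nm = 2 * np.pi / spec.k * 1e3  # descending
        out = resample_to_k(spec.intensity[::-1], lam_nm[::-1])
        back = np.interp(spec.k, out.k, out.intensity)
        scale = np.max(np.abs(spec.intensity))
        core = slice(5, -5)
        assert np.max(np.abs(back[core] - spec.intensity[core])) / scale < 1e-5

    def test_linearisation_sharpens_constant_delay_fringe(self, grid):
        """A fixed-delay fringe sampled uniformly in wavelength is chirped in
        k; resampling restores a transform-limited peak."""
        lam_nm = np.linspace(760.0, 920.0, 1024)
        k = 2 * np.pi / (lam_nm * 1e-3)
        intensity = np.exp(-((lam_nm - 840) ** 2) / (2 * 40 ** 2)) * (
            1 + np.cos(2 * 400.0 * k)
        )
        chirped = Spectrum(
            k=np.linspace(k.min(), k.max(), 1024), intensity=intensity
        )

        def fwhm(spec):
            a = standard_ascan(spec, pad_factor=4)
            mag = a.magnitude
            p = int(np.argmax(mag[32:])) + 32
            half = mag[p] / 2
            left = p - np.argmax(mag[p::-1] < half)
            right = p + np.argmax(mag[p:] < half)
            return right - left

        resampled = resample_to_k(intensity, lam_nm)
        assert fwhm(resampled) < fwhm(chirped)

    def test_reversed_axis_rejected(self):
        lam = np.linspace(920.0, 760.0, 64)
        with pytest.raises(ValueError):
            resample_to_k(np.ones(64), lam)


class TestAssembleScan:
    def test_identity_on_single_ascan(self):
        a = AScan(magnitude=np.arange(8, dtype=float), depth_pitch_um=1.0)
        out = assemble_scan([a])
        assert out.shape == (1, 8)
        assert np.array_equal(out[0], a.magnitude)

    def test_three_hundred_rows_order_preserved(self):
        rows = [np.full(16, float(i)) for i in range(300)]
        out = assemble_scan(rows)
        assert out.shape == (300, 16)
        assert np.array_equal(out[:, 0], np.arange(300.0))

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            assemble_scan([np.zeros(4), np.zeros(5)])


class TestRemoveAutocorrelationPeak:
    def test_flat_region_unchanged(self):
        a = AScan(magnitude=np.full(100, 2.0), depth_pitch_um=1.0)
        out = remove_autocorrelation_peak(a, 50, 5)
        assert np.allclose(out.magnitude, 2.0)

    def test_synthetic_peak_removed(self):
        base = np.full(200, 1.0)
        base[95:106] += 50.0 * np.exp(-((np.arange(95, 106) - 100) ** 2) / 4)
        a = AScan(magnitude=base, depth_pitch_um=1.0)
        out = remove_autocorrelation_peak(a, 100, 8)
        assert out.magnitude[95:106].max() < 0.05 * base.max()
        assert np.array_equal(out.magnitude[:90], base[:90])

    def test_zero_half_width_single_sample(self):
        mag = np.array([1.0, 1.0, 9.0, 1.0, 1.0])
        out = remove_autocorrelation_peak(
            AScan(magnitude=mag, depth_pitch_um=1.0), 2, 0
        )
        assert out.magnitude[2] == pytest.approx(1.0)

    def test_window_outside_axis(self):
        a = AScan(magnitude=np.ones(10), depth_pitch_um=1.0)
        with pytest.raises(ValueError):
            remove_autocorrelation_peak(a, 9, 3)
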