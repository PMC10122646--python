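"""Forward spectral simulator, noise model and object generator."""

import numpy as np
import pytest

from qmoct import (
    Layer,
    LayeredObject,
    NoiseConfig,
    ObjectGeneratorConfig,
    SpectralGrid,
    add_noise,
    make_dataset,
    random_object,
    standard_ascan,
    synthesize_spectrum,
)
from qmoct.forward_model import (
    REFERENCE_FRINGE_AMPLITUDE,
    DepthOverflowError,
    GeneratorConfigError,
)


def _peak_pixel(spectrum, pad_factor=16):
    """Fine-zero-padded A-scan argmax as a depth oracle (skips DC residue)."""
    a = standard_ascan(spectrum, pad_factor=pad_factor)
    skip = 8 * pad_factor
    return (np.argmax(a.magnitude[skip:]) + skip) / pad_factor * (
        a.depth_pitch_um * pad_factor
    )


class TestGrid:
    def test_uniform_wavenumber_sampling(self, grid):
        dk = np.diff(grid.k)
        assert np.allclose(dk, dk[0])
        assert dk[0] > 0
        assert grid.k.size == 1024

    def test_span_edges_match_wavelength_window(self, grid):
        assert grid.k[0] == pytest.approx(2 * np.pi / 0.920)
        assert grid.k[-1] == pytest.approx(2 * np.pi / 0.760)

    def test_resolution_sets_envelope_width(self):
        """The magnitude point-spread FWHM equals the configured axial
        resolution (single-reflector simulation oracle)."""
        grid = SpectralGrid()
        obj = LayeredObject(front_distance_um=300.0, front_reflectivity=1.0)
        a = standard_ascan(synthesize_spectrum(obj, grid), pad_factor=16)
        mag = a.magnitude
        peak = int(np.argmax(mag[100:])) + 100
        half = mag[peak] / 2
        left = peak - np.argmax(mag[peak::-1] < half)
        right = peak + np.argmax(mag[peak:] < half)
        fwhm = (right - left) * a.depth_pitch_um
        assert fwhm == pytest.approx(4.08, rel=0.05)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            SpectralGrid(n_samples=1)
        with pytest.raises(ValueError):
            SpectralGrid(span_nm=-5)


class TestSynthesizeSpectrum:
    def test_no_reflectors_gives_pure_envelope(self, grid):
        obj = LayeredObject(front_distance_um=100.0, front_reflectivity=0.0)
        spec = synthesize_spectrum(obj, grid)
        assert np.allclose(spec.intensity, grid.envelope())

    def test_real_and_nonnegative(self, grid, fig1_object):
        spec = synthesize_spectrum(fig1_object, grid)
        assert np.isrealobj(spec.intensity)
        assert np.all(spec.intensity >= 0)

    def test_single_interface_peak_at_reflector_depth(self, grid):
        obj = LayeredObject(front_distance_um=218.0, front_reflectivity=0.8)
        z = _peak_pixel(synthesize_spectrum(obj, grid))
        assert z == pytest.approx(218.0, abs=1.0)

    def test_peak_position_linear_in_depth(self, grid):
        """Argmax pixel regresses on reflector depth with slope 1/pitch."""
        depths = np.linspace(80, 900, 20)
        pixels = []
        for z in depths:
            obj = LayeredObject(front_distance_um=float(z), front_reflectivity=0.8)
            a = standard_ascan(synthesize_spectrum(obj, grid))
            pixels.append(np.argmax(a.magnitude[8:]) + 8)
        slope, intercept = np.polyfit(depths, pixels, 1)
        pred = slope * depths + intercept
        ss_res = np.sum((pixels - pred) ** 2)
        ss_tot = np.sum((pixels - np.mean(pixels)) ** 2)
        assert 1 - ss_res / ss_tot > 0.999
        assert slope == pytest.approx(1 / a.depth_pitch_um, rel=1e-3)

    def test_dispersion_broadens_back_surface_peak(self, grid):
        """Increasing beta2*L monotonically widens the layer's exit peak."""
        widths = []
        for g in (0.0, 1500.0, 3000.0, 4500.0):
            obj = LayeredObject(
                100.0,
                layers=(Layer(300.0, g, 1.0),),
                front_reflectivity=0.05,
            )
            a = standard_ascan(synthesize_spectrum(obj, grid), pad_factor=4)
            mag = a.magnitude
            peak = int(np.argmax(mag[32:])) + 32
            half = mag[peak] / 2
            left = peak - np.argmax(mag[peak::-1] < half)
            right = peak + np.argmax(mag[peak:] < half)
            widths.append(right - left)
        assert all(b >= a for a, b in zip(widths, widths[1:]))
        assert widths[-1] > widths[0]

    def test_depth_overflow_raises(self, grid):
        obj = LayeredObject(500.0, layers=(Layer(900.0, 0.0, 0.5),))
        with pytest.raises(DepthOverflowError):
            synthesize_spectrum(obj, grid)


class TestAddNoise:
    def test_none_is_identity(self, grid, single_reflector_spectrum):
        out = add_noise(single_reflector_spectrum, NoiseConfig(snr_db=None))
        assert out is single_reflector_spectrum

    def test_deterministic_under_seed(self, single_reflector_spectrum):
        cfg = NoiseConfig(snr_db=30.0, seed=7)
        a = add_noise(single_reflector_spectrum, cfg)
        b = add_noise(single_reflector_spectrum, cfg)
        assert np.array_equal(a.intensity, b.intensity)

    def test_measured_snr_matches_configured(self, grid):
        """20 log10(A_ref / sigma_hat) over 1e5 samples lands on the dial."""
        obj = LayeredObject(300.0, front_reflectivity=1.0)
        spec = synthesize_spectrum(obj, grid)
        rng = np.random.default_rng(0)
        noises = []
        cfg = NoiseConfig(snr_db=30.0)
        for _ in range(100):
            noisy = add_noise(spec, cfg, rng=rng)
            noises.append(noisy.intensity - spec.intensity)
        sigma_hat = np.std(np.concatenate(noises))
        measured = 20 * np.log10(REFERENCE_FRINGE_AMPLITUDE / sigma_hat)
        assert measured == pytest.approx(30.0, abs=0.1)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(snr_db=-3.0)


class TestRandomObject:
    def test_degenerate_ranges_give_exact_object(self):
        cfg = ObjectGeneratorConfig(
            n_interfaces_range=(3, 3),
            thickness_range_um=(100.0, 100.0),
            gvd_range=(2000.0, 2000.0),
            reflectivity_range=(0.5, 0.5),
            front_distance_range_um=(150.0, 150.0),
        )
        obj = random_object(cfg, seed=0)
        assert obj.front_distance_um == 150.0
        assert len(obj.layers) == 2
        assert all(l.thickness_um == 100.0 and l.gvd == 2000.0 for l in obj.layers)

    def test_sampling_statistics(self):
        cfg = ObjectGeneratorConfig(
            n_interfaces_range=(2, 2), thickness_range_um=(50.0, 100.0)
        )
        rng = np.random.default_rng(1)
        gvds = np.array(
            [random_object(cfg, rng).layers[0].gvd for _ in range(1000)]
        )
        assert gvds.min() >= -5000 and gvds.max() <= 5000
        se = 10000 / np.sqrt(12) / np.sqrt(1000)
        assert abs(gvds.mean()) < 3 * se

    def test_same_seed_same_sequence(self):
        cfg = ObjectGeneratorConfig()
        a = [random_object(cfg, np.random.default_rng(5)) for _ in range(1)]
        b = [random_object(cfg, np.random.default_rng(5)) for _ in range(1)]
        assert a == b

    def test_impossible_ranges_raise_config_error(self, grid):
        cfg = ObjectGeneratorConfig(
            n_interfaces_range=(5, 5),
            thickness_range_um=(500.0, 600.0),
            max_retries=20,
        )
        with pytest.raises(GeneratorConfigError):
            random_object(cfg, seed=0, grid=grid)


class TestMakeDataset:
    def test_count_and_shapes(self, grid):
        cfg = ObjectGeneratorConfig(n_interfaces_range=(1, 3),
                                    thickness_range_um=(50.0, 150.0))
        pairs = list(make_dataset(3, cfg, grid, NoiseConfig(snr_db=30.0), seed=0))
        assert len(pairs) == 3
        for stack, profile in pairs:
            assert stack.values.shape == (50, 1024)
            assert len(profile) == 1024

    def test_zero_gvd_generator_encodes_half(self, grid):
        cfg = ObjectGeneratorConfig(
            n_interfaces_range=(2, 2),
            thickness_range_um=(50.0, 150.0),
            gvd_range=(0.0, 0.0),
        )
        _, profile = next(iter(make_dataset(1, cfg, grid, seed=3)))
        assert np.all(profile.values == 0.5)

    def test_stream_bit_identical_across_runs(self, grid):
        cfg = ObjectGeneratorConfig(n_interfaces_range=(1, 2),
                                    thickness_range_um=(50.0, 150.0))
        noise = NoiseConfig(snr_db=25.0)
        a = list(make_dataset(2, cfg, grid, noise, seed=11))
        b = list(make_dataset(2, cfg, grid, noise, seed=11))
        for (sa, pa), (sb, pb) in zip(a, b):
            assert np.array_equal(sa.values, sb.values)
            assert np.array_equal(pa.values, pb.values)
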