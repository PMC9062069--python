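"""Reconstruction chain: k-linearisation, fixed pattern, dispersion,
apodisation, Fourier transform."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.signal import hilbert

from pvocta.phantom import (Layer, PhantomSpec, SourceModel,
                            make_preset_phantom, simulate_calibration_fringe,
                            simulate_volume)
from pvocta.reconstruct import (DispersionModel, ReconstructionOptions,
                                calibrate_k, compensate_dispersion,
                                fft_reconstruct, optimize_dispersion,
                                reconstruct_volume, remove_fixed_pattern,
                                resample_to_k, shape_spectrum)

from conftest import measure_fwhm_px


class TestCalibrateK:
    def test_linear_sweep_gives_identity_map(self):
        src = SourceModel(samples_per_ascan=512)
        curve = calibrate_k(simulate_calibration_fringe(src))
        m = np.arange(512)
        # interior: Hilbert edge effects are confined to the ends
        assert np.max(np.abs(curve.sample_map - m)[6:-6]) < 1e-3 * 512 / 100
        assert curve.is_identity(tol=0.2)

    def test_chirped_sweep_map_inverts_generating_k(self):
        src = SourceModel(samples_per_ascan=512, chirp2=0.25, chirp3=0.1)
        curve = calibrate_k(simulate_calibration_fringe(src))
        m = np.arange(512, dtype=float)
        true_map = np.interp(src.k_uniform(), src.k_of_sample(), m)
        assert np.max(np.abs(curve.sample_map - true_map)) < 0.05

    def test_stalled_sweep_rejected(self):
        # the sweep stalls mid-record: the unwrapped phase is not
        # strictly monotone and the calibration must be refused
        u = np.linspace(0.0, 1.0, 512)
        phase = np.where(u < 0.33, 60 * np.pi * u,
                         np.where(u < 0.66, 60 * np.pi * 0.33,
                                  60 * np.pi * (u - 0.33)))
        with pytest.raises(ValueError, match="monotone"):
            calibrate_k(np.cos(phase))

    def test_too_few_cycles_rejected(self):
        m = np.arange(512)
        fringe = np.cos(2 * np.pi * 3 * m / 512)   # 3 cycles
        with pytest.raises(ValueError, match="cycles"):
            calibrate_k(fringe)


class TestResampleToK:
    def test_identity_map_returns_input(self):
        src = SourceModel(samples_per_ascan=512)
        curve = calibrate_k(simulate_calibration_fringe(src))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 512))
        y = resample_to_k(x, curve)
        # identity within spline interpolation error at the grid points
        assert np.allclose(y[:, 8:-8], x[:, 8:-8], atol=5e-3 * np.abs(x).max())

    def test_resampling_restores_transform_limited_peak(self, mirror_chirped):
        src = mirror_chirped["source"]
        spec = mirror_chirped["spec"]
        raw = mirror_chirped["raw"]
        pitch = src.axial_pitch_um(spec.n)
        limit = src.transform_limited_fwhm_um(spec.n)
        dm = DispersionModel(src.dispersion_a2, src.dispersion_a3)

        def width(resample):
            cv = reconstruct_volume(raw, ReconstructionOptions(
                window="rect", dispersion=dm, resample=resample,
                remove_fixed_pattern=False))
            return measure_fwhm_px(cv.data[0, 0, 0]) * pitch

        assert width(True) == pytest.approx(limit, rel=0.15)
        assert width(False) > 2.0 * width(True)

    def test_white_noise_variance_preserved(self):
        src = SourceModel(samples_per_ascan=512, chirp2=0.2)
        curve = calibrate_k(simulate_calibration_fringe(src))
        rng = np.random.default_rng(1)
        x = rng.normal(size=(64, 512))
        y = resample_to_k(x, curve)
        assert y.var() == pytest.approx(x.var(), rel=0.2)


class TestFixedPattern:
    def test_constant_pattern_removed_exactly(self):
        pattern = np.sin(np.linspace(0, 40, 512))
        vol = np.tile(pattern, (3, 2, 16, 1))
        assert np.allclose(remove_fixed_pattern(vol), 0.0)

    def test_injected_pattern_line_drops_20db(self):
        # fixed-pattern fringe at a known depth across a volume of
        # uncorrelated scatterers: the depth-invariant line must drop
        src = SourceModel(samples_per_ascan=512)
        from pvocta.protocol import ScanProtocol
        prot = ScanProtocol(0.32, 0.04, 5, 5, repeats=1,
                            samples_per_ascan=512, sweep_rate_hz=1.7e6)
        spec = PhantomSpec(
            layers=[Layer(center_um=300.0, thickness_um=100.0,
                          reflectivity=0.3, density=8)],
            fixed_pattern_amplitude=2.0, fixed_pattern_depth_um=60.0,
            dc_level=0.0)
        raw, _ = simulate_volume(spec, src, prot, seed=3)
        spectra = raw.dequantized()
        fp_px = round(60.0 / (spec.n * src.axial_pitch_um(spec.n)))

        def line_power(s):
            A = np.abs(fft_reconstruct(s))
            return A[..., fp_px - 2: fp_px + 3].max(axis=-1).mean()

        before = line_power(spectra)
        after = line_power(remove_fixed_pattern(spectra))
        assert 20 * math.log10(before / after) >= 20.0

    def test_pattern_free_volume_peak_unchanged(self):
        # mean over many uncorrelated A-scans ~ 0: signal survives
        src = SourceModel(samples_per_ascan=512)
        from pvocta.protocol import ScanProtocol
        prot = ScanProtocol(0.64, 0.02, 5, 5, repeats=1,
                            samples_per_ascan=512, sweep_rate_hz=1.7e6)
        spec = PhantomSpec(
            layers=[Layer(center_um=300.0, thickness_um=150.0,
                          reflectivity=0.3, density=6)],
            dc_level=0.0)
        raw, _ = simulate_volume(spec, src, prot, seed=4)
        spectra = raw.dequantized()
        a = np.abs(fft_reconstruct(spectra)).max(axis=-1)
        b = np.abs(fft_reconstruct(remove_fixed_pattern(spectra))).max(axis=-1)
        assert np.mean(np.abs(a - b) / a) < 0.01

    def test_needs_two_ascans(self):
        with pytest.raises(ValueError):
            remove_fixed_pattern(np.zeros((1, 512)))


class TestDispersion:
    def test_zero_model_is_identity_up_to_analytic_signal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 512))
        y = compensate_dispersion(x, DispersionModel(0.0, 0.0))
        assert np.allclose(y, hilbert(x, axis=-1))

    def test_matched_compensation_restores_psf(self, mirror_chirped):
        src = mirror_chirped["source"]
        spec = mirror_chirped["spec"]
        raw = mirror_chirped["raw"]
        pitch = src.axial_pitch_um(spec.n)
        limit = src.transform_limited_fwhm_um(spec.n)

        def width(dm):
            cv = reconstruct_volume(raw, ReconstructionOptions(
                window="rect", dispersion=dm, remove_fixed_pattern=False))
            return measure_fwhm_px(cv.data[0, 0, 0]) * pitch

        good = width(DispersionModel(src.dispersion_a2, src.dispersion_a3))
        none = width(None)
        wrong = width(DispersionModel(-src.dispersion_a2,
                                      -src.dispersion_a3))
        assert good == pytest.approx(limit, rel=0.15)
        assert none > 2.0 * good
        assert wrong > 1.5 * none   # wrong sign roughly doubles the phase

    def test_optimizer_recovers_injected_coefficients(self):
        # inject dispersion into the structured phantom and search for it
        spec, src0, prot = make_preset_phantom("retina_small")
        src = dataclasses.replace(src0, dispersion_a2=12.0,
                                  dispersion_a3=3.0)
        sub = dataclasses.replace(prot, fov_mm_y=0.02)  # 4 BM rows suffice
        raw, _ = simulate_volume(spec, src, sub, seed=21)
        spectra = resample_to_k(raw.dequantized(),
                                calibrate_k(raw.calibration_fringe))
        spectra = remove_fixed_pattern(spectra)
        dm = optimize_dispersion(spectra[2, 0])
        assert dm.a2 == pytest.approx(12.0, rel=0.10)

    def test_optimizer_zero_dispersion_input(self, retina_clean_run):
        raw = retina_clean_run["raw"]
        spectra = resample_to_k(raw.dequantized()[30, 0],
                                calibrate_k(raw.calibration_fringe))
        dm = optimize_dispersion(spectra)
        assert abs(dm.a2) < 2.0    # below the coarse grid step

    def test_optimizer_flat_bscan_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="flat"):
            dm = optimize_dispersion(np.ones((8, 512)))
        assert dm.a2 == 0.0 and dm.a3 == 0.0


class TestShapeSpectrum:
    def test_rect_window_is_identity(self):
        x = np.random.default_rng(3).normal(size=(4, 256))
        assert shape_spectrum(x, "rect") is x

    def test_hann_sidelobe_below_minus_30db(self):
        # flat-envelope single-tone fringe: first sidelobe of the Hann
        # window is -31.5 dB
        m = np.arange(512)
        fringe = np.cos(2 * np.pi * 60.123 * m / 512)
        A = np.abs(fft_reconstruct(shape_spectrum(fringe, "hann")))
        pk = int(np.argmax(A))
        # first local minimum after the main lobe, then the sidelobe peak
        i = pk
        while A[i + 1] < A[i]:
            i += 1
        side = A[i:i + 40].max()
        assert 20 * math.log10(side / A[pk]) <= -30.0

    def test_hann_mainlobe_broadening_factor(self):
        m = np.arange(512)
        fringe = np.cos(2 * np.pi * 60.0 * m / 512)
        w_rect = measure_fwhm_px(
            np.abs(fft_reconstruct(fringe)), min_index=50)
        w_hann = measure_fwhm_px(
            np.abs(fft_reconstruct(shape_spectrum(fringe, "hann"))),
            min_index=50)
        # magnitude-domain widths: |sinc| FWHM 1.21 bins, Hann 2.0 bins
        assert w_hann / w_rect == pytest.approx(2.0 / 1.2067, rel=0.03)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            shape_spectrum(np.zeros((2, 256)), np.ones(128))


class TestFFTReconstruct:
    def test_zero_spectrum_zero_ascan(self):
        out = fft_reconstruct(np.zeros((3, 256)))
        assert out.shape == (3, 512)
        assert np.all(out == 0)

    def test_parseval_identity(self):
        # exact single-bin tone: all energy in the kept one-sided half
        m = np.arange(256)
        x = np.exp(2j * np.pi * 60 * m / 256)
        A = fft_reconstruct(x, pad_length=256)
        assert (np.abs(A) ** 2).sum() == pytest.approx(
            256 * (np.abs(x) ** 2).sum(), rel=1e-6)
        # zero-padded noise: truncation leaks ~1% into the discarded half
        rng = np.random.default_rng(4)
        y = hilbert(rng.normal(size=256))
        B = fft_reconstruct(y, pad_length=1024)
        assert (np.abs(B) ** 2).sum() == pytest.approx(
            1024 * (np.abs(y) ** 2).sum(), rel=0.02)

    def test_end_to_end_linearity(self):
        src = SourceModel(samples_per_ascan=256)
        curve = calibrate_k(simulate_calibration_fringe(src))
        rng = np.random.default_rng(5)
        I = rng.normal(size=(4, 256))
        J = rng.normal(size=(4, 256))
        a, b = 1.7, -0.6

        def rec(s):
            s = resample_to_k(s, curve)
            s = compensate_dispersion(s, DispersionModel(3.0, 1.0))
            s = shape_spectrum(s, "hann")
            return fft_reconstruct(s)

        lhs = rec(a * I + b * J)
        rhs = a * rec(I) + b * rec(J)
        assert np.allclose(lhs, rhs, atol=1e-6 * np.abs(rhs).max())

    def test_static_zero_noise_phase_identical_between_repeats(self):
        spec, src, _ = make_preset_phantom("mirror")
        from pvocta.protocol import ScanProtocol
        prot = ScanProtocol(0.04, 0.01, 5, 5, repeats=3,
                            samples_per_ascan=512, sweep_rate_hz=1.7e6)
        raw, _ = simulate_volume(spec, src, prot, seed=6)
        cv = reconstruct_volume(raw, ReconstructionOptions(
            remove_fixed_pattern=False))
        assert np.array_equal(cv.data[:, 0], cv.data[:, 1])
        assert np.array_equal(cv.data[:, 0], cv.data[:, 2])
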