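"""ESF/MTF estimation, ROI statistics and the NPW detectability index."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import erf

from phantomqc import (MTFCurve, SimulationConfig, analytic_gaussian_mtf,
                       analyze_image, compute_dprime, compute_esf, compute_sdnr,
                       compute_snr, esf_to_mtf, extract_edge_profile,
                       locate_inserts, mtf_percent_frequencies, render_phantom)
from phantomqc.fleet import analytic_dprime
from phantomqc.localization import ROI, InsertLocalization
from phantomqc.synthetic import PhantomImage, gaussian_mtf50

RNG = np.random.default_rng(42)
PITCH = 0.15


def synthetic_edge_samples(sigma_mm, n=20_000, span_mm=6.0, rng=RNG):
    """Closed-form Gaussian-blurred step sampled at random distances."""
    d = rng.uniform(-span_mm, span_mm, n)
    if sigma_mm == 0:
        v = (d > 0).astype(float)
    else:
        v = 0.5 * (1.0 + erf(d / (sigma_mm * math.sqrt(2))))
    return d, 100.0 + 900.0 * v


class TestESF:
    def test_ideal_step_is_step_within_one_bin(self):
        d, v = synthetic_edge_samples(0.0)
        esf = compute_esf(d, v, bin_width_mm=PITCH / 8)
        below = esf.values[esf.bin_centers_mm < -esf.bin_width_mm]
        above = esf.values[esf.bin_centers_mm > esf.bin_width_mm]
        assert np.allclose(below, 0.0, atol=1e-9)
        assert np.allclose(above, 1.0, atol=1e-9)

    def test_gaussian_blurred_edge_matches_cdf(self):
        d, v = synthetic_edge_samples(0.5)
        esf = compute_esf(d, v, bin_width_mm=PITCH / 8)
        expected = 0.5 * (1 + erf(esf.bin_centers_mm / (0.5 * math.sqrt(2))))
        rms = np.sqrt(np.mean((esf.values - expected) ** 2))
        assert rms < 0.01

    def test_binning_permutation_invariant(self):
        d, v = synthetic_edge_samples(0.3, n=5000)
        esf1 = compute_esf(d, v, PITCH / 8)
        perm = np.random.default_rng(1).permutation(d.size)
        esf2 = compute_esf(d[perm], v[perm], PITCH / 8)
        assert np.array_equal(esf1.values, esf2.values)

    def test_one_sided_samples_rejected(self):
        d = np.abs(RNG.uniform(0.1, 3.0, 500))
        with pytest.raises(ValueError, match="not spanned"):
            compute_esf(d, np.ones_like(d), PITCH / 8)

    def test_contract_bins_and_span(self):
        d, v = synthetic_edge_samples(0.5)
        esf = compute_esf(d, v, PITCH / 8)
        widths = np.diff(esf.bin_centers_mm)
        assert np.allclose(widths, esf.bin_width_mm)
        assert esf.bin_centers_mm.size >= 128
        assert esf.bin_centers_mm.min() < -2.0 < 2.0 < esf.bin_centers_mm.max()


class TestMTF:
    def test_zero_frequency_modulation_is_one(self):
        d, v = synthetic_edge_samples(0.5)
        curve = esf_to_mtf(compute_esf(d, v, PITCH / 8), PITCH)
        assert curve.modulation[0] == 1.0

    @pytest.mark.parametrize("sigma", [0.2, 0.5, 1.0])
    def test_matches_analytic_gaussian_mtf(self, sigma):
        """Oracle equivalence on closed-form edges, 3% absolute to MTF10."""
        d, v = synthetic_edge_samples(sigma, span_mm=8.0)
        curve = esf_to_mtf(compute_esf(d, v, PITCH / 8), PITCH)
        f10 = gaussian_mtf50(sigma, 0.1)
        sel = curve.freq_lpmm <= f10
        err = np.abs(curve.modulation[sel]
                     - analytic_gaussian_mtf(sigma, curve.freq_lpmm[sel]))
        assert err.max() < 0.03

    def test_sharp_system_high_modulation_at_half_lpmm(self, geometry):
        """sigma=0: only pixel aperture and windowing attenuate the edge."""
        cfg = SimulationConfig(psf_sigma_mm=0.0, noise_gain=0.0,
                               read_noise_sd=0.0, pixel_spacing_mm=0.15)
        image, _ = render_phantom(geometry, cfg)
        loc = locate_inserts(image)
        edge = [e for e in loc.edge_segments if e.orientation == "near_vertical"][0]
        dist, vals = extract_edge_profile(image, edge)
        curve = esf_to_mtf(compute_esf(dist, vals, PITCH / 8), PITCH)
        at_half = np.interp(0.5, curve.freq_lpmm, curve.modulation)
        assert at_half >= 0.95

    def test_percent_frequencies_linear_curve(self):
        f = np.linspace(0, 2, 2001)
        curve = MTFCurve(freq_lpmm=f, modulation=1 - f / 2)
        freqs = mtf_percent_frequencies(curve)
        assert freqs[0.5] == pytest.approx(1.0, abs=1e-9)
        assert freqs[0.2] == pytest.approx(1.6, abs=1e-9)
        assert freqs[0.1] == pytest.approx(1.8, abs=1e-9)

    def test_percent_frequencies_monotone_for_gaussian(self):
        f = np.linspace(0, 3.4, 600)
        curve = MTFCurve(freq_lpmm=f, modulation=analytic_gaussian_mtf(0.5, f))
        freqs = mtf_percent_frequencies(curve)
        assert freqs[0.5] < freqs[0.2] < freqs[0.1]

    def test_uncrossed_level_reported_as_none(self):
        f = np.linspace(0, 1, 100)
        curve = MTFCurve(freq_lpmm=f, modulation=np.full_like(f, 0.9))
        freqs = mtf_percent_frequencies(curve)
        assert freqs[0.5] is None


def _fake_localization(shape, al_center, bg_center, size=32):
    roi = lambda c: ROI(center_px=c, size_px=(size, size))
    return InsertLocalization(cu_roi=roi((shape[0] // 2, shape[1] // 2)),
                              al_roi=roi(al_center), background_roi=roi(bg_center),
                              edge_segments=[], estimated_rotation_deg=2.5)


def _fake_image(al_mean, bg_mean, bg_sd, shape=(200, 400), spacing=0.15, seed=0):
    """Image whose fake ROIs have exactly the requested statistics."""
    rng = np.random.default_rng(seed)
    px = np.full(shape, bg_mean, float)
    loc = _fake_localization(shape, (100, 100), (100, 300))
    for roi_obj, mean in ((loc.al_roi, al_mean), (loc.background_roi, bg_mean)):
        block = rng.standard_normal(roi_obj.size_px)
        block = (block - block.mean()) / block.std(ddof=1)
        px[roi_obj.slices] = mean + bg_sd * block
    img = PhantomImage(pixels=np.clip(np.rint(px), 0, 4095).astype(np.uint16),
                       pixel_spacing_mm=spacing)
    # rebuild with float pixels to keep the statistics exact
    img.pixels = px
    return img, loc


class TestRoiStatistics:
    def test_snr_no_division_masking(self):
        px = np.full((100, 100), 100.0)
        px[50, 50] = 101.0
        img = PhantomImage(pixels=px, pixel_spacing_mm=0.15)
        loc = _fake_localization((100, 100), (50, 50), (50, 80), size=32)
        snr = compute_snr(img, loc)
        assert np.isfinite(snr) and snr > 1000

    def test_snr_zero_sd_is_error(self):
        img = PhantomImage(pixels=np.full((100, 100), 100.0), pixel_spacing_mm=0.15)
        loc = _fake_localization((100, 100), (50, 50), (50, 80), size=32)
        with pytest.raises(ValueError, match="degenerate"):
            compute_snr(img, loc)

    def test_sdnr_identical_rois_is_zero(self):
        img, loc = _fake_image(1000.0, 1000.0, 25.0)
        assert compute_sdnr(img, loc) == pytest.approx(0.0, abs=0.05)

    def test_sdnr_hand_value(self):
        img, loc = _fake_image(1200.0, 1000.0, 25.0)
        assert compute_sdnr(img, loc) == pytest.approx(8.0, abs=1e-9)

    def test_thicker_al_insert_raises_sdnr(self, geometry):
        from phantomqc.synthetic import al_mean_signal
        vals = {}
        for thickness in (4.0, 4.8):
            means = {"carrier": 2000.0, "cu": 120.0,
                     "al": al_mean_signal(2000.0, thickness)}
            cfg = SimulationConfig(pixel_spacing_mm=0.3, mean_signal=means, seed=2)
            image, _ = render_phantom(geometry, cfg)
            vals[thickness] = compute_sdnr(image, locate_inserts(image))
        assert vals[4.8] > vals[4.0]


class TestDetectability:
    def _flat_curve(self, fmax=100.0, n=20_000):
        f = np.linspace(0.0, fmax, n)
        return MTFCurve(freq_lpmm=f, modulation=np.ones_like(f))

    def test_zero_contrast_gives_zero(self):
        img, loc = _fake_image(1000.0, 1000.0, 25.0, seed=3)
        # force exactly equal means
        img.pixels[loc.al_roi.slices] = img.pixels[loc.background_roi.slices]
        curve = self._flat_curve(3.3, 512)
        assert compute_dprime(img, loc, curve, curve, 0.3) == pytest.approx(0.0)

    @pytest.mark.parametrize("diameter", [0.3, 4.0])
    def test_parseval_limit_flat_mtf(self, diameter):
        """MTF == 1, extended cutoff: d' -> SDNR * (D/a) * sqrt(pi)/2."""
        img, loc = _fake_image(1200.0, 1000.0, 25.0)
        sdnr = compute_sdnr(img, loc)
        curve = self._flat_curve()
        d = compute_dprime(img, loc, curve, curve, diameter, cutoff_lpmm=100.0)
        expected = sdnr * (diameter / img.pixel_spacing_mm) * math.sqrt(math.pi) / 2
        assert d == pytest.approx(expected, rel=0.02)

    def test_large_disk_easier_than_small(self, noisy_default_iq):
        assert noisy_default_iq.dprime_40 > noisy_default_iq.dprime_03

    def test_monotone_in_contrast_noise_and_size(self):
        base = analytic_dprime(10.0, 0.15, 0.3, 1.0)
        assert analytic_dprime(12.0, 0.15, 0.3, 1.0) > base       # more contrast
        assert analytic_dprime(8.0, 0.15, 0.3, 1.0) < base        # less contrast
        assert analytic_dprime(10.0, 0.15, 0.5, 1.0) < base       # more blur
        assert analytic_dprime(10.0, 0.15, 0.3, 2.0) > base       # larger disk

    def test_monotone_under_pointwise_mtf_improvement(self):
        img, loc = _fake_image(1200.0, 1000.0, 25.0)
        f = np.linspace(0, 1 / 0.3, 512)
        good = MTFCurve(freq_lpmm=f, modulation=analytic_gaussian_mtf(0.3, f))
        bad = MTFCurve(freq_lpmm=f, modulation=analytic_gaussian_mtf(0.6, f))
        assert (compute_dprime(img, loc, good, good, 0.3)
                > compute_dprime(img, loc, bad, bad, 0.3))


class TestAnalyzeImage:
    def test_all_metrics_finite_and_unflagged(self, noisy_default_iq):
        for name, value in noisy_default_iq.to_dict().items():
            assert value is not None and np.isfinite(value), name
        assert noisy_default_iq.qc_flags == ()

    def test_threshold_ordering_invariant(self, noisy_default_iq):
        iq = noisy_default_iq
        assert iq.hmtf50 < iq.hmtf20 < iq.hmtf10
        assert iq.vmtf50 < iq.vmtf20 < iq.vmtf10

    def test_orientation_symmetry_for_isotropic_psf(self, noisy_default_iq):
        iq = noisy_default_iq
        assert abs(iq.hmtf50 - iq.vmtf50) / iq.hmtf50 <= 0.05

    def test_zero_slant_flagged(self, geometry):
        cfg = SimulationConfig(pixel_spacing_mm=0.3, seed=4)
        image, _ = render_phantom(replace(geometry, rotation_deg=0.0), cfg)
        iq = analyze_image(image)
        assert "zero_slant_warning" in iq.qc_flags

    def test_determinism(self, geometry):
        cfg = SimulationConfig(pixel_spacing_mm=0.3, seed=17)
        iq1 = analyze_image(render_phantom(geometry, cfg)[0])
        iq2 = analyze_image(render_phantom(geometry, cfg)[0])
        assert iq1 == iq2
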