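"""Generator contracts: rendering, noise law, photometrics, processing, DICOM."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from phantomqc import (DIALECTS, PhantomGeometry, SimulationConfig,
                       analytic_gaussian_mtf, apply_processing, locate_inserts,
                       render_phantom, write_dicom)
from phantomqc.metadata import AcquisitionSetup
from phantomqc.synthetic import (ConfigurationError, al_mean_signal,
                                 gaussian_mtf50)


class TestGeometryValidation:
    def test_defaults_match_phantom_blueprint(self):
        geo = PhantomGeometry()
        assert geo.cu_size_mm == 50.0 and geo.cu_thickness_mm == 2.0
        assert geo.al_size_mm == 10.0 and geo.al_thickness_mm == 4.0
        assert geo.carrier_thickness_mm == 5.0

    @pytest.mark.parametrize("kwargs", [
        {"rotation_deg": 45.0},
        {"rotation_deg": -1.0},
        {"cu_size_mm": -5.0},
        {"cu_center_mm": (10.0, 10.0)},          # exceeds carrier
        {"al_center_mm": (35.0, 35.0)},          # overlaps Cu
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PhantomGeometry(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        {"mean_signal": {"carrier": 9000, "cu": 120, "al": 1350}},  # > 12 bit
        {"mean_signal": {"carrier": 2000, "cu": 2000, "al": 1350}},  # no edge
        {"pixel_spacing_mm": 0.0},
        {"noise_gain": -1.0},
        {"photometric": "RGB"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestRendering:
    def test_degenerate_render_is_piecewise_constant(self, geometry):
        cfg = SimulationConfig(psf_sigma_mm=0.0, noise_gain=0.0,
                               read_noise_sd=0.0, pixel_spacing_mm=0.3)
        geo = replace(geometry, rotation_deg=0.0)
        image, truth = render_phantom(geo, cfg)
        means = cfg.signal_map
        # interior pixels of each region take exactly the region mean
        cy, cx = truth.insert_centers_px["cu"]
        ay, ax = truth.insert_centers_px["al"]
        cy, cx, ay, ax = int(cy), int(cx), int(ay), int(ax)
        assert np.all(image.pixels[cy - 20:cy + 20, cx - 20:cx + 20] == means["cu"])
        assert np.all(image.pixels[ay - 5:ay + 5, ax - 5:ax + 5] == means["al"])
        assert np.all(image.pixels[:20, :20] == means["carrier"])
        # only boundary pixels may take intermediate values
        vals, counts = np.unique(image.pixels, return_counts=True)
        core = counts[np.isin(vals, list(means.values()))].sum()
        assert core / image.pixels.size > 0.95

    def test_insert_area_ratio_is_25(self, fast_noiseless):
        """Attenuation mass (conserved by blur and box-averaging) recovers
        the ideal-scene Cu/Al area ratio (50/10)^2 = 25."""
        image, truth, cfg = fast_noiseless
        means = cfg.signal_map
        deficit = means["carrier"] - image.as_exposure()
        split = image.pixels.shape[1] * 2 // 3  # Cu left of, Al right of
        cu_area = deficit[:, :split].sum() / (means["carrier"] - means["cu"])
        al_area = deficit[:, split:].sum() / (means["carrier"] - means["al"])
        assert cu_area / al_area == pytest.approx(25.0, rel=0.01)

    def test_determinism_bit_identical(self, geometry, fast_config):
        img1, _ = render_phantom(geometry, fast_config)
        img2, _ = render_phantom(geometry, fast_config)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_different_seeds_differ(self, geometry, fast_config):
        img1, _ = render_phantom(geometry, fast_config)
        img2, _ = render_phantom(geometry, replace(fast_config, seed=99))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_region_means_within_3se_of_noise_law(self, geometry):
        cfg = SimulationConfig(psf_sigma_mm=0.5, pixel_spacing_mm=0.15, seed=21)
        image, truth = render_phantom(geometry, cfg)
        loc = locate_inserts(image)
        means = cfg.signal_map
        for roi, region in ((loc.cu_roi, "cu"), (loc.al_roi, "al"),
                            (loc.background_roi, "carrier")):
            vals = roi.pixels(image.as_exposure()).ravel()
            se = math.sqrt(cfg.noise_gain * means[region]
                           + cfg.read_noise_sd ** 2) / math.sqrt(vals.size)
            assert abs(vals.mean() - means[region]) < 3 * se, region

    def test_noise_variance_law_chi2(self, geometry):
        """Empirical per-region variance matches gain*mean + read^2 (alpha=0.01)."""
        cfg = SimulationConfig(seed=5)
        image, _ = render_phantom(geometry, cfg)
        loc = locate_inserts(image)
        means = cfg.signal_map
        # carrier patch in the lower image half, clear of both inserts
        corner = image.as_exposure()[560:720, 80:400]
        for vals, region in ((loc.cu_roi.pixels(image.as_exposure()), "cu"),
                             (corner, "carrier")):
            vals = vals.ravel()
            n = vals.size
            assert n >= 10_000
            expected_var = cfg.noise_gain * means[region] + cfg.read_noise_sd ** 2
            statistic = (n - 1) * vals.var(ddof=1) / expected_var
            lo = stats.chi2.ppf(0.005, n - 1)
            hi = stats.chi2.ppf(0.995, n - 1)
            assert lo < statistic < hi, region

    def test_photometric_duality_before_noise(self, geometry):
        base = dict(pixel_spacing_mm=0.3, noise_gain=0.0, read_noise_sd=0.0)
        img2, _ = render_phantom(geometry, SimulationConfig(photometric="MONOCHROME2", **base))
        img1, _ = render_phantom(geometry, SimulationConfig(photometric="MONOCHROME1", **base))
        maxval = 2 ** 12 - 1
        assert np.array_equal(img1.pixels, maxval - img2.pixels)

    def test_geometry_outside_image_rejected(self):
        geo = PhantomGeometry(carrier_size_mm=(60.0, 60.0),
                              cu_center_mm=(30.0, 30.0), cu_size_mm=30.0,
                              al_center_mm=(52.0, 52.0), al_size_mm=10.0)
        # valid geometry but implausibly small image for the pitch
        with pytest.raises(ConfigurationError):
            render_phantom(geo, SimulationConfig(pixel_spacing_mm=2.0))


class TestAnalyticOracles:
    def test_gaussian_mtf_normalization(self):
        assert analytic_gaussian_mtf(0.7, 0.0) == 1.0
        assert analytic_gaussian_mtf(0.0, 3.0) == 1.0

    def test_gaussian_mtf_half_point_closed_form(self):
        f_half = math.sqrt(math.log(2) / (2 * math.pi ** 2 * 0.25))
        assert analytic_gaussian_mtf(0.5, f_half) == pytest.approx(0.5, abs=1e-12)
        assert gaussian_mtf50(0.5) == pytest.approx(f_half)

    def test_gaussian_mtf_domain_errors(self):
        with pytest.raises(ValueError):
            analytic_gaussian_mtf(-0.1, 1.0)
        with pytest.raises(ValueError):
            analytic_gaussian_mtf(0.5, -1.0)

    def test_al_thickness_to_contrast_monotone(self):
        carrier = 2000.0
        thicknesses = [3.0, 4.0, 4.8, 6.0]
        contrasts = [carrier - al_mean_signal(carrier, t) for t in thicknesses]
        assert all(a < b for a, b in zip(contrasts, contrasts[1:]))


class TestProcessing:
    def test_constant_image_stays_constant(self):
        from phantomqc.synthetic import PhantomImage
        img = PhantomImage(pixels=np.full((64, 64), 1500, np.uint16),
                           pixel_spacing_mm=0.15)
        out = apply_processing(img)
        assert np.unique(out.pixels).size == 1
        assert out.processed

    def test_double_processing_rejected(self, noisy_default):
        image, _, _ = noisy_default
        once = apply_processing(image)
        with pytest.raises(ValueError):
            apply_processing(once)


@pytest.fixture(scope="module")
def small_image(geometry):
    cfg = SimulationConfig(pixel_spacing_mm=0.4, seed=3)
    image, _ = render_phantom(geometry, cfg)
    return image


class TestDicomWriting:
    def test_no_ei_tag_when_dialect_excludes_it(self, small_image, tmp_path):
        import pydicom
        from phantomqc.metadata import EI_TAG_CANDIDATES
        path = tmp_path / "x.dcm"
        write_dicom(small_image, AcquisitionSetup(), DIALECTS["sparse"], path)
        ds = pydicom.dcmread(path)
        assert all(tag not in ds for tag in EI_TAG_CANDIDATES)

    def test_mas_zero_dialect_stores_zero(self, small_image, tmp_path):
        import pydicom
        path = tmp_path / "x.dcm"
        write_dicom(small_image, AcquisitionSetup(), DIALECTS["mas_zero"], path,
                    mas=20.0)
        ds = pydicom.dcmread(path)
        assert int(ds[0x0018, 0x1152].value) == 0

    def test_round_trip_kvp_mas_exact(self, small_image, tmp_path):
        from phantomqc.metadata import harvest_exposure_metadata
        path = tmp_path / "x.dcm"
        write_dicom(small_image, AcquisitionSetup(), DIALECTS["reference"], path,
                    mas=12.5, kvp=81.0)
        meta = harvest_exposure_metadata(path)
        assert meta.kvp == 81.0
        assert meta.mas == 12.5

    def test_file_bytes_deterministic(self, small_image, tmp_path):
        p1, p2 = tmp_path / "a.dcm", tmp_path / "b.dcm"
        for p in (p1, p2):
            write_dicom(small_image, AcquisitionSetup(), DIALECTS["reference"], p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pixel_data_round_trip(self, small_image, tmp_path):
        import pydicom
        path = tmp_path / "x.dcm"
        write_dicom(small_image, AcquisitionSetup(), DIALECTS["reference"], path)
        ds = pydicom.dcmread(path)
        assert np.array_equal(ds.pixel_array, small_image.pixels)
        assert float(ds.ImagerPixelSpacing[0]) == small_image.pixel_spacing_mm
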