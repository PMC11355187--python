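"""Synthetic two-insert QC phantom images with analytic ground truth.

The phantom emulated here is the simple radiography QC object used for
remote/automated image-quality surveillance: a thin PMMA carrier plate with a
5 cm x 5 cm copper square (its slightly slanted edges feed the slanted-edge
MTF analysis) and a 1 cm x 1 cm aluminium square (signal, SNR and SDNR
reference).  The imaging model is a grey-level surrogate of the detector
chain, not a photon-transport simulation: region mean signals are specified
directly, the system PSF is an isotropic (optionally anisotropic) Gaussian,
and noise follows the affine variance law ``var = gain * mean + read^2``.

Because every stage is analytic, each rendered image carries a
:class:`GroundTruth` with the exact MTF, expected SNR/SDNR and true insert
centers, which the analysis modules are validated against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomGeometry",
    "SimulationConfig",
    "VendorDialect",
    "GroundTruth",
    "PhantomImage",
    "render_phantom",
    "apply_processing",
    "write_dicom",
    "analytic_gaussian_mtf",
    "gaussian_mtf50",
    "al_mean_signal",
    "DIALECTS",
]

#: scene oversampling relative to the detector pitch (sub-pixel edge placement
#: accuracy is then ~pitch/16, far below the ESF bin width of pitch/8)
OVERSAMPLE = 8

#: aluminium linear attenuation surrogate (per mm) used to map insert
#: thickness to mean signal; roughly mu_Al at the ~50 keV effective energy of
#: an 80 kVp beam behind 2 mm Cu
AL_MU_PER_MM = 0.0994

# fixed constants of the "for presentation" processing surrogate
LUT_CENTER_FRAC = 0.5     # sigmoid center as a fraction of full scale
LUT_WIDTH_FRAC = 1 / 6.0  # sigmoid width as a fraction of full scale
UNSHARP_SIGMA_PX = 1.0    # 5x5 Gaussian kernel (sigma 1 px, truncated at 2 sigma)
UNSHARP_WEIGHT = 0.6


class ConfigurationError(ValueError):
    """Invalid geometry/simulation configuration."""


@dataclass(frozen=True)
class PhantomGeometry:
    """Physical layout of the QC phantom, in mm.

    Coordinates are (row, col) from the top-left of the carrier; the whole
    phantom is rotated in-plane by ``rotation_deg`` about the carrier center
    (the small slant required by slanted-edge MTF estimation).
    """

    carrier_size_mm: tuple[float, float] = (120.0, 120.0)
    carrier_thickness_mm: float = 5.0
    cu_size_mm: float = 50.0
    cu_thickness_mm: float = 2.0
    al_size_mm: float = 10.0
    al_thickness_mm: float = 4.0
    cu_center_mm: tuple[float, float] = (35.0, 35.0)
    al_center_mm: tuple[float, float] = (35.0, 95.0)
    rotation_deg: float = 2.5

    def __post_init__(self) -> None:
        for name in ("carrier_thickness_mm", "cu_size_mm", "cu_thickness_mm",
                     "al_size_mm", "al_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if any(s <= 0 for s in self.carrier_size_mm):
            raise ConfigurationError("carrier_size_mm must be > 0")
        if not 0.0 <= self.rotation_deg < 45.0:
            raise ConfigurationError("rotation_deg must lie in [0, 45)")
        for center, size, label in ((self.cu_center_mm, self.cu_size_mm, "Cu"),
                                    (self.al_center_mm, self.al_size_mm, "Al")):
            for c, ext in zip(center, self.carrier_size_mm):
                if c - size / 2 < 0 or c + size / 2 > ext:
                    raise ConfigurationError(f"{label} square exceeds carrier")
        # axis-aligned separation in phantom coordinates (rigid rotation
        # preserves it)
        dr = abs(self.cu_center_mm[0] - self.al_center_mm[0])
        dc = abs(self.cu_center_mm[1] - self.al_center_mm[1])
        half = (self.cu_size_mm + self.al_size_mm) / 2
        if dr < half and dc < half:
            raise ConfigurationError("Cu and Al squares overlap")


def _as_sigma_pair(value) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    pair = tuple(float(v) for v in value)
    if len(pair) != 2:
        raise ConfigurationError("psf_sigma_mm must be scalar or (row, col)")
    return pair


@dataclass(frozen=True)
class SimulationConfig:
    """Imaging-chain surrogate parameters.

    ``psf_sigma_mm`` may be a scalar (isotropic PSF) or a ``(row, col)`` pair;
    an anisotropic PSF emulates direction-dependent blur such as a poorly cut
    ("blunt") Cu edge or detector asymmetry.  ``offset_jitter_sd`` adds one
    zero-mean DC offset per exposure, emulating dark-level / auto-ranging
    drift: it moves absolute means (hence SNR) but leaves signal differences
    (hence SDNR) untouched.
    """

    pixel_spacing_mm: float = 0.15
    psf_sigma_mm: tuple[float, float] | float = 0.25
    mean_signal: Mapping[str, float] | tuple = (
        ("al", 1350.0), ("carrier", 2000.0), ("cu", 120.0))
    noise_gain: float = 1.0
    read_noise_sd: float = 5.0
    offset_jitter_sd: float = 0.0
    bit_depth: int = 12
    seed: int = 0
    processed: bool = False
    photometric: str = "MONOCHROME2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "psf_sigma_mm", _as_sigma_pair(self.psf_sigma_mm))
        means = dict(self.mean_signal)
        missing = {"carrier", "cu", "al"} - set(means)
        if missing:
            raise ConfigurationError(f"mean_signal missing regions: {sorted(missing)}")
        object.__setattr__(self, "mean_signal",
                           tuple(sorted((k, float(v)) for k, v in means.items())))
        if self.pixel_spacing_mm <= 0:
            raise ConfigurationError("pixel_spacing_mm must be > 0")
        if min(self.psf_sigma_mm) < 0:
            raise ConfigurationError("psf_sigma_mm must be >= 0")
        if self.noise_gain < 0 or self.read_noise_sd < 0 or self.offset_jitter_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.photometric not in ("MONOCHROME1", "MONOCHROME2"):
            raise ConfigurationError("photometric must be MONOCHROME1|MONOCHROME2")
        maxval = 2 ** self.bit_depth - 1
        for region, value in self.signal_map.items():
            if not 0 <= value <= maxval:
                raise ConfigurationError(
                    f"mean_signal[{region}]={value} outside {self.bit_depth}-bit range")
        if self.signal_map["cu"] == self.signal_map["carrier"]:
            raise ConfigurationError("mean_signal[cu] must differ from carrier (no edge)")

    @property
    def signal_map(self) -> dict[str, float]:
        return dict(self.mean_signal)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class VendorDialect:
    """How a (simulated) vendor populates exposure-related DICOM tags.

    Real fleets show exactly these pathologies: exposure index stored under
    non-standard addresses, mAs rounded or zeroed, organ dose always zero,
    entrance dose / EI simply absent.
    """

    name: str
    ei_tag_path: tuple[tuple[int, int], ...] = ((0x0018, 0x1411),)
    include_entrance_dose: bool = True
    include_ei: bool = True
    mas_rounding: str = "none"  # none | integer | zero
    organ_dose_always_zero: bool = False
    presentation_intent_present: bool = True

    def __post_init__(self) -> None:
        if self.mas_rounding not in ("none", "integer", "zero"):
            raise ConfigurationError("mas_rounding must be none|integer|zero")
        if self.include_ei and not self.ei_tag_path:
            raise ConfigurationError("ei_tag_path empty while include_ei=True")


#: shipped dialects spanning the tag pathologies seen in multi-center fleets
DIALECTS: dict[str, VendorDialect] = {
    "reference": VendorDialect(name="reference"),
    "ei_nonstandard": VendorDialect(
        name="ei_nonstandard", ei_tag_path=((0x0018, 0x1405),)),
    "mas_integer": VendorDialect(name="mas_integer", mas_rounding="integer"),
    "mas_zero": VendorDialect(name="mas_zero", mas_rounding="zero"),
    "organ_zero": VendorDialect(name="organ_zero", organ_dose_always_zero=True),
    "sparse": VendorDialect(
        name="sparse", include_ei=False, include_entrance_dose=False,
        presentation_intent_present=False),
}


@dataclass(frozen=True)
class GroundTruth:
    """Analytic expectations for a rendered phantom (test oracle)."""

    mtf_sigma_mm: tuple[float, float]
    expected_snr: float
    expected_sdnr: float
    region_means: dict[str, float]
    insert_centers_px: dict[str, tuple[float, float]]
    rotation_deg: float


@dataclass
class PhantomImage:
    """A phantom exposure: pixel matrix plus the conventions needed to read it."""

    pixels: np.ndarray  # uint16, (rows, cols)
    pixel_spacing_mm: float
    photometric: str = "MONOCHROME2"
    bit_depth: int = 12
    processed: bool = False

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def as_exposure(self) -> np.ndarray:
        """Pixel values normalized so that higher value = more exposure."""
        arr = self.pixels.astype(np.float64)
        if self.photometric == "MONOCHROME1":
            arr = self.max_value - arr
        return arr


def analytic_gaussian_mtf(sigma_mm: float, f_lpmm) -> np.ndarray | float:
    """MTF of an isotropic Gaussian PSF: ``exp(-2 pi^2 sigma^2 f^2)``."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    f = np.asarray(f_lpmm, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    out = np.exp(-2.0 * math.pi ** 2 * sigma_mm ** 2 * f ** 2)
    return float(out) if np.isscalar(f_lpmm) else out


def gaussian_mtf50(sigma_mm: float, level: float = 0.5) -> float:
    """Frequency (lp/mm) where the Gaussian MTF falls to ``level``."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    return math.sqrt(math.log(1.0 / level) / (2.0 * math.pi ** 2 * sigma_mm ** 2))


def al_mean_signal(carrier_signal: float, al_thickness_mm: float) -> float:
    """Map Al insert thickness to its mean detector signal.

    Monotone Beer-Lambert surrogate: thicker Al attenuates more, so the Al
    mean drops and the Al-to-carrier contrast (hence SDNR) grows.  This is the
    mechanism by which out-of-spec 4.8 mm inserts inflate SDNR.
    """
    return carrier_signal * math.exp(-AL_MU_PER_MM * al_thickness_mm)


# --------------------------------------------------------------------------
# rendering


def _noiseless_key(geometry: PhantomGeometry, config: SimulationConfig):
    return (geometry, replace(config, seed=0))


_RENDER_CACHE: dict = {}
_RENDER_CACHE_MAX = 8


def _blur_and_downsample(scene: np.ndarray, sigma_os: tuple[float, float],
                         n_rows: int, n_cols: int) -> np.ndarray:
    """Gaussian blur at oversampled resolution, then box-average to the grid.

    Column blur and column box-average are applied before the row pair; the
    two axes commute, which keeps the large oversampled array short-lived.
    """
    sr, sc = sigma_os
    if sc > 0:
        scene = ndimage.gaussian_filter1d(scene, sc, axis=1, mode="nearest",
                                          output=np.float32)
    scene = scene.reshape(scene.shape[0], n_cols, OVERSAMPLE).mean(axis=2)
    if sr > 0:
        scene = ndimage.gaussian_filter1d(scene, sr, axis=0, mode="nearest",
                                          output=np.float32)
    scene = scene.reshape(n_rows, OVERSAMPLE, n_cols).mean(axis=1)
    return scene


def _render_expectation(geometry: PhantomGeometry,
                        config: SimulationConfig) -> np.ndarray:
    """Noiseless physical (MONOCHROME2-convention) expectation image."""
    a = config.pixel_spacing_mm
    n_rows = int(round(geometry.carrier_size_mm[0] / a))
    n_cols = int(round(geometry.carrier_size_mm[1] / a))
    if n_rows < 32 or n_cols < 32:
        raise ConfigurationError("geometry/pixel spacing give an implausibly small image")
    sub = a / OVERSAMPLE
    os_rows = n_rows * OVERSAMPLE
    os_cols = n_cols * OVERSAMPLE
    cy = geometry.carrier_size_mm[0] / 2.0
    cx = geometry.carrier_size_mm[1] / 2.0
    theta = math.radians(geometry.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    means = config.signal_map
    scene = np.full((os_rows, os_cols), means["carrier"], dtype=np.float32)
    # evaluate each insert's indicator only inside its padded image-space
    # bounding box (the rotated square's extent plus one pixel of slack)
    for region, center, size in (("cu", geometry.cu_center_mm, geometry.cu_size_mm),
                                 ("al", geometry.al_center_mm, geometry.al_size_mm)):
        h = size / 2.0
        # image position of the rotated insert center
        ry = cos_t * (center[0] - cy) + sin_t * (center[1] - cx) + cy
        rx = -sin_t * (center[0] - cy) + cos_t * (center[1] - cx) + cx
        ext = h * (abs(cos_t) + abs(sin_t)) + a
        i0 = max(0, int((ry - ext) / sub))
        i1 = min(os_rows, int((ry + ext) / sub) + 1)
        j0 = max(0, int((rx - ext) / sub))
        j1 = min(os_cols, int((rx + ext) / sub) + 1)
        if i0 >= i1 or j0 >= j1:
            raise ConfigurationError(f"{region} insert falls outside the image")
        y = (np.arange(i0, i1, dtype=np.float32) + 0.5) * sub - cy
        x = (np.arange(j0, j1, dtype=np.float32) + 0.5) * sub - cx
        dy = y[:, None]
        dx = x[None, :]
        # phantom-frame coordinates q = R(-theta) (p - c) + c
        qy = cos_t * dy - sin_t * dx + cy
        qx = sin_t * dy + cos_t * dx + cx
        inside = ((np.abs(qy - center[0]) <= h) & (np.abs(qx - center[1]) <= h))
        block = scene[i0:i1, j0:j1]
        block[inside] = means[region]
    sigma_os = tuple(s / sub for s in config.psf_sigma_mm)
    return _blur_and_downsample(scene, sigma_os, n_rows, n_cols)


def _expectation_cached(geometry: PhantomGeometry,
                        config: SimulationConfig) -> np.ndarray:
    key = _noiseless_key(geometry, config)
    if key not in _RENDER_CACHE:
        if len(_RENDER_CACHE) >= _RENDER_CACHE_MAX:
            _RENDER_CACHE.pop(next(iter(_RENDER_CACHE)))
        _RENDER_CACHE[key] = _render_expectation(geometry, config)
    return _RENDER_CACHE[key]


def _ground_truth(geometry: PhantomGeometry, config: SimulationConfig) -> GroundTruth:
    means = config.signal_map
    var_bg = config.noise_gain * means["carrier"] + config.read_noise_sd ** 2
    var_al = config.noise_gain * means["al"] + config.read_noise_sd ** 2
    sdnr = abs(means["al"] - means["carrier"]) / math.sqrt(var_bg) if var_bg > 0 else math.inf
    snr = means["al"] / math.sqrt(var_al) if var_al > 0 else math.inf
    a = config.pixel_spacing_mm
    cy = geometry.carrier_size_mm[0] / 2.0
    cx = geometry.carrier_size_mm[1] / 2.0
    theta = math.radians(geometry.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    centers = {}
    for region, c in (("cu", geometry.cu_center_mm), ("al", geometry.al_center_mm)):
        # image position of the (rotated) insert center
        ry = cos_t * (c[0] - cy) + sin_t * (c[1] - cx) + cy
        rx = -sin_t * (c[0] - cy) + cos_t * (c[1] - cx) + cx
        centers[region] = (ry / a - 0.5, rx / a - 0.5)
    return GroundTruth(
        mtf_sigma_mm=tuple(config.psf_sigma_mm),
        expected_snr=snr,
        expected_sdnr=sdnr,
        region_means=means,
        insert_centers_px=centers,
        rotation_deg=geometry.rotation_deg,
    )


def render_phantom(geometry: PhantomGeometry,
                   config: SimulationConfig) -> tuple[PhantomImage, GroundTruth]:
    """Render one phantom exposure plus its analytic ground truth.

    The ideal piecewise-constant scene is evaluated on an 8x-oversampled
    grid, rigidly rotated, convolved with the Gaussian PSF, box-averaged to
    the detector pitch, then noise with variance ``gain*mean + read^2`` is
    added, and the result is clipped and quantized to ``bit_depth`` bits.
    Identical inputs (including seed) give bit-identical images.
    """
    expectation = _expectation_cached(geometry, config)
    rng = np.random.default_rng(config.seed)
    phys = expectation.astype(np.float64)
    if config.noise_gain > 0 or config.read_noise_sd > 0:
        sd = np.sqrt(config.noise_gain * phys + config.read_noise_sd ** 2)
        phys = phys + rng.standard_normal(phys.shape) * sd
    if config.offset_jitter_sd > 0:
        phys = phys + rng.normal(0.0, config.offset_jitter_sd)
    maxval = config.max_value
    # quantize in the physical convention first so the MONOCHROME1 rendering
    # is exactly the bitwise complement of the MONOCHROME2 one
    pixels = np.clip(np.rint(phys), 0, maxval).astype(np.uint16)
    if config.photometric == "MONOCHROME1":
        pixels = (maxval - pixels).astype(np.uint16)
    image = PhantomImage(pixels=pixels, pixel_spacing_mm=config.pixel_spacing_mm,
                         photometric=config.photometric, bit_depth=config.bit_depth,
                         processed=False)
    return image, _ground_truth(geometry, config)


# --------------------------------------------------------------------------
# "for presentation" processing surrogate


def apply_processing(image: PhantomImage) -> PhantomImage:
    """Deterministic surrogate of a vendor "for presentation" rendering.

    A monotone sigmoid grey-level LUT (center at half scale, width one sixth
    of full scale) followed by unsharp-mask edge enhancement (5x5 Gaussian
    kernel, sigma 1 px, weight 0.6).  Edge enhancement raises the measured
    MTF but amplifies high-frequency noise, so SDNR does not improve --
    the directional signature real processed images show.
    """
    if image.processed:
        raise ValueError("image is already processed (no double processing)")
    maxval = image.max_value
    x = image.pixels.astype(np.float64)
    center = LUT_CENTER_FRAC * maxval
    width = LUT_WIDTH_FRAC * maxval
    lut = maxval / (1.0 + np.exp(-(x - center) / width))
    blurred = ndimage.gaussian_filter(lut, UNSHARP_SIGMA_PX, truncate=2.0)
    sharp = lut + UNSHARP_WEIGHT * (lut - blurred)
    pixels = np.clip(np.rint(sharp), 0, maxval).astype(np.uint16)
    return PhantomImage(pixels=pixels, pixel_spacing_mm=image.pixel_spacing_mm,
                        photometric=image.photometric, bit_depth=image.bit_depth,
                        processed=True)


# --------------------------------------------------------------------------
# DICOM writing

SECONDARY_CAPTURE_SOP = "1.2.840.10008.5.1.4.1.1.7"
TAG_EXPOSURE_MAS = (0x0018, 0x1152)       # Exposure, IS (mAs)
TAG_EXPOSURE_UAS = (0x0018, 0x1153)       # ExposureInuAs, IS
TAG_EI_STANDARD = (0x0018, 0x1411)        # ExposureIndex, DS
TAG_ENTRANCE_DOSE = (0x0040, 0x8302)      # EntranceDoseInmGy, DS
TAG_ORGAN_DOSE = (0x0040, 0x0316)         # OrganDose, DS


def write_dicom(image: PhantomImage, acquisition, dialect: VendorDialect,
                path, *, mas: float = 20.0, kvp: float = 80.0,
                exposure_index: float = 250.0, entrance_dose_mgy: float = 0.005,
                organ_dose_dgy: float = 0.0002,
                timestamp: datetime | None = None) -> None:
    """Write a secondary-capture-style DICOM file in the given vendor dialect.

    ``acquisition`` is an :class:`~phantomqc.metadata.AcquisitionSetup` (or
    ``None``); its fields inform descriptive tags only.  Files are
    deterministic for fixed inputs (UIDs derive from content, not the clock).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ts = timestamp or datetime(2022, 6, 1, 12, 0, 0)
    entropy = [dialect.name, str(mas), str(kvp), str(ts),
               str(image.pixels[::97, ::97].tobytes())]
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SECONDARY_CAPTURE_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=entropy + ["sop"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SECONDARY_CAPTURE_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid(entropy_srcs=entropy + ["study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=entropy + ["series"])
    ds.Modality = "DX"
    ds.Manufacturer = f"SyntheticVendor-{dialect.name}"
    ds.ManufacturerModelName = "PhantomQC Simulator"
    ds.PatientName = "QC^Phantom"
    ds.PatientID = "QC"
    ds.ContentDate = ts.strftime("%Y%m%d")
    ds.ContentTime = ts.strftime("%H%M%S")
    ds.StudyDate = ds.ContentDate
    ds.StudyTime = ds.ContentTime

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = image.photometric
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = image.bit_depth
    ds.HighBit = image.bit_depth - 1
    ds.PixelRepresentation = 0
    ds.ImagerPixelSpacing = [image.pixel_spacing_mm, image.pixel_spacing_mm]
    ds.PixelData = np.ascontiguousarray(image.pixels).tobytes()

    ds.ImageType = ["DERIVED", "PRIMARY"] if image.processed else ["ORIGINAL", "PRIMARY"]
    if dialect.presentation_intent_present:
        ds.PresentationIntentType = (
            "FOR PRESENTATION" if image.processed else "FOR PROCESSING")

    ds.KVP = str(kvp)
    if dialect.mas_rounding == "zero":
        ds.add_new(TAG_EXPOSURE_MAS, "IS", 0)
    elif dialect.mas_rounding == "integer":
        ds.add_new(TAG_EXPOSURE_MAS, "IS", int(round(mas)))
    else:
        ds.add_new(TAG_EXPOSURE_MAS, "IS", int(round(mas)))
        ds.add_new(TAG_EXPOSURE_UAS, "IS", int(round(mas * 1000)))
    if dialect.include_ei:
        tag = dialect.ei_tag_path[0]
        ds.add_new(tag, "DS", str(exposure_index))
    if dialect.include_entrance_dose:
        ds.add_new(TAG_ENTRANCE_DOSE, "DS", str(entrance_dose_mgy))
    dose = 0.0 if dialect.organ_dose_always_zero else organ_dose_dgy
    ds.add_new(TAG_ORGAN_DOSE, "DS", str(dose))

    if acquisition is not None:
        if acquisition.sid_cm is not None:
            ds.DistanceSourceToDetector = str(acquisition.sid_cm * 10.0)  # mm
        ds.ProtocolName = acquisition.protocol or ""

    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
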