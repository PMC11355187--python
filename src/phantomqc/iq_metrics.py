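"""Image-quality metrics from a localized phantom image.

The ten surveillance metrics: horizontal and vertical MTF threshold
frequencies at 50/20/10% modulation (slanted-edge method on the Cu square),
SNR and SDNR from the Al square and its carrier background, and the
non-prewhitening (NPW) model-observer detectability index d' for disk
detection tasks of 0.3 mm and 4.0 mm diameter.

Orientation convention: a *near-vertical* Cu edge modulates along the
horizontal axis and therefore measures the *horizontal* MTF; the two edges
of each orientation are averaged.

The d' here uses a white-noise approximation (no measured noise power
spectrum): with signal difference dS, background noise sigma, pixel pitch a,
radially averaged MTF(rho) and disk task spectrum
``T(rho) = (pi D^2/4) * 2 J1(pi D rho)/(pi D rho)``,

    d' = dS/(sigma*a) * sqrt( integral_0^rho_c T^2 MTF^2 2 pi rho d rho )

with the cutoff at the Nyquist frequency 1/(2a) by default.  Absolute values
therefore depend on this documented task model, but the index preserves the
orderings that matter for surveillance (monotone in contrast, noise, disk
size and MTF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .localization import (InsertLocalization, LocalizationFailure,
                           extract_edge_profile, locate_inserts)
from .synthetic import PhantomImage

__all__ = [
    "ESF",
    "MTFCurve",
    "IQResult",
    "compute_esf",
    "esf_to_mtf",
    "mtf_percent_frequencies",
    "compute_snr",
    "compute_sdnr",
    "compute_dprime",
    "analyze_image",
    "METRIC_COLUMNS",
]

#: canonical metric column order for exports
METRIC_COLUMNS = ("SDNR", "SNR", "HMTF50", "HMTF20", "HMTF10",
                  "VMTF50", "VMTF20", "VMTF10", "DPRIME_03", "DPRIME_40")

DPRIME_MODEL = "npw_white_noise"
ZERO_SLANT_THRESHOLD_DEG = 0.2


@dataclass
class ESF:
    """Edge-spread function: mean value per uniform perpendicular-distance bin."""

    bin_centers_mm: np.ndarray
    values: np.ndarray
    bin_width_mm: float
    n_samples_per_bin: np.ndarray


@dataclass
class MTFCurve:
    freq_lpmm: np.ndarray
    modulation: np.ndarray
    orientation: str = ""


@dataclass(frozen=True)
class IQResult:
    snr: float
    sdnr: float
    hmtf50: float | None
    hmtf20: float | None
    hmtf10: float | None
    vmtf50: float | None
    vmtf20: float | None
    vmtf10: float | None
    dprime_03: float
    dprime_40: float
    qc_flags: tuple[str, ...] = ()
    dprime_model: str = DPRIME_MODEL

    def to_dict(self) -> dict[str, float | None]:
        return {"SDNR": self.sdnr, "SNR": self.snr,
                "HMTF50": self.hmtf50, "HMTF20": self.hmtf20,
                "HMTF10": self.hmtf10, "VMTF50": self.vmtf50,
                "VMTF20": self.vmtf20, "VMTF10": self.vmtf10,
                "DPRIME_03": self.dprime_03, "DPRIME_40": self.dprime_40}


def compute_esf(distances_mm: np.ndarray, values: np.ndarray,
                bin_width_mm: float) -> ESF:
    """Bin edge-profile samples into a uniform oversampled ESF.

    Empty interior bins are filled by linear interpolation; the ESF is then
    offset/scale normalized so its asymptotes map to 0 (low side) and 1.
    """
    distances_mm = np.asarray(distances_mm, dtype=float)
    values = np.asarray(values, dtype=float)
    # canonical sample order makes binning exactly permutation-invariant
    order = np.lexsort((values, distances_mm))
    distances_mm = distances_mm[order]
    values = values[order]
    if distances_mm.size < 64:
        raise ValueError("need at least 64 edge samples")
    if (distances_mm < 0).sum() < 16 or (distances_mm > 0).sum() < 16:
        raise ValueError("edge not spanned: samples lie on one side only")
    k0 = int(np.floor(distances_mm.min() / bin_width_mm))
    k1 = int(np.ceil(distances_mm.max() / bin_width_mm))
    idx = np.clip(np.floor(distances_mm / bin_width_mm).astype(int) - k0,
                  0, k1 - k0 - 1)
    nbins = k1 - k0
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=values, minlength=nbins)
    centers = (np.arange(nbins) + k0 + 0.5) * bin_width_mm
    filled = counts > 0
    esf = np.empty(nbins)
    esf[filled] = sums[filled] / counts[filled]
    if not filled.all():
        esf[~filled] = np.interp(centers[~filled], centers[filled], esf[filled])
    # asymptote normalization from the outer 15% of bins on each side
    tail = max(4, nbins // 7)
    lo = float(np.median(esf[:tail]))
    hi = float(np.median(esf[-tail:]))
    if hi == lo:
        raise ValueError("degenerate edge: equal asymptotes")
    esf = (esf - lo) / (hi - lo)
    return ESF(bin_centers_mm=centers, values=esf, bin_width_mm=bin_width_mm,
               n_samples_per_bin=counts)


def esf_to_mtf(esf: ESF, pixel_spacing_mm: float, n_freq: int = 512) -> MTFCurve:
    """Differentiate, window and Fourier-transform an ESF into an MTF curve.

    LSF is the centered finite difference of the ESF; a Hann window centered
    on the LSF peak suppresses tail noise; the modulus of the (zero-padded)
    DFT is normalized at zero frequency and corrected for the transfer
    function of the finite difference.  Reported on a uniform grid up to the
    Nyquist frequency 1/(2 * pixel spacing).
    """
    v = esf.values
    n = v.size
    lsf = np.gradient(v, esf.bin_width_mm)
    peak = int(np.argmax(np.abs(lsf)))
    if peak < n // 10 or peak > n - 1 - n // 10:
        raise ValueError("edge not centered: LSF peak at grid boundary")
    # Hann window symmetric about the peak, widest that fits the grid
    half = min(peak, n - 1 - peak)
    w = np.zeros(n)
    x = np.arange(peak - half, peak + half + 1) - peak
    w[peak - half:peak + half + 1] = np.cos(np.pi * x / (2.0 * half)) ** 2
    lsf_w = lsf * w

    nfft = 1 << max(12, int(math.ceil(math.log2(8 * n))))
    spec = np.abs(np.fft.rfft(lsf_w, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=esf.bin_width_mm)
    if spec[0] == 0:
        raise ValueError("zero-frequency LSF content vanished")
    mtf = spec / spec[0]
    # undo the finite-difference transfer function sin(2 pi f d)/(2 pi f d)
    corr = np.sinc(2.0 * freqs * esf.bin_width_mm)
    valid = corr > 0.2
    mtf[valid] = mtf[valid] / corr[valid]

    nyquist = 1.0 / (2.0 * pixel_spacing_mm)
    grid = np.linspace(0.0, nyquist, n_freq)
    modulation = np.interp(grid, freqs, mtf)
    modulation[0] = 1.0
    return MTFCurve(freq_lpmm=grid, modulation=np.abs(modulation))


def mtf_percent_frequencies(curve: MTFCurve,
                            levels: tuple[float, ...] = (0.5, 0.2, 0.1)
                            ) -> dict[float, float | None]:
    """Frequency (lp/mm) of the first downward crossing of each level.

    A level never crossed below Nyquist maps to ``None`` (recorded by callers
    as a not-evaluable flag, never an exception).
    """
    f = curve.freq_lpmm
    m = curve.modulation
    out: dict[float, float | None] = {}
    for level in levels:
        below = np.nonzero((m[1:] <= level) & (m[:-1] > level))[0]
        if below.size == 0:
            out[level] = None
            continue
        i = below[0]
        frac = (m[i] - level) / (m[i] - m[i + 1])
        out[level] = float(f[i] + frac * (f[i + 1] - f[i]))
    return out


def compute_snr(image: PhantomImage, loc: InsertLocalization) -> float:
    """SNR = mean / sample SD over the Al insert ROI (exposure convention)."""
    vals = loc.al_roi.pixels(image.as_exposure()).ravel()
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate ROI: zero standard deviation")
    return float(vals.mean() / sd)


def compute_sdnr(image: PhantomImage, loc: InsertLocalization) -> float:
    """SDNR = |mean(Al) - mean(background)| / SD(background)."""
    norm = image.as_exposure()
    al = loc.al_roi.pixels(norm).ravel()
    bg = loc.background_roi.pixels(norm).ravel()
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate background ROI: zero standard deviation")
    return float(abs(al.mean() - bg.mean()) / sd)


def _disk_task_spectrum(rho: np.ndarray, diameter_mm: float) -> np.ndarray:
    area = math.pi * diameter_mm ** 2 / 4.0
    x = math.pi * diameter_mm * rho
    out = np.full_like(rho, area, dtype=float)
    nz = x > 1e-12
    out[nz] = area * 2.0 * j1(x[nz]) / x[nz]
    return out


def compute_dprime(image: PhantomImage, loc: InsertLocalization,
                   curve_h: MTFCurve, curve_v: MTFCurve,
                   disk_diameter_mm: float,
                   cutoff_lpmm: float | None = None) -> float:
    """NPW white-noise detectability index for a disk detection task."""
    if disk_diameter_mm <= 0:
        raise ValueError("disk diameter must be > 0")
    norm = image.as_exposure()
    al = loc.al_roi.pixels(norm).ravel()
    bg = loc.background_roi.pixels(norm).ravel()
    delta_s = abs(al.mean() - bg.mean())
    sigma = bg.std(ddof=1)
    if sigma == 0:
        raise ValueError("degenerate background ROI")
    a = image.pixel_spacing_mm
    rho = curve_h.freq_lpmm
    mtf = 0.5 * (curve_h.modulation + np.interp(rho, curve_v.freq_lpmm,
                                                curve_v.modulation))
    cutoff = cutoff_lpmm if cutoff_lpmm is not None else 1.0 / (2.0 * a)
    keep = rho <= cutoff + 1e-12
    rho = rho[keep]
    mtf = mtf[keep]
    task = _disk_task_spectrum(rho, disk_diameter_mm)
    integrand = task ** 2 * mtf ** 2 * 2.0 * math.pi * rho
    integral = float(np.trapezoid(integrand, rho))
    if not math.isfinite(integral) or integral < 0:
        raise ValueError("non-finite task integral")
    return float(delta_s / (sigma * a) * math.sqrt(integral))


def _orientation_curve(image: PhantomImage, edges, pixel_spacing: float,
                       ) -> MTFCurve:
    """Average MTF over the (two) edges of one geometric orientation."""
    curves = []
    for edge in edges:
        dist, vals = extract_edge_profile(image, edge)
        esf = compute_esf(dist, vals, bin_width_mm=pixel_spacing / 8.0)
        curves.append(esf_to_mtf(esf, pixel_spacing))
    grid = curves[0].freq_lpmm
    mod = np.mean([np.interp(grid, c.freq_lpmm, c.modulation) for c in curves],
                  axis=0)
    mod[0] = 1.0
    return MTFCurve(freq_lpmm=grid, modulation=mod)


def analyze_image(image: PhantomImage,
                  loc: InsertLocalization | None = None) -> IQResult:
    """Run the full chain on one image: localization, MTFs, SNR, SDNR, d'."""
    if loc is None:
        loc = locate_inserts(image)
    a = image.pixel_spacing_mm
    flags: list[str] = []
    if abs(loc.estimated_rotation_deg) < ZERO_SLANT_THRESHOLD_DEG:
        flags.append("zero_slant_warning")

    vert_edges = [e for e in loc.edge_segments if e.orientation == "near_vertical"]
    horiz_edges = [e for e in loc.edge_segments if e.orientation == "near_horizontal"]
    # near-vertical edges modulate along the horizontal axis -> horizontal MTF
    curve_h = _orientation_curve(image, vert_edges, a)
    curve_h.orientation = "horizontal"
    curve_v = _orientation_curve(image, horiz_edges, a)
    curve_v.orientation = "vertical"

    h_freqs = mtf_percent_frequencies(curve_h)
    v_freqs = mtf_percent_frequencies(curve_v)
    for tag, freqs in (("h", h_freqs), ("v", v_freqs)):
        for level, value in freqs.items():
            if value is None:
                flags.append(f"{tag}mtf{int(level * 100)}_not_evaluable")

    snr = compute_snr(image, loc)
    sdnr = compute_sdnr(image, loc)
    d03 = compute_dprime(image, loc, curve_h, curve_v, 0.3)
    d40 = compute_dprime(image, loc, curve_h, curve_v, 4.0)
    return IQResult(snr=snr, sdnr=sdnr,
                    hmtf50=h_freqs[0.5], hmtf20=h_freqs[0.2], hmtf10=h_freqs[0.1],
                    vmtf50=v_freqs[0.5], vmtf20=v_freqs[0.2], vmtf10=v_freqs[0.1],
                    dprime_03=d03, dprime_40=d40, qc_flags=tuple(flags))
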