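"""Automatic localization of the Cu and Al inserts and the Cu edge segments.

Detection is intentionally simple and physical-size gated: Otsu thresholding
plus connected components finds the strongly attenuating Cu square, a second
threshold over the remaining field finds the Al square, and sub-pixel
mid-level crossings along the Cu boundary give the four fitted edge lines
that feed the slanted-edge ESF/MTF analysis.  Everything operates on
photometrically normalized values (higher = more exposure), so MONOCHROME1
and MONOCHROME2 renderings of the same scene localize identically.

Conventions: 0-based (row, col) pixel coordinates; physical positions in mm
from the top-left pixel center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .synthetic import PhantomImage

__all__ = [
    "ROI",
    "EdgeSegment",
    "InsertLocalization",
    "LocalizationFailure",
    "locate_inserts",
    "extract_edge_profile",
    "save_overlay",
]

MIN_STATS_ROI_PX = 16
MIN_EDGE_PROFILE_SAMPLES = 64


class LocalizationFailure(RuntimeError):
    """Raised when an insert or edge cannot be found; carries a reason code."""

    def __init__(self, code: str, detail: str = ""):
        self.code = code
        super().__init__(f"{code}: {detail}" if detail else code)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned measurement region, fully inside the image."""

    center_px: tuple[float, float]
    size_px: tuple[int, int]

    @property
    def slices(self) -> tuple[slice, slice]:
        r0 = int(round(self.center_px[0] - self.size_px[0] / 2))
        c0 = int(round(self.center_px[1] - self.size_px[1] / 2))
        return (slice(r0, r0 + self.size_px[0]), slice(c0, c0 + self.size_px[1]))

    def pixels(self, array: np.ndarray) -> np.ndarray:
        return array[self.slices]

    def overlaps(self, other: "ROI") -> bool:
        (r0a, r1a), (c0a, c1a) = [(s.start, s.stop) for s in self.slices]
        (r0b, r1b), (c0b, c1b) = [(s.start, s.stop) for s in other.slices]
        return r0a < r1b and r0b < r1a and c0a < c1b and c0b < c1a


@dataclass(frozen=True)
class EdgeSegment:
    """A fitted Cu-square edge line.

    ``angle_deg`` is the signed deviation from the nominal axis (positive =
    counter-clockwise).  ``point_px`` is a point on the fitted line and
    ``normal`` the unit normal pointing from the Cu side toward the carrier,
    so signed perpendicular distances increase Cu -> carrier.
    """

    orientation: str              # "near_vertical" | "near_horizontal"
    angle_deg: float
    point_px: tuple[float, float]
    normal: tuple[float, float]
    length_px: float


@dataclass
class InsertLocalization:
    cu_roi: ROI
    al_roi: ROI
    background_roi: ROI
    edge_segments: list[EdgeSegment]
    estimated_rotation_deg: float
    cu_center_px: tuple[float, float] = (0.0, 0.0)
    al_center_px: tuple[float, float] = (0.0, 0.0)


def _component_of_size(mask: np.ndarray, side_px: float, tol: float,
                       min_fill: float = 0.6):
    """Largest labeled component whose equivalent square side is within tol."""
    labeled = label(mask)
    best = None
    for prop in regionprops(labeled):
        side = math.sqrt(prop.area)
        if abs(side - side_px) > tol * side_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        fill = prop.area / max((r1 - r0) * (c1 - c0), 1)
        if fill < min_fill:
            continue
        if best is None or prop.area > best.area:
            best = prop
    return best


def _fit_edge(norm: np.ndarray, mask: np.ndarray, side: str,
              cu_level: float, carrier_level: float) -> EdgeSegment:
    """Fit one Cu edge from sub-pixel mid-level crossings.

    ``side`` is one of left/right/top/bottom.  Crossings are searched in a
    band around the mask boundary, on a lightly smoothed profile so that a
    single crossing survives noise, over the central 60% of the edge.
    """
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    mid = 0.5 * (cu_level + carrier_level)
    along_vertical = side in ("left", "right")
    if along_vertical:
        span = rows
        side_len = rows[-1] - rows[0] + 1
    else:
        span = cols
        side_len = cols[-1] - cols[0] + 1
    lo = span[0] + int(0.2 * side_len)
    hi = span[-1] - int(0.2 * side_len)
    idx = np.arange(lo, hi + 1)
    half_win = max(12, int(round(0.12 * side_len)))

    pts_along, pts_across = [], []
    for i in idx:
        line_mask = mask[i, :] if along_vertical else mask[:, i]
        nz = line_mask.nonzero()[0]
        if nz.size == 0:
            continue
        boundary = {"left": nz[0], "right": nz[-1],
                    "top": nz[0], "bottom": nz[-1]}[side]
        a = max(0, boundary - half_win)
        b_len = norm.shape[1] if along_vertical else norm.shape[0]
        b = min(b_len, boundary + half_win + 1)
        prof = norm[i, a:b] if along_vertical else norm[a:b, i]
        if prof.size < 4:
            continue
        smooth = ndimage.gaussian_filter1d(prof.astype(np.float64), 2.0)
        d = smooth - mid
        sign_change = np.nonzero(d[:-1] * d[1:] <= 0)[0]
        if sign_change.size == 0:
            continue
        # crossing closest to the mask boundary
        j = sign_change[np.argmin(np.abs(sign_change + a - boundary))]
        denom = smooth[j] - smooth[j + 1]
        frac = 0.5 if denom == 0 else (smooth[j] - mid) / denom
        pts_along.append(float(i))
        pts_across.append(a + j + float(np.clip(frac, 0.0, 1.0)))
    if len(pts_along) < MIN_EDGE_PROFILE_SAMPLES:
        raise LocalizationFailure("edge_too_short",
                                  f"{side}: only {len(pts_along)} usable crossings")
    t = np.asarray(pts_along)
    x = np.asarray(pts_across)
    slope, intercept = np.polyfit(t, x, 1)
    mid_t = t.mean()
    mid_x = slope * mid_t + intercept
    angle = math.degrees(math.atan(slope))
    length = float(t[-1] - t[0])

    if along_vertical:
        point = (mid_t, mid_x)
        # line direction (1, slope) in (row, col); normal perpendicular to it
        nvec = np.array([-slope, 1.0])
        orientation = "near_vertical"
    else:
        point = (mid_x, mid_t)
        nvec = np.array([1.0, -slope])
        orientation = "near_horizontal"
    nvec /= np.linalg.norm(nvec)
    # orient the normal from Cu (inside) toward carrier (outside)
    centroid = np.array(ndimage.center_of_mass(mask))
    outward = np.array(point) - centroid
    if np.dot(nvec, outward) < 0:
        nvec = -nvec
    return EdgeSegment(orientation=orientation, angle_deg=angle,
                       point_px=point, normal=(float(nvec[0]), float(nvec[1])),
                       length_px=length)


def locate_inserts(image: PhantomImage, cu_size_mm: float = 50.0,
                   al_size_mm: float = 10.0) -> InsertLocalization:
    """Find Cu and Al inserts, measurement ROIs and the four Cu edge lines.

    Raises :class:`LocalizationFailure` with codes ``cu_not_found``,
    ``al_not_found`` or ``edge_too_short``.
    """
    norm = image.as_exposure()
    a = image.pixel_spacing_mm
    smooth = ndimage.gaussian_filter(norm, 2.0)

    lo, hi = float(smooth.min()), float(smooth.max())
    if hi - lo < 1e-9:
        raise LocalizationFailure("cu_not_found", "uniform image")
    try:
        t_cu = threshold_otsu(smooth)
    except ValueError as exc:  # pragma: no cover - degenerate histogram
        raise LocalizationFailure("cu_not_found", str(exc)) from exc
    struct = np.ones((3, 3), dtype=bool)
    cu_mask = smooth < t_cu
    cu_mask = ndimage.binary_closing(ndimage.binary_opening(cu_mask, struct), struct)
    cu_side_px = cu_size_mm / a
    cu_prop = _component_of_size(cu_mask, cu_side_px, tol=0.4)
    if cu_prop is None:
        raise LocalizationFailure("cu_not_found",
                                  "no component of plausible Cu size")
    cu_mask = label(cu_mask) == cu_prop.label
    cu_center = tuple(cu_prop.centroid)
    cu_side_meas = math.sqrt(cu_prop.area)

    # Al: threshold over the field excluding (a dilated) Cu region
    rest = ~ndimage.binary_dilation(cu_mask, iterations=8)
    rest_vals = smooth[rest]
    t_al = threshold_otsu(rest_vals)
    al_mask = (smooth < t_al) & rest
    al_mask = ndimage.binary_closing(ndimage.binary_opening(al_mask, struct), struct)
    al_side_px = al_size_mm / a
    al_prop = _component_of_size(al_mask, al_side_px, tol=0.3)
    if al_prop is None:
        raise LocalizationFailure("al_not_found",
                                  "no component of plausible Al size")
    al_center = tuple(al_prop.centroid)
    al_side_meas = math.sqrt(al_prop.area)

    # interior ROIs, margin-eroded (25% per side for Cu, 20% for Al) so they
    # stay clear of the blurred edge transition
    cu_roi_side = max(MIN_STATS_ROI_PX, int(round(0.5 * cu_side_meas)))
    al_roi_side = max(MIN_STATS_ROI_PX, int(round(0.6 * al_side_meas)))
    cu_roi = ROI(center_px=cu_center, size_px=(cu_roi_side, cu_roi_side))
    al_roi = ROI(center_px=al_center, size_px=(al_roi_side, al_roi_side))

    bg_roi = _place_background_roi(norm.shape, al_center, al_side_meas,
                                   al_roi_side, cu_roi, al_roi)

    cu_level = float(np.median(cu_roi.pixels(norm)))
    carrier_level = float(np.median(bg_roi.pixels(norm)))
    edges = [_fit_edge(norm, cu_mask, side, cu_level, carrier_level)
             for side in ("left", "right", "top", "bottom")]
    # a rigid rotation by +theta tilts near-horizontal edges by +theta but
    # near-vertical edges by -theta in their respective fit parametrizations
    angles = [e.angle_deg if e.orientation == "near_horizontal" else -e.angle_deg
              for e in edges]
    est_rot = float(np.mean([((ang + 45.0) % 90.0) - 45.0 for ang in angles]))

    return InsertLocalization(cu_roi=cu_roi, al_roi=al_roi, background_roi=bg_roi,
                              edge_segments=edges, estimated_rotation_deg=est_rot,
                              cu_center_px=cu_center, al_center_px=al_center)


def _place_background_roi(shape, al_center, al_side_px, roi_side, cu_roi,
                          al_roi) -> ROI:
    """Carrier ROI offset from the Al square toward the image center.

    Offset magnitude: two Al side lengths center-to-center (~one side length
    of clear carrier between Al edge and ROI edge), along the dominant axis
    of the direction to the image center.  Falls back to the other axis /
    opposite directions if that spot leaves the image or hits another ROI.
    """
    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    to_center = center - np.array(al_center)
    axes = sorted(((abs(to_center[0]), (np.sign(to_center[0]) or 1, 0)),
                   (abs(to_center[1]), (0, np.sign(to_center[1]) or 1))),
                  reverse=True)
    candidates = [d for _, d in axes]
    candidates += [(-d[0], -d[1]) for d in candidates]
    for d in candidates:
        c = (al_center[0] + d[0] * 2.0 * al_side_px,
             al_center[1] + d[1] * 2.0 * al_side_px)
        roi = ROI(center_px=c, size_px=(roi_side, roi_side))
        rs, cs = roi.slices
        if rs.start < 0 or cs.start < 0 or rs.stop > shape[0] or cs.stop > shape[1]:
            continue
        if roi.overlaps(cu_roi) or roi.overlaps(al_roi):
            continue
        return roi
    raise LocalizationFailure("al_not_found", "no valid background region")


def extract_edge_profile(image: PhantomImage, edge: EdgeSegment,
                         band_halfwidth_px: int | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Signed perpendicular distance (mm) and value for pixels near an edge.

    Distances are measured against the fitted sub-pixel line, positive toward
    the carrier side.  The default band half-width is the larger of 10 px and
    4 mm of physical distance, which guarantees the downstream ESF spans well
    past +/-2 mm even for heavy blur.  Only the central 80% of the fitted
    edge length is used, keeping clear of the square's corners.
    """
    a = image.pixel_spacing_mm
    if band_halfwidth_px is None:
        band_halfwidth_px = max(10, int(math.ceil(8.0 / a)))
    norm = image.as_exposure()
    p0 = np.array(edge.point_px)
    n = np.array(edge.normal)
    t = np.array([-n[1], n[0]])  # unit along-edge direction
    half_len = 0.4 * edge.length_px

    # bounding box of the sampling band
    corners = [p0 + s1 * half_len * t + s2 * band_halfwidth_px * n
               for s1 in (-1, 1) for s2 in (-1, 1)]
    corners = np.array(corners)
    r0 = int(np.floor(corners[:, 0].min()))
    r1 = int(np.ceil(corners[:, 0].max())) + 1
    c0 = int(np.floor(corners[:, 1].min()))
    c1 = int(np.ceil(corners[:, 1].max())) + 1
    truncated = r0 < 0 or c0 < 0 or r1 > norm.shape[0] or c1 > norm.shape[1]
    if truncated:
        warnings.warn("edge sampling band exits the image; profile truncated",
                      stacklevel=2)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, norm.shape[0]), min(c1, norm.shape[1])

    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - p0[0]
    dc = cc - p0[1]
    dist_px = dr * n[0] + dc * n[1]
    along = dr * t[0] + dc * t[1]
    keep = (np.abs(dist_px) <= band_halfwidth_px) & (np.abs(along) <= half_len)
    if keep.sum() < MIN_EDGE_PROFILE_SAMPLES:
        raise LocalizationFailure("edge_too_short",
                                  f"only {int(keep.sum())} samples in band")
    distances_mm = dist_px[keep] * a
    values = norm[r0:r1, c0:c1][keep]
    return distances_mm.astype(np.float64), values.astype(np.float64)


def save_overlay(image: PhantomImage, loc: InsertLocalization, path) -> None:
    """Write a QC-audit overlay PNG: ROIs and fitted edges on the image.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.as_exposure(), cmap="gray")
    for roi, color in ((loc.cu_roi, "tab:red"), (loc.al_roi, "tab:orange"),
                       (loc.background_roi, "tab:blue")):
        rs, cs = roi.slices
        ax.add_patch(Rectangle((cs.start, rs.start), cs.stop - cs.start,
                               rs.stop - rs.start, fill=False, color=color))
    for edge in loc.edge_segments:
        p = np.array(edge.point_px)
        t = np.array([-edge.normal[1], edge.normal[0]])
        ends = [p - 0.5 * edge.length_px * t, p + 0.5 * edge.length_px * t]
        ax.plot([e[1] for e in ends], [e[0] for e in ends], "g-", lw=0.8)
    ax.set_title(f"rotation {loc.estimated_rotation_deg:.2f} deg")
    fig.savefig(path, dpi=120)
    plt.close(fig)
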