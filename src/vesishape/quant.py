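"""Quantitative vesicle morphometry from fluorescence micrographs.

Pipeline: contrast-limited adaptive histogram equalization (CLAHE)
followed by Otsu global thresholding and connected-component labeling —
"adaptive histogram equalization" is contrast enhancement, not a
binarization, so an explicit threshold step is required — then
moment-based ellipse fits, the 5–20 µm equivalent-diameter filter, and
population statistics of the major–minor (M-m) axis ratio.

Conventions: pixel indices are 0-based row-major; every physical
quantity is in µm.  Components touching the frame border are flagged
and excluded from statistics by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import exposure, filters, measure, morphology


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for CLAHE + Otsu segmentation."""

    clahe_clip_limit: float = 0.01
    clahe_kernel_fraction: float = 0.125  # kernel size as fraction of frame
    opening_radius: int = 2               # pixels; suppresses noise speckle
    min_area_px: int = 100
    fill_holes: bool = True
    refine_boundaries: bool = True        # half-level re-threshold per component


@dataclass
class VesicleMeasurement:
    """Ellipse approximation of one segmented vesicle."""

    vesicle_id: int
    major_axis_um: float
    minor_axis_um: float
    equivalent_diameter_um: float
    mm_ratio: float
    centroid_um: tuple[float, float]
    orientation_rad: float
    plane_index: int = 0
    touches_border: bool = False


class DegenerateMaskError(ValueError):
    """Mask too small or degenerate for an ellipse fit."""


def _refine_labels(img: np.ndarray, labels: np.ndarray, margin: int = 10) -> np.ndarray:
    """Re-threshold every detected component at the half level between its
    interior and local background on the *original* image.

    Histogram equalization distorts the blur ramp at object boundaries, so
    a global threshold on the equalized image lands off the geometric
    edge; the 50% contour of a symmetrically blurred step recovers it.
    """
    out = np.zeros_like(labels)
    slices = ndi.find_objects(labels)
    next_label = 1
    for label, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rows = slice(max(sl[0].start - margin, 0), min(sl[0].stop + margin, img.shape[0]))
        cols = slice(max(sl[1].start - margin, 0), min(sl[1].stop + margin, img.shape[1]))
        box = img[rows, cols]
        m0 = labels[rows, cols] == label
        interior = ndi.binary_erosion(m0, iterations=3)
        if interior.sum() < 10:
            interior = m0
        ring = ndi.binary_dilation(m0, iterations=max(2, margin // 2))
        bg_mask = ~ring & (labels[rows, cols] == 0)
        if bg_mask.sum() < 20:
            bg_mask = labels[rows, cols] == 0
        if bg_mask.sum() < 20:
            out[rows, cols][m0] = next_label
            next_label += 1
            continue
        level = 0.5 * (np.median(box[interior]) + np.median(box[bg_mask]))
        refined = box > level
        lab2, n2 = ndi.label(refined)
        if n2 == 0:
            refined = m0
        else:
            overlap = ndi.sum_labels(m0, lab2, np.arange(1, n2 + 1))
            refined = lab2 == (int(np.argmax(overlap)) + 1)
        refined = ndi.binary_fill_holes(refined)
        target = out[rows, cols]
        target[refined & (target == 0)] = next_label
        next_label += 1
    return out


def segment_image(image: np.ndarray, config: SegmentationConfig = SegmentationConfig()):
    """CLAHE + Otsu segmentation of one grayscale frame.

    Returns ``(labels, border_flags)``: an integer label image (0 =
    background) with holes filled and small components removed, and a
    dict mapping label -> True when the component touches the frame
    border.  A constant image yields zero components.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=int), {}

    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo)
    kernel = max(8, int(round(min(img.shape) * config.clahe_kernel_fraction)))
    eq = exposure.equalize_adapthist(norm, kernel_size=kernel,
                                     clip_limit=config.clahe_clip_limit)
    thresh = filters.threshold_otsu(eq)
    binary = eq > thresh
    if config.opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(config.opening_radius))
    if config.fill_holes:
        binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary)
    if config.min_area_px > 0 and n:
        sizes = ndi.sum_labels(binary, labels, np.arange(1, n + 1))
        small = np.flatnonzero(sizes < config.min_area_px) + 1
        binary[np.isin(labels, small)] = False
    labels, _ = ndi.label(binary)
    if config.refine_boundaries:
        labels = _refine_labels(img, labels)
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = set(np.unique(labels[border])) - {0}
    flags = {int(l): (int(l) in touching) for l in np.unique(labels) if l != 0}
    return labels, flags


def select_best_plane(masks) -> int:
    """Index of the plane with the largest mask area (ties -> lower index).

    Automates the manual step of picking the Z plane that maximizes the
    apparent vesicle size.
    """
    areas = [int(np.count_nonzero(m)) for m in masks]
    if len(areas) == 0 or max(areas) == 0:
        raise ValueError("no non-empty plane in stack")
    return int(np.argmax(areas))


def fit_ellipse(mask: np.ndarray, pixel_size: float, vesicle_id: int = 0,
                plane_index: int = 0) -> VesicleMeasurement:
    """Moment-based ellipse fit of a single binary mask.

    Axis lengths follow the normalized-second-moment convention (the
    ellipse with the same second moments as the region), converted to µm.
    """
    mask = np.asarray(mask).astype(bool)
    n_px = int(mask.sum())
    if n_px < 10:
        raise DegenerateMaskError(f"mask has {n_px} px; need >= 10")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    if minor <= 0:
        raise DegenerateMaskError("zero second moment (collinear mask)")
    major_um = props.axis_major_length * pixel_size
    minor_um = minor * pixel_size
    eq_d_um = 2.0 * pixel_size * np.sqrt(n_px / np.pi)
    cy, cx = props.centroid
    touches = (mask[0, :].any() or mask[-1, :].any()
               or mask[:, 0].any() or mask[:, -1].any())
    return VesicleMeasurement(
        vesicle_id=vesicle_id,
        major_axis_um=major_um,
        minor_axis_um=minor_um,
        equivalent_diameter_um=eq_d_um,
        mm_ratio=major_um / minor_um,
        centroid_um=(cx * pixel_size, cy * pixel_size),
        orientation_rad=float(props.orientation),
        plane_index=plane_index,
        touches_border=bool(touches),
    )


def _component_fit(img, labels, sl, label, pixel_size, supersample, margin=10,
                   plane_index=0):
    """Subpixel ellipse fit of one component: re-threshold its upsampled
    neighborhood at the local half level, then fit the refined mask."""
    rows = slice(max(sl[0].start - margin, 0), min(sl[0].stop + margin, img.shape[0]))
    cols = slice(max(sl[1].start - margin, 0), min(sl[1].stop + margin, img.shape[1]))
    box = img[rows, cols]
    m0 = labels[rows, cols] == label
    interior = ndi.binary_erosion(m0, iterations=3)
    if interior.sum() < 10:
        interior = m0
    bg_mask = ~ndi.binary_dilation(m0, iterations=5) & (labels[rows, cols] == 0)
    if bg_mask.sum() < 20:
        bg_mask = labels[rows, cols] == 0
    if bg_mask.sum() < 20:
        mask, scale = m0, 1
    else:
        level = 0.5 * (np.median(box[interior]) + np.median(box[bg_mask]))
        scale = max(1, int(supersample))
        hi = ndi.zoom(box, scale, order=1) if scale > 1 else box
        mask = hi > level
        lab2, n2 = ndi.label(mask)
        if n2 == 0:
            mask, scale = m0, 1
        else:
            seed = ndi.zoom(m0.astype(np.uint8), scale, order=0).astype(bool)
            overlap = ndi.sum_labels(seed, lab2, np.arange(1, n2 + 1))
            mask = ndi.binary_fill_holes(lab2 == (int(np.argmax(overlap)) + 1))
    m = fit_ellipse(mask, pixel_size / scale, vesicle_id=label,
                    plane_index=plane_index)
    m.centroid_um = (cols.start * pixel_size + m.centroid_um[0],
                     rows.start * pixel_size + m.centroid_um[1])
    return m


def measure_frame(image: np.ndarray, pixel_size: float,
                  config: SegmentationConfig = SegmentationConfig(),
                  exclude_border: bool = True,
                  plane_index: int = 0,
                  supersample: int = 2) -> list[VesicleMeasurement]:
    """Segment a frame and fit an ellipse to every detected vesicle."""
    img = np.asarray(image, dtype=float)
    labels, flags = segment_image(img, config)
    slices = ndi.find_objects(labels)
    out = []
    for label in sorted(flags):
        if exclude_border and flags[label]:
            continue
        sl = slices[label - 1]
        if sl is None:
            continue
        try:
            m = _component_fit(img, labels, sl, label, pixel_size,
                               supersample, plane_index=plane_index)
        except DegenerateMaskError:
            continue
        m.touches_border = flags[label]
        out.append(m)
    return out


def size_filter(measurements, min_d: float = 5.0, max_d: float = 20.0):
    """Keep vesicles with equivalent diameter in [min_d, max_d] µm
    (inclusive bounds), preserving order.  Idempotent."""
    return [m for m in measurements
            if min_d <= m.equivalent_diameter_um <= max_d]


@dataclass
class PopulationStats:
    """Summary statistics of a set of M-m ratios."""

    n: int
    mean_ratio: float
    sd_ratio: float
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_locations: np.ndarray  # bin centers of detected histogram peaks

    def as_dict(self) -> dict:
        return {
            "n": self.n, "mean_ratio": self.mean_ratio, "sd_ratio": self.sd_ratio,
            "bin_edges": list(map(float, self.bin_edges)),
            "counts": list(map(int, self.counts)),
            "peak_locations": list(map(float, self.peak_locations)),
        }


def population_statistics(ratios, bin_width: float = 0.1,
                          peak_prominence_fraction: float = 0.2) -> PopulationStats:
    """Mean, SD, histogram (bins starting at 1.0) and peak locations.

    Peaks are local maxima of the counts exceeding both neighbors with
    prominence at least ``peak_prominence_fraction`` of the maximum
    count; the histogram is zero-padded so boundary bins can qualify.
    """
    from scipy.signal import find_peaks

    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("population_statistics requires at least one ratio")
    top = max(1.0 + bin_width, float(ratios.max()))
    n_bins = int(np.ceil((top - 1.0) / bin_width - 1e-9))
    edges = 1.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(ratios, bins=edges)
    padded = np.concatenate([[0], counts, [0]]).astype(float)
    peaks, _ = find_peaks(padded, prominence=peak_prominence_fraction * counts.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PopulationStats(
        n=int(ratios.size),
        mean_ratio=float(ratios.mean()),
        sd_ratio=float(ratios.std(ddof=0)),
        bin_edges=edges,
        counts=counts,
        peak_locations=centers[peaks - 1],
    )


def measurements_to_frame(measurements) -> pd.DataFrame:
    rows = [{
        "id": m.vesicle_id, "plane": m.plane_index,
        "major_um": m.major_axis_um, "minor_um": m.minor_axis_um,
        "ratio": m.mm_ratio, "diameter_um": m.equivalent_diameter_um,
        "centroid_x_um": m.centroid_um[0], "centroid_y_um": m.centroid_um[1],
        "orientation_rad": m.orientation_rad,
        "touches_border": m.touches_border,
    } for m in measurements]
    return pd.DataFrame(rows)
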