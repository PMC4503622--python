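"""Synthetic fluorescence microscopy of dye-filled vesicles.

Generates single-plane images, multi-vesicle frames and confocal
Z-stacks with exact ground truth, emulating epifluorescence/confocal
imaging of giant vesicles with encapsulated dye: bright, roughly convex
interiors on a dark background, Gaussian blur standing in for the PSF,
and additive Gaussian (optionally Poisson) noise.  Vesicles are
rendered as filled interiors, not membrane rings, because the imaging
being emulated encapsulates the fluorophore in the lumen.

Geometries supported: spheres, spheroids (symmetry axis in the focal
plane or along the optical axis) and axisymmetric shape-library entries
laid on their side — mirroring the experimental observation that a
deformed vesicle's major axis settles parallel to the slide.

All randomness flows from a single integer seed; identical
configuration and seed give bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_TWO_PI = 2.0 * np.pi


class PackingError(RuntimeError):
    """Could not place the requested vesicles without overlap."""


@dataclass(frozen=True)
class ImagingConfig:
    """Virtual microscope settings.

    ``pixel_size`` is the lateral sampling in µm/pixel (0.2 by default so
    a 5 µm vesicle spans 25 pixels); ``z_step`` the axial spacing of
    stacks in µm; ``blur_sigma`` the PSF stand-in width in µm;
    ``noise_sigma`` the additive Gaussian noise level in intensity units.
    """

    pixel_size: float = 0.2
    z_step: float = 1.0
    blur_sigma: float = 0.3
    background_level: float = 10.0
    noise_sigma: float = 5.0
    poisson_noise: bool = False
    frame_shape: tuple[int, int] = (512, 512)  # rows, cols
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")

    @property
    def frame_extent(self) -> tuple[float, float]:
        """(height, width) of the frame in µm."""
        return (self.frame_shape[0] * self.pixel_size,
                self.frame_shape[1] * self.pixel_size)


@dataclass(frozen=True)
class VesicleSpec:
    """Ground-truth carrier for one rendered vesicle.

    ``geometry`` is ("sphere", diameter), ("spheroid", (a, c)) with
    semi-axes in µm (c along the symmetry axis), or
    ("library_shape", solution, scale) with ``scale`` the equivalent
    radius R_A in µm.  ``orientation``: unit vector of the symmetry
    axis; in-plane orientations are (cos t, sin t, 0), axial is (0,0,1).
    ``center`` is (x, y, z) in µm; z = 0 is the nominal focal plane.
    """

    geometry: tuple
    center: tuple[float, float, float]
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    interior_intensity: float = 100.0

    def __post_init__(self):
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("orientation must be unit-norm")

    # -- geometric queries -------------------------------------------------

    def z_extent(self) -> tuple[float, float]:
        """Min and max z (µm) occupied by the vesicle."""
        kind = self.geometry[0]
        cz = self.center[2]
        if kind == "sphere":
            r = 0.5 * self.geometry[1]
            return cz - r, cz + r
        if kind == "spheroid":
            a, c = self.geometry[1]
            axis_z = abs(self.orientation[2])
            half = np.sqrt((c * axis_z) ** 2 + (a ** 2) * (1 - axis_z ** 2))
            return cz - half, cz + half
        if kind == "library_shape":
            sol, scale = self.geometry[1], self.geometry[2]
            from .classify import meridian_profile

            p = meridian_profile(sol.shape)
            r_a = sol.measures.equivalent_radius
            if abs(self.orientation[2]) > 0.99:  # axis along z
                lo, hi = p.z.min(), p.z.max()
            else:  # lying in-plane: z extent set by rho
                hi = float(p.rho.max())
                lo = -hi
            return cz + scale * lo / r_a, cz + scale * hi / r_a
        raise ValueError(f"unknown geometry {kind!r}")

    def true_mm_ratio(self) -> float:
        """Major/minor axis ratio of the equatorial (z through center) section."""
        kind = self.geometry[0]
        if kind == "sphere":
            return 1.0
        if kind == "spheroid":
            a, c = self.geometry[1]
            if abs(self.orientation[2]) > 0.99:
                return 1.0  # axis along z: circular section
            hi, lo = max(a, c), min(a, c)
            return hi / lo
        if kind == "library_shape":
            sol = self.geometry[1]
            from .classify import silhouette_mm_ratio

            return silhouette_mm_ratio(sol)
        raise ValueError(f"unknown geometry {kind!r}")

    def equivalent_diameter(self) -> float:
        """Diameter (µm) of the sphere with the same volume."""
        kind = self.geometry[0]
        if kind == "sphere":
            return self.geometry[1]
        if kind == "spheroid":
            a, c = self.geometry[1]
            return 2.0 * (a * a * c) ** (1.0 / 3.0)
        if kind == "library_shape":
            sol, scale = self.geometry[1], self.geometry[2]
            v = sol.measures.reduced_volume
            return 2.0 * scale * v ** (1.0 / 3.0)
        raise ValueError(f"unknown geometry {kind!r}")


def _rotation_to_axis(orientation) -> np.ndarray:
    """Rotation matrix mapping the symmetry axis onto +z."""
    axis = np.asarray(orientation, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _inside_mask(spec: VesicleSpec, xx: np.ndarray, yy: np.ndarray, z: float) -> np.ndarray:
    """Boolean interior test of the z-slice on pixel-center grids (µm)."""
    kind = spec.geometry[0]
    dx = xx - spec.center[0]
    dy = yy - spec.center[1]
    dz = z - spec.center[2]
    if kind == "sphere":
        r = 0.5 * spec.geometry[1]
        return dx * dx + dy * dy + dz * dz <= r * r
    # rotate world coords into the body frame (axis -> z)
    R = _rotation_to_axis(spec.orientation)
    bx = R[0, 0] * dx + R[0, 1] * dy + R[0, 2] * dz
    by = R[1, 0] * dx + R[1, 1] * dy + R[1, 2] * dz
    bz = R[2, 0] * dx + R[2, 1] * dy + R[2, 2] * dz
    if kind == "spheroid":
        a, c = spec.geometry[1]
        return (bx / a) ** 2 + (by / a) ** 2 + (bz / c) ** 2 <= 1.0
    if kind == "library_shape":
        sol, scale = spec.geometry[1], spec.geometry[2]
        from .classify import meridian_profile

        p = meridian_profile(sol.shape)
        factor = scale / sol.measures.equivalent_radius
        z_prof = p.z * factor
        rho_prof = p.rho * factor
        rr = np.sqrt(bx * bx + by * by)
        # interior iff radial distance below the profile at that body height
        order = np.argsort(z_prof)
        rho_at = np.interp(bz, z_prof[order], rho_prof[order],
                           left=-1.0, right=-1.0)
        return rr <= rho_at
    raise ValueError(f"unknown geometry {kind!r}")



def _clipped(spec: VesicleSpec, config: ImagingConfig) -> bool:
    h, w = config.frame_extent
    d = spec.equivalent_diameter() * spec.true_mm_ratio() ** (2.0 / 3.0)
    half = 0.6 * d  # conservative in-plane bounding radius
    x, y, _ = spec.center
    return x - half < 0 or y - half < 0 or x + half > w or y + half > h


def _ground_truth_frame(specs, config, z) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(specs):
        z0, z1 = s.z_extent()
        rows.append({
            "id": i,
            "geometry": s.geometry[0],
            "center_x_um": s.center[0],
            "center_y_um": s.center[1],
            "center_z_um": s.center[2],
            "equivalent_diameter_um": s.equivalent_diameter(),
            "true_mm_ratio": s.true_mm_ratio(),
            "in_slice": bool(z0 < z < z1),
            "clipped": _clipped(s, config),
        })
    return pd.DataFrame(rows)


_AA_SUBPIXELS = 4  # 4x4 coverage sampling per pixel


def _render_one(image: np.ndarray, spec: VesicleSpec, config: ImagingConfig,
                z: float) -> None:
    """Anti-aliased rasterization of one vesicle into ``image``.

    The interior test is evaluated on a subpixel grid and averaged to a
    coverage fraction: hard pixel-center sampling would quantize the
    object width independently along x and y, imprinting a spurious
    percent-level ellipticity on small vesicles.
    """
    px = config.pixel_size
    rows, cols = config.frame_shape
    half = 0.65 * spec.equivalent_diameter() * spec.true_mm_ratio() ** (2.0 / 3.0) + 2.0
    c0 = max(0, int((spec.center[0] - half) / px))
    c1 = min(cols, int(np.ceil((spec.center[0] + half) / px)) + 1)
    r0 = max(0, int((spec.center[1] - half) / px))
    r1 = min(rows, int(np.ceil((spec.center[1] + half) / px)) + 1)
    if c1 <= c0 or r1 <= r0:
        return
    xs = (np.arange(c0, c1) + 0.5) * px
    ys = (np.arange(r0, r1) + 0.5) * px
    offsets = ((np.arange(_AA_SUBPIXELS) + 0.5) / _AA_SUBPIXELS - 0.5) * px
    coverage = np.zeros((r1 - r0, c1 - c0))
    for oy in offsets:
        for ox in offsets:
            xxs, yys = np.meshgrid(xs + ox, ys + oy)
            coverage += _inside_mask(spec, xxs, yys, z)
    coverage /= _AA_SUBPIXELS ** 2
    view = image[r0:r1, c0:c1]
    np.maximum(view, spec.interior_intensity * coverage, out=view)


def render_plane(specs, config: ImagingConfig, z: float = 0.0,
                 rng: np.random.Generator | None = None):
    """Rasterize one focal plane of the given vesicles.

    Interiors are filled at each vesicle's intensity with anti-aliased
    (subpixel coverage) edges, blurred with a Gaussian PSF stand-in,
    then background and noise are added.  Returns ``(image,
    ground_truth)`` where the table carries true geometry per vesicle
    and flags for out-of-slice and frame-clipped vesicles.
    """
    from scipy.ndimage import gaussian_filter

    if isinstance(specs, VesicleSpec):
        specs = [specs]
    image = np.zeros(config.frame_shape, dtype=float)
    for s in specs:
        z0, z1 = s.z_extent()
        if not (z0 < z < z1):
            continue
        _render_one(image, s, config, z)
    if config.blur_sigma > 0:
        image = gaussian_filter(image, config.blur_sigma / config.pixel_size)
    image += config.background_level
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.poisson_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    return image, _ground_truth_frame(specs, config, z)


def render_zstack(spec: VesicleSpec, config: ImagingConfig):
    """Confocal-style Z-stack of one vesicle with ground truth (A, V, v).

    Slices run from below to above the shape at ``z_step`` spacing with
    at least one empty slice on each end.  Ground-truth reduced volume
    is analytic for spheres/spheroids and taken from the library entry's
    measures otherwise.
    """
    z0, z1 = spec.z_extent()
    if config.z_step > (z1 - z0):
        raise ValueError("z_step exceeds the object's axial extent")
    n_below = int(np.floor(z0 / config.z_step)) - 1
    n_above = int(np.ceil(z1 / config.z_step)) + 1
    z_levels = np.arange(n_below, n_above + 1) * config.z_step
    rng = np.random.default_rng(config.seed)
    planes = []
    for z in z_levels:
        img, _ = render_plane([spec], config, z=z, rng=rng)
        planes.append(img)
    stack = np.stack(planes)

    kind = spec.geometry[0]
    if kind == "sphere":
        d = spec.geometry[1]
        area = np.pi * d * d
        volume = np.pi * d ** 3 / 6.0
        v = 1.0
    elif kind == "spheroid":
        from .geometry import spheroid_closed_form

        a, c = spec.geometry[1]
        area, volume, v = spheroid_closed_form(a, c)
    else:
        sol, scale = spec.geometry[1], spec.geometry[2]
        factor = scale / sol.measures.equivalent_radius
        area = sol.measures.area * factor ** 2
        volume = sol.measures.volume * factor ** 3
        v = sol.measures.reduced_volume
    truth = {"area_um2": area, "volume_um3": volume, "reduced_volume": v,
             "z_levels_um": z_levels}
    return stack, truth


# --------------------------------------------------------------------------
# population model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """Mixture model of a vesicle population under a PEG-lipid-like dose.

    A fraction ``p_def(c)`` of vesicles deform; deformed aspect ratios
    follow 1 + Gamma(shape, scale) with an optional narrow "budded" mode
    at ``budded_ratio`` (weight ``budded_fraction`` within the deformed
    class) emulating the secondary histogram peak at intermediate doses.
    ``p_def(c) = c / (c + c_half)`` is monotone non-decreasing, mirroring
    dose-dependent incorporation into the outer leaflet.  Diameters are
    uniform on ``diameter_range`` (µm).
    """

    n_vesicles: int = 300
    diameter_range: tuple[float, float] = (5.0, 20.0)
    c_half: float = 20.0
    gamma_shape: float = 2.0
    gamma_scale: float = 0.25
    budded_fraction: float = 0.0
    budded_ratio: float = 2.0
    budded_sd: float = 0.1
    max_ratio: float = 3.5
    seed: int = 0

    def p_def(self, c: float) -> float:
        if c < 0:
            raise ValueError("concentration must be non-negative")
        return c / (c + self.c_half) if c > 0 else 0.0

    def deformed_mean_ratio(self) -> float:
        base = 1.0 + self.gamma_shape * self.gamma_scale
        return ((1.0 - self.budded_fraction) * base
                + self.budded_fraction * self.budded_ratio)

    def true_mean_ratio(self, c: float) -> float:
        """Closed-form population mean of the M-m ratio at dose c."""
        p = self.p_def(c)
        return (1.0 - p) * 1.0 + p * self.deformed_mean_ratio()

    def sample_ratios(self, c: float, rng: np.random.Generator) -> np.ndarray:
        p = self.p_def(c)
        n = self.n_vesicles
        deformed = rng.random(n) < p
        ratios = np.ones(n)
        n_def = int(deformed.sum())
        if n_def:
            budded = rng.random(n_def) < self.budded_fraction
            r = 1.0 + rng.gamma(self.gamma_shape, self.gamma_scale, size=n_def)
            r_bud = rng.normal(self.budded_ratio, self.budded_sd, size=n_def)
            r = np.where(budded, r_bud, r)
            ratios[deformed] = np.clip(r, 1.0, self.max_ratio)
        return ratios


def _place_vesicles(radii, config, rng, max_attempts=200, margin=1.0):
    """Non-overlap placement by rejection sampling, opening a new frame
    whenever a vesicle cannot be placed; returns per-vesicle frame index
    and (x, y) centers."""
    h, w = config.frame_extent
    frames = [[]]  # list of lists of (x, y, r)
    assignment = []
    for r in radii:
        if 2 * (r + margin) >= min(h, w):
            raise PackingError(f"vesicle of radius {r:.1f} µm cannot fit the frame")
        placed = False
        for frame_idx in range(len(frames)):
            for _ in range(max_attempts):
                x = rng.uniform(r + margin, w - r - margin)
                y = rng.uniform(r + margin, h - r - margin)
                if all((x - x2) ** 2 + (y - y2) ** 2 >= (r + r2 + margin) ** 2
                       for x2, y2, r2 in frames[frame_idx]):
                    frames[frame_idx].append((x, y, r))
                    assignment.append((frame_idx, x, y))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            frames.append([])
            x = rng.uniform(r + margin, w - r - margin)
            y = rng.uniform(r + margin, h - r - margin)
            frames[-1].append((x, y, r))
            assignment.append((len(frames) - 1, x, y))
    return len(frames), assignment


def sample_population(model: PopulationModel, c: float, config: ImagingConfig):
    """Render a population at dose ``c``; returns (frames, ground_truth).

    Deformed vesicles are prolate spheroids lying in the focal plane at
    uniformly random in-plane orientation, all centered on the focal
    plane (the analysis convention selects the widest section anyway).
    Deterministic for a fixed (model.seed, config.seed, c).
    """
    if model.n_vesicles < 1:
        raise ValueError("population must contain at least one vesicle")
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed, config.seed, int(round(1000 * c))]))
    d_lo, d_hi = model.diameter_range
    diameters = rng.uniform(d_lo, d_hi, size=model.n_vesicles)
    ratios = model.sample_ratios(c, rng)
    angles = rng.uniform(0.0, np.pi, size=model.n_vesicles)

    # equatorial in-plane bounding radius: half the major axis
    major_half = 0.5 * diameters * ratios ** (2.0 / 3.0)
    n_frames, placement = _place_vesicles(major_half, config, rng)

    specs_by_frame = [[] for _ in range(n_frames)]
    records = []
    for i in range(model.n_vesicles):
        frame_idx, x, y = placement[i]
        d, q, t = diameters[i], ratios[i], angles[i]
        if q <= 1.0 + 1e-9:
            spec = VesicleSpec(("sphere", d), (x, y, 0.0))
        else:
            a = 0.5 * d * q ** (-1.0 / 3.0)
            spec = VesicleSpec(("spheroid", (a, q * a)), (x, y, 0.0),
                               orientation=(np.cos(t), np.sin(t), 0.0))
        specs_by_frame[frame_idx].append((i, spec))
        records.append({
            "id": i, "frame": frame_idx,
            "center_x_um": x, "center_y_um": y,
            "equivalent_diameter_um": d, "true_mm_ratio": q,
            # diameter of the circle matching the equatorial section area,
            # which is what a mask-area measurement estimates
            "section_diameter_um": d * q ** (1.0 / 6.0),
            "orientation_rad": t,
        })

    frames = []
    for frame_idx, items in enumerate(specs_by_frame):
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([model.seed, config.seed,
                                    int(round(1000 * c)), frame_idx]))
        img, _ = render_plane([s for _, s in items], config, z=0.0, rng=sub_rng)
        frames.append(img)
    return frames, pd.DataFrame(records)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def write_tiff(path, image_or_stack) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image_or_stack, dtype=np.float32))


def write_ground_truth(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
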