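"""Deterministic classification of axisymmetric vesicle shapes.

The rules operate on the meridian profile (rho(theta), z(theta)) of a
converged minimum-energy shape.  Thresholds are calibrated so that
genuine features of the energy-minimizing families are respected: the
relaxed bilayer-coupling prolate carries a real equatorial waist of
about 10% at moderate reduced volume, so only necks deeper than
``NECK_PROMINENCE`` (15% of the maximal radius) count as buds, and only
inward polar folds that descend at least ``FOLD_DEPTH`` of the body
height count as invaginations.

* sphere        — radial deviation from the angular mean below ``SPHERE_TOL``;
* stomatocyte   — a one-sided polar invagination: the axial height z(theta)
                  is non-monotonic, folding inward at one pole only.  A
                  biconcave discocyte dimples *both* poles symmetrically
                  and falls through to the oblate rule;
* pin / pear    — a neck (interior minimum of rho between two maxima,
                  depth >= ``NECK_PROMINENCE``); pin when the two lobes
                  hold nearly equal volumes (ratio >= ``PIN_THRESHOLD``),
                  pear otherwise;
* oblate / prolate — no neck, no fold: disc-like when the equatorial
                  extent exceeds the axial extent, cigar-like otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import meridian_arrays
from .shapes import SHPShape

SHAPE_CLASSES = ("sphere", "stomatocyte", "oblate", "prolate", "pear", "pin")

SPHERE_TOL = 0.01       # max relative radial deviation for "sphere"
PIN_THRESHOLD = 0.8     # lobe volume ratio splitting pin from pear
NECK_PROMINENCE = 0.15  # neck depth relative to max rho that counts as a bud
FOLD_DEPTH = 0.05       # min z-rise of an inward fold, relative to height


class NotConvergedError(ValueError):
    """Classification requested on a non-converged solution."""


@dataclass
class MeridianProfile:
    """Densely sampled meridian of an axisymmetric shape."""

    theta: np.ndarray
    r: np.ndarray
    rho: np.ndarray
    z: np.ndarray
    z_t: np.ndarray
    mean_curvature_sum: np.ndarray


def meridian_profile(shape: SHPShape, n: int = 2048) -> MeridianProfile:
    theta = np.linspace(1e-4, np.pi - 1e-4, n)
    u = np.cos(theta)
    r, r_u, r_uu = shape.radial(u)
    rho, z, _, z_t, _, H = meridian_arrays(r, r_u, r_uu, u)
    return MeridianProfile(theta=theta, r=r, rho=rho, z=z, z_t=z_t, mean_curvature_sum=H)


def _fold_runs(profile: MeridianProfile, min_depth: float):
    """Contiguous runs where z rises with theta (inward folds), keeping
    only those whose total rise exceeds ``min_depth`` * height."""
    z, z_t, theta = profile.z, profile.z_t, profile.theta
    height = float(z.max() - z.min())
    pos = z_t > 1e-9
    runs = []
    i = 0
    n = len(pos)
    while i < n:
        if pos[i]:
            j = i
            while j + 1 < n and pos[j + 1]:
                j += 1
            rise = float(z[j] - z[i])
            if rise >= min_depth * height:
                runs.append((theta[i], theta[j]))
            i = j + 1
        else:
            i += 1
    return runs


def _local_extrema(y: np.ndarray):
    d = np.diff(y)
    sign = np.sign(d)
    sign[sign == 0] = 1
    turns = np.diff(sign)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def _find_neck(profile: MeridianProfile, prominence: float):
    """Deepest interior minimum of rho flanked by two maxima, or None."""
    rho = profile.rho
    maxima, minima = _local_extrema(rho)
    if len(maxima) < 2 or len(minima) < 1:
        return None
    best = None
    scale = float(rho.max())
    for i in minima:
        left = maxima[maxima < i]
        right = maxima[maxima > i]
        if len(left) == 0 or len(right) == 0:
            continue
        depth = min(rho[left].max(), rho[right].max()) - rho[i]
        if depth >= prominence * scale and (best is None or rho[i] < rho[best]):
            best = i
    return best


def _lobe_volumes(profile: MeridianProfile, neck_index: int) -> tuple[float, float]:
    """Volumes on either side of the plane through the neck circle.

    Uses V = pi * integral rho^2 (-dz/dtheta) dtheta per meridian segment,
    exact when z is monotone along the meridian (true for necked shapes).
    """
    theta, rho, z_t = profile.theta, profile.rho, profile.z_t
    integrand = np.pi * rho ** 2 * (-z_t)
    v_top = float(np.trapezoid(integrand[: neck_index + 1], theta[: neck_index + 1]))
    v_bottom = float(np.trapezoid(integrand[neck_index:], theta[neck_index:]))
    return abs(v_top), abs(v_bottom)


def classify_profile(
    profile: MeridianProfile,
    sphere_tol: float = SPHERE_TOL,
    pin_threshold: float = PIN_THRESHOLD,
    neck_prominence: float = NECK_PROMINENCE,
    fold_depth: float = FOLD_DEPTH,
) -> tuple[str, float]:
    """Shape class and lobe volume ratio (1.0 when there is no neck)."""
    r = profile.r
    mean_r = float(r.mean())
    if np.max(np.abs(r - mean_r)) / mean_r < sphere_tol:
        return "sphere", 1.0

    # qualifying inward folds per hemisphere; a stomatocyte needs a clear
    # one-sided invagination (deep fold one side, at most half-depth rise
    # on the other), so a slightly perturbed biconcave disc stays oblate
    deep = _fold_runs(profile, fold_depth)
    shallow = _fold_runs(profile, 0.5 * fold_depth)
    if deep:
        mid = np.pi / 2.0
        deep_n = any(0.5 * (a + b) < mid for a, b in deep)
        deep_s = any(0.5 * (a + b) >= mid for a, b in deep)
        shal_n = any(0.5 * (a + b) < mid for a, b in shallow)
        shal_s = any(0.5 * (a + b) >= mid for a, b in shallow)
        if (deep_n and not shal_s) or (deep_s and not shal_n):
            return "stomatocyte", 1.0
        # folds at both poles: biconcave disc, handled below

    neck = _find_neck(profile, neck_prominence)
    if neck is not None:
        v1, v2 = _lobe_volumes(profile, neck)
        ratio = min(v1, v2) / max(v1, v2)
        return ("pin" if ratio >= pin_threshold else "pear"), float(ratio)

    height = float(profile.z.max() - profile.z.min())
    width = 2.0 * float(profile.rho.max())
    return ("oblate" if width > height else "prolate"), 1.0


def classify_shp(shape: SHPShape, **thresholds) -> tuple[str, float]:
    return classify_profile(meridian_profile(shape), **thresholds)


def classify_shape(solution, **thresholds) -> tuple[str, float]:
    """Classify a converged ShapeSolution (error on non-converged input)."""
    if not solution.converged:
        raise NotConvergedError("cannot classify a non-converged solution")
    return classify_shp(solution.shape, **thresholds)


def silhouette_mm_ratio(solution) -> float:
    """Major/minor extent ratio of the meridian silhouette (>= 1).

    The section plane contains the symmetry axis, matching the imaging
    convention in which a vesicle's long axis lies in the focal plane.
    """
    if not solution.converged:
        raise NotConvergedError("cannot measure a non-converged solution")
    profile = meridian_profile(solution.shape)
    height = float(profile.z.max() - profile.z.min())
    width = 2.0 * float(profile.rho.max())
    return max(height, width) / min(height, width)
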