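"""Deterministic constructed starting shapes for the energy minimizer.

Perturbed spheres alone do not reach every branch of the bilayer-coupling
shape diagram: budded dumbbells and deeply invaginated cups sit behind
energy barriers.  These helpers build coefficient vectors for the
canonical branch prototypes — spheroids matched to a target reduced
volume, two-sphere dumbbells with a prescribed neck, and dimpled spheres
— by least-squares projection onto the zonal Legendre basis.  All are
closed-form constructions with fixed parameters, so the start family
(and hence the minimizer) is fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .geometry import spheroid_closed_form
from .shapes import SHPShape, shape_from_radial_function


def spheroid_start(max_degree: int, target_v: float, prolate: bool = True) -> np.ndarray:
    """Spheroid with reduced volume ``target_v`` projected onto the basis."""
    f = lambda c: spheroid_closed_form(1.0, c)[2] - target_v
    if prolate:
        aspect = brentq(f, 1.0 + 1e-9, 60.0) if target_v < 1.0 else 1.0
    else:
        aspect = brentq(f, 1e-3, 1.0 - 1e-9) if target_v < 1.0 else 1.0

    def radial(u):
        return ((1.0 - u * u) + u * u / aspect ** 2) ** -0.5

    return shape_from_radial_function(radial, max_degree).coefficients


def dumbbell_start(max_degree: int, lobe_ratio: float, neck_radius: float) -> np.ndarray:
    """Union of two spheres (radii 1 and ``lobe_ratio``) whose intersection
    circle has radius ``neck_radius``, projected onto the basis.

    ``lobe_ratio = 1`` gives a symmetric dumbbell prototype; smaller values
    give pear-like prototypes with a bud on the +z side.
    """
    r1, r2 = 1.0, float(lobe_ratio)
    rn = float(neck_radius)
    if not (0.0 < rn < min(r1, r2)):
        raise ValueError("neck_radius must lie in (0, min radii)")
    c1 = np.sqrt(r1 * r1 - rn * rn)  # big lobe centre at z = -c1
    c2 = np.sqrt(r2 * r2 - rn * rn)  # small lobe centre at z = +c2
    # centre the construction between the two poles
    z_top, z_bot = c2 + r2, -(c1 + r1)
    z0 = 0.5 * (z_top + z_bot)

    def radial(u):
        s2 = 1.0 - u * u
        out = np.empty_like(u)
        for i, (ui, s2i) in enumerate(zip(np.atleast_1d(u), np.atleast_1d(s2))):
            # ray from (0,0,z0) in direction (sin t, cos t): hit on each sphere
            best = 0.0
            for (zc, rad) in ((-c1, r1), (c2, r2)):
                dz = zc - z0
                disc = rad * rad - s2i * dz * dz
                if disc > 0.0:
                    t = ui * dz + np.sqrt(disc)
                    best = max(best, t)
            out[i] = best
        return out

    return shape_from_radial_function(radial, max_degree).coefficients


def dimple_start(max_degree: int, depth: float, width: float = 0.7) -> np.ndarray:
    """Sphere with a Gaussian inward dimple at the north pole (stomatocyte
    prototype): r(theta) = 1 - depth * exp(-(theta/width)^2)."""
    if not (0.0 < depth < 1.0):
        raise ValueError("depth must lie in (0, 1)")

    def radial(u):
        theta = np.arccos(np.clip(u, -1.0, 1.0))
        return 1.0 - depth * np.exp(-((theta / width) ** 2))

    return shape_from_radial_function(radial, max_degree).coefficients
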