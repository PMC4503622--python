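"""Differential geometry of axisymmetric star-shaped surfaces.

A closed surface is described by its radial function r(theta) about an
interior origin; the surface is the solid of revolution of the meridian
(rho, z) = (r sin(theta), r cos(theta)) about the z axis.  All global
measures (area A, volume V, integrated mean curvature M and the Helfrich
bending energy) are obtained by Gauss-Legendre quadrature in u = cos(theta),
which is exact for smooth profiles to near machine precision at modest
orders.

Normalisations follow the bilayer-coupling convention in which the unit
sphere scores 1 on every dimensionless measure:

* reduced volume        v   = V / ((4 pi / 3) R_A^3),  R_A = sqrt(A / 4 pi)
* area difference       da  = M / (4 pi R_A),          M = 1/2 ∮ (C1+C2) dA
* reduced bending energy wb = (1 / 16 pi) ∮ (C1+C2)^2 dA

The bending rigidity kappa_b is factored out entirely (W_b = 8 pi kappa_b wb)
and never enters numerically.

All routines accept complex-valued radial samples so that derivatives with
respect to shape coefficients can be taken by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as _leg


class DegenerateShapeError(ValueError):
    """Radial function is non-positive somewhere: not a star-shaped surface."""


class UnderResolvedError(ValueError):
    """Quadrature order too low for the requested harmonic degree."""


# --------------------------------------------------------------------------
# quadrature and Legendre basis tables
# --------------------------------------------------------------------------

_BASIS_CACHE: dict[tuple[int, int], tuple] = {}


def gauss_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights on u = cos(theta) in (-1, 1)."""
    u, w = np.polynomial.legendre.leggauss(order)
    return u, w


def legendre_tables(u: np.ndarray, max_degree: int):
    """Values and first/second u-derivatives of P_0..P_L at the nodes.

    Returns three (len(u), L+1) matrices B, B1, B2 with B[:, l] = P_l(u).
    """
    key = (len(u), max_degree) if u.flags.writeable is False else None
    L = max_degree
    B = _leg.legvander(u, L)
    B1 = np.zeros_like(B)
    B2 = np.zeros_like(B)
    for l in range(L + 1):
        c = np.zeros(l + 1)
        c[l] = 1.0
        if l >= 1:
            B1[:, l] = _leg.legval(u, _leg.legder(c, 1))
        if l >= 2:
            B2[:, l] = _leg.legval(u, _leg.legder(c, 2))
    return B, B1, B2


def _cached_tables(order: int, max_degree: int):
    key = (order, max_degree)
    hit = _BASIS_CACHE.get(key)
    if hit is None:
        u, w = gauss_nodes(order)
        B, B1, B2 = legendre_tables(u, max_degree)
        hit = (u, w, B, B1, B2)
        _BASIS_CACHE[key] = hit
    return hit


# --------------------------------------------------------------------------
# measures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometricMeasures:
    """Global measures of one closed axisymmetric surface.

    ``area`` (squared length), ``volume`` (cubed length) and
    ``total_mean_curvature`` M (length) carry the shape's own scale;
    ``reduced_volume`` v, ``area_difference`` da and
    ``reduced_bending_energy`` wb are scale-invariant and equal 1 for a
    sphere.  The bending rigidity kappa_b is documentation only:
    W_b = 8 pi kappa_b wb.
    """

    area: float
    volume: float
    total_mean_curvature: float
    equivalent_radius: float
    reduced_volume: float
    area_difference: float
    reduced_bending_energy: float

    bending_rigidity_note: str = "W_b = 8*pi*kappa_b*w_b; kappa_b never used numerically"

    def as_dict(self) -> dict:
        return {
            "area": self.area,
            "volume": self.volume,
            "total_mean_curvature": self.total_mean_curvature,
            "equivalent_radius": self.equivalent_radius,
            "reduced_volume": self.reduced_volume,
            "area_difference": self.area_difference,
            "reduced_bending_energy": self.reduced_bending_energy,
        }


@dataclass(frozen=True)
class SurfaceSample:
    """Per-node surface data on the quadrature grid.

    ``weights`` integrate to the sphere measure 4 pi in (theta, phi);
    ``area_elements`` sum to the surface area; ``mean_curvature_sum`` is
    C1 + C2 at each node.  ``positions`` are representative 3-D meridian
    points (phi = 0).
    """

    theta: np.ndarray
    weights: np.ndarray
    positions: np.ndarray
    area_elements: np.ndarray
    mean_curvature_sum: np.ndarray


def meridian_arrays(r, r_u, r_uu, u):
    """Meridian quantities from radial samples (complex-safe, broadcasting).

    Input arrays may be (n,) or (n, m); ``u`` is (n,) and is broadcast.
    Returns rho, z, their theta-derivatives, the metric g = ds/dtheta and
    the mean-curvature sum H = C1 + C2 (sphere of radius R -> 2/R).
    """
    u = np.asarray(u)
    if r.ndim == 2:
        u = u[:, None]
    s = np.sqrt(1.0 - u * u)  # sin(theta) > 0 at interior nodes
    r_t = -s * r_u
    r_tt = -u * r_u + (1.0 - u * u) * r_uu
    rho = r * s
    z = r * u
    rho_t = r_t * s + r * u
    z_t = r_t * u - r * s
    rho_tt = r_tt * s + 2.0 * r_t * u - r * s
    z_tt = r_tt * u - 2.0 * r_t * s - r * u
    g2 = rho_t * rho_t + z_t * z_t
    g = np.sqrt(g2)
    k_meridian = (z_t * rho_tt - rho_t * z_tt) / (g2 * g)
    k_parallel = -z_t / (rho * g)
    H = k_meridian + k_parallel
    return rho, z, rho_t, z_t, g, H


def measures_from_profile(r, r_u, r_uu, u, w) -> dict:
    """A, V, M, wb and derived scale-free measures by quadrature.

    Complex-safe and batched: radial arrays of shape (n,) or (n, m) give
    scalar or length-m entries.  Used both for public geometry evaluation
    and (with complex columns) for coefficient gradients.
    """
    r = np.asarray(r)
    _, _, _, _, g, H = meridian_arrays(r, np.asarray(r_u), np.asarray(r_uu), u)
    w = np.asarray(w)
    wv = w[:, None] if r.ndim == 2 else w
    # dA = 2 pi rho g dtheta = 2 pi r g du  (rho/sin(theta) = r)
    area = 2.0 * np.pi * np.sum(wv * r * g, axis=0)
    volume = (2.0 * np.pi / 3.0) * np.sum(wv * r ** 3, axis=0)
    total_mc = np.pi * np.sum(wv * H * r * g, axis=0)
    wb = 0.125 * np.sum(wv * H * H * r * g, axis=0)
    r_a = np.sqrt(area / (4.0 * np.pi))
    v = volume / ((4.0 * np.pi / 3.0) * r_a ** 3)
    da = total_mc / (4.0 * np.pi * r_a)
    return {
        "area": area,
        "volume": volume,
        "total_mean_curvature": total_mc,
        "equivalent_radius": r_a,
        "reduced_volume": v,
        "area_difference": da,
        "reduced_bending_energy": wb,
    }


def measures_dataclass(raw: dict) -> GeometricMeasures:
    return GeometricMeasures(
        area=float(np.real(raw["area"])),
        volume=float(np.real(raw["volume"])),
        total_mean_curvature=float(np.real(raw["total_mean_curvature"])),
        equivalent_radius=float(np.real(raw["equivalent_radius"])),
        reduced_volume=float(np.real(raw["reduced_volume"])),
        area_difference=float(np.real(raw["area_difference"])),
        reduced_bending_energy=float(np.real(raw["reduced_bending_energy"])),
    )


# --------------------------------------------------------------------------
# analytic spheroid oracle
# --------------------------------------------------------------------------


class SpheroidProfile:
    """Radial function of a spheroid with semi-axes (a, a, c), axis = z.

    Provides analytic r(u) and derivatives for quadrature, and closed-form
    area/volume for use as an independent oracle.
    """

    def __init__(self, a: float, c: float):
        if a <= 0 or c <= 0:
            raise ValueError("semi-axes must be positive")
        self.a = float(a)
        self.c = float(c)

    def radial(self, u):
        a, c = self.a, self.c
        f = (1.0 - u * u) / a ** 2 + u * u / c ** 2
        fp = 2.0 * u * (1.0 / c ** 2 - 1.0 / a ** 2)
        fpp = 2.0 * (1.0 / c ** 2 - 1.0 / a ** 2)
        r = f ** -0.5
        r_u = -0.5 * f ** -1.5 * fp
        r_uu = 0.75 * f ** -2.5 * fp * fp - 0.5 * f ** -1.5 * fpp
        return r, r_u, r_uu

    def measures(self, quadrature_order: int = 96) -> GeometricMeasures:
        u, w = gauss_nodes(quadrature_order)
        r, r_u, r_uu = self.radial(u)
        return measures_dataclass(measures_from_profile(r, r_u, r_uu, u, w))


def spheroid_closed_form(a: float, c: float) -> tuple[float, float, float]:
    """Closed-form (area, volume, reduced volume) for semi-axes (a, a, c)."""
    volume = 4.0 / 3.0 * np.pi * a * a * c
    if np.isclose(a, c):
        area = 4.0 * np.pi * a * a
    elif c > a:  # prolate
        e = np.sqrt(1.0 - a * a / (c * c))
        area = 2.0 * np.pi * a * a * (1.0 + (c / (a * e)) * np.arcsin(e))
    else:  # oblate
        e = np.sqrt(1.0 - c * c / (a * a))
        area = 2.0 * np.pi * a * a * (1.0 + ((1.0 - e * e) / e) * np.arctanh(e))
    r_a = np.sqrt(area / (4.0 * np.pi))
    v = volume / (4.0 / 3.0 * np.pi * r_a ** 3)
    return float(area), float(volume), float(v)
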