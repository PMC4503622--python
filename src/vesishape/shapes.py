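"""Spherical-harmonics parameterization (SHP) of star-shaped vesicle surfaces.

In axisymmetric mode the radial function is a zonal harmonic series

    r(theta) = sum_{l=0}^{L} a_l P_l(cos theta),

so a shape is just its coefficient vector.  Shapes are scale-free: the
dimensionless measures v, da and wb are invariant under uniform rescaling
of the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateShapeError,
    GeometricMeasures,
    SurfaceSample,
    UnderResolvedError,
    _cached_tables,
    legendre_tables,
    measures_dataclass,
    measures_from_profile,
    meridian_arrays,
)

# Harmonic degree cutoff.  Branch competition near the budding line is
# resolution-limited: truncation below ~24 biases the symmetric dumbbell
# against the pear, flipping the predicted bud symmetry.  24 is the
# smallest cutoff at which the budded-shape lobe ratios are converged.
DEFAULT_MAX_DEGREE = 24


@dataclass
class SHPShape:
    """A star-shaped closed surface given by zonal Legendre coefficients.

    ``coefficients[l]`` multiplies P_l(cos theta); the degree-0 term is the
    angular mean radius and must be positive.  ``length_unit`` is
    documentation only — every quantity used downstream is scale-invariant.
    """

    max_degree: int
    coefficients: np.ndarray
    axisymmetric: bool = True
    length_unit: str = "dimensionless"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")
        if not self.axisymmetric:
            raise NotImplementedError("only axisymmetric (zonal) mode is implemented")
        if self.coefficients.shape != (self.max_degree + 1,):
            raise ValueError(
                f"expected {self.max_degree + 1} zonal coefficients, "
                f"got shape {self.coefficients.shape}"
            )
        if self.coefficients[0] <= 0:
            raise ValueError("degree-0 coefficient (mean radius) must be positive")

    # -- evaluation -------------------------------------------------------

    def radial(self, u: np.ndarray):
        """r, dr/du, d2r/du2 at arbitrary u = cos(theta)."""
        B, B1, B2 = legendre_tables(np.asarray(u, dtype=float), self.max_degree)
        a = self.coefficients
        return B @ a, B1 @ a, B2 @ a

    def scaled(self, factor: float) -> "SHPShape":
        return SHPShape(self.max_degree, self.coefficients * factor)

    @property
    def mean_radius(self) -> float:
        return float(self.coefficients[0])


def sphere_shape(radius: float = 1.0, max_degree: int = DEFAULT_MAX_DEGREE) -> SHPShape:
    coeff = np.zeros(max_degree + 1)
    coeff[0] = radius
    return SHPShape(max_degree, coeff)


def shape_from_radial_function(func, max_degree: int, n_fit: int = 256) -> SHPShape:
    """Least-squares projection of an arbitrary radial function r(u) onto
    the zonal basis; ``func`` maps u = cos(theta) in [-1, 1] to radii."""
    from .geometry import gauss_nodes

    u, w = gauss_nodes(n_fit)
    target = np.asarray(func(u), dtype=float)
    B, _, _ = legendre_tables(u, max_degree)
    # weighted least squares with the quadrature weights = L2 projection
    sw = np.sqrt(w)
    coeff, *_ = np.linalg.lstsq(B * sw[:, None], target * sw, rcond=None)
    return SHPShape(max_degree, coeff)


def default_quadrature_order(max_degree: int) -> int:
    # >= 2L+2 required; 4(L+1) leaves ample headroom for curvature terms
    return 4 * (max_degree + 1)


def _checked_profile(shape: SHPShape, quadrature_order: int | None):
    L = shape.max_degree
    order = default_quadrature_order(L) if quadrature_order is None else int(quadrature_order)
    if order < L + 1:
        raise UnderResolvedError(
            f"quadrature order {order} cannot resolve degree {L} (need >= {L + 1})"
        )
    u, w, B, B1, B2 = _cached_tables(order, L)
    a = shape.coefficients
    r = B @ a
    if np.any(r <= 0):
        raise DegenerateShapeError("radial function non-positive at a quadrature node")
    return u, w, r, B1 @ a, B2 @ a


def evaluate_geometry(shape: SHPShape, quadrature_order: int | None = None) -> GeometricMeasures:
    """Area, volume, integrated mean curvature and the scale-free measures
    (v, da, wb) of an SHP shape by Gauss-Legendre quadrature."""
    u, w, r, r_u, r_uu = _checked_profile(shape, quadrature_order)
    return measures_dataclass(measures_from_profile(r, r_u, r_uu, u, w))


def surface_sample(shape: SHPShape, quadrature_order: int | None = None) -> SurfaceSample:
    """Per-node geometry on the quadrature grid (meridian at phi = 0)."""
    u, w, r, r_u, r_uu = _checked_profile(shape, quadrature_order)
    rho, z, _, _, g, H = meridian_arrays(r, r_u, r_uu, u)
    theta = np.arccos(u)
    positions = np.column_stack([rho, np.zeros_like(rho), z])
    weights = 2.0 * np.pi * w  # sums to 4 pi
    area_elements = 2.0 * np.pi * w * r * g  # sums to A
    if np.any(area_elements <= 0):
        raise DegenerateShapeError("non-positive area element")
    return SurfaceSample(
        theta=theta,
        weights=weights,
        positions=positions,
        area_elements=area_elements,
        mean_curvature_sum=H,
    )
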