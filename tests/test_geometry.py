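"""Quadrature geometry of SHP surfaces against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesishape import (
    DegenerateShapeError,
    SpheroidProfile,
    SHPShape,
    UnderResolvedError,
    evaluate_geometry,
    sphere_shape,
    spheroid_closed_form,
    surface_sample,
)
from vesishape.geometry import gauss_nodes, measures_from_profile


def test_unit_sphere_closed_forms():
    m = evaluate_geometry(sphere_shape(1.0))
    assert m.area == pytest.approx(4 * np.pi, rel=1e-12)
    assert m.volume == pytest.approx(4 * np.pi / 3, rel=1e-12)
    assert m.total_mean_curvature == pytest.approx(4 * np.pi, rel=1e-12)
    assert m.equivalent_radius == pytest.approx(1.0, rel=1e-12)
    assert m.reduced_volume == pytest.approx(1.0, rel=1e-12)
    assert m.area_difference == pytest.approx(1.0, rel=1e-12)
    assert m.reduced_bending_energy == pytest.approx(1.0, rel=1e-12)


def test_sphere_scale_invariance():
    m = evaluate_geometry(sphere_shape(2.0))
    assert m.area == pytest.approx(16 * np.pi, rel=1e-12)
    assert m.volume == pytest.approx(32 * np.pi / 3, rel=1e-12)
    for val in (m.reduced_volume, m.area_difference, m.reduced_bending_energy):
        assert val == pytest.approx(1.0, rel=1e-12)


@pytest.mark.parametrize("a,c", [(1.0, 2.0), (2.0, 1.0), (1.0, 1.3), (1.0, 0.5)])
def test_spheroid_quadrature_matches_closed_form(a, c):
    m = SpheroidProfile(a, c).measures(96)
    area, volume, v = spheroid_closed_form(a, c)
    assert m.area == pytest.approx(area, rel=1e-6)
    assert m.volume == pytest.approx(volume, rel=1e-6)
    assert m.reduced_volume == pytest.approx(v, rel=1e-6)


def test_prolate_12_spheroid_reduced_volume_value():
    # independent closed form: a=1, c=2 gives v ~ 0.8950
    _, _, v = spheroid_closed_form(1.0, 2.0)
    assert v == pytest.approx(0.895, abs=5e-4)
    m = SpheroidProfile(1.0, 2.0).measures()
    assert m.reduced_volume == pytest.approx(v, rel=1e-8)


def test_spheroid_curvature_measures_converged_in_order():
    # M and wb stable under doubling the quadrature resolution
    m1 = SpheroidProfile(1.0, 2.0).measures(96)
    m2 = SpheroidProfile(1.0, 2.0).measures(192)
    assert m2.total_mean_curvature == pytest.approx(m1.total_mean_curvature, rel=1e-10)
    assert m2.reduced_bending_energy == pytest.approx(m1.reduced_bending_energy, rel=1e-10)


@st.composite
def smooth_shapes(draw):
    # amplitudes decay as 1/l^2, matching the spectra of smooth closed
    # surfaces (curvature content of mode l scales as l^2 * a_l)
    L = draw(st.sampled_from([4, 8, 12, 16]))
    amps = draw(st.lists(st.floats(-1.0, 1.0), min_size=L - 1, max_size=L - 1))
    coeff = np.zeros(L + 1)
    coeff[0] = 1.0
    coeff[2:] = [0.3 * a / l ** 2 for l, a in enumerate(amps, start=2)]
    return SHPShape(L, coeff)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(shape=smooth_shapes(), scale=st.floats(0.1, 10.0))
def test_scale_invariance_property(shape, scale):
    m1 = evaluate_geometry(shape)
    m2 = evaluate_geometry(shape.scaled(scale))
    assert m2.area == pytest.approx(scale ** 2 * m1.area, rel=1e-10)
    assert m2.volume == pytest.approx(scale ** 3 * m1.volume, rel=1e-10)
    assert m2.reduced_volume == pytest.approx(m1.reduced_volume, abs=1e-10)
    assert m2.area_difference == pytest.approx(m1.area_difference, abs=1e-10)
    assert m2.reduced_bending_energy == pytest.approx(m1.reduced_bending_energy, abs=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(shape=smooth_shapes())
def test_willmore_bound_and_quadrature_convergence(shape):
    from vesishape.shapes import default_quadrature_order

    L = shape.max_degree
    assert evaluate_geometry(shape, 2 * L + 2).reduced_bending_energy >= 1.0 - 1e-6
    order = default_quadrature_order(L)
    m1 = evaluate_geometry(shape, order)
    m2 = evaluate_geometry(shape, 2 * order)
    assert abs(m2.reduced_volume - m1.reduced_volume) < 1e-6
    assert abs(m2.area_difference - m1.area_difference) < 1e-6
    assert abs(m2.reduced_bending_energy - m1.reduced_bending_energy) < 1e-6


def test_degenerate_radius_rejected():
    coeff = np.zeros(3)
    coeff[0] = 1.0
    coeff[2] = 3.0  # drives r negative near the equator
    with pytest.raises(DegenerateShapeError):
        evaluate_geometry(SHPShape(2, coeff))


def test_under_resolved_quadrature_rejected():
    with pytest.raises(UnderResolvedError):
        evaluate_geometry(sphere_shape(1.0, max_degree=12), quadrature_order=6)


def test_surface_sample_invariants():
    shape = SHPShape(4, np.array([1.0, 0.0, 0.1, 0.0, 0.05]))
    sample = surface_sample(shape)
    assert np.all(sample.area_elements > 0)
    assert sample.weights.sum() == pytest.approx(4 * np.pi, rel=1e-12)
    m = evaluate_geometry(shape)
    assert sample.area_elements.sum() == pytest.approx(m.area, rel=1e-10)
    # mean curvature sum of a sphere is 2/R at every node
    sph = surface_sample(sphere_shape(2.0))
    assert np.allclose(sph.mean_curvature_sum, 1.0, atol=1e-10)


def test_batched_profile_measures_match_scalar_path():
    # the complex-step evaluator relies on column batching being exact
    u, w = gauss_nodes(48)
    shapes = [sphere_shape(1.0, 4), SHPShape(4, np.array([1.0, 0, 0.2, 0, 0.05]))]
    R = np.stack([s.radial(u)[0] for s in shapes], axis=1)
    R1 = np.stack([s.radial(u)[1] for s in shapes], axis=1)
    R2 = np.stack([s.radial(u)[2] for s in shapes], axis=1)
    batch = measures_from_profile(R, R1, R2, u, w)
    for j, s in enumerate(shapes):
        m = evaluate_geometry(s, 48)
        assert batch["reduced_bending_energy"][j] == pytest.approx(
            m.reduced_bending_energy, rel=1e-12)
        assert batch["area"][j] == pytest.approx(m.area, rel=1e-12)
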