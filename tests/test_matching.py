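"""Silhouette matching: identity, invariances and robustness."""

import numpy as np
import pytest

from vesishape import match_to_library
from vesishape.matching import (
    NoMatchError,
    curvature_signature,
    normalize_contour,
    solution_silhouette,
)


def _rotate(pts, angle):
    c, s = np.cos(angle), np.sin(angle)
    return pts @ np.array([[c, -s], [s, c]]).T


def test_self_match_identity(tiny_library):
    for key, sol in tiny_library.converged_entries().items():
        sil = solution_silhouette(sol)
        res = match_to_library(sil, tiny_library)
        assert (res.da, res.v) == key
        assert res.distance < 1e-6


def test_match_invariant_to_pose_and_scale(tiny_library):
    sil = solution_silhouette(tiny_library.get(1.15, 0.83))
    base = match_to_library(sil, tiny_library)
    moved = _rotate(sil * 37.0, 1.1) + np.array([250.0, -40.0])
    res = match_to_library(moved, tiny_library)
    assert (res.da, res.v) == (base.da, base.v)
    assert res.distance == pytest.approx(base.distance, abs=1e-6)


def test_circle_matches_most_spherical_entry(tiny_library):
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    circle = np.column_stack([np.cos(t), np.sin(t)]) * 12.0
    res = match_to_library(circle, tiny_library)
    # most spherical corner of the grid: lowest da, highest v
    das = tiny_library.grid_spec.da_values()
    vs = tiny_library.grid_spec.v_values()
    assert abs(res.da - das.min()) <= tiny_library.grid_spec.da_step + 1e-9
    assert abs(res.v - vs.max()) <= tiny_library.grid_spec.v_step + 1e-9


def test_v_restriction_and_no_match_error(tiny_library):
    sil = solution_silhouette(tiny_library.get(1.15, 0.83))
    res = match_to_library(sil, tiny_library, measured_v=0.83)
    assert res.v == pytest.approx(0.83)
    with pytest.raises(NoMatchError):
        match_to_library(sil, tiny_library, measured_v=0.30)


def test_mask_input_equivalent_to_contour(tiny_library):
    sol = tiny_library.get(1.05, 0.83)
    sil = solution_silhouette(sol)
    # rasterize the silhouette into a mask
    pts = (sil - sil.min(axis=0)) / np.ptp(sil, axis=0).max() * 180 + 10
    from skimage.draw import polygon

    mask = np.zeros((220, 220), dtype=bool)
    rr, cc = polygon(pts[:, 1], pts[:, 0], mask.shape)
    mask[rr, cc] = True
    res = match_to_library(mask, tiny_library)
    assert abs(res.da - 1.05) <= tiny_library.grid_spec.da_step + 1e-9
    assert abs(res.v - 0.83) <= tiny_library.grid_spec.v_step + 1e-9


def test_jittered_renders_match_within_one_grid_step(tiny_library, rng):
    """2% smooth boundary jitter must not move the match by more than one
    grid step (seeded trial set)."""
    key = (1.15, 0.83)
    sil = solution_silhouette(tiny_library.get(*key))
    c = sil.mean(axis=0)
    q = sil - c
    ang = np.arctan2(q[:, 1], q[:, 0])
    hits = 0
    trials = 40
    for _ in range(trials):
        noise = sum(rng.normal(0, 0.01) * np.cos(m * ang)
                    + rng.normal(0, 0.01) * np.sin(m * ang) for m in range(1, 6))
        jittered = q * (1.0 + noise)[:, None] + c
        res = match_to_library(jittered, tiny_library)
        if (abs(res.da - key[0]) <= tiny_library.grid_spec.da_step + 1e-9
                and abs(res.v - key[1]) <= tiny_library.grid_spec.v_step + 1e-9):
            hits += 1
    assert hits >= 0.9 * trials


def test_normalize_contour_flags_non_star_shapes():
    t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    _, star = normalize_contour(circle)
    assert star
    # C-shaped horseshoe: rays from the centroid through the body cross
    # both the inner and outer arcs, so the radial profile is multivalued
    arc = np.linspace(-2.4, 2.4, 800)
    outer = np.column_stack([np.cos(arc), np.sin(arc)])
    inner = np.column_stack([0.55 * np.cos(arc[::-1]), 0.55 * np.sin(arc[::-1])])
    horseshoe = np.vstack([outer, inner])
    _, star = normalize_contour(horseshoe)
    assert not star


def test_curvature_signature_scale_invariant():
    t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    blob = np.column_stack([(1 + 0.3 * np.cos(2 * t)) * np.cos(t),
                            (1 + 0.3 * np.cos(2 * t)) * np.sin(t)])
    s1 = curvature_signature(blob)
    s2 = curvature_signature(blob * 17.0)
    np.testing.assert_allclose(s1, s2, atol=1e-8)
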