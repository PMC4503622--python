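"""Synthetic microscopy generator: geometry, noise, and ground truth."""

import numpy as np
import pytest

from vesishape import (
    ImagingConfig,
    PopulationModel,
    VesicleSpec,
    render_plane,
    render_zstack,
    sample_population,
)
from vesishape.synth import PackingError

CLEAN = dict(blur_sigma=0.0, noise_sigma=0.0, background_level=0.0)


def test_sphere_equator_renders_correct_disk():
    cfg = ImagingConfig(**CLEAN)
    spec = VesicleSpec(("sphere", 10.0), (51.2, 51.2, 0.0))
    img, gt = render_plane(spec, cfg, z=0.0)
    # 10 µm disk at 0.2 µm/px: radius 25 px, area ~1963 px; with
    # anti-aliased edges the half-intensity footprint and the total
    # coverage integral both recover the disk area
    assert (img > 50).sum() == pytest.approx(np.pi * 25 ** 2, rel=0.02)
    assert img.sum() / 100.0 == pytest.approx(np.pi * 25 ** 2, rel=1e-3)
    assert gt.true_mm_ratio[0] == 1.0
    assert not gt.clipped[0]


def test_slice_outside_sphere_is_blank():
    cfg = ImagingConfig(**CLEAN)
    spec = VesicleSpec(("sphere", 10.0), (51.2, 51.2, 0.0))
    img, gt = render_plane(spec, cfg, z=6.0)
    assert (img > 0).sum() == 0
    assert not gt.in_slice[0]


def test_spheroid_equatorial_slice_has_ratio_two():
    cfg = ImagingConfig(**CLEAN)
    spec = VesicleSpec(("spheroid", (3.0, 6.0)), (51.2, 51.2, 0.0),
                       orientation=(1.0, 0.0, 0.0))
    img, gt = render_plane(spec, cfg, z=0.0)
    assert gt.true_mm_ratio[0] == pytest.approx(2.0)
    cols = np.where((img > 0).any(axis=0))[0]
    rows = np.where((img > 0).any(axis=1))[0]
    extent_ratio = (cols.max() - cols.min()) / (rows.max() - rows.min())
    assert extent_ratio == pytest.approx(2.0, rel=0.05)


def test_zstack_sphere_slices_and_truth():
    cfg = ImagingConfig(seed=0, frame_shape=(128, 128))
    spec = VesicleSpec(("sphere", 10.0), (12.8, 12.8, 0.0))
    stack, truth = render_zstack(spec, cfg)
    non_empty = (stack > cfg.background_level + 5 * cfg.noise_sigma).any(axis=(1, 2))
    assert non_empty.sum() >= 9  # ~11 slices intersect a 10 µm sphere at 1 µm
    assert not non_empty[0] and not non_empty[-1]  # empty guard slices
    assert truth["reduced_volume"] == 1.0
    assert truth["area_um2"] == pytest.approx(np.pi * 100, rel=1e-12)


def test_zstack_spheroid_truth_uses_closed_form():
    cfg = ImagingConfig(seed=0, frame_shape=(160, 160))
    spec = VesicleSpec(("spheroid", (5.0, 10.0)), (16.0, 16.0, 0.0),
                       orientation=(1.0, 0.0, 0.0))
    _, truth = render_zstack(spec, cfg)
    assert truth["reduced_volume"] == pytest.approx(0.895, abs=5e-4)


def test_zstack_step_larger_than_object_rejected():
    cfg = ImagingConfig(z_step=20.0)
    spec = VesicleSpec(("sphere", 10.0), (51.2, 51.2, 0.0))
    with pytest.raises(ValueError):
        render_zstack(spec, cfg)


def test_seed_determinism_bit_identical():
    cfg = ImagingConfig(seed=42)
    model = PopulationModel(n_vesicles=20, seed=7)
    frames1, truth1 = sample_population(model, 10.0, cfg)
    frames2, truth2 = sample_population(model, 10.0, cfg)
    assert len(frames1) == len(frames2)
    for f1, f2 in zip(frames1, frames2):
        assert np.array_equal(f1, f2)
    assert truth1.equals(truth2)


def test_population_no_dose_all_spherical(rng):
    model = PopulationModel(n_vesicles=50, seed=1)
    ratios = model.sample_ratios(0.0, rng)
    assert np.all(ratios == 1.0)
    assert model.true_mean_ratio(0.0) == 1.0


def test_population_degenerate_deformed_mixture(rng):
    # saturating dose (c_half=0) with a delta distribution at ratio 2
    model = PopulationModel(n_vesicles=40, seed=1, c_half=0.0,
                            budded_fraction=1.0, budded_ratio=2.0, budded_sd=0.0)
    ratios = model.sample_ratios(5.0, rng)
    assert np.all(ratios == 2.0)
    assert model.true_mean_ratio(5.0) == pytest.approx(2.0)


def test_population_mean_monotone_in_dose(rng):
    model = PopulationModel(n_vesicles=400, seed=2)
    doses = [0.0, 2.5, 5.0, 10.0, 20.0, 40.0]
    closed = [model.true_mean_ratio(c) for c in doses]
    assert np.all(np.diff(closed) >= 0)
    sampled = [model.sample_ratios(c, np.random.default_rng(5)).mean() for c in doses]
    # sample means track the closed-form means within a few standard errors
    for s, m in zip(sampled, closed):
        assert s == pytest.approx(m, abs=4 * 0.5 / np.sqrt(model.n_vesicles))


def test_ground_truth_carries_section_diameter():
    model = PopulationModel(n_vesicles=30, seed=3)
    _, truth = sample_population(model, 20.0, ImagingConfig(seed=4))
    expected = truth.equivalent_diameter_um * truth.true_mm_ratio ** (1 / 6)
    np.testing.assert_allclose(truth.section_diameter_um, expected, rtol=1e-12)


def test_impossible_packing_raises():
    model = PopulationModel(n_vesicles=1, diameter_range=(30.0, 30.0), seed=0)
    small = ImagingConfig(frame_shape=(64, 64))  # 12.8 µm frame
    with pytest.raises(PackingError):
        sample_population(model, 0.0, small)


def test_orientation_must_be_unit():
    with pytest.raises(ValueError):
        VesicleSpec(("sphere", 10.0), (0, 0, 0), orientation=(2.0, 0.0, 0.0))
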