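"""Segmentation, ellipse fitting, size filtering and ratio statistics."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from vesishape import (
    ImagingConfig,
    VesicleSpec,
    fit_ellipse,
    measure_frame,
    population_statistics,
    render_plane,
    segment_image,
    select_best_plane,
    size_filter,
)
from vesishape.quant import DegenerateMaskError, VesicleMeasurement


def _measurement(d_um, ratio=1.0):
    return VesicleMeasurement(
        vesicle_id=0, major_axis_um=d_um * ratio ** 0.5,
        minor_axis_um=d_um / ratio ** 0.5, equivalent_diameter_um=d_um,
        mm_ratio=ratio, centroid_um=(0, 0), orientation_rad=0.0,
    )


def test_blank_noise_frame_yields_no_masks(rng):
    frame = rng.normal(10.0, 5.0, size=(256, 256))
    labels, flags = segment_image(frame)
    assert labels.max() == 0
    assert flags == {}


def test_constant_frame_yields_no_masks():
    labels, flags = segment_image(np.full((128, 128), 7.0))
    assert labels.max() == 0 and flags == {}


def test_single_vesicle_mask_area_accurate():
    cfg = ImagingConfig(seed=3)
    img, _ = render_plane(VesicleSpec(("sphere", 10.0), (51.2, 51.2, 0.0)), cfg)
    labels, flags = segment_image(img)
    assert len(flags) == 1
    area_px = (labels == 1).sum()
    assert area_px == pytest.approx(np.pi * 25 ** 2, rel=0.05)


def test_two_separated_vesicles_give_two_masks():
    cfg = ImagingConfig(seed=4)
    specs = [VesicleSpec(("sphere", 8.0), (25.0, 25.0, 0.0)),
             VesicleSpec(("sphere", 12.0), (75.0, 75.0, 0.0))]
    img, _ = render_plane(specs, cfg)
    _, flags = segment_image(img)
    assert len(flags) == 2


def test_best_plane_selection_rules():
    disk = np.zeros((21, 64, 64), dtype=bool)
    for k in range(21):
        r = np.sqrt(max(0.0, 10.0 ** 2 - (k - 10) ** 2))
        yy, xx = np.mgrid[:64, :64]
        disk[k] = (yy - 32) ** 2 + (xx - 32) ** 2 <= r ** 2
    assert select_best_plane(disk) == 10  # sphere: middle slice

    growing = [np.zeros((8, 8), dtype=bool) for _ in range(5)]
    for k in range(5):
        growing[k][: k + 2, : k + 2] = True
    assert select_best_plane(growing) == 4  # monotone growth: last slice

    with pytest.raises(ValueError):
        select_best_plane([np.zeros((4, 4), dtype=bool)] * 3)


def test_best_plane_tie_breaks_low_index():
    a = np.ones((5, 5), dtype=bool)
    assert select_best_plane([a, a.copy()]) == 0


def test_fit_ellipse_circle_and_ellipse():
    yy, xx = np.mgrid[:128, :128]
    circle = (yy - 64) ** 2 + (xx - 64) ** 2 <= 25 ** 2  # 10 µm at 0.2 µm/px
    m = fit_ellipse(circle, 0.2)
    assert m.major_axis_um == pytest.approx(10.0, abs=0.2)
    assert m.minor_axis_um == pytest.approx(10.0, abs=0.2)
    assert m.mm_ratio == pytest.approx(1.0, abs=0.02)

    ellipse = ((yy - 64) / 15) ** 2 + ((xx - 64) / 30) ** 2 <= 1  # 12 x 6 µm
    m = fit_ellipse(ellipse, 0.2)
    assert m.mm_ratio == pytest.approx(2.0, rel=0.02)


def test_fit_ellipse_rejects_degenerate_masks():
    single = np.zeros((16, 16), dtype=bool)
    single[8, 8] = True
    with pytest.raises(DegenerateMaskError):
        fit_ellipse(single, 0.2)
    line = np.zeros((16, 16), dtype=bool)
    line[8, 2:14] = True
    with pytest.raises(DegenerateMaskError):
        fit_ellipse(line, 0.2)


def test_mm_ratio_rotation_invariant():
    yy, xx = np.mgrid[:192, :192]
    ellipse = (((yy - 96) / 20) ** 2 + ((xx - 96) / 45) ** 2) <= 1
    base = fit_ellipse(ellipse, 0.2).mm_ratio
    for angle in (20, 45, 75):
        rot = ndi.rotate(ellipse.astype(float), angle, reshape=False, order=1) > 0.5
        ratio = fit_ellipse(rot, 0.2).mm_ratio
        assert ratio == pytest.approx(base, rel=0.01)


def test_size_filter_bounds_inclusive_and_idempotent():
    ms = [_measurement(d) for d in (4.0, 5.0, 12.0, 20.0, 21.0)]
    kept = size_filter(ms)
    assert [m.equivalent_diameter_um for m in kept] == [5.0, 12.0, 20.0]
    assert size_filter(kept) == kept
    assert size_filter([]) == []
    within = [_measurement(d) for d in (6.0, 7.0)]
    assert size_filter(within) == within


def test_population_statistics_degenerate_and_bimodal():
    stats = population_statistics([1.0] * 25)
    assert stats.mean_ratio == 1.0 and stats.sd_ratio == 0.0
    assert len(stats.peak_locations) == 1
    assert stats.bin_edges[0] == 1.0
    assert stats.peak_locations[0] == pytest.approx(1.05, abs=1e-9)
    assert stats.counts.sum() == 25

    bimodal = [1.02] * 30 + [2.03] * 20
    stats = population_statistics(bimodal)
    assert len(stats.peak_locations) == 2
    with pytest.raises(ValueError):
        population_statistics([])


def test_border_touching_components_flagged_and_excluded():
    cfg = ImagingConfig(seed=5)
    specs = [VesicleSpec(("sphere", 10.0), (2.0, 51.2, 0.0)),   # clipped at left
             VesicleSpec(("sphere", 10.0), (70.0, 51.2, 0.0))]
    img, _ = render_plane(specs, cfg)
    _, flags = segment_image(img)
    assert any(flags.values()) and not all(flags.values())
    measured = measure_frame(img, 0.2, exclude_border=True)
    assert len(measured) == 1
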