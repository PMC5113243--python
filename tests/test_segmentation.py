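import numpy as np
import pytest
from scipy import ndimage

from aaastress.phantom import LABELS
from aaastress.segmentation import (
    SliceGeometry,
    angle_from_anterior,
    derive_ilt,
    dice,
    grow_lumen,
    lumen_polygons,
    polygon_radial_function,
    rasterize_polygon,
    segment_calcium,
    shrink_wall_contour,
    sweep_calcium_threshold,
)
from aaastress.volumes import ImageVolume


def circle(r, n=256, c=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([c[0] + r * np.sin(th), c[1] + r * np.cos(th)])


def test_angle_from_anterior_convention():
    # +y is anterior (0 deg); +x is 90 deg clockwise when viewed from feet
    assert angle_from_anterior(0.0, 1.0) == 0.0
    assert angle_from_anterior(1.0, 0.0) == 90.0
    assert angle_from_anterior(0.0, -1.0) == 180.0
    assert angle_from_anterior(-1.0, 0.0) == 270.0


def test_polygon_radial_function_circle():
    poly = circle(7.0)
    th = np.linspace(0, 2 * np.pi, 50)
    np.testing.assert_allclose(polygon_radial_function(poly, (0, 0), th), 7.0, rtol=1e-3)


def test_grow_lumen_flood_fill_oracle():
    """Region growing equals the connected component of the tolerance band."""
    data = np.full((4, 20, 20), 50.0)
    data[:, 5:15, 5:15] = 200.0
    data[:, 8:12, 17:19] = 200.0  # disconnected bright block must be excluded
    ct = ImageVolume(data, spacing=(3.0, 1.0, 1.0))
    mask = grow_lumen(ct, (2, 10, 10), tolerance=0.2)
    expected = np.zeros_like(mask)
    expected[:, 5:15, 5:15] = True
    np.testing.assert_array_equal(mask, expected)


def test_grow_lumen_input_validation():
    ct = ImageVolume(np.full((3, 8, 8), 100.0), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        grow_lumen(ct, (0, 0, 0), tolerance=1.5)
    with pytest.raises(ValueError):
        grow_lumen(ct, (9, 0, 0))


def test_shrink_circle_oracle():
    shrunk = shrink_wall_contour(circle(10.0), 1.5)
    r = np.hypot(shrunk[:, 0], shrunk[:, 1])
    assert abs(r.mean() - 8.5) < 0.02
    assert np.ptp(r) < 0.05


def test_shrink_matches_distance_transform_on_ellipse():
    """Polygon inward offset agrees with the Euclidean distance transform."""
    a, b, t = 12.0, 8.0, 2.0
    poly = circle(1.0) * np.array([a, b])
    n = 241
    h = 0.125
    x = (np.arange(n) - n // 2) * h
    XX, YY = np.meshgrid(x, x)
    inside = (XX / a) ** 2 + (YY / b) ** 2 < 1.0
    dist = ndimage.distance_transform_edt(inside, sampling=h)
    expected = dist > t
    shrunk = shrink_wall_contour(poly, t)
    import shapely
    from shapely.geometry import Polygon

    got = shapely.contains_xy(Polygon(shrunk), XX, YY)
    assert dice(got, expected) > 0.99


def test_shrink_collapse_raises():
    with pytest.raises(ValueError, match="collapses"):
        shrink_wall_contour(circle(1.0), 2.0)


def test_derive_ilt_annulus_area():
    """Lumen r=5 inside outer r=10 with 1.5 mm wall: ILT ring area matches."""
    grid, sp, orig = (201, 201), (0.1, 0.1), (-10.0, -10.0)
    ilt = derive_ilt(circle(5.0), circle(10.0), 1.5, grid, sp, orig)
    area = ilt.sum() * 0.01
    expected = np.pi * (8.5**2 - 5.0**2)
    assert abs(area - expected) / expected < 0.02


def test_rasterize_polygon_counts_centres():
    m = rasterize_polygon(circle(3.0), (81, 81), (0.1, 0.1), (-4.0, -4.0))
    assert abs(m.sum() * 0.01 - np.pi * 9.0) / (np.pi * 9.0) < 0.02


def test_dice_conventions():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    assert dice(a, b) == 1.0
    a[0, 0] = True
    assert dice(a, b) == 0.0
    b[0, 0] = True
    assert dice(a, b) == 1.0


def test_calcium_exact_on_phantom(small_phantom):
    cfg, _, ct, _, truth = small_phantom
    truth_cal = truth.labels == LABELS["calcium"]
    assert truth_cal.any(), "phantom seed should plant calcium"
    lumen = grow_lumen(ct, truth.lumen_seed_voxel)
    band = np.isin(
        truth.labels, [LABELS["ilt"], LABELS["wall"], LABELS["calcium"]]
    )
    mask = segment_calcium(ct, lumen, 110.0, band_mask=band)
    assert dice(mask, truth_cal) == 1.0


def test_calcium_sweep_monotone_and_shape(small_phantom):
    _, _, ct, _, truth = small_phantom
    lumen = grow_lumen(ct, truth.lumen_seed_voxel)
    band = np.isin(truth.labels, [LABELS["ilt"], LABELS["wall"], LABELS["calcium"]])
    sizes = [
        segment_calcium(ct, lumen, float(p), band_mask=band).sum()
        for p in range(100, 165, 5)
    ]
    assert all(x >= y for x, y in zip(sizes, sizes[1:]))
    sweep = sweep_calcium_threshold(ct, lumen, truth.labels == LABELS["calcium"], band)
    assert len(sweep) == 13
    assert sweep.attrs["best_threshold_pct"] in range(100, 165, 5)


def test_calcium_threshold_validation(small_phantom):
    _, _, ct, _, truth = small_phantom
    lumen = grow_lumen(ct, truth.lumen_seed_voxel)
    with pytest.raises(ValueError):
        segment_calcium(ct, lumen, 99.0)
    with pytest.raises(ValueError):
        segment_calcium(ct, np.zeros_like(lumen), 110.0)


def test_lumen_polygons_recover_circle():
    data = np.zeros((2, 61, 61))
    y, x = np.mgrid[0:61, 0:61]
    data[:, ((x - 30) ** 2 + (y - 30) ** 2) < 20**2] = 1.0
    vol = ImageVolume(data, spacing=(3.0, 0.5, 0.5))
    polys = lumen_polygons(data > 0.5, vol)
    assert set(polys) == {0, 1}
    r = np.hypot(polys[0][:, 0] - 15.0, polys[0][:, 1] - 15.0)
    assert abs(r.mean() - 10.0) < 0.3


def test_slice_geometry_diameters():
    geo = SliceGeometry(
        slice_index=0,
        lumen_polygon=circle(5.0, c=(20, 20)),
        outer_wall_polygon=circle(16.0, c=(20, 20)),
        ilt_mask=None,
        calcium_mask=None,
        spacing=(0.5, 0.5),
    )
    assert abs(geo.outer_diameter - 3.2) < 1e-6
    assert abs(geo.lumen_diameter - 1.0) < 1e-6
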