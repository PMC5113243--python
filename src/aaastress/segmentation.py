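"""Lumen, wall, thrombus and calcium delineation on contrast CT.

The lumen is found by region growing from a seed inside the contrast-bright
blood pool.  CT cannot separate intraluminal thrombus (ILT) from wall, so the
ILT outer boundary is obtained by shrinking the outer wall contour inward by
a constant wall thickness; whatever lies between that shrunk contour and the
lumen boundary is ILT.  Calcium is thresholded relative to the mean lumen
intensity (110% default, sweepable 100-160% in 5% steps).

Polygons are ordered (x, y) point lists in mm.  In-plane masks live on the
volume's voxel grid.  Angles are measured from the anterior direction (+y),
increasing clockwise when viewed from the feet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon

from .volumes import ImageVolume

__all__ = [
    "SliceGeometry",
    "angle_from_anterior",
    "polygon_radial_function",
    "grow_lumen",
    "lumen_polygons",
    "shrink_wall_contour",
    "derive_ilt",
    "segment_calcium",
    "sweep_calcium_threshold",
    "dice",
    "rasterize_polygon",
]


def angle_from_anterior(dx, dy):
    """Angle in degrees from the anterior direction (+y), clockwise, in [0, 360)."""
    return np.mod(np.degrees(np.arctan2(dx, dy)), 360.0)


def polygon_radial_function(polygon: np.ndarray, center, theta: np.ndarray) -> np.ndarray:
    """Radius of a star-shaped polygon along rays at ``theta`` (radians,
    measured from anterior clockwise) about ``center``."""
    d = polygon - np.asarray(center)
    ang = np.mod(np.arctan2(d[:, 0], d[:, 1]), 2.0 * np.pi)
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang)
    return np.interp(theta, ang[order], r[order], period=2.0 * np.pi)


@dataclass
class SliceGeometry:
    """Per-axial-slice geometry: the FE and octant-sampling substrate.

    ``ilt_mask``/``calcium_mask`` are in-plane boolean arrays on the CT voxel
    grid described by ``grid_shape`` (ny, nx), ``spacing`` (dy, dx) and
    ``origin`` (y0, x0) in mm.  Diameters are anteroposterior extents in cm.
    """

    slice_index: int
    lumen_polygon: np.ndarray  # (n, 2) x,y mm
    outer_wall_polygon: np.ndarray
    ilt_mask: np.ndarray | None
    calcium_mask: np.ndarray | None
    spacing: tuple[float, float]  # (dy, dx) mm
    origin: tuple[float, float] = (0.0, 0.0)
    outer_diameter: float = 0.0  # cm
    lumen_diameter: float = 0.0  # cm

    def __post_init__(self):
        self.lumen_polygon = np.asarray(self.lumen_polygon, float)
        self.outer_wall_polygon = np.asarray(self.outer_wall_polygon, float)
        if self.outer_diameter == 0.0:
            self.outer_diameter = _ap_extent_cm(self.outer_wall_polygon)
        if self.lumen_diameter == 0.0:
            self.lumen_diameter = _ap_extent_cm(self.lumen_polygon)

    def with_polygons(self, lumen_polygon=None, outer_wall_polygon=None) -> "SliceGeometry":
        new = replace(
            self,
            lumen_polygon=self.lumen_polygon if lumen_polygon is None else lumen_polygon,
            outer_wall_polygon=(
                self.outer_wall_polygon if outer_wall_polygon is None else outer_wall_polygon
            ),
        )
        new.outer_diameter = _ap_extent_cm(new.outer_wall_polygon)
        new.lumen_diameter = _ap_extent_cm(new.lumen_polygon)
        return new

    def mask_lookup(self, mask: np.ndarray, points_xy: np.ndarray) -> np.ndarray:
        """Nearest-voxel values of an in-plane mask at (x, y) mm points."""
        pts = np.atleast_2d(points_xy)
        iy = np.rint((pts[:, 1] - self.origin[0]) / self.spacing[0]).astype(int)
        ix = np.rint((pts[:, 0] - self.origin[1]) / self.spacing[1]).astype(int)
        ny, nx = mask.shape
        ok = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        out = np.zeros(len(pts), dtype=bool)
        out[ok] = mask[iy[ok], ix[ok]]
        return out


def _ap_extent_cm(polygon: np.ndarray) -> float:
    return float((polygon[:, 1].max() - polygon[:, 1].min()) / 10.0)


# ---------------------------------------------------------------------------
# lumen
# ---------------------------------------------------------------------------


def grow_lumen(ct: ImageVolume, seed_point, tolerance: float = 0.2) -> np.ndarray:
    """Region-growing lumen mask.

    Voxels within ``tolerance`` (fraction) of the mean intensity of the
    3x3x3 neighbourhood around ``seed_point`` (z, y, x index) form the
    candidate set; the 26-connected component containing the seed is the
    lumen.
    """
    if not (0.0 < tolerance < 1.0):
        raise ValueError("tolerance must lie in (0, 1)")
    k, j, i = (int(v) for v in seed_point)
    nz, ny, nx = ct.shape
    if not (0 <= k < nz and 0 <= j < ny and 0 <= i < nx):
        raise ValueError("seed point outside volume")
    nb = ct.data[
        max(k - 1, 0) : k + 2, max(j - 1, 0) : j + 2, max(i - 1, 0) : i + 2
    ]
    m = float(nb.mean())
    cand = np.abs(ct.data - m) <= tolerance * abs(m)
    if not cand[k, j, i]:
        raise ValueError("seed voxel excluded by its own tolerance band")
    lab, _ = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=int))
    mask = lab == lab[k, j, i]
    if not mask.any():
        raise ValueError("region growing produced an empty mask")
    return mask


def lumen_polygons(mask: np.ndarray, volume: ImageVolume) -> dict[int, np.ndarray]:
    """Boundary polygon of the lumen mask per axial slice, in mm (x, y)."""
    from skimage import measure

    out = {}
    for k in range(mask.shape[0]):
        sl = mask[k]
        if not sl.any():
            continue
        contours = measure.find_contours(sl.astype(float), 0.5)
        if not contours:
            continue
        c = max(contours, key=len)  # rows are (y_index, x_index)
        x = c[:, 1] * volume.spacing[2] + volume.origin[2]
        y = c[:, 0] * volume.spacing[1] + volume.origin[1]
        out[k] = np.column_stack([x, y])
    return out


# ---------------------------------------------------------------------------
# wall shrinking and ILT
# ---------------------------------------------------------------------------


def shrink_wall_contour(outer_polygon: np.ndarray, wall_thickness: float) -> np.ndarray:
    """Inward normal offset of the outer wall contour by the wall thickness."""
    if wall_thickness < 0:
        raise ValueError("wall thickness must be >= 0")
    pts = np.asarray(outer_polygon, float)
    if wall_thickness == 0:
        return pts.copy()
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("outer contour polygon is not simple")
    inner = poly.buffer(-wall_thickness)
    if inner.is_empty:
        raise ValueError(
            f"wall contour collapses when shrunk by {wall_thickness} mm"
        )
    if isinstance(inner, MultiPolygon):
        inner = max(inner.geoms, key=lambda g: g.area)
    coords = np.asarray(inner.exterior.coords)[:-1]
    return coords


def rasterize_polygon(
    polygon: np.ndarray,
    grid_shape: tuple[int, int],
    spacing: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Boolean in-plane mask of voxel centres inside a polygon."""
    ny, nx = grid_shape
    y = np.arange(ny) * spacing[0] + origin[0]
    x = np.arange(nx) * spacing[1] + origin[1]
    XX, YY = np.meshgrid(x, y)
    return shapely.contains_xy(Polygon(np.asarray(polygon, float)), XX, YY)


def derive_ilt(
    lumen_polygon: np.ndarray,
    outer_polygon: np.ndarray,
    wall_thickness: float,
    grid_shape: tuple[int, int],
    spacing: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """ILT mask: inside the shrunk wall contour, outside the lumen.

    If the lumen pokes more than one voxel outside the shrunk contour a
    warning is emitted and the overlap clipped (the mask construction clips
    by definition).
    """
    shrunk = shrink_wall_contour(outer_polygon, wall_thickness)
    inside_shrunk = rasterize_polygon(shrunk, grid_shape, spacing, origin)
    inside_lumen = rasterize_polygon(lumen_polygon, grid_shape, spacing, origin)
    # sub-voxel excursions are rasterization jitter; only a lumen that pokes
    # deeper than one voxel beyond the shrunk contour is suspicious
    overhang = Polygon(lumen_polygon).difference(Polygon(shrunk).buffer(max(spacing)))
    if not overhang.is_empty and overhang.area > max(spacing) ** 2:
        warnings.warn(
            "lumen extends outside the shrunk wall contour; clipping",
            stacklevel=2,
        )
    return inside_shrunk & ~inside_lumen


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap; two empty masks count as perfect agreement (1)."""
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def segment_calcium(
    ct: ImageVolume,
    lumen_mask: np.ndarray,
    threshold_pct: float = 110.0,
    band_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Calcium: band voxels brighter than threshold_pct% of the mean lumen
    intensity.

    ``band_mask`` restricts the search to the wall/ILT band; without it every
    non-lumen voxel is eligible.
    """
    if not (100.0 <= threshold_pct <= 160.0):
        raise ValueError("threshold_pct must lie in [100, 160]")
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")
    mean_lumen = float(ct.data[lumen_mask].mean())
    band = ~lumen_mask if band_mask is None else (band_mask & ~lumen_mask)
    return band & (ct.data > (threshold_pct / 100.0) * mean_lumen)


def sweep_calcium_threshold(
    ct: ImageVolume,
    lumen_mask: np.ndarray,
    reference_mask: np.ndarray,
    band_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Dice agreement against a reference over the 100-160% threshold sweep.

    Thirteen thresholds in 5% steps; the returned frame carries the argmax
    threshold in ``df.attrs["best_threshold_pct"]``.
    """
    rows = []
    for pct in range(100, 165, 5):
        mask = segment_calcium(ct, lumen_mask, float(pct), band_mask)
        rows.append({"threshold_pct": pct, "dice": dice(mask, reference_mask)})
    df = pd.DataFrame(rows)
    df.attrs["best_threshold_pct"] = int(df.loc[df["dice"].idxmax(), "threshold_pct"])
    return df
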