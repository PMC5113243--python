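"""Octant-wise sampling of SUV, composition and stress.

Each axial slice of the aneurysm (anteroposterior outer diameter > 3.0 cm)
is divided into eight 45-degree sectors about the outer-wall centroid,
starting at the anterior direction (+y) and proceeding clockwise as seen
from the feet.  Per octant the analysis records the maximum wall SUV, the
ILT and calcium area fractions of the lumen-to-outer-wall band, the maximum
retained normalized wall stress, and the slice diameters.  Slices within
~6.5 mm of the first aneurysmal slice form the neck; the rest of the
aneurysm is the sac.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .segmentation import (
    SliceGeometry,
    angle_from_anterior,
    rasterize_polygon,
    shrink_wall_contour,
)
from .volumes import ImageVolume

__all__ = [
    "OctantRecord",
    "octant_index_of_angle",
    "define_aaa_extent",
    "divide_octants",
    "sample_slice",
    "sample_octant",
    "build_octant_table",
    "wall_thickness_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass
class OctantRecord:
    """One row of the hierarchical analysis table."""

    patient_id: int
    slice_index: int
    octant_index: int  # 1..8
    suv_max: float
    ilt_ratio: float
    calcium_ratio: float
    norm_stress: float
    outer_diameter: float  # cm
    lumen_diameter: float  # cm
    region: str  # "neck" | "sac"
    octant_area: float  # mm^2


def octant_index_of_angle(angle_deg) -> np.ndarray:
    """Octant 1..8 from the anterior-clockwise angle; sector k covers
    (45(k-1), 45k], i.e. boundary angles resolve to the lower octant."""
    a = np.mod(np.asarray(angle_deg, float), 360.0)
    idx = np.floor(a / 45.0).astype(int) + 1
    exact = (np.mod(a, 45.0) == 0) & (a > 0)
    idx = np.where(exact, idx - 1, idx)
    return np.clip(idx, 1, 8)


def define_aaa_extent(
    slices,
    slice_spacing_mm: float,
    diameter_cutoff_cm: float = 3.0,
    neck_extent_mm: float = 6.5,
) -> pd.DataFrame:
    """Included aneurysm slices with neck/sac labels.

    ``slices`` is a sequence of (slice_index, outer_diameter_cm) pairs, a
    DataFrame with those columns, or SliceGeometry objects.  The included set
    is the contiguous run of slices exceeding the cutoff that contains the
    maximum diameter; slices within ``neck_extent_mm`` of the run's first
    slice are the neck.
    """
    if isinstance(slices, pd.DataFrame):
        pairs = list(zip(slices["slice_index"], slices["outer_diameter"]))
    else:
        pairs = [
            (s.slice_index, s.outer_diameter) if isinstance(s, SliceGeometry) else tuple(s)
            for s in slices
        ]
    pairs.sort(key=lambda t: t[0])
    idxs = np.array([p[0] for p in pairs])
    diams = np.array([p[1] for p in pairs], float)
    above = diams > diameter_cutoff_cm
    if not above.any():
        logger.warning("no slice exceeds %.1f cm; empty aneurysm extent", diameter_cutoff_cm)
        return pd.DataFrame(columns=["slice_index", "outer_diameter", "region"])
    # contiguous run containing the maximum diameter
    imax = int(np.argmax(diams))
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(pairs) - 1 and above[hi + 1]:
        hi += 1
    sel = slice(lo, hi + 1)
    first = idxs[lo]
    dist = np.abs(idxs[sel] - first) * slice_spacing_mm
    region = np.where(dist <= neck_extent_mm, "neck", "sac")
    return pd.DataFrame(
        {"slice_index": idxs[sel], "outer_diameter": diams[sel], "region": region}
    )


def divide_octants(slice_geo: SliceGeometry) -> dict:
    """Sector definition for one slice: centroid and the 45-degree edges."""
    center = slice_geo.outer_wall_polygon.mean(axis=0)
    if not np.all(np.isfinite(center)):
        raise ValueError("degenerate outer contour centroid")
    return {"center": center, "edges_deg": np.arange(0.0, 361.0, 45.0)}


def _octants_of_points(points_xy: np.ndarray, center) -> np.ndarray:
    d = np.atleast_2d(points_xy) - np.asarray(center)
    return octant_index_of_angle(angle_from_anterior(d[:, 0], d[:, 1]))


def sample_slice(
    slice_geo: SliceGeometry,
    pet_on_ct: ImageVolume,
    stress_field,
    patient_id: int,
    region: str,
    wall_thickness: float = 1.5,
    wall_delta_mm: float = 0.0,
) -> pd.DataFrame:
    """All octant records of one slice.

    ``stress_field`` is a post-processed per-slice StressField (may be None
    when only SUV/composition are needed).  ``wall_delta_mm`` extends the
    SUV-sampling wall band inward (partial-volume sensitivity analysis).
    """
    k = slice_geo.slice_index
    grid_shape = pet_on_ct.shape[1:]
    spacing = (pet_on_ct.spacing[1], pet_on_ct.spacing[2])
    origin = (pet_on_ct.origin[1], pet_on_ct.origin[2])

    inside_outer = rasterize_polygon(slice_geo.outer_wall_polygon, grid_shape, spacing, origin)
    inside_lumen = rasterize_polygon(slice_geo.lumen_polygon, grid_shape, spacing, origin)
    band = inside_outer & ~inside_lumen
    shrunk = shrink_wall_contour(slice_geo.outer_wall_polygon, wall_thickness + wall_delta_mm)
    wall_band = inside_outer & ~rasterize_polygon(shrunk, grid_shape, spacing, origin)

    center = slice_geo.outer_wall_polygon.mean(axis=0)
    jj, ii = np.nonzero(band)
    xy = np.column_stack(
        [ii * spacing[1] + origin[1], jj * spacing[0] + origin[0]]
    )
    oct_of_band = _octants_of_points(xy, center)
    in_wall_band = wall_band[jj, ii]
    pet_vals = pet_on_ct.data[k][jj, ii]
    ilt_vals = (
        slice_geo.ilt_mask[jj, ii] if slice_geo.ilt_mask is not None else np.zeros(len(jj), bool)
    )
    cal_vals = (
        slice_geo.calcium_mask[jj, ii]
        if slice_geo.calcium_mask is not None
        else np.zeros(len(jj), bool)
    )

    if stress_field is not None:
        keep = (stress_field.material == "wall") & ~stress_field.discarded
        el_oct = _octants_of_points(stress_field.centroids[keep], center)
        el_norm = stress_field.normalized[keep]
    else:
        el_oct = np.array([], int)
        el_norm = np.array([])

    voxel_area = spacing[0] * spacing[1]
    rows = []
    for o in range(1, 9):
        m = oct_of_band == o
        wm = m & in_wall_band
        if not wm.any():
            logger.info("patient %s slice %s octant %s has no wall voxels; dropped",
                        patient_id, k, o)
            continue
        n_band = int(m.sum())
        em = el_oct == o
        rows.append(
            OctantRecord(
                patient_id=patient_id,
                slice_index=k,
                octant_index=o,
                suv_max=float(pet_vals[wm].max()),
                ilt_ratio=float(ilt_vals[m].sum() / n_band),
                calcium_ratio=float(cal_vals[m].sum() / n_band),
                norm_stress=float(el_norm[em].max()) if em.any() else 0.0,
                outer_diameter=slice_geo.outer_diameter,
                lumen_diameter=slice_geo.lumen_diameter,
                region=region,
                octant_area=n_band * voxel_area,
            )
        )
    return pd.DataFrame([asdict(r) for r in rows])


def sample_octant(
    slice_geo: SliceGeometry,
    octant: int,
    pet_on_ct: ImageVolume,
    stress_field,
    patient_id: int = 0,
    region: str = "sac",
    wall_thickness: float = 1.5,
) -> OctantRecord | None:
    """Single-octant convenience wrapper around :func:`sample_slice`."""
    df = sample_slice(slice_geo, pet_on_ct, stress_field, patient_id, region, wall_thickness)
    hit = df[df["octant_index"] == octant]
    if hit.empty:
        return None
    return OctantRecord(**hit.iloc[0].to_dict())


def build_octant_table(
    slices: list[SliceGeometry],
    pet_on_ct: ImageVolume,
    stress_fields: dict,
    patient_id: int,
    slice_spacing_mm: float,
    wall_thickness: float = 1.5,
    diameter_cutoff_cm: float = 3.0,
    neck_extent_mm: float = 6.5,
    wall_delta_mm: float = 0.0,
) -> pd.DataFrame:
    """Octant table of one patient over the aneurysm extent."""
    extent = define_aaa_extent(slices, slice_spacing_mm, diameter_cutoff_cm, neck_extent_mm)
    region_of = dict(zip(extent["slice_index"], extent["region"]))
    geo_of = {s.slice_index: s for s in slices}
    frames = []
    for k, region in region_of.items():
        frames.append(
            sample_slice(
                geo_of[k],
                pet_on_ct,
                stress_fields.get(k),
                patient_id,
                region,
                wall_thickness,
                wall_delta_mm,
            )
        )
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def wall_thickness_sensitivity(
    slices: list[SliceGeometry],
    pet_on_ct: ImageVolume,
    stress_fields: dict,
    patient_id: int,
    slice_spacing_mm: float,
    wall_thickness: float = 1.5,
    delta_mm: float = 0.6,
    ilt_cutoff: float = 0.67,
) -> dict:
    """Partial-volume sensitivity: re-extract SUV_max with the wall band
    extended inward by ``delta_mm`` (about one in-plane pixel) and compare.

    Returns both tables, the median [IQR] under each setting, and the
    percent difference of the median overall and in the high-ILT stratum.
    """

    def _table(delta):
        return build_octant_table(
            slices,
            pet_on_ct,
            stress_fields,
            patient_id,
            slice_spacing_mm,
            wall_thickness,
            wall_delta_mm=delta,
        )

    base = _table(0.0)
    thick = _table(delta_mm)
    merged = base.merge(
        thick[["slice_index", "octant_index", "suv_max"]],
        on=["slice_index", "octant_index"],
        suffixes=("", "_thick"),
    )

    def _summary(df):
        s, st = df["suv_max"], df["suv_max_thick"]
        med, med_t = float(s.median()), float(st.median())
        return {
            "median": med,
            "iqr": (float(s.quantile(0.25)), float(s.quantile(0.75))),
            "median_thick": med_t,
            "iqr_thick": (float(st.quantile(0.25)), float(st.quantile(0.75))),
            "pct_diff_median": 100.0 * (med_t - med) / med if med else float("nan"),
            "n": len(df),
        }

    out = {
        "delta_mm": delta_mm,
        "baseline": base,
        "thickened": thick,
        "overall": _summary(merged),
    }
    stratum = merged[merged["ilt_ratio"] > ilt_cutoff]
    out["high_ilt"] = _summary(stratum) if len(stratum) else None
    return out
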