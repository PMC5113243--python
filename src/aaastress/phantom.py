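"""Synthetic AAA PET-CT patients with known ground truth.

Every downstream stage (segmentation, stress, registration, octant sampling,
statistics) is exercised against phantoms whose geometry, composition,
misregistration and SUV structure are planted and recorded:

* CT: a bright contrast-filled lumen inside a perturbed-ellipse aneurysm with
  constant wall thickness, a crescent of intraluminal thrombus (ILT), bright
  calcific deposits, and a vertebra block posterior to the aorta that serves
  as the registration landmark.
* PET: per octant the wall (and ILT, at a configurable attenuation) is
  painted as a plateau whose maximum is drawn from a linear mixed-effects
  model -- fixed effects of normalized stress, composition and diameter plus
  random intercepts for patient, slice and octant number -- so octant-level
  SUV_max extraction can recover the planted values exactly when no blur is
  applied.  The painted PET is then displaced by a planted rigid transform.
* The "provisional" stress entering the generative model is a Laplace-law
  estimate (pressure x lumen radius / band thickness), normalized per patient
  over the aneurysmal slices, which mimics how the finite-element normalized
  stress behaves across octants.

``simulate_cohort`` produces the octant truth table directly from the same
generative model, skipping voxel rendering, for fast cohort-level statistics
simulations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .octants import define_aaa_extent, octant_index_of_angle
from .registration import RigidTransform, resample
from .volumes import ImageVolume

__all__ = [
    "LABELS",
    "PhantomConfig",
    "GenerativeModel",
    "PhantomTruth",
    "generate_patient",
    "paint_suv",
    "write_phantom",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

LABELS = {"background": 0, "lumen": 1, "ilt": 2, "wall": 3, "calcium": 4, "vertebra": 5}

_MIN_LUMEN_RADIUS_MM = 3.0
_SUV_FLOOR = 0.05


@dataclass(frozen=True)
class GenerativeModel:
    """Mixed-effects generative model of octant-level wall SUV_max.

    The linear predictor is
    ``beta0 + beta_stress*s + beta_ilt*ilt + beta_cal*cal + beta_diam*d +
    beta_inter*s*ilt`` with ``s`` the normalized stress, ``ilt``/``cal`` the
    area ratios (0-1; the ILT slope is per unit, i.e. -0.121 per 10% means
    -1.21), ``d`` the outer diameter in cm.  Random intercepts: patient,
    slice (nested in patient) and octant number (1-8, drawn per patient).
    In univariate mode only ``beta0`` and ``beta_stress`` are active.
    """

    beta0: float = 1.4
    beta_stress: float = 0.552
    beta_ilt: float = -1.21
    beta_cal: float = 0.3
    beta_diam: float = 0.1
    beta_inter: float = 1.0
    sd_patient: float = 0.158
    sd_slice: float = float(np.sqrt(3.464e-4))
    sd_octant: float = float(np.sqrt(0.012))
    sd_resid: float = 0.30
    mode: str = "univariate"

    def __post_init__(self):
        for name in ("sd_patient", "sd_slice", "sd_octant", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("univariate", "multivariate"):
            raise ValueError("mode must be 'univariate' or 'multivariate'")

    @classmethod
    def univariate(cls, **kw) -> "GenerativeModel":
        return cls(mode="univariate", **kw)

    @classmethod
    def multivariate(cls, **kw) -> "GenerativeModel":
        kw.setdefault("beta0", 1.2)
        kw.setdefault("beta_stress", 0.0)
        return cls(mode="multivariate", **kw)

    def linear_predictor(self, stress, ilt, cal, diam):
        stress = np.asarray(stress, float)
        if self.mode == "univariate":
            return self.beta0 + self.beta_stress * stress
        return (
            self.beta0
            + self.beta_stress * stress
            + self.beta_ilt * np.asarray(ilt, float)
            + self.beta_cal * np.asarray(cal, float)
            + self.beta_diam * np.asarray(diam, float)
            + self.beta_inter * stress * np.asarray(ilt, float)
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and misregistration settings of the phantom cohort."""

    n_patients: int = 21
    grid_shape: tuple[int, int, int] = (24, 144, 144)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (3.0, 0.6, 0.6)  # mm
    wall_thickness: float = 1.5  # mm
    diameter_range_cm: tuple[float, float] = (3.5, 5.5)
    aaa_cutoff_cm: float = 3.0
    neck_extent_mm: float = 6.5
    baseline_radius_mm: float = 11.0
    ilt_burden: float = 1.0  # scales crescent depth; 0 disables ILT
    calcium_fraction: float = 0.35  # per-slice probability of a deposit
    lumen_hu: float = 200.0
    wall_hu: float = 60.0
    ilt_hu: float = 40.0
    background_hu: float = 20.0
    calcium_rel: float = 1.5  # CT calcium level relative to mean lumen
    vertebra_hu: float = 500.0
    ilt_suv_attenuation: float = 1.0  # PET plateau factor inside ILT
    octant_guard_mm: float = 1.0  # boundary guard band painted with the min of neighbours
    rigid_offset_mode: str = "integer_voxel"  # or "continuous"
    max_offset_mm: float = 6.0
    max_offset_deg: float = 3.0
    max_offset_axial_mm: float = 3.0
    interp: str = "nearest"  # PET displacement interpolation
    psf_sigma_mm: float = 0.0
    systolic_range: tuple[float, float] = (110.0, 160.0)
    diastolic_range: tuple[float, float] = (65.0, 90.0)
    seed: int = 0

    def __post_init__(self):
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.calcium_rel <= 1.10:
            raise ValueError("calcium_rel must exceed 1.10 (the segmentation threshold)")
        if self.interp not in ("nearest", "linear"):
            raise ValueError("interp must be 'nearest' or 'linear'")
        if self.rigid_offset_mode not in ("integer_voxel", "continuous", "none"):
            raise ValueError("rigid_offset_mode must be integer_voxel|continuous|none")


@dataclass
class PhantomTruth:
    """Planted ground truth of one synthetic patient."""

    patient_id: int
    labels: np.ndarray  # int8 volume, codes in LABELS
    true_octants: pd.DataFrame
    rigid_offset: RigidTransform
    blood_pressure: dict  # systolic, diastolic, map (mmHg)
    model: GenerativeModel
    config: PhantomConfig
    aorta_center: tuple[float, float]  # (x, y) mm
    outer_polygons: dict  # slice -> (n,2) mm
    lumen_polygons: dict
    lumen_seed_voxel: tuple[int, int, int]
    vertebra_box: tuple  # ((y0,y1),(x0,x1)) mm


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

_N_THETA = 720
_THETA = (np.arange(_N_THETA) + 0.5) * (2.0 * np.pi / _N_THETA)
_N_POLY = 256


@dataclass
class _PatientGeometry:
    center: tuple[float, float]  # (x, y) mm
    ax_ratio: float  # x semi-axis / y semi-axis
    r_base: float
    r_max: float
    zc: float
    zw: float
    n_slices: int
    wall_thickness: float
    ilt_theta_deg: float
    ilt_extent_deg: float
    ilt_depth_frac: float  # 0 disables ILT
    max_diameter_cm: float

    def r0(self, z) -> np.ndarray:
        z = np.asarray(z, float)
        return self.r_base + (self.r_max - self.r_base) * np.exp(-(((z - self.zc) / self.zw) ** 2))

    def bulge(self, z) -> np.ndarray:
        return (self.r0(z) - self.r_base) / max(self.r_max - self.r_base, 1e-9)

    def ap_diameter_cm(self, z) -> np.ndarray:
        return 2.0 * self.r0(z) / 10.0

    def radial_functions(self, z: int):
        """(r_out, r_in, r_lum) on the shared angular grid for one slice."""
        ay = float(self.r0(z))
        ax = self.ax_ratio * ay
        dx, dy = np.sin(_THETA), np.cos(_THETA)
        r_out = 1.0 / np.sqrt((dx / ax) ** 2 + (dy / ay) ** 2)
        # inward normal offset of the ellipse (exact parametric form)
        phi = np.linspace(0.0, 2.0 * np.pi, 4 * _N_THETA, endpoint=False)
        px, py = ax * np.sin(phi), ay * np.cos(phi)
        nx, ny = ay * np.sin(phi), ax * np.cos(phi)
        nn = np.hypot(nx, ny)
        qx, qy = px - self.wall_thickness * nx / nn, py - self.wall_thickness * ny / nn
        ang = np.mod(np.arctan2(qx, qy), 2.0 * np.pi)
        rad = np.hypot(qx, qy)
        order = np.argsort(ang)
        r_in = np.interp(_THETA, ang[order], rad[order], period=2.0 * np.pi)
        # ILT crescent depth
        depth = np.zeros(_N_THETA)
        if self.ilt_depth_frac > 0:
            delta = np.degrees(_THETA) - self.ilt_theta_deg
            delta = (delta + 180.0) % 360.0 - 180.0
            inside = np.abs(delta) < self.ilt_extent_deg / 2.0
            bump = np.where(
                inside, 0.5 * (1.0 + np.cos(np.pi * delta / (self.ilt_extent_deg / 2.0))), 0.0
            )
            depth = (
                self.ilt_depth_frac
                * float(self.bulge(z))
                * bump
                * np.maximum(r_in - _MIN_LUMEN_RADIUS_MM, 0.0)
            )
        r_lum = np.maximum(r_in - depth, _MIN_LUMEN_RADIUS_MM)
        r_lum = np.minimum(r_lum, r_in)
        return r_out, r_in, r_lum

    def polygon(self, radial: np.ndarray) -> np.ndarray:
        """(x, y) polygon from a radial function, about the aorta center."""
        th = np.linspace(0.0, 2.0 * np.pi, _N_POLY, endpoint=False)
        r = np.interp(th, _THETA, radial, period=2.0 * np.pi)
        cx, cy = self.center
        return np.column_stack([cx + r * np.sin(th), cy + r * np.cos(th)])


def _sample_geometry(
    cfg: PhantomConfig,
    rng: np.random.Generator,
    n_slices: int,
    center,
    axial_margin_slices: int | None = None,
) -> _PatientGeometry:
    d_cm = float(rng.uniform(*cfg.diameter_range_cm))
    r_max = d_cm * 10.0 / 2.0
    zc = (n_slices - 1) / 2.0
    if axial_margin_slices is None:
        zw = 0.5 * n_slices
    else:
        # choose the bulge width so the aneurysmal extent (diameter above the
        # cutoff) keeps an axial margin inside the volume: the PET field must
        # cover it even after the planted axial offset is applied and undone
        cutoff_r = cfg.aaa_cutoff_cm * 10.0 / 2.0 - 0.5
        half = max(zc - axial_margin_slices, 1.0)
        ratio = (r_max - cfg.baseline_radius_mm) / max(cutoff_r - cfg.baseline_radius_mm, 0.5)
        zw = half / np.sqrt(np.log(ratio)) if ratio > 1.05 else half
    return _PatientGeometry(
        center=center,
        ax_ratio=float(rng.uniform(0.8, 1.2)),
        r_base=cfg.baseline_radius_mm,
        r_max=r_max,
        zc=zc,
        zw=float(zw),
        n_slices=n_slices,
        wall_thickness=cfg.wall_thickness,
        ilt_theta_deg=float(rng.uniform(0.0, 360.0)),
        ilt_extent_deg=float(rng.uniform(120.0, 300.0)),
        ilt_depth_frac=cfg.ilt_burden * float(rng.uniform(0.3, 0.95)),
        max_diameter_cm=d_cm,
    )


def _blood_pressure(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    sys_ = float(rng.uniform(*cfg.systolic_range))
    dia = float(rng.uniform(*cfg.diastolic_range))
    dia = min(dia, sys_ - 20.0)
    return {"systolic": sys_, "diastolic": dia, "map": dia + (sys_ - dia) / 3.0}


def _laplace_stress(r_out, r_lum, map_mmhg: float, octant_of_theta: np.ndarray) -> np.ndarray:
    """Laplace-law stress estimate per octant: p * r_lumen / band thickness."""
    sigma = map_mmhg * r_lum / np.maximum(r_out - r_lum, 1e-6)
    return np.array([sigma[octant_of_theta == o].mean() for o in range(1, 9)])


_OCT_OF_THETA = octant_index_of_angle(np.degrees(_THETA))


def _octant_truth_rows(geo: _PatientGeometry, bp: dict, slices) -> pd.DataFrame:
    """Analytic per-octant composition, diameters and Laplace stress."""
    dtheta = 2.0 * np.pi / _N_THETA
    rows = []
    for z in slices:
        r_out, r_in, r_lum = geo.radial_functions(z)
        band_a = 0.5 * (r_out**2 - r_lum**2) * dtheta
        ilt_a = 0.5 * (r_in**2 - r_lum**2) * dtheta
        sig = _laplace_stress(r_out, r_lum, bp["map"], _OCT_OF_THETA)
        lum_d = (
            np.interp(0.0, _THETA, r_lum, period=2 * np.pi)
            + np.interp(np.pi, _THETA, r_lum, period=2 * np.pi)
        ) / 10.0
        for o in range(1, 9):
            m = _OCT_OF_THETA == o
            band = float(band_a[m].sum())
            rows.append(
                {
                    "slice_index": int(z),
                    "octant_index": o,
                    "ilt_ratio": float(ilt_a[m].sum() / band),
                    "calcium_ratio": 0.0,
                    "stress_raw": float(sig[o - 1]),
                    "outer_diameter": float(geo.ap_diameter_cm(z)),
                    "lumen_diameter": float(lum_d),
                    "octant_area": band,
                }
            )
    return pd.DataFrame(rows)


def _finalize_truth_table(
    df: pd.DataFrame,
    geo: _PatientGeometry,
    cfg: PhantomConfig,
    slice_spacing: float,
) -> pd.DataFrame:
    """Mark the aneurysm extent, label neck/sac, normalize stress."""
    per_slice = df.drop_duplicates("slice_index")[["slice_index", "outer_diameter"]]
    extent = define_aaa_extent(
        list(per_slice.itertuples(index=False, name=None)),
        slice_spacing,
        cfg.aaa_cutoff_cm,
        cfg.neck_extent_mm,
    )
    region_of = dict(zip(extent["slice_index"], extent["region"]))
    df = df.copy()
    df["included"] = df["slice_index"].isin(region_of)
    df["region"] = df["slice_index"].map(lambda k: region_of.get(k, "outside"))
    inc = df["included"].to_numpy()
    peak = df.loc[inc, "stress_raw"].max() if inc.any() else df["stress_raw"].max()
    df["norm_stress"] = np.minimum(df["stress_raw"] / peak, 1.0)
    return df


def _draw_suv(
    df: pd.DataFrame, model: GenerativeModel, patient_id: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-octant SUV_max from the mixed-effects generative model."""
    df = df.copy()
    b_pat = rng.normal(0.0, model.sd_patient)
    slices = np.sort(df["slice_index"].unique())
    b_slice = dict(zip(slices, rng.normal(0.0, model.sd_slice, len(slices))))
    b_oct = dict(zip(range(1, 9), rng.normal(0.0, model.sd_octant, 8)))
    eta = model.linear_predictor(
        df["norm_stress"], df["ilt_ratio"], df["calcium_ratio"], df["outer_diameter"]
    )
    eps = rng.normal(0.0, model.sd_resid, len(df))
    suv = (
        np.asarray(eta)
        + b_pat
        + df["slice_index"].map(b_slice).to_numpy()
        + df["octant_index"].map(b_oct).to_numpy()
        + eps
    )
    n_clip = int((suv < _SUV_FLOOR).sum())
    if n_clip:
        logger.info("patient %s: clipped %d negative SUV draws to %.2f",
                    patient_id, n_clip, _SUV_FLOOR)
    df["suv_max"] = np.maximum(suv, _SUV_FLOOR)
    df["patient_id"] = patient_id
    return df


# ---------------------------------------------------------------------------
# voxel rendering
# ---------------------------------------------------------------------------


def _grid_polar(cfg: PhantomConfig, center):
    nz, ny, nx = cfg.grid_shape
    y = np.arange(ny) * cfg.spacing[1]
    x = np.arange(nx) * cfg.spacing[2]
    XX, YY = np.meshgrid(x, y)
    dx, dy = XX - center[0], YY - center[1]
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dx, dy), 2.0 * np.pi)
    return XX, YY, r, theta


def _vertebra_box_mm(cfg: PhantomConfig, center) -> tuple:
    x0, x1 = center[0] - 12.0, center[0] + 12.0
    return ((6.0, 18.0), (x0, x1))


def _vertebra_pattern(cfg: PhantomConfig, box) -> np.ndarray:
    """Smooth, non-degenerate intensity pattern shared by CT and PET."""
    nz, ny, nx = cfg.grid_shape
    z = np.arange(nz) * cfg.spacing[0]
    y = np.arange(ny) * cfg.spacing[1]
    x = np.arange(nx) * cfg.spacing[2]
    ZZ, YY, XX = np.meshgrid(z, y, x, indexing="ij")
    pat = (
        np.sin(2 * np.pi * XX / 21.0) * np.cos(2 * np.pi * YY / 17.0)
        + 0.5 * np.sin(2 * np.pi * (XX + YY) / 29.0)
        + 0.5 * np.sin(2 * np.pi * ZZ / 27.0)
    )
    return pat


def _vertebra_mask(cfg: PhantomConfig, box) -> np.ndarray:
    nz, ny, nx = cfg.grid_shape
    y = np.arange(ny) * cfg.spacing[1]
    x = np.arange(nx) * cfg.spacing[2]
    (y0, y1), (x0, x1) = box
    my = (y >= y0) & (y <= y1)
    mx = (x >= x0) & (x <= x1)
    m2 = np.outer(my, mx)
    return np.broadcast_to(m2, (nz, ny, nx)).copy()


def _render_labels(cfg: PhantomConfig, geo: _PatientGeometry, rng: np.random.Generator):
    """Label volume plus the analytic contour polygons per slice."""
    nz, ny, nx = cfg.grid_shape
    cx, cy = geo.center
    margin = 2.0
    if (
        cy + geo.r_max + margin > (ny - 1) * cfg.spacing[1]
        or cx + geo.ax_ratio * geo.r_max + margin > (nx - 1) * cfg.spacing[2]
        or cx - geo.ax_ratio * geo.r_max - margin < 0
    ):
        raise ValueError(
            f"aneurysm of diameter {geo.max_diameter_cm:.2f} cm does not fit the grid"
        )
    _, _, r, theta = _grid_polar(cfg, geo.center)
    labels = np.full(cfg.grid_shape, LABELS["background"], dtype=np.int8)
    outer_polys, lumen_polys = {}, {}
    for z in range(nz):
        r_out, r_in, r_lum = geo.radial_functions(z)
        ro = np.interp(theta, _THETA, r_out, period=2 * np.pi)
        ri = np.interp(theta, _THETA, r_in, period=2 * np.pi)
        rl = np.interp(theta, _THETA, r_lum, period=2 * np.pi)
        sl = labels[z]
        sl[r < ro] = LABELS["wall"]
        sl[r < ri] = LABELS["ilt"]
        sl[r < rl] = LABELS["lumen"]
        # calcific deposits: small discs in the wall/ILT band
        if rng.random() < cfg.calcium_fraction:
            for _ in range(int(rng.integers(1, 3))):
                a = rng.uniform(0.0, 2.0 * np.pi)
                rr = float(np.interp(a, _THETA, (r_in + r_out) / 2.0, period=2 * np.pi))
                ccx = cx + rr * np.sin(a)
                ccy = cy + rr * np.cos(a)
                rad = rng.uniform(0.9, 1.8)
                _, _, r_disc, _ = _grid_polar(cfg, (ccx, ccy))
                disc = r_disc < rad
                band = (sl == LABELS["wall"]) | (sl == LABELS["ilt"])
                sl[disc & band] = LABELS["calcium"]
        outer_polys[z] = geo.polygon(r_out)
        lumen_polys[z] = geo.polygon(r_lum)
    box = _vertebra_box_mm(cfg, geo.center)
    labels[_vertebra_mask(cfg, box)] = LABELS["vertebra"]
    return labels, outer_polys, lumen_polys, box


def _voxel_octant_truth(cfg: PhantomConfig, geo: _PatientGeometry, labels: np.ndarray, bp: dict) -> pd.DataFrame:
    """Per-octant truth by voxel counting, matching the sampling convention."""
    _, _, r, theta = _grid_polar(cfg, geo.center)
    oct_map = octant_index_of_angle(angle_deg=np.degrees(theta))
    rows = []
    for z in range(cfg.grid_shape[0]):
        sl = labels[z]
        band = (sl == LABELS["ilt"]) | (sl == LABELS["wall"]) | (sl == LABELS["calcium"])
        r_out, r_in, r_lum = geo.radial_functions(z)
        sig = _laplace_stress(r_out, r_lum, bp["map"], _OCT_OF_THETA)
        lum_d = (
            np.interp(0.0, _THETA, r_lum, period=2 * np.pi)
            + np.interp(np.pi, _THETA, r_lum, period=2 * np.pi)
        ) / 10.0
        for o in range(1, 9):
            m = band & (oct_map == o)
            n = int(m.sum())
            if n == 0:
                continue
            rows.append(
                {
                    "slice_index": z,
                    "octant_index": o,
                    "ilt_ratio": float((sl[m] == LABELS["ilt"]).sum() / n),
                    "calcium_ratio": float((sl[m] == LABELS["calcium"]).sum() / n),
                    "stress_raw": float(sig[o - 1]),
                    "outer_diameter": float(geo.ap_diameter_cm(z)),
                    "lumen_diameter": float(lum_d),
                    "octant_area": n * cfg.spacing[1] * cfg.spacing[2],
                }
            )
    return pd.DataFrame(rows)


def _planted_offset(cfg: PhantomConfig, rng: np.random.Generator, center) -> RigidTransform:
    if cfg.rigid_offset_mode == "none":
        return RigidTransform(center=center)
    if cfg.rigid_offset_mode == "integer_voxel":
        nvox = int(cfg.max_offset_mm / cfg.spacing[1])
        tx = int(rng.integers(-nvox, nvox + 1)) * cfg.spacing[2]
        ty = int(rng.integers(-nvox, nvox + 1)) * cfg.spacing[1]
        nax = int(cfg.max_offset_axial_mm / cfg.spacing[0])
        tz = int(rng.integers(-nax, nax + 1)) * cfg.spacing[0]
        return RigidTransform(tx, ty, tz, 0.0, center)
    return RigidTransform(
        float(rng.uniform(-cfg.max_offset_mm, cfg.max_offset_mm)),
        float(rng.uniform(-cfg.max_offset_mm, cfg.max_offset_mm)),
        float(rng.uniform(-cfg.max_offset_axial_mm, cfg.max_offset_axial_mm)),
        float(rng.uniform(-cfg.max_offset_deg, cfg.max_offset_deg)),
        center,
    )


def paint_suv(truth: PhantomTruth, model: GenerativeModel | None = None, rng=None) -> ImageVolume:
    """Paint the aligned PET volume from the truth table's octant SUV plateaus.

    If the truth table has no ``suv_max`` column yet, values are drawn from
    the generative model first (requires ``rng``).  Wall and calcium voxels
    of an octant take the octant's SUV value; ILT voxels take it scaled by
    the configured attenuation; lumen and background are 0; the vertebra
    carries the same smooth pattern as the CT (for registration).
    """
    cfg = truth.config
    model = model or truth.model
    if "suv_max" not in truth.true_octants.columns:
        if rng is None:
            raise ValueError("rng required to draw SUV values")
        truth.true_octants = _draw_suv(truth.true_octants, model, truth.patient_id, rng)
    labels = truth.labels
    _, _, r, theta = _grid_polar(cfg, truth.aorta_center)
    oct_map = octant_index_of_angle(np.degrees(theta))
    # voxels within the guard arc of a 45-degree boundary are painted with the
    # smaller of the two adjacent octant values, so that sub-voxel differences
    # in the sector centre between painting and later sampling can never raise
    # an octant's maximum
    ang = np.degrees(theta)
    frac = np.mod(ang, 45.0)
    dist_deg = np.minimum(frac, 45.0 - frac)
    arc_mm = r * np.radians(dist_deg)
    in_guard = arc_mm < cfg.octant_guard_mm
    step = np.where(frac < 22.5, -1, 1)
    adj_map = ((oct_map - 1 + step) % 8) + 1
    pet = np.zeros(cfg.grid_shape)
    suv_of = {
        (int(row.slice_index), int(row.octant_index)): float(row.suv_max)
        for row in truth.true_octants.itertuples()
    }
    for z in range(cfg.grid_shape[0]):
        sl = labels[z]
        plateau = (sl == LABELS["wall"]) | (sl == LABELS["calcium"])
        ilt = sl == LABELS["ilt"]
        vals = np.zeros(sl.shape)
        v_here = np.zeros(sl.shape)
        v_adj = np.zeros(sl.shape)
        for o in range(1, 9):
            v = suv_of.get((z, o))
            if v is None:
                continue
            v_here[oct_map == o] = v
            v_adj[adj_map == o] = v
        v_eff = np.where(in_guard & (v_adj > 0), np.minimum(v_here, v_adj), v_here)
        vals[plateau] = v_eff[plateau]
        vals[ilt] = cfg.ilt_suv_attenuation * v_eff[ilt]
        pet[z] = vals
    pat = _vertebra_pattern(cfg, truth.vertebra_box)
    vm = labels == LABELS["vertebra"]
    pet[vm] = 3.5 + 1.0 * pat[vm]
    return ImageVolume(pet, spacing=cfg.spacing, modality="PET-SUV")


def generate_patient(
    cfg: PhantomConfig, model: GenerativeModel, patient_index: int
) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """One synthetic patient: CT volume, displaced PET volume, ground truth.

    Deterministic in (cfg, model, patient_index): the RNG stream is seeded
    from ``(cfg.seed, patient_index)``.
    """
    if patient_index >= cfg.n_patients:
        raise ValueError("patient_index out of range")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, patient_index)))
    nz, ny, nx = cfg.grid_shape
    center = ((nx - 1) * cfg.spacing[2] / 2.0, 52.0 * ((ny - 1) * cfg.spacing[1] / 85.8))
    pad = int(np.ceil(2.0 * cfg.max_offset_axial_mm / cfg.spacing[0])) + 1
    geo = _sample_geometry(cfg, rng, nz, center, axial_margin_slices=pad)
    bp = _blood_pressure(cfg, rng)
    labels, outer_polys, lumen_polys, box = _render_labels(cfg, geo, rng)

    # CT intensities
    ct = np.full(cfg.grid_shape, cfg.background_hu)
    ct[labels == LABELS["lumen"]] = cfg.lumen_hu
    ct[labels == LABELS["wall"]] = cfg.wall_hu
    ct[labels == LABELS["ilt"]] = cfg.ilt_hu
    ct[labels == LABELS["calcium"]] = cfg.calcium_rel * cfg.lumen_hu
    pat = _vertebra_pattern(cfg, box)
    vm = labels == LABELS["vertebra"]
    ct[vm] = cfg.vertebra_hu + 150.0 * pat[vm]
    ct_vol = ImageVolume(ct, spacing=cfg.spacing, modality="CT")

    table = _voxel_octant_truth(cfg, geo, labels, bp)
    table = _finalize_truth_table(table, geo, cfg, cfg.spacing[0])
    table = _draw_suv(table, model, patient_index, rng)

    offset = _planted_offset(cfg, rng, center)
    lumen_seed = (
        nz // 2,
        int(round(center[1] / cfg.spacing[1])),
        int(round(center[0] / cfg.spacing[2])),
    )
    truth = PhantomTruth(
        patient_id=patient_index,
        labels=labels,
        true_octants=table,
        rigid_offset=offset,
        blood_pressure=bp,
        model=model,
        config=cfg,
        aorta_center=center,
        outer_polygons=outer_polys,
        lumen_polygons=lumen_polys,
        lumen_seed_voxel=lumen_seed,
        vertebra_box=box,
    )
    pet_aligned = paint_suv(truth, model)
    pet = resample(pet_aligned, offset, mode=cfg.interp)
    if cfg.psf_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter

        sig = [cfg.psf_sigma_mm / s for s in cfg.spacing]
        pet = pet.copy_with(gaussian_filter(pet.data, sig))
    return ct_vol, pet, truth


def write_phantom(ct: ImageVolume, pet: ImageVolume, truth: PhantomTruth, outdir) -> dict:
    """Persist one phantom patient: NIfTI volumes, truth CSV, JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pid = truth.patient_id
    paths = {
        "ct": out / f"patient{pid:03d}_ct.nii.gz",
        "pet": out / f"patient{pid:03d}_pet.nii.gz",
        "labels": out / f"patient{pid:03d}_labels.nii.gz",
        "octants": out / f"patient{pid:03d}_true_octants.csv",
        "meta": out / f"patient{pid:03d}_meta.json",
    }
    ct.to_nifti(paths["ct"])
    pet.to_nifti(paths["pet"])
    ImageVolume(truth.labels.astype(np.float64), spacing=ct.spacing, origin=ct.origin).to_nifti(
        paths["labels"]
    )
    truth.true_octants.to_csv(paths["octants"], index=False)
    meta = {
        "patient_id": pid,
        "seed": truth.config.seed,
        "lumen_seed_voxel": list(truth.lumen_seed_voxel),
        "aorta_center": list(truth.aorta_center),
        "model": asdict(truth.model),
        "blood_pressure": truth.blood_pressure,
        "rigid_offset": json.loads(truth.rigid_offset.to_json()),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(truth.config).items()
        },
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# fast table-level cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: PhantomConfig | None = None,
    model: GenerativeModel | None = None,
    seed: int | None = None,
    n_patients: int | None = None,
    slices_range: tuple[int, int] = (50, 80),
) -> pd.DataFrame:
    """Octant truth table of a whole cohort, generated analytically.

    Skips voxel rendering: composition and Laplace stress are integrated on
    the angular grid and octant SUV_max values drawn from the generative
    model, giving the same study conditions as the volume phantoms at a
    fraction of the cost.  Calcium ratios are drawn from a zero-inflated
    uniform (deposits are discrete in the rendered phantoms).  Only
    aneurysm-extent rows (AP diameter above the cutoff) are returned.
    """
    cfg = cfg or PhantomConfig()
    model = model or GenerativeModel()
    seed = cfg.seed if seed is None else seed
    n_patients = cfg.n_patients if n_patients is None else n_patients
    frames = []
    for pid in range(n_patients):
        rng = np.random.default_rng(np.random.SeedSequence((seed, pid)))
        nsl = int(rng.integers(slices_range[0], slices_range[1] + 1))
        geo = _sample_geometry(cfg, rng, nsl, center=(0.0, 0.0))
        bp = _blood_pressure(cfg, rng)
        df = _octant_truth_rows(geo, bp, range(nsl))
        cal = np.where(
            rng.random(len(df)) < 0.25, rng.uniform(0.0, 0.15, len(df)), 0.0
        )
        df["calcium_ratio"] = cal
        df = _finalize_truth_table(df, geo, cfg, cfg.spacing[0])
        df = _draw_suv(df, model, pid, rng)
        frames.append(df[df["included"]])
    return pd.concat(frames, ignore_index=True)
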