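"""Rigid PET-to-CT alignment on the vertebral landmark.

PET and CT share a patient but not a grid: the PET volume is displaced by an
unknown in-plane rigid motion (two translations and a rotation about the
slice axis) plus an axial shift.  The transform is recovered by minimizing
the intensity mismatch over vertebra voxels -- the vertebra is rigid and
visible in both modalities.  Because SUV and HU live on different scales,
both intensity sets are standardized (z-scored) over the vertebra mask before
differencing by default, which makes the squared-difference metric invariant
to affine intensity changes; raw SSD is available for same-modality use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize

from .volumes import ImageVolume

__all__ = ["RigidTransform", "register_rigid", "resample"]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotation about the slice (z) axis around
    ``center`` plus a 3D translation, all in mm.

    Applied to a world point ``(x, y, z)``:
    ``(x', y') = R(rot) ((x, y) - c) + c + (tx, ty)``, ``z' = z + tz``.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rotation_deg: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)  # (x, y) mm

    def __post_init__(self):
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation must lie in (-180, 180]")

    def _rot(self) -> np.ndarray:
        a = math.radians(self.rotation_deg)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Transform (n, 3) world points ordered (x, y, z)."""
        pts = np.atleast_2d(np.asarray(xyz, float))
        c = np.asarray(self.center)
        out = pts.copy()
        out[:, :2] = (pts[:, :2] - c) @ self._rot().T + c + np.array([self.tx, self.ty])
        out[:, 2] = pts[:, 2] + self.tz
        return out

    def inverse(self) -> "RigidTransform":
        R = self._rot()
        t = R.T @ np.array([self.tx, self.ty])
        return RigidTransform(
            tx=float(-t[0]),
            ty=float(-t[1]),
            tz=-self.tz,
            rotation_deg=-self.rotation_deg,
            center=self.center,
        )

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """``self.compose(first)`` applies ``first`` then ``self``."""
        if tuple(self.center) != tuple(first.center):
            raise ValueError("compose requires a common rotation center")
        R2 = self._rot()
        t1 = np.array([first.tx, first.ty])
        t = R2 @ t1 + np.array([self.tx, self.ty])
        rot = (self.rotation_deg + first.rotation_deg + 180.0) % 360.0 - 180.0
        if rot == -180.0:
            rot = 180.0
        return RigidTransform(
            tx=float(t[0]),
            ty=float(t[1]),
            tz=self.tz + first.tz,
            rotation_deg=rot,
            center=self.center,
        )

    def to_json(self, metric_value: float | None = None) -> str:
        d = {
            "translation_mm": [self.tx, self.ty, self.tz],
            "rotation_deg": self.rotation_deg,
            "center_mm": list(self.center),
        }
        if metric_value is not None:
            d["metric_value"] = metric_value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        d = json.loads(s)
        tx, ty, tz = d["translation_mm"]
        return cls(tx, ty, tz, d["rotation_deg"], tuple(d["center_mm"]))


def _volume_center_xy(vol: ImageVolume) -> tuple[float, float]:
    _, ny, nx = vol.shape
    return (
        float(vol.origin[2] + (nx - 1) / 2.0 * vol.spacing[2]),
        float(vol.origin[1] + (ny - 1) / 2.0 * vol.spacing[1]),
    )


def _sample(vol: ImageVolume, pts_xyz: np.ndarray, order: int) -> np.ndarray:
    """Interpolate a volume at world (x, y, z) points; outside -> 0."""
    iz = (pts_xyz[:, 2] - vol.origin[0]) / vol.spacing[0]
    iy = (pts_xyz[:, 1] - vol.origin[1]) / vol.spacing[1]
    ix = (pts_xyz[:, 0] - vol.origin[2]) / vol.spacing[2]
    return map_coordinates(
        vol.data, np.vstack([iz, iy, ix]), order=order, mode="constant", cval=0.0
    )


def resample(
    pet: ImageVolume,
    t: RigidTransform,
    target: ImageVolume | None = None,
    mode: str = "linear",
) -> ImageVolume:
    """Pull PET values back through ``t`` onto the target grid.

    ``out(x) = pet(t(x))`` with trilinear (default) or nearest-neighbour
    interpolation; voxels mapping outside the PET field become 0.
    """
    if target is None:
        target = pet
    order = {"linear": 1, "nearest": 0}[mode]
    nz, ny, nx = target.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * target.spacing[0] + target.origin[0],
        np.arange(ny) * target.spacing[1] + target.origin[1],
        np.arange(nx) * target.spacing[2] + target.origin[2],
        indexing="ij",
    )
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    vals = _sample(pet, t.apply(pts), order)
    data = vals.reshape(target.shape)
    if pet.modality == "PET-SUV":
        data = np.maximum(data, 0.0)
    return ImageVolume(data, spacing=target.spacing, origin=target.origin, modality=pet.modality)


def register_rigid(
    pet: ImageVolume,
    ct: ImageVolume,
    vertebra_mask: np.ndarray,
    dof: int = 4,
    metric: str = "ssd",
    standardize: bool = True,
    search_mm: float = 10.0,
    search_deg: float = 5.0,
    search_mm_axial: float = 3.0,
    coarse_subsample: int = 3,
    mask_erosion: int = 2,
) -> tuple[RigidTransform, dict]:
    """Recover the PET-to-CT rigid transform on the vertebra.

    Multi-start local optimization: a coarse grid over +-``search_mm`` /
    +-``search_deg`` (subsampled mask) seeds Powell refinements of the mean
    squared intensity difference over vertebra voxels.  ``dof`` 3 fits
    (tx, ty, rot); 4 adds the axial shift tz.  Returns the transform (to be
    used directly with :func:`resample`) and an info dict with the final
    metric value and a convergence flag.
    """
    if dof not in (3, 4):
        raise ValueError("dof must be 3 (in-plane) or 4 (in-plane + axial)")
    if metric not in ("ssd", "ncc"):
        raise ValueError("metric must be 'ssd' or 'ncc'")
    if mask_erosion > 0:
        from scipy.ndimage import binary_erosion

        eroded = binary_erosion(vertebra_mask, iterations=mask_erosion, border_value=0)
        if eroded.sum() >= 8:  # keep boundary voxels only when erosion empties the mask
            vertebra_mask = eroded
    idx = np.argwhere(vertebra_mask)
    if len(idx) < 8:
        raise ValueError(f"vertebra mask has only {len(idx)} voxels; registration ill-posed")
    pts = np.column_stack(
        [
            idx[:, 2] * ct.spacing[2] + ct.origin[2],
            idx[:, 1] * ct.spacing[1] + ct.origin[1],
            idx[:, 0] * ct.spacing[0] + ct.origin[0],
        ]
    )
    ref = ct.data[vertebra_mask]
    center = _volume_center_xy(ct)

    def _standardize(v):
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    ref_z = _standardize(ref)

    def objective(params, pts_, ref_, ref_z_):
        tx, ty, rot = params[0], params[1], params[2]
        tz = params[3] if dof == 4 else 0.0
        t = RigidTransform(tx, ty, tz, rot, center)
        mov = _sample(pet, t.apply(pts_), order=1)
        if metric == "ncc":
            a, b = _standardize(mov), ref_z_
            return 1.0 - float(np.mean(a * b))
        if standardize:
            return float(np.mean((_standardize(mov) - ref_z_) ** 2))
        return float(np.mean((mov - ref_) ** 2))

    # coarse multi-start on a subsampled mask
    sub = slice(None, None, max(coarse_subsample, 1))
    pts_c, ref_c = pts[sub], ref[sub]
    ref_cz = _standardize(ref_c)
    txs = np.arange(-search_mm, search_mm + 1e-9, 2.5)
    rots = np.arange(-search_deg, search_deg + 1e-9, 2.5)
    tzs = np.arange(-search_mm_axial, search_mm_axial + 1e-9, 3.0) if dof == 4 else [0.0]
    best = []
    for tx in txs:
        for ty in txs:
            for rot in rots:
                for tz in tzs:
                    p = [tx, ty, rot] + ([tz] if dof == 4 else [])
                    best.append((objective(p, pts_c, ref_c, ref_cz), p))
    best.sort(key=lambda t_: t_[0])

    results = []
    for _, start in best[:3]:
        res = minimize(
            objective,
            np.asarray(start, float),
            args=(pts, ref, ref_z),
            method="Powell",
            options=dict(xtol=1e-6, ftol=1e-10, maxiter=2000),
        )
        results.append(res)
    res = min(results, key=lambda r: r.fun)
    tx, ty, rot = res.x[0], res.x[1], res.x[2]
    tz = res.x[3] if dof == 4 else 0.0
    t = RigidTransform(float(tx), float(ty), float(tz), float(rot), center)
    info = {
        "metric": metric,
        "metric_value": float(res.fun),
        "converged": bool(res.success),
        "dof": dof,
        "n_vertebra_voxels": int(len(idx)),
    }
    if not res.success:
        info["warning"] = "optimizer did not report convergence; best-so-far returned"
    return t, info
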