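"""End-to-end orchestration: phantom -> segmentation -> registration ->
stress -> octant sampling -> statistics.

A run is configured by a :class:`RunConfig` (YAML round-trippable), executed
stage by stage, and leaves a ``manifest.json`` recording the configuration
hash, the seed, and a content hash of every artifact each stage wrote, so a
run can be audited and reproduced byte for byte.  Stages communicate through
files in the run directory; :func:`run_all` additionally threads an
in-memory state dict so a full run does not re-read what it just wrote.  If
a stage fails, the manifest (with all completed stages) is still written and
partial outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mechanics, octants, phantom, registration, segmentation, stats
from .volumes import ImageVolume

__all__ = ["RunConfig", "STAGES", "run_stage", "run_all"]

logger = logging.getLogger(__name__)

STAGES = ("phantom", "segment", "register", "stress", "sample", "analyze")

_TUPLE_FIELDS = {"grid_shape", "spacing", "ilt_strata"}


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; every analysis threshold lives here."""

    out_dir: str = "results/run"
    seed: int = 0
    n_patients: int = 2
    grid_shape: tuple[int, int, int] = (24, 144, 144)
    spacing: tuple[float, float, float] = (3.0, 0.6, 0.6)
    ilt_burden: float = 1.0
    calcium_fraction: float = 0.35
    rigid_offset_mode: str = "integer_voxel"
    interp: str = "nearest"
    psf_sigma_mm: float = 0.0
    suv_model_mode: str = "multivariate"
    # segmentation
    wall_thickness: float = 1.5
    lumen_tolerance: float = 0.2
    calcium_threshold_pct: float = 110.0
    smoothing_window: int = 3
    # registration
    registration_dof: int = 4
    vertebra_hu_threshold: float = 300.0
    # stress
    fe_n_radial: int = 6
    fe_n_circ: int = 96
    apply_start_shape: bool = False
    discard_pct: float = 5.0
    # extent and analysis
    aaa_cutoff_cm: float = 3.0
    neck_extent_mm: float = 6.5
    suv_cutpoint: float = 2.0
    stress_threshold: float = 0.45
    ilt_strata: tuple[float, float] = (0.33, 0.67)
    run_backward_elimination: bool = True

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing_window must be odd")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        for k in _TUPLE_FIELDS:
            d[k] = list(d[k])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in _TUPLE_FIELDS & set(d):
            d[k] = tuple(d[k])
        return cls(**d)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()

    def phantom_config(self) -> phantom.PhantomConfig:
        return phantom.PhantomConfig(
            n_patients=self.n_patients,
            grid_shape=self.grid_shape,
            spacing=self.spacing,
            wall_thickness=self.wall_thickness,
            ilt_burden=self.ilt_burden,
            calcium_fraction=self.calcium_fraction,
            rigid_offset_mode=self.rigid_offset_mode,
            interp=self.interp,
            psf_sigma_mm=self.psf_sigma_mm,
            aaa_cutoff_cm=self.aaa_cutoff_cm,
            neck_extent_mm=self.neck_extent_mm,
            seed=_stage_seed(self.seed, 0),
        )


def _stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence((seed, stage_index)).generate_state(1)[0] % (2**31))


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage implementations (each returns {artifact name: path} and updates state)
# ---------------------------------------------------------------------------


def _stage_phantom(cfg: RunConfig, out: Path, state: dict) -> dict:
    pcfg = cfg.phantom_config()
    model = (
        phantom.GenerativeModel.multivariate()
        if cfg.suv_model_mode == "multivariate"
        else phantom.GenerativeModel.univariate()
    )
    outdir = out / "phantom"
    paths = {}
    state["patients"] = {}
    for pid in range(cfg.n_patients):
        ct, pet, truth = phantom.generate_patient(pcfg, model, pid)
        paths.update(
            {f"p{pid}_{k}": v for k, v in phantom.write_phantom(ct, pet, truth, outdir).items()}
        )
        state["patients"][pid] = {"ct": ct, "pet": pet, "truth": truth}
    return paths


_AORTA_LABELS = (
    phantom.LABELS["lumen"],
    phantom.LABELS["ilt"],
    phantom.LABELS["wall"],
    phantom.LABELS["calcium"],
)


def _load_patient(out: Path, pid: int) -> dict:
    pdir = out / "phantom"
    ct = ImageVolume.from_nifti(pdir / f"patient{pid:03d}_ct.nii.gz", modality="CT")
    pet = ImageVolume.from_nifti(pdir / f"patient{pid:03d}_pet.nii.gz", modality="PET-SUV")
    labels = ImageVolume.from_nifti(pdir / f"patient{pid:03d}_labels.nii.gz")
    meta = json.loads((pdir / f"patient{pid:03d}_meta.json").read_text())
    return {"ct": ct, "pet": pet, "labels": labels.data.astype(np.int8), "meta": meta}


def _patient_entry(cfg: RunConfig, out: Path, state: dict, pid: int) -> dict:
    entry = state.setdefault("patients", {}).setdefault(pid, {})
    if "ct" not in entry:
        entry.update(_load_patient(out, pid))
    if "meta" not in entry:
        meta = json.loads(
            (out / "phantom" / f"patient{pid:03d}_meta.json").read_text()
        )
        entry["meta"] = meta
    if "labels" not in entry and "truth" in entry:
        entry["labels"] = entry["truth"].labels
    return entry


def _segment_patient(cfg: RunConfig, entry: dict) -> list:
    """Slice geometries of one patient from its CT and 'manual' outer contours.

    The lumen is region-grown on CT; the outer wall contour -- drawn by hand
    in a clinical workflow -- is taken from the rendered aorta boundary; ILT
    follows from the constant-thickness wall shrink and calcium from the
    relative intensity threshold.
    """
    ct = entry["ct"]
    meta = entry.get("meta")
    if meta is not None and "lumen_seed_voxel" in meta:
        seed_vox = tuple(meta["lumen_seed_voxel"])
    else:
        truth = entry["truth"]
        seed_vox = truth.lumen_seed_voxel
    lumen_mask = segmentation.grow_lumen(ct, seed_vox, cfg.lumen_tolerance)
    lum_polys = segmentation.lumen_polygons(lumen_mask, ct)
    aorta_mask = np.isin(entry["labels"], _AORTA_LABELS)
    outer_polys = segmentation.lumen_polygons(aorta_mask, ct)

    grid_shape = ct.shape[1:]
    spacing = (ct.spacing[1], ct.spacing[2])
    origin = (ct.origin[1], ct.origin[2])
    slices = []
    for k in sorted(set(lum_polys) & set(outer_polys)):
        ilt = segmentation.derive_ilt(
            lum_polys[k], outer_polys[k], cfg.wall_thickness, grid_shape, spacing, origin
        )
        band = segmentation.rasterize_polygon(outer_polys[k], grid_shape, spacing, origin)
        cal2d = segmentation.segment_calcium(
            ct.copy_with(ct.data[k][None, ...]),
            lumen_mask[k][None, ...],
            cfg.calcium_threshold_pct,
            band_mask=band[None, ...],
        )[0]
        slices.append(
            segmentation.SliceGeometry(
                slice_index=k,
                lumen_polygon=lum_polys[k],
                outer_wall_polygon=outer_polys[k],
                ilt_mask=ilt,
                calcium_mask=cal2d,
                spacing=spacing,
                origin=origin,
            )
        )
    return mechanics.stack_and_smooth(slices, window=cfg.smoothing_window)


def _stage_segment(cfg: RunConfig, out: Path, state: dict) -> dict:
    paths = {}
    seg_dir = out / "derived"
    seg_dir.mkdir(parents=True, exist_ok=True)
    for pid in range(cfg.n_patients):
        entry = _patient_entry(cfg, out, state, pid)
        slices = _segment_patient(cfg, entry)
        entry["slices"] = slices
        rows = [
            {
                "slice_index": s.slice_index,
                "outer_diameter": s.outer_diameter,
                "lumen_diameter": s.lumen_diameter,
                "ilt_area_mm2": float(s.ilt_mask.sum()) * s.spacing[0] * s.spacing[1],
                "calcium_area_mm2": float(s.calcium_mask.sum()) * s.spacing[0] * s.spacing[1],
            }
            for s in slices
        ]
        p = seg_dir / f"patient{pid:03d}_slices.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[f"p{pid}_slices"] = str(p)
    return paths


def _stage_register(cfg: RunConfig, out: Path, state: dict) -> dict:
    paths = {}
    reg_dir = out / "derived"
    reg_dir.mkdir(parents=True, exist_ok=True)
    for pid in range(cfg.n_patients):
        entry = _patient_entry(cfg, out, state, pid)
        ct, pet = entry["ct"], entry["pet"]
        vert = ct.data > cfg.vertebra_hu_threshold
        from scipy import ndimage as ndi

        lab, n = ndi.label(vert)
        if n > 1:
            sizes = ndi.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            vert = lab == (1 + int(np.argmax(sizes)))
        t, info = registration.register_rigid(pet, ct, vert, dof=cfg.registration_dof)
        entry["transform"] = t
        entry["pet_on_ct"] = registration.resample(pet, t, target=ct, mode=cfg.interp)
        p = reg_dir / f"patient{pid:03d}_transform.json"
        p.write_text(t.to_json(metric_value=info["metric_value"]))
        paths[f"p{pid}_transform"] = str(p)
    return paths


def _stage_stress(cfg: RunConfig, out: Path, state: dict) -> dict:
    paths = {}
    der = out / "derived"
    der.mkdir(parents=True, exist_ok=True)
    for pid in range(cfg.n_patients):
        entry = _patient_entry(cfg, out, state, pid)
        if "slices" not in entry:
            entry["slices"] = _segment_patient(cfg, entry)
        slices = entry["slices"]
        pressure = entry["meta"]["blood_pressure"]["map"]
        extent = octants.define_aaa_extent(
            slices, cfg.spacing[0], cfg.aaa_cutoff_cm, cfg.neck_extent_mm
        )
        included = set(extent["slice_index"])
        mats = mechanics.MaterialSet()
        fields = []
        for s in slices:
            if s.slice_index not in included:
                continue
            geo = s
            if cfg.apply_start_shape:
                shape = mechanics.compute_start_shape(
                    s, pressure, mats, n_radial=cfg.fe_n_radial,
                    n_circ=cfg.fe_n_circ, wall_thickness=cfg.wall_thickness,
                )
                c = s.outer_wall_polygon.mean(axis=0)
                geo = s.with_polygons(
                    lumen_polygon=c + shape["scale"] * (s.lumen_polygon - c),
                    outer_wall_polygon=c + shape["scale"] * (s.outer_wall_polygon - c),
                )
            mesh = mechanics.build_mesh(
                geo, cfg.fe_n_radial, cfg.fe_n_circ, cfg.wall_thickness
            )
            fields.append(
                mechanics.solve_plane_strain(mesh, pressure, mats, slice_index=s.slice_index)
            )
        fields = mechanics.postprocess_stress(fields, cfg.discard_pct)
        entry["stress_fields"] = {f.slice_index: f for f in fields}
        rows = [
            {
                "slice_index": f.slice_index,
                "peak_vm_pa": float(f.sigma_vm[(f.material == "wall") & ~f.discarded].max()),
                "n_elements": len(f.sigma_vm),
            }
            for f in fields
        ]
        p = der / f"patient{pid:03d}_stress.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[f"p{pid}_stress"] = str(p)
    return paths


def _stage_sample(cfg: RunConfig, out: Path, state: dict) -> dict:
    frames = []
    for pid in range(cfg.n_patients):
        entry = _patient_entry(cfg, out, state, pid)
        if "slices" not in entry:
            entry["slices"] = _segment_patient(cfg, entry)
        if "pet_on_ct" not in entry or "stress_fields" not in entry:
            raise RuntimeError(
                "sample stage needs the register and stress stages in the same run"
            )
        frames.append(
            octants.build_octant_table(
                entry["slices"],
                entry["pet_on_ct"],
                entry["stress_fields"],
                patient_id=pid,
                slice_spacing_mm=cfg.spacing[0],
                wall_thickness=cfg.wall_thickness,
                diameter_cutoff_cm=cfg.aaa_cutoff_cm,
                neck_extent_mm=cfg.neck_extent_mm,
            )
        )
    table = pd.concat(frames, ignore_index=True)
    state["octant_table"] = table
    p = out / "octant_table.csv"
    table.to_csv(p, index=False)
    return {"octant_table": str(p)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _stage_analyze(cfg: RunConfig, out: Path, state: dict) -> dict:
    table = state.get("octant_table")
    if table is None:
        table = pd.read_csv(out / "octant_table.csv")
    results: dict = {"n_octants": len(table), "n_patients": int(table["patient_id"].nunique())}

    uni = stats.fit_lme(table, ("norm_stress",), reml=True)
    results["univariate"] = {
        "slope": uni.coef("norm_stress"),
        "fixed_effects": uni.fixed_effects,
        "psi": uni.psi,
        "residual_variance": uni.residual_variance,
    }
    # drop degenerate terms (e.g. no calcium found in a small run)
    def _varies(term):
        cols = term.split(":")
        return all(table[c].nunique() > 1 for c in cols)

    active = tuple(t for t in stats.FULL_MODEL_TERMS if _varies(t))
    dropped = [t for t in stats.FULL_MODEL_TERMS if t not in active]
    if dropped:
        logger.warning("dropping constant terms from the multivariate model: %s", dropped)
    results["dropped_terms"] = dropped
    full = stats.fit_lme(table, active, reml=True)
    results["multivariate"] = {
        "fixed_effects": full.fixed_effects,
        "psi": full.psi,
        "residual_variance": full.residual_variance,
        "aic": full.aic,
    }
    stress_terms = tuple(t for t in stats.STRESS_TERMS if t in active)
    results["stress_aic"] = {
        k: v
        for k, v in stats.compare_null_full(table, active, stress_terms).items()
        if k in ("delta_aic", "aic_full", "aic_null")
    }
    if cfg.run_backward_elimination:
        final, trace = stats.backward_eliminate(table, active)
        results["backward_elimination"] = {
            "final_terms": list(final.fixed_effects.index),
            "trace": trace,
        }
    roc = stats.roc_analysis(
        table, "norm_stress", suv_cutpoint=cfg.suv_cutpoint, ilt_strata=(None, *cfg.ilt_strata)
    )
    results["roc"] = {
        k: {"auc": r.auc, "youden_threshold": r.youden_threshold, "n": r.n}
        for k, r in roc.items()
    }
    try:
        split = stats.high_low_stress_split(
            table, stress_threshold=cfg.stress_threshold, ilt_cutoff=cfg.ilt_strata[-1]
        )
        results["high_low_stress"] = dataclasses.asdict(split)
    except ValueError as err:
        results["high_low_stress"] = {"flag": str(err)}
    p = out / "analysis.json"
    p.write_text(json.dumps(_jsonable(results), indent=2))
    state["analysis"] = results
    return {"analysis": str(p)}


_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "segment": _stage_segment,
    "register": _stage_register,
    "stress": _stage_stress,
    "sample": _stage_sample,
    "analyze": _stage_analyze,
}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _manifest_path(out: Path) -> Path:
    return out / "manifest.json"


def _load_manifest(cfg: RunConfig, out: Path) -> dict:
    p = _manifest_path(out)
    if p.exists():
        return json.loads(p.read_text())
    return {
        "config": yaml.safe_load(cfg.to_yaml()),
        "config_sha256": cfg.sha256(),
        "seed": cfg.seed,
        "stages": {},
    }


def run_stage(stage: str, cfg: RunConfig, state: dict | None = None) -> dict:
    """Execute one pipeline stage, update the manifest, return artifact paths.

    Unknown stage names raise a ValueError listing the valid stages.  The
    manifest is written even if the stage fails, preserving the record of
    completed stages and any partial outputs on disk.
    """
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage '{stage}'; valid stages: {', '.join(STAGES)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = _load_manifest(cfg, out)
    if state is None:
        state = {}
    t0 = time.time()
    try:
        paths = _STAGE_FUNCS[stage](cfg, out, state)
    except Exception as err:
        manifest["stages"][stage] = {
            "status": "failed",
            "error": f"{type(err).__name__}: {err}",
            "elapsed_s": round(time.time() - t0, 3),
        }
        _manifest_path(out).write_text(json.dumps(manifest, indent=2))
        raise
    manifest["stages"][stage] = {
        "status": "ok",
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {name: _sha256_file(Path(p)) for name, p in sorted(paths.items())},
    }
    _manifest_path(out).write_text(json.dumps(manifest, indent=2))
    logger.info("stage %s done in %.1f s (%d artifacts)", stage, time.time() - t0, len(paths))
    return paths


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order; returns {stage: {artifact: path}}."""
    state: dict = {}
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, cfg, state)
    return out
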