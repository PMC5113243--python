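"""Per-slice structural wall stress by plane-strain finite elements.

Each axial aneurysm cross-section (lumen contour, outer wall contour, ILT and
calcium masks) is meshed with a structured ring of bilinear quadrilaterals
between the lumen and outer contours, loaded with the patient's blood
pressure as a normal traction on the lumen edge, and solved under small-strain
plane-strain linear elasticity.  Von Mises stress is evaluated at element
centroids; per patient the top 5 percentile of wall stresses is discarded
(mesh-imperfection guard) and the remainder normalized by its peak so every
patient's wall stress lies in [0, 1].

Near-incompressible tissue (Poisson ratio 0.49) locks bilinear quads under
full integration, so the volumetric strain uses selective reduced (B-bar)
integration, evaluated at the element centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .segmentation import SliceGeometry, polygon_radial_function

__all__ = [
    "Material",
    "MaterialSet",
    "Mesh2D",
    "StressField",
    "MMHG_TO_PA",
    "von_mises",
    "stack_and_smooth",
    "build_mesh",
    "solve_plane_strain",
    "compute_start_shape",
    "postprocess_stress",
]

MMHG_TO_PA = 133.322

_MAT_CODES = {"wall": 0, "ilt": 1, "calcium": 2}


@dataclass(frozen=True)
class Material:
    young: float  # Pa
    poisson: float

    def __post_init__(self):
        if self.young <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 < self.poisson < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


@dataclass(frozen=True)
class MaterialSet:
    """Linear-elastic parameters per tissue component.

    Defaults are literature-typical orders of magnitude: wall 2.0 MPa, ILT
    0.2 MPa, calcification 20 MPa, all nearly incompressible.
    """

    wall: Material = Material(2.0e6, 0.49)
    ilt: Material = Material(0.2e6, 0.49)
    calcium: Material = Material(20.0e6, 0.49)

    def __post_init__(self):
        if not (self.calcium.young > self.wall.young > self.ilt.young):
            raise ValueError("expected calcium modulus > wall modulus > ILT modulus")

    def get(self, name: str) -> Material:
        return getattr(self, name)


@dataclass
class Mesh2D:
    """Structured quad ring between the lumen and outer wall contours."""

    nodes: np.ndarray  # (n_nodes, 2) mm
    elements: np.ndarray  # (n_elems, 4) node ids, CCW
    element_material: np.ndarray  # (n_elems,) str in {"wall","ilt","calcium"}
    inner_nodes: np.ndarray  # lumen-edge node ids, closed ring in order
    outer_nodes: np.ndarray
    n_radial: int
    n_circ: int

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def jacobians(self) -> np.ndarray:
        """Determinant of the isoparametric map at each element centroid."""
        X = self.nodes[self.elements]  # (E,4,2)
        dN = _dN_dxi(0.0, 0.0)  # (4,2)
        J = np.einsum("eai,ak->eik", X, dN)
        return J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]


@dataclass
class StressField:
    """Element-level von Mises stress for one slice."""

    sigma_vm: np.ndarray  # Pa
    material: np.ndarray
    centroids: np.ndarray  # (E, 2) mm
    slice_index: int
    normalized: np.ndarray | None = None  # filled by postprocess_stress
    discarded: np.ndarray | None = None
    components: np.ndarray | None = None  # (E, 4): sx, sy, sz, txy


def von_mises(stress_tensor) -> np.ndarray:
    """Von Mises equivalent stress from (sx, sy, sz, txy) components.

    Accepts a 4-vector or an (n, 4) array; the out-of-plane normal stress sz
    is an input (plane strain: sz = nu * (sx + sy))."""
    t = np.atleast_2d(np.asarray(stress_tensor, float))
    sx, sy, sz, txy = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    vm2 = sx**2 + sy**2 + sz**2 - sx * sy - sy * sz - sz * sx + 3.0 * txy**2
    vm = np.sqrt(np.maximum(vm2, 0.0))
    return vm if np.ndim(stress_tensor) > 1 else float(vm[0])


# ---------------------------------------------------------------------------
# axial contour smoothing
# ---------------------------------------------------------------------------


def stack_and_smooth(slices: list, window: int = 3, n_theta: int = 128) -> list:
    """Smooth lumen/outer contours axially with a centred moving average.

    Contours are resampled onto a common angular grid about each slice's
    outer-contour centroid, the radial functions averaged over ``window``
    adjacent slices, and polygons rebuilt.  Slices too close to the ends for
    a full window are left untouched.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    centers = []
    r_out = np.empty((len(slices), n_theta))
    r_lum = np.empty((len(slices), n_theta))
    for i, s in enumerate(slices):
        c = s.outer_wall_polygon.mean(axis=0)
        centers.append(c)
        r_out[i] = polygon_radial_function(s.outer_wall_polygon, c, theta)
        r_lum[i] = polygon_radial_function(s.lumen_polygon, c, theta)
    half = window // 2
    r_out_s, r_lum_s = r_out.copy(), r_lum.copy()
    for i in range(half, len(slices) - half):
        r_out_s[i] = r_out[i - half : i + half + 1].mean(axis=0)
        r_lum_s[i] = r_lum[i - half : i + half + 1].mean(axis=0)
    out = []
    for i, s in enumerate(slices):
        cx, cy = centers[i]
        dx, dy = np.sin(theta), np.cos(theta)  # angle from anterior (+y), clockwise
        outer = np.column_stack([cx + r_out_s[i] * dx, cy + r_out_s[i] * dy])
        lum = np.column_stack([cx + r_lum_s[i] * dx, cy + r_lum_s[i] * dy])
        out.append(s.with_polygons(lumen_polygon=lum, outer_wall_polygon=outer))
    return out


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def build_mesh(
    slice_geo: SliceGeometry,
    n_radial: int = 6,
    n_circ: int = 96,
    wall_thickness: float = 1.5,
) -> Mesh2D:
    """Structured quad mesh between the lumen and outer contours.

    Elements whose centroid falls in the slice's ILT/calcium masks are
    labelled accordingly; everything else, and always the outermost band of
    ``wall_thickness`` mm, is wall.
    """
    if n_radial < 2 or n_circ < 32:
        raise ValueError("need n_radial >= 2 and n_circ >= 32")
    c = slice_geo.outer_wall_polygon.mean(axis=0)
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    ro = polygon_radial_function(slice_geo.outer_wall_polygon, c, theta)
    rl = polygon_radial_function(slice_geo.lumen_polygon, c, theta)
    if np.any(rl >= ro):
        raise ValueError(f"slice {slice_geo.slice_index}: lumen reaches outer contour")
    dx, dy = np.sin(theta), np.cos(theta)
    frac = np.linspace(0.0, 1.0, n_radial + 1)[:, None]  # (nr+1, 1)
    r = rl[None, :] + frac * (ro - rl)[None, :]
    nodes = np.empty(((n_radial + 1) * n_circ, 2))
    nodes[:, 0] = (c[0] + r * dx[None, :]).ravel()
    nodes[:, 1] = (c[1] + r * dy[None, :]).ravel()

    def nid(ring, j):
        return ring * n_circ + (j % n_circ)

    elems = np.empty((n_radial * n_circ, 4), dtype=np.int64)
    k = 0
    for ring in range(n_radial):
        for j in range(n_circ):
            # CCW ordering for the (x=sin, y=cos) clockwise angular grid
            elems[k] = (nid(ring, j), nid(ring, j + 1), nid(ring + 1, j + 1), nid(ring + 1, j))
            k += 1
    mesh = Mesh2D(
        nodes=nodes,
        elements=elems,
        element_material=np.full(len(elems), "wall", dtype=object),
        inner_nodes=np.arange(n_circ),
        outer_nodes=np.arange(n_radial * n_circ, (n_radial + 1) * n_circ),
        n_radial=n_radial,
        n_circ=n_circ,
    )
    det = mesh.jacobians()
    if np.any(det <= 0):
        raise ValueError(f"slice {slice_geo.slice_index}: tangled mesh (negative Jacobian)")

    cents = mesh.centroids
    mat = mesh.element_material
    for name, mask in (("ilt", slice_geo.ilt_mask), ("calcium", slice_geo.calcium_mask)):
        if mask is None or not mask.any():
            continue
        hit = slice_geo.mask_lookup(mask, cents)
        mat[hit] = name
    # the outermost wall_thickness band is wall by construction
    dcx = cents[:, 0] - c[0]
    dcy = cents[:, 1] - c[1]
    ang = np.mod(np.arctan2(dcx, dcy), 2.0 * np.pi)
    rc = np.hypot(dcx, dcy)
    ro_at = np.interp(ang, theta, ro, period=2.0 * np.pi)
    mat[(ro_at - rc) < wall_thickness] = "wall"
    mesh.element_material = mat.astype("U8")
    return mesh


# ---------------------------------------------------------------------------
# plane-strain solver
# ---------------------------------------------------------------------------

_GAUSS = 1.0 / math.sqrt(3.0)
_GPS = [(-_GAUSS, -_GAUSS), (_GAUSS, -_GAUSS), (_GAUSS, _GAUSS), (-_GAUSS, _GAUSS)]


def _dN_dxi(xi: float, eta: float) -> np.ndarray:
    """Derivatives of the four bilinear shape functions wrt (xi, eta)."""
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [+(1 - eta), -(1 + xi)],
            [+(1 + eta), +(1 + xi)],
            [-(1 + eta), +(1 - xi)],
        ]
    )


def _d_matrix(mat: Material) -> np.ndarray:
    E, nu = mat.young, mat.poisson
    f = E / ((1 + nu) * (1 - 2 * nu))
    return f * np.array(
        [[1 - nu, nu, 0.0], [nu, 1 - nu, 0.0], [0.0, 0.0, (1 - 2 * nu) / 2.0]]
    )


def _b_matrices(X: np.ndarray, xi: float, eta: float):
    """B (E,3,8), volumetric part Bvol and detJ at one quadrature point."""
    dN = _dN_dxi(xi, eta)  # (4,2)
    J = np.einsum("eai,ak->eik", X, dN)  # (E,2,2)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1]
    invJ[:, 1, 1] = J[:, 0, 0]
    invJ[:, 0, 1] = -J[:, 0, 1]
    invJ[:, 1, 0] = -J[:, 1, 0]
    invJ /= detJ[:, None, None]
    dNdx = np.einsum("ak,eki->eai", dN, invJ)  # (E,4,2): dN_a/dx, dN_a/dy
    E = X.shape[0]
    B = np.zeros((E, 3, 8))
    B[:, 0, 0::2] = dNdx[:, :, 0]
    B[:, 1, 1::2] = dNdx[:, :, 1]
    B[:, 2, 0::2] = dNdx[:, :, 1]
    B[:, 2, 1::2] = dNdx[:, :, 0]
    bv = B[:, 0, :] + B[:, 1, :]  # m'B, (E,8)
    Bvol = 0.5 * np.einsum("r,ec->erc", np.array([1.0, 1.0, 0.0]), bv)
    return B, Bvol, detJ


def _element_matrices(mesh: Mesh2D, materials: MaterialSet):
    """Per-element stiffness (B-bar) and the centroid B-bar operator."""
    X = mesh.nodes[mesh.elements]
    D = np.empty((len(mesh.elements), 3, 3))
    for name in ("wall", "ilt", "calcium"):
        m = mesh.element_material == name
        if m.any():
            D[m] = _d_matrix(materials.get(name))
    _, Bvol0, _ = _b_matrices(X, 0.0, 0.0)
    B0, _, _ = _b_matrices(X, 0.0, 0.0)
    Ke = np.zeros((len(mesh.elements), 8, 8))
    for xi, eta in _GPS:
        B, Bvol, detJ = _b_matrices(X, xi, eta)
        Bbar = B - Bvol + Bvol0
        Ke += np.einsum("erc,ers,esd,e->ecd", Bbar, D, Bbar, detJ)
    return Ke, B0, D


def _assemble(mesh: Mesh2D, Ke: np.ndarray):
    ndof = 2 * len(mesh.nodes)
    dofs = np.empty((len(mesh.elements), 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    K = coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _pressure_load(mesh: Mesh2D, pressure_pa: float) -> np.ndarray:
    """Consistent nodal forces for constant pressure on the lumen edge."""
    f = np.zeros(2 * len(mesh.nodes))
    ring = mesh.inner_nodes
    c = mesh.nodes[ring].mean(axis=0)
    for i in range(len(ring)):
        n1, n2 = ring[i], ring[(i + 1) % len(ring)]
        p1, p2 = mesh.nodes[n1], mesh.nodes[n2]
        e = p2 - p1
        n = np.array([e[1], -e[0]])  # |n| = edge length
        mid = 0.5 * (p1 + p2)
        if np.dot(n, mid - c) < 0:  # pressure pushes the wall outward
            n = -n
        fe = 0.5 * pressure_pa * n
        f[2 * n1 : 2 * n1 + 2] += fe
        f[2 * n2 : 2 * n2 + 2] += fe
    return f


def solve_plane_strain(
    mesh: Mesh2D,
    pressure_mmhg: float,
    materials: MaterialSet = MaterialSet(),
    slice_index: int = 0,
) -> StressField:
    """Small-strain plane-strain solution under lumen pressure.

    Rigid-body modes of the traction-only problem are removed by the
    two-node pinning convention: the outer-ring node at the anterior angular
    origin is fully fixed and the in-plane x component of the diametrically
    opposite node is fixed; for the self-balanced pressure load the
    associated reactions vanish (up to discretisation).
    """
    Ke, B0, D = _element_matrices(mesh, materials)
    K = _assemble(mesh, Ke)
    f = _pressure_load(mesh, pressure_mmhg * MMHG_TO_PA)

    nA = int(mesh.outer_nodes[0])
    nB = int(mesh.outer_nodes[mesh.n_circ // 2])
    fixed = np.array([2 * nA, 2 * nA + 1, 2 * nB])
    free = np.setdiff1d(np.arange(2 * len(mesh.nodes)), fixed)
    u = np.zeros(2 * len(mesh.nodes))
    Kff = K[free][:, free]
    try:
        u[free] = spsolve(Kff.tocsc(), f[free])
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"singular stiffness system: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular stiffness system (non-finite displacements)")

    ue = np.empty((len(mesh.elements), 8))
    ue[:, 0::2] = u[2 * mesh.elements]
    ue[:, 1::2] = u[2 * mesh.elements + 1]
    eps = np.einsum("erc,ec->er", B0, ue)
    sig = np.einsum("ers,es->er", D, eps)  # sx, sy, txy
    nu = np.array([materials.get(m).poisson for m in mesh.element_material])
    sz = nu * (sig[:, 0] + sig[:, 1])
    comps = np.column_stack([sig[:, 0], sig[:, 1], sz, sig[:, 2]])
    return StressField(
        sigma_vm=von_mises(comps),
        material=mesh.element_material.copy(),
        centroids=mesh.centroids,
        slice_index=slice_index,
        components=comps,
        normalized=None,
        discarded=None,
    )


def solve_with_displacements(mesh: Mesh2D, pressure_mmhg: float, materials: MaterialSet):
    """Like :func:`solve_plane_strain` but also returns nodal displacements."""
    Ke, B0, D = _element_matrices(mesh, materials)
    K = _assemble(mesh, Ke)
    f = _pressure_load(mesh, pressure_mmhg * MMHG_TO_PA)
    nA = int(mesh.outer_nodes[0])
    nB = int(mesh.outer_nodes[mesh.n_circ // 2])
    fixed = np.array([2 * nA, 2 * nA + 1, 2 * nB])
    free = np.setdiff1d(np.arange(2 * len(mesh.nodes)), fixed)
    u = np.zeros(2 * len(mesh.nodes))
    u[free] = spsolve(K[free][:, free].tocsc(), f[free])
    return u.reshape(-1, 2)


def _ap_diameter(points: np.ndarray) -> float:
    return float(points[:, 1].max() - points[:, 1].min())


def compute_start_shape(
    slice_geo: SliceGeometry,
    pressure_mmhg: float,
    materials: MaterialSet = MaterialSet(),
    tol: float = 1e-3,
    n_radial: int = 6,
    n_circ: int = 96,
    wall_thickness: float = 1.5,
    max_iter: int = 50,
) -> dict:
    """Circumferential shrink factor mapping the imaged (pressurized) shape
    to a computational start shape.

    Fixed point: scale the imaged geometry by ``s`` about its centroid,
    pressurize, and match the deformed outer anteroposterior diameter to the
    imaged one.  Axial shrink has no 2D counterpart and is reported as 1.0.
    Returns ``{"scale", "axial_scale", "iterations", "residual"}``.
    """
    if pressure_mmhg < 0:
        raise ValueError("pressure must be non-negative")
    mesh0 = build_mesh(slice_geo, n_radial, n_circ, wall_thickness)
    c = mesh0.nodes[mesh0.outer_nodes].mean(axis=0)
    target = _ap_diameter(mesh0.nodes[mesh0.outer_nodes])
    s = 1.0
    trace = []
    for it in range(1, max_iter + 1):
        mesh = Mesh2D(
            nodes=c + s * (mesh0.nodes - c),
            elements=mesh0.elements,
            element_material=mesh0.element_material,
            inner_nodes=mesh0.inner_nodes,
            outer_nodes=mesh0.outer_nodes,
            n_radial=mesh0.n_radial,
            n_circ=mesh0.n_circ,
        )
        disp = solve_with_displacements(mesh, pressure_mmhg, materials)
        deformed = mesh.nodes[mesh.outer_nodes] + disp[mesh.outer_nodes]
        d = _ap_diameter(deformed)
        resid = abs(d - target) / target
        trace.append((s, d, resid))
        if resid < tol:
            return {"scale": s, "axial_scale": 1.0, "iterations": it, "residual": resid}
        s *= target / d
    raise RuntimeError(
        f"start-shape iteration did not converge in {max_iter} steps; trace={trace[-5:]}"
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def postprocess_stress(fields: list[StressField], discard_pct: float = 5.0) -> list[StressField]:
    """Discard the patient's top stress percentile and normalize by the peak.

    All the patient's wall elements are pooled across slices; the top
    ``discard_pct`` percent (``ceil`` count, ties broken by pooled element
    order) are flagged discarded.  The peak is the largest retained wall
    stress; every element's ``normalized`` value is ``sigma_vm / peak``
    clipped to 1.  ILT/calcium stresses are computed but carry no weight
    downstream ("only stress in the wall" enters the analysis).
    """
    wall_vals = np.concatenate([f.sigma_vm[f.material == "wall"] for f in fields])
    n_wall = len(wall_vals)
    if n_wall < 20:
        raise ValueError(f"only {n_wall} wall elements; percentile discard ill-defined")
    k = math.ceil(discard_pct / 100.0 * n_wall)
    # descending stress, ascending pooled index on ties
    order = np.lexsort((np.arange(n_wall), -wall_vals))
    discard_idx = np.zeros(n_wall, dtype=bool)
    discard_idx[order[:k]] = True
    peak = float(wall_vals[~discard_idx].max())
    if peak <= 0:
        peak = 1.0  # unloaded patient: all stresses zero

    pos = 0
    out = []
    for f in fields:
        wall_m = f.material == "wall"
        nf = int(wall_m.sum())
        disc = np.zeros(len(f.sigma_vm), dtype=bool)
        disc[wall_m] = discard_idx[pos : pos + nf]
        pos += nf
        out.append(
            StressField(
                sigma_vm=f.sigma_vm,
                material=f.material,
                centroids=f.centroids,
                slice_index=f.slice_index,
                normalized=np.minimum(f.sigma_vm / peak, 1.0),
                discarded=disc,
                components=f.components,
            )
        )
    return out
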