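"""Finite-element verification against the Lamé thick-cylinder solution.

Pressurized homogeneous annulus (a = 10 mm, b = 20 mm, p = 100 mmHg,
nu = 0.49): reports the von Mises error of the plane-strain solver at three
mesh resolutions and the observed convergence order.

Writes results/fe_verification.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aaastress.mechanics import MMHG_TO_PA, Material, MaterialSet, build_mesh, solve_plane_strain
from aaastress.segmentation import SliceGeometry

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

a, b, p_mmhg, nu = 10.0, 20.0, 100.0, 0.49
p = p_mmhg * MMHG_TO_PA
mats = MaterialSet(Material(2.0e6, nu), Material(0.2e6, nu), Material(20e6, nu))


def vm_exact(r):
    A = p * a**2 / (b**2 - a**2)
    B = p * a**2 * b**2 / (b**2 - a**2)
    sr, st = A - B / r**2, A + B / r**2
    sz = nu * (sr + st)
    return np.sqrt(0.5 * ((sr - st) ** 2 + (st - sz) ** 2 + (sz - sr) ** 2))


def circle(r, n=512):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.sin(th), r * np.cos(th)])


rows = []
for nr, nc in [(4, 64), (8, 128), (16, 256)]:
    geo = SliceGeometry(0, circle(a), circle(b), None, None, (0.6, 0.6))
    mesh = build_mesh(geo, nr, nc, wall_thickness=b - a)
    f = solve_plane_strain(mesh, p_mmhg, mats)
    r = np.hypot(*mesh.centroids.T)
    rel = np.abs(f.sigma_vm - vm_exact(r)) / vm_exact(r)
    rows.append({"n_radial": nr, "n_circ": nc, "max_rel_err": rel.max(), "mean_rel_err": rel.mean()})
    print(f"n_radial={nr:3d} n_circ={nc:4d}  max err {rel.max():.4%}  mean err {rel.mean():.4%}")

df = pd.DataFrame(rows)
orders = np.log2(df["max_rel_err"].to_numpy()[:-1] / df["max_rel_err"].to_numpy()[1:])
print("observed convergence order per refinement:", np.round(orders, 2))
df.to_csv(OUT / "fe_verification.csv", index=False)
print(f"wrote {OUT / 'fe_verification.csv'}")
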