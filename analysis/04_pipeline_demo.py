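"""End-to-end pipeline demonstration on two rendered phantom patients.

Runs phantom generation, segmentation, registration, finite-element stress,
octant sampling and the statistical stage, then verifies that every sampled
octant SUV_max equals the planted value exactly (zero PET blur, nearest-
neighbour resampling).

Writes results/run_demo/ (volumes, derived tables, manifest, analysis).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aaastress.phantom import GenerativeModel, generate_patient
from aaastress.pipeline import RunConfig, run_all

OUT = Path(__file__).resolve().parents[1] / "results" / "run_demo"

cfg = RunConfig(
    out_dir=str(OUT),
    seed=11,
    n_patients=2,
    grid_shape=(16, 128, 128),
    spacing=(3.0, 0.7, 0.7),
    interp="nearest",
    rigid_offset_mode="integer_voxel",
    run_backward_elimination=False,
)
run_all(cfg)

table = pd.read_csv(OUT / "octant_table.csv")
print(f"sampled {len(table)} octants from {cfg.n_patients} patients")
print(table.head(8).round(3).to_string(index=False))

model = GenerativeModel.multivariate()
worst = 0.0
for pid in range(cfg.n_patients):
    _, _, truth = generate_patient(cfg.phantom_config(), model, pid)
    tt = truth.true_octants.rename(columns={"suv_max": "suv_true"})
    merged = table[table["patient_id"] == pid].merge(
        tt[["slice_index", "octant_index", "suv_true"]],
        on=["slice_index", "octant_index"],
    )
    worst = max(worst, float(np.abs(merged["suv_max"] - merged["suv_true"]).max()))
print(f"\nmax |sampled - planted| SUV_max over all octants: {worst:.2e}")
print(f"wrote {OUT}")
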