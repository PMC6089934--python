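"""One-time calibration sweep for the trabecular phantom generator.

Maps the structural wavelength of the layered field to the trabecular thickness the
morphometry module actually measures, on a grid of bone volume fractions,
and writes the lookup table shipped as ``src/sparsebone/calibration.json``.
The quantile threshold already pins BV/TV exactly, so only Tb.Th needs a
calibrated knob; Tb.S is emergent.

Run from the repository root:  python scripts/build_calibration.py
"""
from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sparsebone.morphometry import tb_s, tb_th  # noqa: E402
from sparsebone.phantoms import PhantomSpec, make_trabecular_phantom  # noqa: E402

BVTV_GRID = [40.0, 45.0, 50.0, 55.0, 60.0]
CORR_GRID_UM = [350.0, 425.0, 500.0, 575.0, 650.0, 725.0]
ANISOTROPY = 0.5
SHAPE = (64, 32, 32)
VOXEL_UM = 25.0
N_REPS = 4


def main() -> None:
    tbth = np.zeros((len(BVTV_GRID), len(CORR_GRID_UM)))
    tbs = np.zeros_like(tbth)
    for i, bv in enumerate(BVTV_GRID):
        for j, corr in enumerate(CORR_GRID_UM):
            th_vals, sp_vals = [], []
            for rep in range(N_REPS):
                spec = PhantomSpec(
                    grid_shape=SHAPE, voxel_size_um=VOXEL_UM,
                    structure="trabecular",
                    structure_params={"bvtv_pct": bv, "corr_um": corr,
                                      "anisotropy": ANISOTROPY},
                    seed=1000 + 17 * rep)
                _, gt = make_trabecular_phantom(spec)
                voi = gt.region_masks["trabecular"]
                bone = gt.bone_mask() & voi
                th_vals.append(tb_th(bone, VOXEL_UM))
                sp_vals.append(tb_s(bone, voi, VOXEL_UM))
            tbth[i, j] = float(np.mean(th_vals))
            tbs[i, j] = float(np.mean(sp_vals))
            print(f"bvtv {bv:5.1f}  corr {corr:6.1f}  "
                  f"Tb.Th {tbth[i, j]:6.1f}  Tb.S {tbs[i, j]:6.1f}")

    out = {
        "description": "trabecular generator calibration: measured Tb.Th/Tb.S "
                       "(um) over (BV/TV %, correlation length um)",
        "anisotropy": ANISOTROPY,
        "voxel_size_um": VOXEL_UM,
        "grid_shape": list(SHAPE),
        "n_reps": N_REPS,
        "bvtv_grid": BVTV_GRID,
        "corr_grid_um": CORR_GRID_UM,
        "tbth_um": tbth.tolist(),
        "tbs_um": tbs.tolist(),
    }
    dest = Path(__file__).resolve().parents[1] / "src" / "sparsebone" / "calibration.json"
    dest.write_text(json.dumps(out, indent=1))
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
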