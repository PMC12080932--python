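"""Output writers: legacy-ASCII VTK fields, CSV tables, run manifests.

Fields live on the uniform lattice, so the structured-points flavor of
the legacy VTK format is sufficient for visualization in ParaView or
pyvista; physical units are recorded in the field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import LatticeGrid

__all__ = ["write_vtk_fields", "write_run_outputs"]


def write_vtk_fields(path, grid: LatticeGrid, scalars: dict | None = None,
                     vectors: dict | None = None) -> None:
    """Write node fields to a legacy-ASCII VTK structured-points file.

    ``scalars`` maps names to arrays of the grid shape; ``vectors`` to
    arrays of shape ``(dim,) + grid shape`` (2D vectors are padded with
    a zero z-component). Axis order in the file is x fastest — arrays
    are transposed accordingly.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    shape = grid.shape
    dims = tuple(shape) + (1,) * (3 - len(shape))
    n = int(np.prod(shape))
    sp = grid.spacing

    def flat(a):
        # VTK expects x varying fastest; numpy C-order has x slowest
        return np.asarray(a).transpose(tuple(range(len(shape))[::-1])).ravel()

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("thrombosim lattice fields (lengths um)\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"ORIGIN 0 0 0\nSPACING {sp} {sp} {sp}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, flat(arr), fmt="%.6g")
        for name, arr in vectors.items():
            arr = np.asarray(arr)
            comps = [flat(arr[i]) for i in range(arr.shape[0])]
            while len(comps) < 3:
                comps.append(np.zeros(n))
            fh.write(f"VECTORS {name} float\n")
            np.savetxt(fh, np.column_stack(comps), fmt="%.6g")


def write_run_outputs(out_dir, traj, metrics=None) -> None:
    """Write counts.csv, events.csv, metrics.json, platelets.csv and the
    final field snapshot for one trajectory."""
    import pandas as pd

    from .simulate import compute_metrics
    from .transport import SPECIES

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = metrics or compute_metrics(traj)

    pd.DataFrame({"t_s": traj.times, "bound_count": traj.bound_count}
                 ).to_csv(out / "counts.csv", index=False)
    kinds = {1: "insert", 2: "attach", 3: "detach", 4: "exit"}
    pd.DataFrame({
        "t_s": traj.ev_t,
        "event": [kinds.get(int(k), str(k)) for k in traj.ev_kind],
        "platelet_id": traj.ev_pid,
        "node": traj.ev_node,
    }).to_csv(out / "events.csv", index=False)
    p = traj.platelets
    pd.DataFrame({
        "platelet_id": np.arange(len(p["pos"])),
        "node": p["pos"], "status": p["status"], "xi": p["xi"],
        "F": p["F"], "released": p["released"],
        "t_release": p["t_release"],
    }).to_csv(out / "platelets.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump({
            "tau_crit_s": m.tau_crit,
            "fold_increase": m.fold_increase,
            "n_final": m.n_final,
            "centroid_x_um": m.centroid_x_um,
            "peak_x_um": m.peak_x_um,
            "config_hash": traj.config_hash,
            "n_inserted": traj.n_inserted,
            "scenario": traj.config.scenario,
            "seed": traj.config.seed,
        }, fh, indent=2)
    occ = np.zeros(traj.grid.shape)
    bound = p["status"] == 2
    occ[np.unravel_index(p["pos"][bound], traj.grid.shape)] = 1.0
    write_vtk_fields(out / "final_fields.vtk", traj.grid,
                     scalars={"occupancy": occ,
                              **{f"{s}_uM": traj.conc_final[i]
                                 for i, s in enumerate(SPECIES)}})
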