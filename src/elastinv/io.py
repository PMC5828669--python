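"""CSV/JSON interchange for load cases and calibration tables.

Surface displacement files carry one marker per line (1-based row/column in
the grid convention of the rig, displacements in meters); the forces file
lists one magnitude per load case; calibration files carry the five voltage
channels plus the reference force in grams.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import LoadCase, SyntheticExperiment
from .synthetic import CalibrationData

__all__ = ["write_load_case_csv", "read_load_case_csv", "write_experiment",
           "read_experiment", "write_calibration_csv", "read_calibration_csv"]


def write_load_case_csv(path, mesh, case: LoadCase) -> None:
    """Surface displacements of one load case: columns row, col, dx, dy, dz."""
    n_rows, n_cols = mesh.surface_grid_shape
    rows = np.repeat(np.arange(1, n_rows + 1), n_cols)
    cols = np.tile(np.arange(1, n_cols + 1), n_rows)
    d = np.asarray(case.surface_disp)
    pd.DataFrame({"row": rows, "col": cols, "dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2]}).to_csv(
        path, index=False
    )


def read_load_case_csv(path, mesh, magnitude: float, load_node: int) -> LoadCase:
    df = pd.read_csv(path)
    n_rows, n_cols = mesh.surface_grid_shape
    if len(df) != n_rows * n_cols:
        raise ValueError(f"{path}: expected {n_rows * n_cols} markers, found {len(df)}")
    order = np.argsort((df["row"].to_numpy() - 1) * n_cols + (df["col"].to_numpy() - 1))
    d = df[["dx", "dy", "dz"]].to_numpy(dtype=float)[order]
    return LoadCase(magnitude=magnitude, load_node=load_node, surface_disp=d)


def write_experiment(outdir, exp: SyntheticExperiment) -> None:
    """Write one CSV per load case, a forces file and a JSON truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mags = []
    for i, lc in enumerate(exp.load_cases):
        write_load_case_csv(outdir / f"displacements_{i:02d}.csv", exp.mesh, lc)
        mags.append(lc.magnitude)
    pd.DataFrame({"load_case": range(len(mags)), "force_N": mags}).to_csv(
        outdir / "forces.csv", index=False
    )
    manifest = {
        "provenance": exp.provenance,
        "load_node": int(exp.load_cases[0].load_node),
        "n_load_cases": len(mags),
        "true_alpha": [float(a) for a in exp.true_alpha],
        "true_v": [float(v) for v in exp.true_v],
        "true_E": [float(e) for e in exp.true_E],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_experiment(outdir, mesh) -> tuple[list[LoadCase], dict]:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    forces = pd.read_csv(outdir / "forces.csv")
    cases = [
        read_load_case_csv(
            outdir / f"displacements_{int(row.load_case):02d}.csv",
            mesh, float(row.force_N), int(manifest["load_node"]),
        )
        for row in forces.itertuples()
    ]
    return cases, manifest


def write_calibration_csv(path, data: CalibrationData) -> None:
    cols = {f"v{i + 1}": data.voltages[:, i] for i in range(5)}
    cols["force_g"] = data.force_g
    pd.DataFrame(cols).to_csv(path, index=False)


def read_calibration_csv(path) -> CalibrationData:
    df = pd.read_csv(path)
    volts = df[[f"v{i + 1}" for i in range(5)]].to_numpy(dtype=float)
    return CalibrationData(voltages=volts, force_g=df["force_g"].to_numpy(dtype=float))
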