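"""Derived quantities and serialization.

Areas are measured on the quarter domain from the thresholded phase fields
(tumor: phi > 0.5; capillary: c > 0) by sub-cell counting on a bilinearly
refined field; relative quantities such as the growth ratio
g_re = (A_t - A_0)/A_0 and the equivalent-radius ratio sqrt(A_t/A_0) are
therefore quadrant-invariant.  Inside the tumor mask the nutrient level
classifies each point as necrotic (sigma < sigma_nh), hypoxic
(sigma_nh <= sigma < sigma_hv) or proliferative (sigma >= sigma_hv).

Outputs of a run: a time-series CSV (one row per record), legacy-ASCII VTK
image-data snapshots of the four fields plus a compressed array container,
the tip-cell event log as CSV, and a JSON manifest with the configuration,
seed and grid for exact reproduction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .constitutive import ModelParameters
from .grid_numerics import FieldState, Grid
from .tec_agents import TecEvent, TipCell
from .vasculature import VascularNetwork

__all__ = [
    "ObservableRecord",
    "tumor_area",
    "capillary_area",
    "equivalent_radius_ratio",
    "classify_regions",
    "hypoxia_distance",
    "collect_record",
    "records_to_frame",
    "read_records_csv",
    "write_outputs",
    "write_vtk_snapshot",
]

#: Refinement factor for sub-cell area counting.
_REFINE = 4


@dataclass(frozen=True)
class ObservableRecord:
    """Per-output-time scalar observables of a run."""

    t: float            # nondim time
    t_days: float
    A_t: float          # tumor area (quarter domain, nondim^2)
    g_re: float         # (A_t - A_0) / A_0
    capillary_area: float
    S: float
    necrotic_area: float
    hypoxic_area: float
    proliferative_area: float
    n_tecs_active: int
    n_anastomoses: int


def _threshold_area(arr: np.ndarray, level: float, grid: Grid) -> float:
    """Area of {arr > level} with linear sub-cell refinement."""
    fine = ndimage.zoom(arr, _REFINE, order=1, mode="nearest", grid_mode=True)
    return float((fine > level).sum()) * grid.cell_area / _REFINE ** 2


def tumor_area(phi: np.ndarray, grid: Grid) -> float:
    """Area of the tumor region {phi > 0.5} in nondim^2."""
    return _threshold_area(phi, 0.5, grid)


def capillary_area(c: np.ndarray, grid: Grid) -> float:
    """Area of the capillary region {c > 0} in nondim^2."""
    return _threshold_area(c, 0.0, grid)


def equivalent_radius_ratio(A_t: float, A_0: float) -> float:
    """sqrt(A_t / A_0): the radius ratio of equal-area discs."""
    if A_0 <= 0:
        raise ValueError("A_0 must be positive")
    return float(np.sqrt(A_t / A_0))


def classify_regions(phi: np.ndarray, sigma: np.ndarray,
                     p: ModelParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Necrotic / hypoxic / proliferative masks inside the tumor.

    Disjoint by construction; their union is the tumor mask {phi > 0.5}.
    """
    tumor = phi > 0.5
    necrotic = tumor & (sigma < p.sigma_nh)
    hypoxic = tumor & (sigma >= p.sigma_nh) & (sigma < p.sigma_hv)
    proliferative = tumor & (sigma >= p.sigma_hv)
    return necrotic, hypoxic, proliferative


def hypoxia_distance(sigma: np.ndarray, grid: Grid, p: ModelParameters,
                     strip_height: float | None = None,
                     column: int | None = None) -> float:
    """Distance (um) from the capillary at which sigma first falls to sigma_hv.

    Sampled along one grid column through host tissue (by default the
    outermost column, farthest from the tumor at the opposite corner),
    starting from the inner boundary of the capillary strip; the crossing is
    linearly interpolated.
    """
    if strip_height is None:
        strip_height = 25.0 / p.L_scale
    if column is None:
        column = grid.nx - 1
    ys = grid.y_centers()
    profile = sigma[:, column]
    start = int(np.searchsorted(ys, strip_height))
    for j in range(start, grid.ny - 1):
        s0, s1 = profile[j], profile[j + 1]
        if s0 >= p.sigma_hv > s1:
            frac = (s0 - p.sigma_hv) / (s0 - s1)
            y_cross = ys[j] + frac * (ys[j + 1] - ys[j])
            return (y_cross - strip_height) * p.L_scale
        if s0 == p.sigma_hv:
            return (ys[j] - strip_height) * p.L_scale
    raise ValueError("nutrient profile never crosses sigma_hv along the column")


def collect_record(state: FieldState, grid: Grid, p: ModelParameters,
                   network: VascularNetwork, tecs: list[TipCell],
                   n_anastomoses: int, A0: float | None,
                   S_override: float | None = None) -> ObservableRecord:
    """Measure all scalar observables of the current state."""
    A_t = tumor_area(state.phi, grid)
    g_re = 0.0 if A0 is None else (A_t - A0) / A0
    necrotic, hypoxic, proliferative = classify_regions(state.phi, state.sigma, p)
    cell = grid.cell_area
    return ObservableRecord(
        t=state.t,
        t_days=state.t * p.T_scale / 86400.0,
        A_t=A_t,
        g_re=g_re,
        capillary_area=capillary_area(state.c, grid),
        S=network.S if S_override is None else S_override,
        necrotic_area=float(necrotic.sum()) * cell,
        hypoxic_area=float(hypoxic.sum()) * cell,
        proliferative_area=float(proliferative.sum()) * cell,
        n_tecs_active=sum(t.active for t in tecs),
        n_anastomoses=n_anastomoses,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def records_to_frame(records: list[ObservableRecord]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(ObservableRecord)]
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)


def read_records_csv(path: str | Path) -> list[ObservableRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [ObservableRecord(**{k: (int(v) if k.startswith("n_") else float(v))
                                for k, v in row.items()})
            for row in df.to_dict(orient="records")]


def write_vtk_snapshot(state: FieldState, grid: Grid, path: str | Path) -> None:
    """Write the four fields as a legacy-ASCII VTK STRUCTURED_POINTS file."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"tumor-angiogenesis fields t={state.t:.6g}\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {grid.nx} {grid.ny} 1\n")
        fh.write(f"ORIGIN {grid.dx / 2:.8g} {grid.dy / 2:.8g} 0\n")
        fh.write(f"SPACING {grid.dx:.8g} {grid.dy:.8g} 1\n")
        fh.write(f"POINT_DATA {grid.nx * grid.ny}\n")
        for name, arr in (("phi", state.phi), ("sigma", state.sigma),
                          ("c", state.c), ("f", state.f)):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")


def write_outputs(result, outdir: str | Path) -> dict[str, Path]:
    """Write time series, snapshots, event log and manifest for one run.

    ``result`` is a `scenarios.ScenarioResult`.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = result.config.grid()
    paths: dict[str, Path] = {}

    series = outdir / "timeseries.csv"
    records_to_frame(result.records).to_csv(series, index=False,
                                            float_format="%.17g")
    paths["timeseries"] = series

    events = outdir / "tec_events.csv"
    pd.DataFrame([dataclasses.asdict(e) for e in result.events],
                 columns=[f.name for f in dataclasses.fields(TecEvent)]
                 ).to_csv(events, index=False)
    paths["tec_events"] = events

    for snap, t in zip(result.snapshots, result.snapshot_times):
        tag = f"{t:012.3f}".replace(".", "_")
        vtk_path = outdir / f"fields_t{tag}.vtk"
        write_vtk_snapshot(snap, grid, vtk_path)
        np.savez_compressed(outdir / f"fields_t{tag}.npz",
                            phi=snap.phi, sigma=snap.sigma, c=snap.c,
                            f=snap.f, t=snap.t)
        paths["last_snapshot"] = vtk_path

    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({
            "config": result.config.to_dict(),
            "seed": result.config.seed,
            "grid": {"nx": grid.nx, "ny": grid.ny,
                     "dx": grid.dx, "dy": grid.dy},
            "tumor_area_rule": "phi > 0.5, sub-cell refined",
            "package": "angiofield 0.1.0",
            "network": {"n_segments": result.network.n,
                        "lengths": result.network.lengths.tolist(),
                        "S": result.network.S},
        }, fh, indent=2)
    paths["manifest"] = manifest
    return paths
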