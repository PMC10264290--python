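"""File formats: CSV tables, HDF5 plane containers, legacy-VTK export.

All columns carry their units in the name (``flow_mL_s``,
``R_tot_mmHg_per_mL_s``); numeric payloads round-trip at full precision
(written with ``repr``-faithful formatting). See docs/FORMATS.md for the
column-level layout of every format.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .inlet import MovingPlaneSeries, PlaneVelocityField
from .metrics import WSSHistory
from .zerod import FlowWaveform, WK3Params

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_wk3_table",
    "write_wk3_table",
    "read_plane_series_csv",
    "write_plane_series_csv",
    "read_plane_series_h5",
    "write_plane_series_h5",
    "read_wss_history_h5",
    "write_wss_history_h5",
    "export_vtk_pointdata",
]

_FULL = "%.17g"


def write_waveform_csv(waveform: FlowWaveform, path: str | Path) -> None:
    """Two-column waveform table (time_s, flow_mL_s); period is implied by
    one trailing comment line."""
    df = pd.DataFrame({"time_s": waveform.times, "flow_mL_s": waveform.flows})
    with open(path, "w") as fh:
        fh.write(f"# period_s={waveform.period!r}\n")
        df.to_csv(fh, index=False, float_format=_FULL)


def read_waveform_csv(path: str | Path) -> FlowWaveform:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# period_s="):
            raise ValueError(f"{path}: missing '# period_s=' header line")
        period = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    _require_columns(df, ["time_s", "flow_mL_s"], path)
    return FlowWaveform(
        times=df["time_s"].to_numpy(), flows=df["flow_mL_s"].to_numpy(), period=period
    )


def write_wk3_table(params: dict[str, WK3Params], path: str | Path) -> None:
    rows = [
        {
            "outlet": name,
            "R_tot_mmHg_per_mL_s": p.R_tot,
            "rho": p.rho,
            "R_p_mmHg_per_mL_s": p.R_p,
            "R_d_mmHg_per_mL_s": p.R_d,
            "C_mL_per_mmHg": p.C,
        }
        for name, p in params.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FULL)


def read_wk3_table(path: str | Path) -> dict[str, WK3Params]:
    """Read a WK3 parameter table; malformed rows raise with the row number."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["outlet", "R_tot_mmHg_per_mL_s", "rho", "C_mL_per_mmHg"], path
    )
    out: dict[str, WK3Params] = {}
    for i, row in df.iterrows():
        try:
            out[str(row["outlet"])] = WK3Params(
                float(row["R_tot_mmHg_per_mL_s"]),
                float(row["rho"]),
                float(row["C_mL_per_mmHg"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


_PLANE_COLS = ["x_mm", "y_mm", "z_mm", "vx_m_s", "vy_m_s", "vz_m_s", "area_mm2", "t_s"]


def write_plane_series_csv(series: MovingPlaneSeries, path: str | Path) -> None:
    """Long-format frame table with the plane normal and period in a header
    comment (one normal per frame, repeated per row)."""
    rows = []
    for f in series.frames:
        n = len(f.points)
        rows.append(
            pd.DataFrame(
                {
                    "x_mm": f.points[:, 0],
                    "y_mm": f.points[:, 1],
                    "z_mm": f.points[:, 2],
                    "vx_m_s": f.velocities[:, 0],
                    "vy_m_s": f.velocities[:, 1],
                    "vz_m_s": f.velocities[:, 2],
                    "area_mm2": f.area_weights,
                    "t_s": np.full(n, f.timestamp),
                    "nx": np.full(n, f.normal[0]),
                    "ny": np.full(n, f.normal[1]),
                    "nz": np.full(n, f.normal[2]),
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(f"# period_s={series.period!r}\n")
        pd.concat(rows).to_csv(fh, index=False, float_format=_FULL)


def read_plane_series_csv(path: str | Path) -> MovingPlaneSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# period_s="):
            raise ValueError(f"{path}: missing '# period_s=' header line")
        period = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    _require_columns(df, _PLANE_COLS + ["nx", "ny", "nz"], path)
    frames = []
    for t, g in df.groupby("t_s", sort=True):
        normal = g[["nx", "ny", "nz"]].iloc[0].to_numpy()
        frames.append(
            PlaneVelocityField(
                points=g[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                velocities=g[["vx_m_s", "vy_m_s", "vz_m_s"]].to_numpy(),
                area_weights=g["area_mm2"].to_numpy(),
                normal=normal / np.linalg.norm(normal),
                timestamp=float(t),
                out_of_plane_tol=np.inf,
            )
        )
    return MovingPlaneSeries(frames=frames, period=period)


def write_plane_series_h5(series: MovingPlaneSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["period_s"] = series.period
        for i, f in enumerate(series.frames):
            g = h5.create_group(f"frame_{i:04d}")
            g.attrs["t_s"] = f.timestamp
            g.create_dataset("points_mm", data=f.points)
            g.create_dataset("velocities_m_s", data=f.velocities)
            g.create_dataset("area_mm2", data=f.area_weights)
            g.create_dataset("normal", data=f.normal)


def read_plane_series_h5(path: str | Path) -> MovingPlaneSeries:
    with h5py.File(path, "r") as h5:
        period = float(h5.attrs["period_s"])
        frames = []
        for key in sorted(h5.keys()):
            g = h5[key]
            frames.append(
                PlaneVelocityField(
                    points=g["points_mm"][()],
                    velocities=g["velocities_m_s"][()],
                    area_weights=g["area_mm2"][()],
                    normal=g["normal"][()],
                    timestamp=float(g.attrs["t_s"]),
                    out_of_plane_tol=np.inf,
                )
            )
    return MovingPlaneSeries(frames=frames, period=period)


def write_wss_history_h5(history: WSSHistory, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("node_ids", data=np.asarray(history.node_ids))
        h5.create_dataset("times_s", data=history.times)
        h5.create_dataset("tau_Pa", data=history.tau)


def read_wss_history_h5(path: str | Path) -> WSSHistory:
    with h5py.File(path, "r") as h5:
        return WSSHistory(
            node_ids=h5["node_ids"][()],
            times=h5["times_s"][()],
            tau=h5["tau_Pa"][()],
        )


def export_vtk_pointdata(
    points: np.ndarray, maps: dict[str, np.ndarray], path: str | Path
) -> None:
    """Write per-node scalar maps as legacy-VTK (ASCII) polydata point data.

    One VERTEX cell per point; each entry of ``maps`` (e.g. TAWSS, OSI,
    ECAP) becomes a named SCALARS array readable by any VTK-compatible
    viewer.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = pts.shape[0]
    for name, arr in maps.items():
        if np.asarray(arr).shape != (n,):
            raise ValueError(f"map {name!r} must have one value per point")
    lines = [
        "# vtk DataFile Version 3.0",
        "dissectflow point data export",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(_FULL % c for c in p) for p in pts]
    lines.append(f"VERTICES {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    lines.append(f"POINT_DATA {n}")
    for name, arr in maps.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [_FULL % v for v in np.asarray(arr, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
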