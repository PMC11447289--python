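"""CSV/TIFF/JSON readers and writers for the package's data dialects.

Column headers are versioned by the ``format_version`` comment written at
the top of each CSV (``# bbbkit-<kind>-v1``); readers accept files with or
without that header line.

Dialects
--------
tracks:  cell_id, frame, t_s, x_um, y_um, compartment, boundary_flag
counts:  frame, t_s, luminal, transmigrated, lost
records: group, Ct, V, Ci, t, A, Pm, membrane_type  (Pm may be empty)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

from bbbkit.migration import Trajectory
from bbbkit.permeability import PermeabilityRecord
from bbbkit.trafficking import CountTable

__all__ = [
    "tracks_to_frame",
    "frame_to_tracks",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_counts_csv",
    "read_counts_csv",
    "write_records_csv",
    "read_records_csv",
    "write_tiff",
    "read_tiff",
    "write_result_json",
]

_HEADERS = {
    "tracks": "# bbbkit-tracks-v1",
    "counts": "# bbbkit-counts-v1",
    "records": "# bbbkit-records-v1",
}


def tracks_to_frame(tracks: Sequence[Trajectory]) -> pd.DataFrame:
    """Tidy long-format table of a track collection."""
    parts = []
    for tr in tracks:
        parts.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "frame": np.arange(len(tr)),
            "t_s": tr.t,
            "x_um": tr.x,
            "y_um": tr.y,
            "compartment": tr.compartment,
            "boundary_flag": tr.boundary_flag,
        }))
    return pd.concat(parts, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame) -> list[Trajectory]:
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(Trajectory(
            cell_id=cell_id,
            t=grp["t_s"].to_numpy(),
            x=grp["x_um"].to_numpy(),
            y=grp["y_um"].to_numpy(),
            compartment=grp["compartment"].to_numpy()
            if "compartment" in grp else None,
            boundary_flag=bool(grp["boundary_flag"].iloc[0])
            if "boundary_flag" in grp else False,
        ))
    return tracks


def _write_csv(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_HEADERS[kind] + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_tracks_csv(tracks: Sequence[Trajectory], path: str | Path) -> None:
    _write_csv(tracks_to_frame(tracks), path, "tracks")


def read_tracks_csv(path: str | Path) -> list[Trajectory]:
    return frame_to_tracks(_read_csv(path))


def write_counts_csv(table: CountTable, path: str | Path) -> None:
    _write_csv(table.to_frame(), path, "counts")


def read_counts_csv(path: str | Path) -> CountTable:
    return CountTable.from_frame(_read_csv(path))


def write_records_csv(
    records: Sequence[PermeabilityRecord],
    path: str | Path,
    groups: Sequence[str] | None = None,
) -> None:
    """One row per device; ``groups`` labels rows (default 'device')."""
    if groups is None:
        groups = ["device"] * len(records)
    df = pd.DataFrame([{
        "group": g, "Ct": r.Ct, "V": r.V, "Ci": r.Ci, "t": r.t, "A": r.A,
        "Pm": r.Pm if r.Pm is not None else np.nan,
        "membrane_type": r.membrane_type,
    } for g, r in zip(groups, records)])
    _write_csv(df, path, "records")


def read_records_csv(path: str | Path) -> tuple[list[PermeabilityRecord], list[str]]:
    df = _read_csv(path)
    records, groups = [], []
    for _, row in df.iterrows():
        pm = row.get("Pm", np.nan)
        records.append(PermeabilityRecord(
            Ct=float(row["Ct"]), V=float(row["V"]), Ci=float(row["Ci"]),
            t=float(row["t"]), A=float(row["A"]),
            Pm=None if pd.isna(pm) else float(pm),
            membrane_type=str(row.get("membrane_type", "NPN")),
        ))
        groups.append(str(row.get("group", "device")))
    return records, groups


def write_tiff(array: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(array))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_result_json(result: Any, path: str | Path) -> None:
    """Serialize a result dataclass (or dict) to JSON, arrays as lists."""
    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)!r}")

    with Path(path).open("w") as fh:
        json.dump(result, fh, indent=2, default=default)
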