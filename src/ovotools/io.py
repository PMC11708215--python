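"""File I/O: OME-TIFF stacks with voxel calibration, CSV tables, JSON curves.

Stacks are written as multi-channel OME-TIFF with PhysicalSizeX/Y/Z metadata
(micrometres) and channel names, and read back into :class:`ImageStack`.
Tabular data (surveys, traces, tracks, region series) travel as plain CSV
with documented headers.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .growthtrack import EggChamberTrace
from .kinematics import CellTrack
from .segment3d import ImageStack
from .timeline import FixedSurvey, GrowthCurve

__all__ = [
    "write_stack",
    "read_stack",
    "write_survey",
    "read_survey",
    "curve_to_json",
    "curve_from_json",
    "write_traces",
    "read_traces",
    "write_tracks",
    "read_tracks",
]


# ---------------------------------------------------------------------------
# OME-TIFF
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-channel stack as OME-TIFF with voxel-size metadata."""
    arr = np.stack(
        [stack.data[ch] for ch in stack.channel_names], axis=0
    ).astype(np.float32)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        arr,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": stack.channel_names},
        },
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_stack`."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        ome = tif.ome_metadata
    if arr.ndim == 3:
        arr = arr[None]
    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    dx = float(pixels.get("PhysicalSizeX", 1.0))
    dy = float(pixels.get("PhysicalSizeY", 1.0))
    dz = float(pixels.get("PhysicalSizeZ", 1.0))
    names = [
        ch.get("Name") or f"channel{i}"
        for i, ch in enumerate(pixels.findall("ome:Channel", ns))
    ]
    if len(names) != arr.shape[0]:
        names = [f"channel{i}" for i in range(arr.shape[0])]
    data = {name: arr[i].astype(np.float64) for i, name in enumerate(names)}
    return ImageStack(data=data, voxel_size=(dz, dy, dx))


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def write_survey(survey: FixedSurvey, females_csv: str | Path, chambers_csv: str | Path) -> None:
    """Write a survey to two CSVs (per-female and per-chamber tables)."""
    survey.females.to_csv(females_csv, index=False)
    survey.chambers.to_csv(chambers_csv, index=False)


def read_survey(females_csv: str | Path, chambers_csv: str | Path) -> FixedSurvey:
    return FixedSurvey(
        females=pd.read_csv(females_csv), chambers=pd.read_csv(chambers_csv)
    )


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def curve_to_json(curve: GrowthCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(curve), indent=2))


def curve_from_json(path: str | Path) -> GrowthCurve:
    d = json.loads(Path(path).read_text())
    return GrowthCurve(d["amplitude"], d["rate"], d.get("kind", "area"))


# ---------------------------------------------------------------------------
# traces and tracks
# ---------------------------------------------------------------------------

def write_traces(traces: list[EggChamberTrace], path: str | Path) -> None:
    """Columns: chamber_id, elapsed_h, area_um2, oocyte_fraction[, t0_h]."""
    frames = []
    for tr in traces:
        df = tr.samples.copy()
        df.insert(0, "chamber_id", tr.chamber_id)
        df["t0_h"] = tr.t0_h
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[EggChamberTrace]:
    df = pd.read_csv(path)
    out = []
    for cid, g in df.groupby("chamber_id", sort=False):
        t0 = float(g["t0_h"].iloc[0]) if "t0_h" in g else float("nan")
        cols = [c for c in ("elapsed_h", "area_um2", "oocyte_fraction") if c in g]
        out.append(
            EggChamberTrace(str(cid), g[cols].reset_index(drop=True), t0_h=t0)
        )
    return out


def write_tracks(
    tracks: list[CellTrack], csv_path: str | Path, geometry_json: str | Path
) -> None:
    """Tracks as CSV (cell_id, t_h, x_um, y_um) plus chamber geometry JSON."""
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t_h, tr.x_um, tr.y_um):
            rows.append({"cell_id": tr.cell_id, "t_h": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    geo = {"y_mid_um": tracks[0].y_mid_um, "r_um": tracks[0].r_um}
    Path(geometry_json).write_text(json.dumps(geo, indent=2))


def read_tracks(csv_path: str | Path, geometry_json: str | Path) -> list[CellTrack]:
    df = pd.read_csv(csv_path)
    geo = json.loads(Path(geometry_json).read_text())
    out = []
    for cid, g in df.groupby("cell_id", sort=False):
        out.append(
            CellTrack(
                cell_id=str(cid),
                t_h=g["t_h"].to_numpy(),
                x_um=g["x_um"].to_numpy(),
                y_um=g["y_um"].to_numpy(),
                y_mid_um=float(geo["y_mid_um"]),
                r_um=float(geo["r_um"]),
            )
        )
    return out
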