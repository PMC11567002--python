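"""Readers and writers for every artifact the pipeline touches.

Movies are multi-frame TIFF with calibration (pixel size, frame
interval) in a JSON sidecar — never guessed from TIFF tags, whose
conventions vary across acquisition software. Tables are UTF-8 CSV
with a header row and '.' decimals; every distance column name carries
its unit (nm, s). Readers validate schemas and report the offending
column or line rather than propagating a pandas traceback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, Polygon

from .kinetics import Trace
from .synth import Movie

ROI_COLUMNS = ["synapse_id", "vertex_index", "x_nm", "y_nm"]
TRACE_COLUMNS = ["roi_id", "frame", "value"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


@dataclass
class RoiSet:
    """Per-synapse regions of interest as polygons in nm.

    The polygons live in the same coordinate frame as event
    localizations (origin at the centre of pixel (0, 0)). Circular
    ROIs — the common case for ~2 µm boutons — are stored as polygonal
    approximations via :meth:`add_circle`.
    """

    polygons: dict

    def __post_init__(self) -> None:
        for name, poly in self.polygons.items():
            if not poly.is_valid:
                raise ValueError(f"ROI {name!r} is not a simple polygon")

    @classmethod
    def from_circles(cls, circles: dict, n_vertices: int = 32) -> "RoiSet":
        """Build from ``{synapse_id: (cx_nm, cy_nm, radius_nm)}``."""
        polys = {}
        for name, (cx, cy, r) in circles.items():
            ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
            polys[name] = Polygon(np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang)])
        return cls(polygons=polys)

    def __len__(self) -> int:
        return len(self.polygons)

    def __iter__(self):
        return iter(self.polygons.items())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(path, movie: Movie) -> None:
    """Write a multi-frame TIFF plus its calibration sidecar JSON."""
    path = Path(path)
    # explicit photometric tag: small frames would otherwise be
    # misread as RGB planes
    tifffile.imwrite(path, movie.data.astype(np.float32), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {"pixel_size_nm": movie.pixel_size_nm, "frame_interval_s": movie.frame_interval_s}
        )
    )


def read_movie(path, pixel_size_nm: float | None = None, frame_interval_s: float | None = None) -> Movie:
    """Read a multi-frame TIFF; calibration comes from the sidecar or arguments.

    Raises
    ------
    ValueError
        If neither a sidecar JSON nor explicit calibration values are
        provided — calibration is never guessed silently.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, IndexError) as exc:
        raise ValueError(f"{path} is not a readable TIFF movie: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.size == 0:
        raise ValueError(f"{path} is not a readable TIFF movie (truncated or malformed file)")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size_nm = pixel_size_nm or meta.get("pixel_size_nm")
        frame_interval_s = frame_interval_s or meta.get("frame_interval_s")
    if pixel_size_nm is None or frame_interval_s is None:
        raise ValueError(
            f"no calibration for {path}: provide pixel_size_nm and frame_interval_s "
            "explicitly or in a sidecar JSON"
        )
    return Movie(data=np.asarray(data, dtype=float), pixel_size_nm=pixel_size_nm, frame_interval_s=frame_interval_s)


def _read_csv_checked(path, required: list[str], float_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} (found {list(df.columns)})")
    for col in float_cols:
        values = df[col]
        try:
            df[col] = values.astype(float)
        except ValueError:
            bad = values[pd.to_numeric(values, errors="coerce").isna()]
            line = bad.index[0] + 2  # header + 1-based
            val = bad.iloc[0]
            hint = " (decimal commas are not accepted; use '.' decimals)" if "," in str(val) else ""
            raise SchemaError(f"{path}, line {line}: cannot parse {val!r} in column {col!r}{hint}") from None
    return df


def write_rois(path, rois: RoiSet) -> None:
    rows = []
    for name, poly in rois:
        coords = np.asarray(poly.exterior.coords)[:-1]  # drop closing vertex
        for i, (x, y) in enumerate(coords):
            rows.append((name, i, x, y))
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, index=False)


def read_rois(path) -> RoiSet:
    """Read polygon ROIs from CSV (synapse_id, vertex_index, x_nm, y_nm)."""
    df = _read_csv_checked(path, ROI_COLUMNS, ["x_nm", "y_nm"])
    df["vertex_index"] = df["vertex_index"].astype(int)
    polys = {}
    for name, grp in df.groupby("synapse_id"):
        grp = grp.sort_values("vertex_index")
        if len(grp) < 3:
            raise SchemaError(f"{path}: ROI {name!r} has fewer than 3 vertices")
        polys[name] = Polygon(grp[["x_nm", "y_nm"]].to_numpy())
    return RoiSet(polygons=polys)


def write_traces(path, traces: list[Trace]) -> None:
    """Write traces as long-form CSV plus a JSON sidecar with the windows."""
    path = Path(path)
    rows = []
    meta = {}
    for k, tr in enumerate(traces):
        roi = tr.roi_id if tr.roi_id is not None else f"roi{k}"
        for frame, v in enumerate(tr.values):
            rows.append((roi, frame, v))
        meta[roi] = {
            "frame_interval_s": tr.frame_interval_s,
            "baseline": list(tr.baseline),
            "stimulus": list(tr.stimulus),
        }
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(meta))


def read_traces(path) -> list[Trace]:
    path = Path(path)
    df = _read_csv_checked(path, TRACE_COLUMNS, ["value"])
    df["frame"] = df["frame"].astype(int)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"no sidecar JSON for {path}: trace windows and frame interval are required")
    meta = json.loads(sidecar.read_text())
    traces = []
    for roi, grp in df.groupby("roi_id", sort=False):
        if roi not in meta:
            raise SchemaError(f"{path}: roi {roi!r} has no entry in the sidecar JSON")
        m = meta[roi]
        grp = grp.sort_values("frame")
        traces.append(
            Trace(
                values=grp["value"].to_numpy(),
                frame_interval_s=m["frame_interval_s"],
                baseline=tuple(m["baseline"]),
                stimulus=tuple(m["stimulus"]),
                roi_id=roi,
            )
        )
    return traces


def write_table(path, df: pd.DataFrame) -> None:
    """Write any pipeline table as CSV (UTF-8, '.' decimals, header row)."""
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read a localization table written by the detect stage."""
    from .detect import EVENT_TABLE_COLUMNS

    df = _read_csv_checked(
        path,
        EVENT_TABLE_COLUMNS,
        ["x_nm", "y_nm", "amplitude", "background", "sigma_psf_nm", "precision_nm"],
    )
    df["frame"] = df["frame"].astype(int)
    df["n_kernels_in_fit"] = df["n_kernels_in_fit"].astype(int)
    return df
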