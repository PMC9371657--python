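"""File formats: trace/ROI/truth CSVs, config files, and TIFF ROI extraction.

Trace CSV columns: ``cell_id, channel, time_s, intensity_au,
distance_um, laser_on`` (laser_on 0/1).  ROI CSV: ``cell_id, x_px,
y_px, radius_px, distance_um`` plus an optional ``role`` column
(heated / unheated / background / sheet).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import FluorescenceTrace, HeatPulseProtocol

TRACE_COLUMNS = ["cell_id", "channel", "time_s", "intensity_au",
                 "distance_um", "laser_on"]

__all__ = [
    "read_traces",
    "write_traces",
    "read_roi_table",
    "load_config_file",
    "extract_rois",
]


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "channel": tr.channel,
            "time_s": tr.time_s,
            "intensity_au": tr.intensity,
            "distance_um": tr.distance_um,
            "laser_on": tr.laser_on.astype(int),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def traces_from_frame(df: pd.DataFrame) -> list[FluorescenceTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError("trace table is empty")
    dup = df.duplicated(subset=["cell_id", "channel", "time_s"])
    if dup.any():
        bad = df.loc[dup, ["cell_id", "time_s"]].iloc[0]
        raise ValueError(
            f"duplicate (cell_id, channel, time) row: {bad.cell_id} at {bad.time_s} s")
    traces = []
    for (cid, ch), g in df.groupby(["cell_id", "channel"], sort=True):
        g = g.sort_index()
        t = g.time_s.to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone time in cell {cid!r}")
        traces.append(FluorescenceTrace(
            cell_id=str(cid),
            channel=str(ch),
            time_s=t,
            intensity=g.intensity_au.to_numpy(float),
            distance_um=float(g.distance_um.iloc[0]),
            laser_on=g.laser_on.to_numpy() > 0,
        ))
    return traces


def read_traces(path) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV into one trace per (cell, channel)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    return traces_from_frame(df)


def read_roi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["cell_id", "x_px", "y_px", "radius_px", "distance_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table missing column(s): {', '.join(missing)}")
    return df


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def protocol_from_dict(d: dict) -> HeatPulseProtocol:
    fields = {f.name for f in dataclasses.fields(HeatPulseProtocol)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown protocol field(s): {sorted(unknown)}")
    return HeatPulseProtocol(**d)


def extract_rois(
    tiff_path,
    roi_table: pd.DataFrame | str | Path,
    *,
    frame_interval_s: float,
    heat_source_px: tuple[float, float] | None = None,
    px_size_um: float = 1.0,
    protocol: HeatPulseProtocol | None = None,
    channel: str = "fluo4",
) -> list[FluorescenceTrace]:
    """Per-frame mean intensity inside disk ROIs of a multi-page TIFF.

    ``heat_source_px`` is the (x, y) pixel of the laser focus; each
    ROI's distance to it (centre-to-source, in um) overrides the table's
    ``distance_um`` when given.  Laser-on flags are derived from
    ``protocol`` when supplied.  Pixel coordinates are 0-based.
    """
    import tifffile
    from skimage.draw import disk as sk_disk

    if not isinstance(roi_table, pd.DataFrame):
        roi_table = read_roi_table(roi_table)
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    n_frames, h, w = stack.shape
    if n_frames < 2:
        raise ValueError("TIFF stack must have at least 2 pages")
    times = np.arange(n_frames) * frame_interval_s
    laser = None
    if protocol is not None:
        laser = (times >= protocol.t_start) & (times < protocol.t_end)

    traces = []
    for _, row in roi_table.iterrows():
        if not (0 <= row.x_px < w and 0 <= row.y_px < h):
            raise ValueError(f"ROI {row.cell_id} centre outside the image")
        rr, cc = sk_disk((row.y_px, row.x_px), row.radius_px, shape=(h, w))
        if rr.size == 0:
            rr = np.array([int(round(row.y_px))])
            cc = np.array([int(round(row.x_px))])
        mean = stack[:, rr, cc].mean(axis=1)
        if heat_source_px is not None:
            dist = px_size_um * float(np.hypot(row.x_px - heat_source_px[0],
                                               row.y_px - heat_source_px[1]))
        else:
            dist = float(row.distance_um)
        traces.append(FluorescenceTrace(
            cell_id=str(row.cell_id), channel=channel, time_s=times,
            intensity=mean.astype(float), distance_um=dist, laser_on=laser))
    return traces
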