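"""CSV readers/writers for recordings, bouts and label vectors.

CSV (header row, RFC-4180-style) is the canonical exchange format;
column mapping is user-supplied so any export dialect can be ingested.
Units are fixed by contract: gyroscope columns are deg/s, acceleration
columns are g. Bout files get a JSON sidecar carrying the full per-bout
event lists that the flat CSV cannot hold.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FormatError, ImuRecording, LabelVector, ValidationError, WalkingBout

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_recording",
    "write_recording",
    "write_bouts",
    "read_bouts",
    "write_labels",
    "read_labels",
]

DEFAULT_COLUMN_MAP = {
    "time": "time_s",
    "gyro": ["gyro_x", "gyro_y", "gyro_z"],
    "acc": ["acc_x", "acc_y", "acc_z"],
}


def _resolve_columns(df: pd.DataFrame, column_map: dict) -> dict:
    resolved = {}
    time_col = column_map.get("time")
    if time_col is None or time_col not in df.columns:
        raise FormatError(f"time column {time_col!r} not found")
    resolved["time"] = time_col
    for ch in ("gyro", "acc"):
        cols = column_map.get(ch)
        if cols is None:
            continue
        if len(cols) != 3:
            raise FormatError(f"{ch} mapping must name 3 columns")
        missing = [c for c in cols if c not in df.columns]
        if missing:
            # a channel is only optional when it is absent from the map
            if set(missing) == set(cols):
                continue
            raise FormatError(f"missing mapped column(s): {missing}")
        resolved[ch] = cols
    return resolved


def read_recording(
    path: str | Path,
    column_map: dict | None = None,
    fs: float | None = None,
    side: str = "unspecified",
) -> ImuRecording:
    """Read one IMU recording from CSV.

    ``column_map`` names the time column and the gyro/acc column triples
    (defaults to :data:`DEFAULT_COLUMN_MAP`); a channel absent from the
    map (or entirely absent from the file) is left out of the recording.
    ``fs`` defaults to the reciprocal median sample spacing.
    """
    column_map = column_map or DEFAULT_COLUMN_MAP
    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = _resolve_columns(df, column_map)
    t = df[cols["time"]].to_numpy(dtype=float)
    if "gyro" not in cols and "acc" not in cols:
        raise ValidationError("neither gyro nor acc columns mapped/present")
    if fs is None:
        if t.size < 2:
            raise ValidationError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    kwargs = {}
    for ch in ("gyro", "acc"):
        if ch in cols:
            kwargs[ch] = df[cols[ch]].to_numpy(dtype=float)
    return ImuRecording(side=side, fs=fs, t=t, **kwargs)


def write_recording(
    recording: ImuRecording, path: str | Path, column_map: dict | None = None
) -> None:
    """Write a recording to CSV using ``column_map`` names (full precision)."""
    column_map = column_map or DEFAULT_COLUMN_MAP
    data = {column_map["time"]: recording.t}
    for ch in ("gyro", "acc"):
        arr = getattr(recording, ch)
        if arr is not None:
            for j, col in enumerate(column_map[ch]):
                data[col] = arr[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def write_bouts(bouts: list[WalkingBout], path: str | Path) -> None:
    """Write bouts to CSV plus a ``.events.json`` sidecar with event lists."""
    path = Path(path)
    rows = [
        {
            "bout_id": i + 1,
            "start_s": b.start,
            "end_s": b.end,
            "n_events": b.n_events,
            "config": b.config,
            "source": b.signal_source,
        }
        for i, b in enumerate(bouts)
    ]
    columns = ["bout_id", "start_s", "end_s", "n_events", "config", "source"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.9f")
    sidecar = path.with_suffix(path.suffix + ".events.json")
    payload = [
        {"bout_id": i + 1, "events_s": b.events.tolist()}
        for i, b in enumerate(bouts)
    ]
    sidecar.write_text(json.dumps(payload, indent=1))


def read_bouts(path: str | Path) -> list[WalkingBout]:
    """Read bouts written by :func:`write_bouts` (CSV + JSON sidecar)."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".events.json")
    events: dict[int, list[float]] = {}
    if sidecar.exists():
        events = {
            rec["bout_id"]: rec["events_s"] for rec in json.loads(sidecar.read_text())
        }
    return [
        WalkingBout(
            start=row.start_s,
            end=row.end_s,
            events=np.asarray(events.get(int(row.bout_id), []), dtype=float),
            config=row.config,
            signal_source=row.source,
        )
        for row in df.itertuples()
    ]


def write_labels(labels: LabelVector, path: str | Path) -> None:
    """One 0/1 column; the header records the rate as ``label@<fs>Hz``."""
    header = f"label@{labels.fs:g}Hz"
    pd.DataFrame({header: labels.values}).to_csv(path, index=False)


def read_labels(path: str | Path) -> LabelVector:
    df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise FormatError("label file must have exactly one column")
    header = df.columns[0]
    if "@" not in header or not header.endswith("Hz"):
        raise FormatError("label header must look like 'label@40Hz'")
    fs = float(header.split("@")[1][:-2])
    values = df.iloc[:, 0].to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError("labels must be binary (0/1)")
    return LabelVector(fs=fs, values=values)
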