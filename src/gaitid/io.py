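"""CSV file formats for strides and skeleton logs.

Strides are stored one per file: commented header metadata followed by the
columns ``time_s, fx_L, fy_L, fz_L, fx_R, fy_R, fz_R`` (forces in Newtons,
uniform time step).  Skeleton logs are long-format CSV with the columns
``timestamp, sensor_id, joint_id, x, y, z, tracking_state``.  All files are
UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    SKELETON_COLUMNS,
    STRIDE_COLUMNS,
    SkeletonFrameLog,
    StrideRecord,
)

logger = logging.getLogger(__name__)

_STRIDE_FILE_COLUMNS = ("time_s", *STRIDE_COLUMNS)
_REL_TIMESTEP_TOL = 1e-6


class ParseError(ValueError):
    """A stride or skeleton file violated the format contract."""


def write_stride(record: StrideRecord, path) -> None:
    path = Path(path)
    n = record.n_samples
    time_s = np.arange(n) / record.sampling_rate
    header = [
        f"# subject_id: {record.subject_id}",
        f"# footwear: {record.footwear}",
        f"# body_weight_n: {record.body_weight_n:.6f}",
        f"# sampling_rate_hz: {record.sampling_rate:.6f}",
    ]
    if record.cycle_duration_s is not None:
        header.append(f"# cycle_duration_s: {record.cycle_duration_s:.6f}")
    if record.stance_duration_s is not None:
        header.append(f"# stance_duration_s: {record.stance_duration_s:.6f}")
    frame = pd.DataFrame({"time_s": time_s})
    for i, col in enumerate(STRIDE_COLUMNS):
        frame[col] = record.forces[:, i]
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.9g")
    path.write_text("\n".join(header) + "\n" + buf.getvalue(), encoding="utf-8")


def read_stride(path) -> StrideRecord:
    """Read one stride CSV, validating columns, metadata and time step."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    meta: dict[str, str] = {}
    body_lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed metadata line") from None
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    for key in ("subject_id", "footwear", "body_weight_n", "sampling_rate_hz"):
        if key not in meta:
            raise ParseError(f"{path}: missing metadata field {key!r}")
    if not body_lines:
        raise ParseError(f"{path}: no data rows")
    frame = pd.read_csv(_io.StringIO("\n".join(body_lines)))
    missing = [c for c in _STRIDE_FILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = frame[list(_STRIDE_FILE_COLUMNS)].isna().any(axis=1)
    if bad.any():
        lines = [str(i + 2) for i in frame.index[bad][:5]]
        raise ParseError(f"{path}: malformed row(s) at data line(s) {', '.join(lines)}")
    body_weight = float(meta["body_weight_n"])
    if body_weight <= 0:
        raise ParseError(f"{path}: non-positive body weight {body_weight}")
    rate = float(meta["sampling_rate_hz"])
    if rate <= 0:
        raise ParseError(f"{path}: non-positive sampling rate {rate}")
    t = frame["time_s"].to_numpy(dtype=np.float64)
    if t.size > 1:
        steps = np.diff(t)
        expected = 1.0 / rate
        if np.any(np.abs(steps - expected) > _REL_TIMESTEP_TOL * max(expected, 1e-12)):
            raise ParseError(f"{path}: non-uniform time step (expected {expected:.6g} s)")
    return StrideRecord(
        subject_id=meta["subject_id"],
        footwear=meta["footwear"],
        body_weight_n=body_weight,
        sampling_rate=rate,
        forces=frame[list(STRIDE_COLUMNS)].to_numpy(dtype=np.float64),
        cycle_duration_s=float(meta["cycle_duration_s"]) if "cycle_duration_s" in meta else None,
        stance_duration_s=float(meta["stance_duration_s"]) if "stance_duration_s" in meta else None,
    )


def read_strides(path) -> list[StrideRecord]:
    """Read a stride file, or every ``*.csv`` stride in a directory (sorted)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ParseError(f"{path}: no stride CSV files found")
        return [read_stride(f) for f in files]
    return [read_stride(path)]


def write_skeleton(log: SkeletonFrameLog, path) -> None:
    frame = log.frames[list(SKELETON_COLUMNS)]
    frame.to_csv(path, index=False, float_format="%.9g")


def read_skeleton(path) -> SkeletonFrameLog:
    """Read a skeleton CSV; out-of-order timestamps are sorted with a warning."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    missing = [c for c in SKELETON_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        raise ParseError(f"{path}: no frames")
    ts = frame["timestamp"].to_numpy()
    if np.any(np.diff(ts) < 0):
        logger.warning("%s: out-of-order timestamps; sorting", path)
        frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
    try:
        return SkeletonFrameLog(frames=frame)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_gallery(strides: Sequence[StrideRecord], heights_cm: dict[str, float], directory) -> None:
    """Write an enrolled gallery: stride files plus a heights table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stride_dir = directory / "strides"
    stride_dir.mkdir(exist_ok=True)
    counters: dict[str, int] = {}
    for record in strides:
        i = counters.get(record.subject_id, 0)
        counters[record.subject_id] = i + 1
        write_stride(record, stride_dir / f"{record.subject_id}_{record.footwear}_{i:03d}.csv")
    pd.DataFrame(
        {"subject_id": list(heights_cm), "height_cm": [round(h, 1) for h in heights_cm.values()]}
    ).to_csv(directory / "heights.csv", index=False)


def read_gallery(directory):
    from .recognition import Gallery

    directory = Path(directory)
    strides = read_strides(directory / "strides")
    heights = pd.read_csv(directory / "heights.csv")
    return Gallery(
        strides=strides,
        heights_cm=dict(zip(heights["subject_id"].astype(str), heights["height_cm"].astype(float))),
    )
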