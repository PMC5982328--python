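"""Body-height estimation from two-sensor skeleton logs, with footwear
height correction and height-based gallery gating.

Height is reconstructed from the virtual skeleton rather than read off a
single joint: segment lengths are summed along a fixed chain running from
the head joint down the spine (head - neck - spine shoulder - spine mid -
spine base) plus the mean of the two leg chains (hip - knee - ankle - foot),
plus a constant head-top offset because the head joint is not the vertex of
the skull.  A segment contributes only when both endpoint joints are
reported as fully tracked; a failed leg segment falls back to the
contralateral segment, otherwise to the other sensor, and when both sensors
provide a segment their values are averaged.  Frames that cannot be
resolved are skipped and counted.

Walking in high heels raises the measured height by a nearly constant
offset, so before gating the gallery the measured height of a probe
classified as high heels is reduced by a fixed 5 cm.  The gallery is then
restricted to enrolled subjects whose (sport-shoe) height lies within
+/- 2 cm of the corrected probe height; the boundary is inclusive.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import HeightRecord, SkeletonFrameLog

# Kinect-v2 style joint indices (subset used by the height chain).
SPINE_BASE = 0
SPINE_MID = 1
NECK = 2
HEAD = 3
HIP_LEFT = 12
KNEE_LEFT = 13
ANKLE_LEFT = 14
FOOT_LEFT = 15
HIP_RIGHT = 16
KNEE_RIGHT = 17
ANKLE_RIGHT = 18
FOOT_RIGHT = 19
SPINE_SHOULDER = 20

TRUNK_SEGMENTS = (
    (HEAD, NECK),
    (NECK, SPINE_SHOULDER),
    (SPINE_SHOULDER, SPINE_MID),
    (SPINE_MID, SPINE_BASE),
)
LEG_SEGMENTS = {
    "L": ((HIP_LEFT, KNEE_LEFT), (KNEE_LEFT, ANKLE_LEFT), (ANKLE_LEFT, FOOT_LEFT)),
    "R": ((HIP_RIGHT, KNEE_RIGHT), (KNEE_RIGHT, ANKLE_RIGHT), (ANKLE_RIGHT, FOOT_RIGHT)),
}

#: Distance from the head joint to the top of the skull, cm.  The synthetic
#: generator and the estimator share this constant so that noise-free
#: round-trips are exact.
HEAD_TOP_OFFSET_CM = 12.0

#: Footwear height correction, cm (applied when the footwear classifier
#: reports high heels).
HEIGHT_CORRECTION_CM = 5.0

#: Default half-width of the height gate, cm.
DEFAULT_HEIGHT_TOL_CM = 2.0

_N_JOINTS = 25


def _chain_heights(frames: pd.DataFrame, head_top_offset_cm: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-timestamp chain heights (cm); NaN where a frame is unresolvable."""
    ts = np.sort(frames["timestamp"].unique())
    pos = np.full((2, ts.size, _N_JOINTS, 3), np.nan)
    ok = np.zeros((2, ts.size, _N_JOINTS), dtype=bool)
    si = frames["sensor_id"].to_numpy(dtype=np.int64) - 1
    fi = np.searchsorted(ts, frames["timestamp"].to_numpy())
    ji = frames["joint_id"].to_numpy(dtype=np.int64)
    pos[si, fi, ji] = frames[["x", "y", "z"]].to_numpy(dtype=np.float64)
    ok[si, fi, ji] = (frames["tracking_state"] == "fully_tracked").to_numpy()

    def seg_len(j1: int, j2: int) -> np.ndarray:
        d = np.linalg.norm(pos[:, :, j1] - pos[:, :, j2], axis=-1)  # (2, nf)
        valid = ok[:, :, j1] & ok[:, :, j2]
        return np.where(valid, d, np.nan)

    def across_sensors(arr: np.ndarray) -> np.ndarray:
        cnt = np.sum(~np.isnan(arr), axis=0)
        total = np.where(np.isnan(arr), 0.0, arr).sum(axis=0)
        return np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)

    trunk = [across_sensors(seg_len(a, b)) for a, b in TRUNK_SEGMENTS]
    legs = {
        side: [across_sensors(seg_len(a, b)) for a, b in LEG_SEGMENTS[side]]
        for side in ("L", "R")
    }
    # Contralateral fallback, segment by segment.
    for i in range(3):
        left, right = legs["L"][i], legs["R"][i]
        legs["L"][i] = np.where(np.isnan(left), right, left)
        legs["R"][i] = np.where(np.isnan(right), left, right)

    trunk_sum = np.sum(trunk, axis=0)
    leg_mean = 0.5 * (np.sum(legs["L"], axis=0) + np.sum(legs["R"], axis=0))
    heights = (trunk_sum + leg_mean) * 100.0 + head_top_offset_cm
    return ts, heights


def frame_height(
    frame: pd.DataFrame,
    fallback_frame: pd.DataFrame | None = None,
    head_top_offset_cm: float = HEAD_TOP_OFFSET_CM,
) -> float | None:
    """Chain height (cm) of a single frame, or ``None`` if unresolvable.

    ``frame`` holds one sensor's joints for one instant; ``fallback_frame``
    the other sensor's joints for the same instant.
    """
    parts = [frame] if fallback_frame is None else [frame, fallback_frame]
    combined = pd.concat(parts, ignore_index=True).copy()
    combined["timestamp"] = 0.0
    _, heights = _chain_heights(combined, head_top_offset_cm)
    h = float(heights[0])
    return None if np.isnan(h) else h


def estimate_body_height(
    log: SkeletonFrameLog,
    head_top_offset_cm: float = HEAD_TOP_OFFSET_CM,
) -> HeightRecord:
    """Mean per-frame chain height over all usable frames of a walk.

    The sensors see more than one gait cycle, so averaging the oscillating
    instantaneous height brings the estimate close to the subject's walking
    height.  Raises ``ValueError`` when no frame is usable.
    """
    _, heights = _chain_heights(log.frames, head_top_offset_cm)
    usable = heights[np.isfinite(heights)]
    if usable.size == 0:
        raise ValueError("no usable frames: every frame had unresolvable segments")
    return HeightRecord(
        bh_measured_cm=float(np.mean(usable)),
        n_frames_used=int(usable.size),
    )


def normalize_height(bh_measured_cm: float, footwear_y: int) -> float:
    """Footwear-corrected body height.

    ``BH_norm = BH_measured`` for sport shoes (``y = 0``) and
    ``BH_measured - 5`` cm for high heels (``y = 1``).
    """
    if bh_measured_cm <= 0:
        raise ValueError("measured height must be positive")
    if footwear_y not in (0, 1):
        raise ValueError("footwear_y must be 0 or 1")
    return float(bh_measured_cm) - HEIGHT_CORRECTION_CM * int(footwear_y)


def reduce_gallery(
    enrolled_heights: Mapping[str, float],
    bh_norm_cm: float,
    tol_cm: float = DEFAULT_HEIGHT_TOL_CM,
) -> list[str]:
    """Subjects whose enrolled height is within ``tol_cm`` of the probe.

    Retains subjects with ``|enrolled - BH_norm| <= tol`` (inclusive
    boundary), preserving enrollment order.  May be empty, in which case
    the downstream decision is open-set rejection (NONE).
    """
    if tol_cm < 0:
        raise ValueError("tolerance must be nonnegative")
    return [
        subject
        for subject, height in enrolled_heights.items()
        if abs(float(height) - bh_norm_cm) <= tol_cm
    ]
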