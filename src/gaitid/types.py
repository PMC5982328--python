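"""Shared domain containers for the gait-identification pipeline.

The pipeline works on per-stride stance-phase ground reaction force (GRF)
recordings (three force components per limb, sampled at a fixed rate, body
weight known) and on skeleton frame logs captured by up to two depth
sensors.  The containers defined here are deliberately thin: plain NumPy
arrays and pandas frames with validated metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: GRF component names: anterior-posterior, vertical, medio-lateral.
COMPONENTS = ("fx", "fy", "fz")
LIMBS = ("L", "R")
#: Column order of :attr:`StrideRecord.forces`.
STRIDE_COLUMNS = ("fx_L", "fy_L", "fz_L", "fx_R", "fy_R", "fz_R")

SPORT = "sport"
HEELS = "heels"
FOOTWEAR_TYPES = (SPORT, HEELS)

TRACKING_STATES = ("fully_tracked", "inferred", "not_tracked")
SKELETON_COLUMNS = ("timestamp", "sensor_id", "joint_id", "x", "y", "z", "tracking_state")


@dataclass
class GRFSeries:
    """One force component of one limb over (part of) the stance phase."""

    samples: np.ndarray
    sampling_rate: float
    component: str
    limb: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("empty force series")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force series contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class StrideRecord:
    """One stride's stance-phase forces for both limbs.

    ``forces`` has shape ``(n_samples, 6)`` with columns ordered as
    :data:`STRIDE_COLUMNS`, in Newtons.  Both limbs share the same stance
    window so the whole stride lives on one time axis.
    """

    subject_id: str
    footwear: str
    body_weight_n: float
    sampling_rate: float
    forces: np.ndarray
    cycle_duration_s: float | None = None
    stance_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=np.float64)
        if self.forces.ndim != 2 or self.forces.shape[1] != len(STRIDE_COLUMNS):
            raise ValueError("forces must have shape (n_samples, 6)")
        if self.body_weight_n <= 0:
            raise ValueError("body weight must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.footwear not in FOOTWEAR_TYPES:
            raise ValueError(f"unknown footwear {self.footwear!r}")

    @property
    def n_samples(self) -> int:
        return int(self.forces.shape[0])

    def column(self, limb: str, component: str) -> np.ndarray:
        idx = STRIDE_COLUMNS.index(f"{component}_{limb}")
        return self.forces[:, idx]

    def series(self, limb: str, component: str, normalized: bool = False) -> GRFSeries:
        samples = self.column(limb, component)
        if normalized:
            samples = samples / self.body_weight_n
        return GRFSeries(samples, self.sampling_rate, component, limb)

    def normalized_forces(self) -> np.ndarray:
        """Forces as fraction of body weight, shape ``(n_samples, 6)``."""
        return self.forces / self.body_weight_n


@dataclass
class DistanceVector:
    """Fusion vector: four phase DTW distances, the whole-stride DTW
    distance, and the measured body height in cm."""

    rho_mst_l: float
    rho_tst_l: float
    rho_mst_r: float
    rho_tst_r: float
    rho_stride: float
    bh_cm: float

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rhos):
            raise ValueError("DTW distances must be nonnegative")
        if self.bh_cm <= 0:
            raise ValueError("body height must be positive")

    @property
    def rhos(self) -> tuple[float, float, float, float, float]:
        return (self.rho_mst_l, self.rho_tst_l, self.rho_mst_r, self.rho_tst_r, self.rho_stride)


@dataclass
class HeightRecord:
    """Body height estimated from a skeleton stream.

    ``footwear_y`` is the footwear classifier output (0 = sport shoes,
    1 = high heels); when set, :attr:`bh_norm_cm` applies the fixed
    footwear correction.
    """

    bh_measured_cm: float
    n_frames_used: int
    footwear_y: int | None = None

    def __post_init__(self) -> None:
        if self.bh_measured_cm <= 0:
            raise ValueError("measured height must be positive")
        if self.n_frames_used < 1:
            raise ValueError("at least one usable frame required")
        if self.footwear_y is not None and self.footwear_y not in (0, 1):
            raise ValueError("footwear_y must be 0 or 1")

    @property
    def bh_norm_cm(self) -> float:
        if self.footwear_y is None:
            raise ValueError("footwear_y is unset; cannot normalize height")
        from .anthropometry import normalize_height

        return normalize_height(self.bh_measured_cm, self.footwear_y)


@dataclass
class SkeletonFrameLog:
    """Timestamped joint positions with tracking states from up to two sensors.

    ``frames`` is a long-format table with columns :data:`SKELETON_COLUMNS`;
    positions are in meters.  Synthetic logs additionally carry diagnostic
    ground truth (``base_height_cm`` and the noise-free instantaneous height
    per timestamp in ``true_heights``), which file round-trips drop.
    """

    frames: pd.DataFrame
    subject_id: str | None = None
    footwear: str | None = None
    cycle_duration_s: float | None = None
    base_height_cm: float | None = None
    true_heights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SKELETON_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"skeleton log missing columns: {missing}")
        sensors = set(self.frames["sensor_id"].unique())
        if not sensors <= {1, 2}:
            raise ValueError(f"sensor_id must be 1 or 2, got {sorted(sensors)}")
        states = set(self.frames["tracking_state"].unique())
        unknown = states - set(TRACKING_STATES)
        if unknown:
            raise ValueError(f"unknown tracking_state values: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return int(self.frames["timestamp"].nunique())
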