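"""Synthetic gait generator: GRF strides and skeleton height streams.

No public dataset accompanies the method this package implements, so every
downstream stage is exercised on synthetic walks whose statistical structure
matches what the pipeline assumes about adult female gait:

* the vertical force Fy is double-peaked with maxima near 120% of body
  weight (weight acceptance and push-off) and a mid-stance minimum below
  body weight;
* the anterior-posterior force Fx is biphasic, braking then propulsive,
  with extremes near 20% of body weight and a zero crossing at mid stance;
* the medio-lateral force Fz plateaus near 10% of body weight, positive for
  the left limb and negative for the right;
* the stance occupies about 60% of the gait cycle;
* high heels raise all force extremes, shorten the stance, and sharpen the
  heel-strike transient (earlier loading peaks);
* the measured walking height exceeds the sport-shoe height by a heel delta
  distributed N(4.988, 0.7504^2) cm, and the head height oscillates within
  a cycle by a few centimeters (never more than 9.5 cm peak-to-trough).

Each force component is a shape-preserving piecewise-cubic (PCHIP) curve
through a small per-subject table of control points (timing as fraction of
stance, amplitude as fraction of body weight), so the printed extreme
magnitudes are exactly the perturbed control amplitudes.  Between-subject
variation perturbs the control table once per subject; within-subject noise
perturbs it again per stride, with strictly smaller scales, which is the
separability knob of the population.

All randomness flows from explicit integer seeds through per-purpose
``numpy`` substreams, so identical configurations reproduce identical
datasets bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .anthropometry import (
    ANKLE_LEFT,
    ANKLE_RIGHT,
    FOOT_LEFT,
    FOOT_RIGHT,
    HEAD,
    HEAD_TOP_OFFSET_CM,
    HIP_LEFT,
    HIP_RIGHT,
    KNEE_LEFT,
    KNEE_RIGHT,
    NECK,
    SPINE_BASE,
    SPINE_MID,
    SPINE_SHOULDER,
)
from .types import (
    COMPONENTS,
    FOOTWEAR_TYPES,
    HEELS,
    LIMBS,
    SPORT,
    SkeletonFrameLog,
    StrideRecord,
)

GRAVITY_M_S2 = 9.80665

#: Control-point template per component: (time as fraction of stance,
#: amplitude as fraction of body weight).  Extremes sit exactly on interior
#: knots because PCHIP is monotone between knots.
DEFAULT_SHAPE_TEMPLATE: dict[str, tuple[tuple[float, float], ...]] = {
    "fy": ((0.00, 0.00), (0.25, 1.20), (0.50, 0.75), (0.75, 1.20), (1.00, 0.00)),
    "fx": ((0.00, 0.00), (0.22, -0.20), (0.50, 0.00), (0.78, 0.20), (1.00, 0.00)),
    "fz": ((0.00, 0.00), (0.17, 0.10), (0.50, 0.10), (0.83, 0.10), (1.00, 0.00)),
}

# Vertical placement of the chain joints as fraction of (height - head-top
# offset); paired with a constant lateral offset per chain so that segment
# lengths reduce to vertical distances.
_JOINT_LAYOUT: dict[int, tuple[float, float]] = {
    SPINE_BASE: (0.45, 0.0),
    SPINE_MID: (0.65, 0.0),
    NECK: (0.85, 0.0),
    HEAD: (1.00, 0.0),
    SPINE_SHOULDER: (0.80, 0.0),
    HIP_LEFT: (0.45, -0.10),
    KNEE_LEFT: (0.25, -0.10),
    ANKLE_LEFT: (0.05, -0.10),
    FOOT_LEFT: (0.00, -0.10),
    HIP_RIGHT: (0.45, 0.10),
    KNEE_RIGHT: (0.25, 0.10),
    ANKLE_RIGHT: (0.05, 0.10),
    FOOT_RIGHT: (0.00, 0.10),
}

_SENSOR_DISTANCE_M = 2.5


@dataclass
class ShapeVariation:
    """Between-subject perturbation scales of the control-point table."""

    amplitude_sd: float = 0.06  # relative, multiplicative on knot amplitudes
    timing_sd: float = 0.015  # absolute, on knot times (fraction of stance)

    def __post_init__(self) -> None:
        if self.amplitude_sd < 0 or self.timing_sd < 0:
            raise ValueError("variation scales must be nonnegative")


@dataclass
class WithinStrideNoise:
    """Within-subject (stride-to-stride) perturbation scales."""

    amplitude_sd: float = 0.02
    timing_sd: float = 0.005
    cycle_sd: float = 0.02  # relative, on cycle duration
    stance_sd: float = 0.005  # absolute, on stance fraction

    def __post_init__(self) -> None:
        if min(self.amplitude_sd, self.timing_sd, self.cycle_sd, self.stance_sd) < 0:
            raise ValueError("noise scales must be nonnegative")


@dataclass
class SubjectParams:
    """Everything needed to synthesize one subject's walks."""

    subject_id: str
    body_weight_n: float
    true_height_sport_cm: float
    heel_delta_cm: float
    grf_shape: dict[tuple[str, str], np.ndarray]  # (limb, component) -> (5, 2)
    stance_fraction: float = 0.60
    cycle_duration_s: float = 1.05
    osc_peak_to_trough_cm: float = 4.0
    noise: WithinStrideNoise = field(default_factory=WithinStrideNoise)
    sensor_noise_sd_cm: float = 1.0
    dropout_prob: float = 0.02
    sampling_rate_hz: float = 960.0
    frame_rate_hz: float = 30.0
    heels_amp_scale: float = 1.10
    heels_stance_scale: float = 0.95
    heels_timing_scale: float = 0.90

    def __post_init__(self) -> None:
        if self.body_weight_n <= 0:
            raise ValueError("body weight must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance fraction must lie in (0, 1)")
        if self.heel_delta_cm <= 0:
            raise ValueError("heel delta must be positive")
        if self.true_height_sport_cm <= 0:
            raise ValueError("height must be positive")
        for key, knots in self.grf_shape.items():
            knots = np.asarray(knots, dtype=np.float64)
            if knots.shape != (5, 2) or not np.all(np.isfinite(knots)):
                raise ValueError(f"control table for {key} must be a finite (5, 2) array")
            self.grf_shape[key] = knots

    def walk_height_cm(self, footwear: str) -> float:
        """Noise-free walking height (cm) before within-cycle oscillation."""
        _check_footwear(footwear)
        return self.true_height_sport_cm + (self.heel_delta_cm if footwear == HEELS else 0.0)


@dataclass
class PopulationConfig:
    """Population-level generator parameters.

    Cohort anthropometrics default to an adult-female study group (body mass
    61.90 +/- 11.07 kg, height 166.41 +/- 5.74 cm); the heel delta defaults
    to mean 4.988 cm, sd 0.7504 cm for heel heights of 8-10 cm.
    """

    n_subjects: int = 10
    seed: int = 0
    between: ShapeVariation = field(default_factory=ShapeVariation)
    within: WithinStrideNoise = field(default_factory=WithinStrideNoise)
    heel_delta_mean_cm: float = 4.988
    heel_delta_sd_cm: float = 0.7504
    sensor_noise_sd_cm: float = 1.0
    dropout_prob: float = 0.02
    body_mass_mean_kg: float = 61.90
    body_mass_sd_kg: float = 11.07
    height_mean_cm: float = 166.41
    height_sd_cm: float = 5.74
    stance_fraction_mean: float = 0.60
    stance_fraction_sd: float = 0.01
    cycle_duration_mean_s: float = 1.05
    cycle_duration_sd_s: float = 0.05
    osc_ptp_mean_cm: float = 4.0
    osc_ptp_sd_cm: float = 0.8
    osc_ptp_max_cm: float = 9.5
    heels_amp_scale: float = 1.10
    heels_stance_scale: float = 0.95
    heels_timing_scale: float = 0.90
    sampling_rate_hz: float = 960.0
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if min(self.heel_delta_sd_cm, self.sensor_noise_sd_cm) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.osc_ptp_max_cm > 9.5:
            raise ValueError("within-cycle height oscillation is capped at 9.5 cm")


def _check_footwear(footwear: str) -> None:
    if footwear not in FOOTWEAR_TYPES:
        raise ValueError(f"unknown footwear {footwear!r}; expected one of {FOOTWEAR_TYPES}")


def _tnorm(rng: np.random.Generator, sd: float, size=None):
    """Normal draw clipped at +/- 3 sd (keeps knot ordering safe)."""
    if sd == 0:
        return 0.0 if size is None else np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size), -3.0 * sd, 3.0 * sd)


def _perturb_knots(
    knots: np.ndarray,
    rng: np.random.Generator,
    amplitude_sd: float,
    timing_sd: float,
) -> np.ndarray:
    """Perturb interior knots; boundaries stay pinned to zero force."""
    out = knots.copy()
    out[1:4, 0] += _tnorm(rng, timing_sd, 3)
    out[1:4, 1] *= 1.0 + _tnorm(rng, amplitude_sd, 3)
    return out


def sample_population(config: PopulationConfig) -> list[SubjectParams]:
    """Draw a deterministic population of synthetic subjects.

    Per-subject control tables are the shared template perturbed with the
    between-subject scales, independently per limb and component; the heel
    delta follows the configured normal law.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    subjects: list[SubjectParams] = []
    for i in range(config.n_subjects):
        mass = max(float(rng.normal(config.body_mass_mean_kg, config.body_mass_sd_kg)), 38.0)
        height = max(float(rng.normal(config.height_mean_cm, config.height_sd_cm)), 120.0)
        heel = max(float(rng.normal(config.heel_delta_mean_cm, config.heel_delta_sd_cm)), 0.1)
        stance = float(np.clip(rng.normal(config.stance_fraction_mean, config.stance_fraction_sd), 0.45, 0.75))
        cycle = max(float(rng.normal(config.cycle_duration_mean_s, config.cycle_duration_sd_s)), 0.6)
        osc = float(np.clip(rng.normal(config.osc_ptp_mean_cm, config.osc_ptp_sd_cm), 0.0, config.osc_ptp_max_cm))
        shape: dict[tuple[str, str], np.ndarray] = {}
        for limb in LIMBS:
            for comp in COMPONENTS:
                template = np.asarray(DEFAULT_SHAPE_TEMPLATE[comp], dtype=np.float64)
                if comp == "fz" and limb == "R":
                    template = template.copy()
                    template[:, 1] *= -1.0  # lateral force mirrors across limbs
                shape[(limb, comp)] = _perturb_knots(
                    template, rng, config.between.amplitude_sd, config.between.timing_sd
                )
        subjects.append(
            SubjectParams(
                subject_id=f"S{i + 1:03d}",
                body_weight_n=mass * GRAVITY_M_S2,
                true_height_sport_cm=height,
                heel_delta_cm=heel,
                grf_shape=shape,
                stance_fraction=stance,
                cycle_duration_s=cycle,
                osc_peak_to_trough_cm=osc,
                noise=replace(config.within),
                sensor_noise_sd_cm=config.sensor_noise_sd_cm,
                dropout_prob=config.dropout_prob,
                sampling_rate_hz=config.sampling_rate_hz,
                frame_rate_hz=config.frame_rate_hz,
                heels_amp_scale=config.heels_amp_scale,
                heels_stance_scale=config.heels_stance_scale,
                heels_timing_scale=config.heels_timing_scale,
            )
        )
    return subjects


def synth_grf_stride(
    subject: SubjectParams,
    footwear: str,
    stride_seed: int,
    sampling_rate_hz: float | None = None,
) -> StrideRecord:
    """Synthesize one stride's stance-phase forces for both limbs.

    The stance length follows the subject's cycle duration and stance
    fraction with stride-to-stride jitter; high heels scale the interior
    control amplitudes up, shorten the stance, and pull the loading peaks
    of Fx and Fy earlier (a sharper heel-strike transient).  Forces are
    PCHIP curves through the perturbed control points, evaluated on a
    uniform grid over the normalized stance, times body weight.
    """
    _check_footwear(footwear)
    rate = float(sampling_rate_hz if sampling_rate_hz is not None else subject.sampling_rate_hz)
    rng = np.random.default_rng(np.random.SeedSequence([int(stride_seed), 211]))
    noise = subject.noise

    cycle = subject.cycle_duration_s * (1.0 + float(_tnorm(rng, noise.cycle_sd)))
    stance_fraction = subject.stance_fraction + float(_tnorm(rng, noise.stance_sd))
    stance = stance_fraction * cycle
    if footwear == HEELS:
        stance *= subject.heels_stance_scale
    n = max(12, int(math.floor(stance * rate + 0.5)))
    grid = np.linspace(0.0, 1.0, n)

    forces = np.empty((n, 6), dtype=np.float64)
    for col, (limb, comp) in enumerate(
        (("L", "fx"), ("L", "fy"), ("L", "fz"), ("R", "fx"), ("R", "fy"), ("R", "fz"))
    ):
        knots = subject.grf_shape[(limb, comp)].copy()
        if footwear == HEELS:
            knots[1:4, 1] *= subject.heels_amp_scale
            if comp in ("fx", "fy"):
                knots[1, 0] *= subject.heels_timing_scale
        knots = _perturb_knots(knots, rng, noise.amplitude_sd, noise.timing_sd)
        if np.any(np.diff(knots[:, 0]) <= 0):  # pragma: no cover - defensive
            knots[:, 0] = np.sort(knots[:, 0])
        curve = PchipInterpolator(knots[:, 0], knots[:, 1])
        forces[:, col] = curve(grid) * subject.body_weight_n

    return StrideRecord(
        subject_id=subject.subject_id,
        footwear=footwear,
        body_weight_n=subject.body_weight_n,
        sampling_rate=rate,
        forces=forces,
        cycle_duration_s=cycle,
        stance_duration_s=stance,
    )


def synth_skeleton_stream(
    subject: SubjectParams,
    footwear: str,
    n_cycles: int,
    seed: int,
) -> SkeletonFrameLog:
    """Two-sensor skeleton frame log of a walk of ``n_cycles`` gait cycles.

    The instantaneous noise-free height is the walking height (sport height
    plus the heel delta when wearing heels) plus a sinusoidal within-cycle
    oscillation at stride frequency.  Each sensor observes that height with
    independent zero-mean noise; joint coordinates are laid out so that the
    anthropometric chain sum reproduces the observed height exactly when
    all joints are fully tracked.  Joints degrade to "inferred" with the
    configured dropout probability, independently per sensor.
    """
    _check_footwear(footwear)
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 307]))
    fps = subject.frame_rate_hz
    cycle = subject.cycle_duration_s
    n_frames = max(2, int(round(n_cycles * cycle * fps)))
    t = np.arange(n_frames) / fps
    base = subject.walk_height_cm(footwear)
    osc = 0.5 * subject.osc_peak_to_trough_cm * np.sin(2.0 * np.pi * t / cycle)
    true_heights = base + osc

    joint_ids = np.array(sorted(_JOINT_LAYOUT), dtype=np.int64)
    fracs = np.array([_JOINT_LAYOUT[j][0] for j in joint_ids])
    lateral = np.array([_JOINT_LAYOUT[j][1] for j in joint_ids])
    n_joints = joint_ids.size

    parts = []
    for sensor in (1, 2):
        noisy = true_heights + rng.normal(0.0, subject.sensor_noise_sd_cm, n_frames)
        chain_m = (noisy - HEAD_TOP_OFFSET_CM) / 100.0  # (n_frames,)
        y = np.outer(chain_m, fracs)  # (n_frames, n_joints)
        inferred = rng.random((n_frames, n_joints)) < subject.dropout_prob
        parts.append(
            pd.DataFrame(
                {
                    "timestamp": np.repeat(t, n_joints),
                    "sensor_id": sensor,
                    "joint_id": np.tile(joint_ids, n_frames),
                    "x": np.tile(lateral, n_frames),
                    "y": y.ravel(),
                    "z": _SENSOR_DISTANCE_M,
                    "tracking_state": np.where(inferred, "inferred", "fully_tracked").ravel(),
                }
            )
        )
    frames = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["timestamp", "sensor_id", "joint_id"], kind="stable")
        .reset_index(drop=True)
    )
    return SkeletonFrameLog(
        frames=frames,
        subject_id=subject.subject_id,
        footwear=footwear,
        cycle_duration_s=cycle,
        base_height_cm=base,
        true_heights=pd.DataFrame({"timestamp": t, "height_cm": true_heights}),
    )


@dataclass(frozen=True)
class FootwearPlan:
    """Which footwear types appear in the gallery and in the probe set."""

    gallery: tuple[str, ...]
    probe: tuple[str, ...]

    def __post_init__(self) -> None:
        for fw in (*self.gallery, *self.probe):
            _check_footwear(fw)
        if not self.gallery or not self.probe:
            raise ValueError("plan must name at least one gallery and one probe footwear")


#: Footwear plans of the five evaluation scenarios.  (a)/(c): sport-only
#: gallery and probes; (b)/(d)/(e): sport-only gallery, mixed probes.
SCENARIO_PLANS: dict[str, FootwearPlan] = {
    "a": FootwearPlan((SPORT,), (SPORT,)),
    "b": FootwearPlan((SPORT,), (SPORT, HEELS)),
    "c": FootwearPlan((SPORT,), (SPORT,)),
    "d": FootwearPlan((SPORT,), (SPORT, HEELS)),
    "e": FootwearPlan((SPORT,), (SPORT, HEELS)),
}


@dataclass
class GaitDataset:
    """Labeled gallery/probe stride collections with disjoint strides."""

    gallery: list[StrideRecord]
    probe: list[StrideRecord]


def build_dataset(
    population: Sequence[SubjectParams],
    per_subject_strides: int,
    plan: FootwearPlan,
    seed: int,
    sampling_rate_hz: float | None = None,
) -> GaitDataset:
    """Generate gallery and probe stride collections following a plan.

    Each subject contributes exactly ``per_subject_strides`` strides per
    footwear named anywhere in the plan.  Footwear present in both gallery
    and probe is split per subject: half the strides (rounded up) enroll,
    the rest probe, with a seeded shuffle; footwear present on one side
    only goes entirely to that side.  Gallery and probe strides are always
    disjoint.
    """
    if per_subject_strides < 1:
        raise ValueError("per_subject_strides must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 401]))
    gallery: list[StrideRecord] = []
    probe: list[StrideRecord] = []
    for subject in population:
        for fw in FOOTWEAR_TYPES:
            in_gallery = fw in plan.gallery
            in_probe = fw in plan.probe
            if not (in_gallery or in_probe):
                continue
            strides = [
                synth_grf_stride(subject, fw, int(rng.integers(2**31)), sampling_rate_hz)
                for _ in range(per_subject_strides)
            ]
            if in_gallery and in_probe:
                order = rng.permutation(per_subject_strides)
                n_enroll = math.ceil(per_subject_strides / 2)
                gallery.extend(strides[i] for i in sorted(order[:n_enroll]))
                probe.extend(strides[i] for i in sorted(order[n_enroll:]))
            elif in_gallery:
                gallery.extend(strides)
            else:
                probe.extend(strides)
    return GaitDataset(gallery=gallery, probe=probe)
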