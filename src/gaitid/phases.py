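"""Stance-phase segmentation into gait sub-phases.

The gait cycle is conventionally divided into a support (stance) phase of
roughly 60% of the cycle and a swing phase for the remainder.  The stance
itself decomposes into loading response (LR, 0-10% of cycle), mid stance
(MSt, 10-30%), terminal stance (TSt, 30-50%) and pre-swing (PSw, 50-60%).
A force plate records the stance only, so the cycle percentages are mapped
onto stance fractions assuming stance = 60% of the cycle, giving the
boundaries 0, 1/6, 1/2, 5/6 and 1 of the stance samples.

Windows are 0-based half-open index ranges; boundaries are placed at
``round(fraction * n)`` with ties rounded away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import GRFSeries

PHASES = ("LR", "MSt", "TSt", "PSw")

#: Stance-fraction boundaries of LR / MSt / TSt / PSw.
STANCE_BOUNDARIES = (0.0, 1.0 / 6.0, 1.0 / 2.0, 5.0 / 6.0, 1.0)

#: A stance needs at least two samples per sub-phase.
MIN_STANCE_SAMPLES = 12


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open sample window ``[start_index, end_index)`` of one sub-phase."""

    phase: str
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 0 <= self.start_index < self.end_index:
            raise ValueError("window indices must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end_index - self.start_index


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def segment_stance(n: int) -> list[PhaseWindow]:
    """Partition ``n`` stance samples into the four sub-phase windows.

    Parameters
    ----------
    n:
        Number of stance samples; must be at least
        :data:`MIN_STANCE_SAMPLES`.

    Returns
    -------
    list of :class:`PhaseWindow`
        LR, MSt, TSt, PSw windows that tile ``[0, n)`` exactly.
    """
    n = int(n)
    if n < MIN_STANCE_SAMPLES:
        raise ValueError(
            f"stance too short: {n} samples, need at least {MIN_STANCE_SAMPLES}"
        )
    bounds = [_round_half_away(f * n) for f in STANCE_BOUNDARIES]
    bounds[0], bounds[-1] = 0, n
    windows = [
        PhaseWindow(phase, bounds[i], bounds[i + 1]) for i, phase in enumerate(PHASES)
    ]
    return windows


def phase_window(n: int, phase: str) -> PhaseWindow:
    """The window of a single named sub-phase for an ``n``-sample stance."""
    for w in segment_stance(n):
        if w.phase == phase:
            return w
    raise ValueError(f"unknown phase {phase!r}")


def extract_phase(series: GRFSeries, window: PhaseWindow) -> GRFSeries:
    """Cut the contiguous sub-series covered by ``window``."""
    n = len(series)
    if window.end_index > n:
        raise ValueError(f"window [{window.start_index}, {window.end_index}) exceeds series length {n}")
    return GRFSeries(
        series.samples[window.start_index : window.end_index].copy(),
        series.sampling_rate,
        series.component,
        series.limb,
    )
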