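"""Open-set identification with an ensemble of five distance-based voters.

Each of the five stride distances (MSt left/right, TSt left/right, whole
stride) drives one k-nearest-neighbor base classifier over the enrolled
gallery strides.  A base classifier contributes rank-ordered weights
``w_R = (k + 1 - R) / k`` to the subject owning the stride at rank R; a
subject occupying several ranks in one base classifier accumulates all of
its ranks' weights.  The decided identity is the subject with the largest
total, unless the top totals tie or the winning total falls below the
rejection threshold Th, in which case the probe is labeled NONE (open-set
rejection).

Before voting, the gallery may be reduced to subjects whose enrolled
sport-shoe height lies within a tolerance of the probe's footwear-corrected
height (see :mod:`gaitid.anthropometry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .anthropometry import DEFAULT_HEIGHT_TOL_CM, normalize_height, reduce_gallery
from .dtw import profile_tensor
from .footwear import lr_poly_features, predict_footwear
from .types import StrideRecord

#: Totals within this margin of each other count as a tie.
TIE_EPS = 1e-9


@dataclass
class VoteConfig:
    """Ensemble voting parameters."""

    k: int = 5
    th: float = 0.0
    band: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.th < 0:
            raise ValueError("threshold must be nonnegative")


@dataclass
class VoteOutcome:
    """Per-class accumulated weights and the decided label (None = NONE)."""

    totals: dict[str, float]
    decided: str | None

    @property
    def winning_total(self) -> float:
        return max(self.totals.values()) if self.totals else 0.0

    @property
    def winner(self) -> str | None:
        """Top-total label regardless of ties/threshold (None if empty)."""
        if not self.totals:
            return None
        return max(self.totals, key=self.totals.get)


@dataclass
class Gallery:
    """Enrolled strides plus per-subject sport-shoe heights (cm)."""

    strides: list[StrideRecord]
    heights_cm: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [s.subject_id for s in self.strides]


def rank_weights(k: int) -> list[float]:
    """Rank-order weights ``w_R = (k + 1 - R) / k`` for R = 1..k."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return [(k + 1 - r) / k for r in range(1, k + 1)]


def base_votes(distances: Sequence[float], labels: Sequence[str], k: int) -> list[str]:
    """Labels of the k smallest distances, ascending.

    Distance ties break by enrollment order (stable sort).  When the
    gallery holds fewer than ``k`` strides, all labels are returned ranked.
    """
    distances = np.asarray(distances, dtype=np.float64)
    if distances.shape[0] != len(labels):
        raise ValueError("one label per distance required")
    order = np.argsort(distances, kind="stable")
    return [labels[i] for i in order[: min(k, len(labels))]]


def ensemble_decide(vote_lists: Sequence[Sequence[str]], config: VoteConfig) -> VoteOutcome:
    """Fuse the base classifiers' ranked votes into one decision.

    Returns NONE (``decided=None``) when the vote lists are empty, when at
    least two classes share the winning total, or when the winning total is
    smaller than the threshold Th.
    """
    weights = rank_weights(config.k)
    totals: dict[str, float] = {}
    for votes in vote_lists:
        for rank, label in enumerate(votes):
            totals[label] = totals.get(label, 0.0) + weights[rank]
    if not totals:
        return VoteOutcome(totals={}, decided=None)
    ranked = sorted(totals.items(), key=lambda kv: -kv[1])
    top_label, top_total = ranked[0]
    tied = len(ranked) > 1 and ranked[1][1] >= top_total - TIE_EPS
    if tied or top_total < config.th:
        return VoteOutcome(totals=totals, decided=None)
    return VoteOutcome(totals=totals, decided=top_label)


def decide_from_profile(
    profile: np.ndarray,
    labels: Sequence[str],
    config: VoteConfig,
) -> VoteOutcome:
    """Decision from a precomputed ``(n_gallery, 5)`` distance block."""
    profile = np.asarray(profile, dtype=np.float64)
    if profile.shape[0] == 0:
        return VoteOutcome(totals={}, decided=None)
    votes = [base_votes(profile[:, col], labels, config.k) for col in range(profile.shape[1])]
    return ensemble_decide(votes, config)


def identify(
    probe_stride: StrideRecord,
    gallery: Gallery,
    config: VoteConfig | None = None,
    bh_measured_cm: float | None = None,
    footwear_classifier=None,
    footwear_y: int | None = None,
    height_tol_cm: float = DEFAULT_HEIGHT_TOL_CM,
) -> VoteOutcome:
    """Identify the probe subject, optionally with height gating.

    When a measured body height is supplied, the footwear type is taken
    from ``footwear_y`` (if given) or predicted from the probe's
    loading-response features; the measured height is corrected
    accordingly, the gallery is reduced to height-compatible subjects, and
    the ensemble votes over the reduced gallery.  An empty reduced gallery
    yields NONE rather than an error.  Without a measured height, the vote
    runs over the full gallery (force-only identification).
    """
    config = config or VoteConfig()
    strides = gallery.strides
    labels = gallery.labels
    if bh_measured_cm is not None:
        if footwear_y is None:
            if footwear_classifier is None:
                raise ValueError("need footwear_y or a trained footwear classifier")
            footwear_y = int(predict_footwear(footwear_classifier, lr_poly_features(probe_stride))[0])
        bh_norm = normalize_height(bh_measured_cm, footwear_y)
        allowed = set(reduce_gallery(gallery.heights_cm, bh_norm, height_tol_cm))
        keep = [i for i, lab in enumerate(labels) if lab in allowed]
        strides = [strides[i] for i in keep]
        labels = [labels[i] for i in keep]
    if not strides:
        return VoteOutcome(totals={}, decided=None)
    tensor = profile_tensor([probe_stride], strides, band=config.band)
    return decide_from_profile(tensor[0], labels, config)
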