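"""Identification metrics and the five-scenario evaluation harness.

Open-set identification over enrolled probes is scored with three rates
that partition the probe set: CCR (decided label equals the true subject),
FRR (probe rejected as NONE) and FAR (probe accepted under a wrong
identity); the three always sum to 100%.  Footwear recognition is scored
with sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP), heels positive.

The harness reproduces the structure of the study scenarios on synthetic
populations:

``a``  sport-only gallery and probes, force distances only;
``b``  sport-only gallery, mixed probes, force distances only;
``c``  like (a) plus footwear identification and height gating;
``d``  like (b) plus footwear identification and height gating (the full
       two-stage pipeline);
``e``  like (d) with the footwear classifier replaced by the true label.

Per repetition, every subject's strides are freshly generated and split
(half enroll, rounded up; the rest probe); the footwear classifier is
trained on a disjoint set of strides of both footwear types, mirroring a
classifier built on a separate enrollment corpus.  The five DTW distances
are computed once per repetition for all probe/gallery pairs and shared
across scenarios and population sizes, which makes paired scenario
comparisons cheap and exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anthropometry import estimate_body_height, normalize_height
from .dtw import profile_tensor
from .footwear import footwear_dataset, lr_poly_features, predict_footwear, train_footwear
from .recognition import VoteConfig, VoteOutcome, decide_from_profile
from .synth import HEELS, SPORT, SubjectParams, synth_grf_stride, synth_skeleton_stream
from .types import StrideRecord

SCENARIOS = ("a", "b", "c", "d", "e")
_GATED = {"c", "d", "e"}
_SPORT_ONLY_PROBES = {"a", "c"}


@dataclass
class ConfusionCounts:
    """Binary confusion counts; heels strides are the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity in percent."""
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no positive examples")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no negative examples")
    sensitivity = 100.0 * counts.tp / (counts.tp + counts.fn)
    specificity = 100.0 * counts.tn / (counts.tn + counts.fp)
    return sensitivity, specificity


def identification_metrics(
    decisions: Iterable[tuple[str, str | None]],
) -> tuple[float, float, float]:
    """CCR, FRR and FAR in percent over enrolled probes.

    ``decisions`` yields ``(true_label, decided_label_or_None)`` pairs.
    The three rates partition the probes, so they sum to 100 exactly.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("no decisions to score")
    n = len(decisions)
    correct = sum(1 for true, dec in decisions if dec == true)
    rejected = sum(1 for _, dec in decisions if dec is None)
    wrong = n - correct - rejected
    return 100.0 * correct / n, 100.0 * rejected / n, 100.0 * wrong / n


def roc_curve(
    trials: Sequence[tuple[str, str | None, float]],
    thresholds: Sequence[float],
) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC from a rejection-threshold sweep.

    Each trial is ``(true_label, winner_label_or_None, winning_total)``;
    the winner is the top-total class before thresholding (``None`` when
    the vote was empty or tied, i.e. never accepted).  For each threshold
    Th a probe is accepted iff its winning total is at least Th; the point
    is (FAR fraction, CCR fraction).  The curve is anchored at (0, 0) and
    (1, 1) before integration.
    """
    thresholds = sorted(set(float(t) for t in thresholds))
    if len(thresholds) < 2:
        raise ValueError("need at least 2 distinct threshold values")
    if not trials:
        raise ValueError("no trials to score")
    n = len(trials)
    rows = []
    for th in thresholds:
        correct = wrong = 0
        for true, winner, total in trials:
            if winner is None or total < th:
                continue
            if winner == true:
                correct += 1
            else:
                wrong += 1
        rows.append({"th": th, "far": wrong / n, "ccr": correct / n})
    points = pd.DataFrame(rows)
    xy = {(0.0, 0.0), (1.0, 1.0)} | set(zip(points["far"], points["ccr"]))
    xy = sorted(xy)
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


@dataclass
class ScenarioConfig:
    """Problem sizes and options of the scenario harness.

    The harness samples strides at a reduced rate (the generator's curves
    are smooth, so alignment costs at 120 Hz preserve the ordering they
    would have at the plate's native rate while keeping the quadratic DTW
    cost manageable).
    """

    sampling_rate_hz: float = 120.0
    sport_strides: int = 6
    heels_strides: int = 4
    footwear_train_strides: int = 2
    height_cycles: int = 3
    vote: VoteConfig = field(default_factory=VoteConfig)
    height_tol_cm: float = 2.0
    classifier: str = "svm"


@dataclass
class _Repetition:
    gallery_labels: np.ndarray
    enrolled_heights: dict[str, float]
    probe_meta: pd.DataFrame  # subject, footwear, y_true, y_pred, bh_measured
    tensor: np.ndarray  # (n_probes, n_gallery, 5)


class ScenarioLab:
    """Shared engine behind :func:`run_scenario` and scenario comparisons."""

    def __init__(self, population: Sequence[SubjectParams], config: ScenarioConfig | None = None):
        if not population:
            raise ValueError("population must be non-empty")
        self.population = list(population)
        self.config = config or ScenarioConfig()

    def repetition(self, seed: int, rep: int) -> _Repetition:
        """Generate one repetition's strides, heights, classifier and
        distance tensor."""
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(rep), 601]))
        gallery: list[StrideRecord] = []
        probes: list[StrideRecord] = []
        train: list[StrideRecord] = []
        meta_rows = []
        enrolled_heights: dict[str, float] = {}
        heights: dict[tuple[str, str], float] = {}

        for subject in self.population:
            sid = subject.subject_id
            for fw in (SPORT, HEELS):
                train.extend(
                    synth_grf_stride(subject, fw, int(rng.integers(2**31)), cfg.sampling_rate_hz)
                    for _ in range(cfg.footwear_train_strides)
                )
            sport = [
                synth_grf_stride(subject, SPORT, int(rng.integers(2**31)), cfg.sampling_rate_hz)
                for _ in range(cfg.sport_strides)
            ]
            order = rng.permutation(cfg.sport_strides)
            n_enroll = math.ceil(cfg.sport_strides / 2)
            gallery.extend(sport[i] for i in order[:n_enroll])
            sport_probes = [sport[i] for i in order[n_enroll:]]
            heel_probes = [
                synth_grf_stride(subject, HEELS, int(rng.integers(2**31)), cfg.sampling_rate_hz)
                for _ in range(cfg.heels_strides)
            ]
            enroll_log = synth_skeleton_stream(subject, SPORT, cfg.height_cycles, int(rng.integers(2**31)))
            enrolled_heights[sid] = estimate_body_height(enroll_log).bh_measured_cm
            for fw in (SPORT, HEELS):
                walk = synth_skeleton_stream(subject, fw, cfg.height_cycles, int(rng.integers(2**31)))
                heights[(sid, fw)] = estimate_body_height(walk).bh_measured_cm
            for stride in (*sport_probes, *heel_probes):
                probes.append(stride)
                meta_rows.append(
                    {
                        "subject": sid,
                        "footwear": stride.footwear,
                        "y_true": 1 if stride.footwear == HEELS else 0,
                        "bh_measured": heights[(sid, stride.footwear)],
                    }
                )

        X_train, y_train, _ = footwear_dataset(train)
        clf = train_footwear(
            X_train, y_train, seed=int(rng.integers(2**31)), model=cfg.classifier
        )
        X_probe = np.vstack([lr_poly_features(p) for p in probes])
        y_pred = predict_footwear(clf, X_probe)

        meta = pd.DataFrame(meta_rows)
        meta["y_pred"] = y_pred
        tensor = profile_tensor(probes, gallery, band=cfg.vote.band)
        return _Repetition(
            gallery_labels=np.array([s.subject_id for s in gallery]),
            enrolled_heights=enrolled_heights,
            probe_meta=meta,
            tensor=tensor,
        )

    def decide(
        self,
        rep: _Repetition,
        scenario: str,
        subjects: Sequence[str],
    ) -> list[tuple[str, VoteOutcome]]:
        """Scenario decisions for every probe of the given subject subset."""
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        cfg = self.config
        subject_set = set(subjects)
        meta = rep.probe_meta
        probe_mask = meta["subject"].isin(subject_set).to_numpy()
        if scenario in _SPORT_ONLY_PROBES:
            probe_mask &= (meta["footwear"] == SPORT).to_numpy()
        gal_in_subset = np.isin(rep.gallery_labels, list(subject_set))
        results: list[tuple[str, VoteOutcome]] = []
        for p in np.flatnonzero(probe_mask):
            row = meta.iloc[p]
            gal_mask = gal_in_subset
            if scenario in _GATED:
                y = int(row["y_true"] if scenario == "e" else row["y_pred"])
                bh_norm = normalize_height(float(row["bh_measured"]), y)
                allowed = {
                    s
                    for s in subject_set
                    if abs(rep.enrolled_heights[s] - bh_norm) <= cfg.height_tol_cm
                }
                gal_mask = gal_in_subset & np.isin(rep.gallery_labels, list(allowed))
            outcome = decide_from_profile(
                rep.tensor[p][gal_mask], list(rep.gallery_labels[gal_mask]), cfg.vote
            )
            results.append((row["subject"], outcome))
        return results

    def evaluate(
        self,
        scenarios: Sequence[str],
        sizes: Sequence[int],
        repetitions: int = 10,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Per-(scenario, size, repetition) identification rates.

        Subject subsets are drawn per repetition and size (seeded) and
        shared across scenarios, so scenario comparisons are paired.
        """
        n_pop = len(self.population)
        if max(sizes) > n_pop:
            raise ValueError(f"requested subset of {max(sizes)} from {n_pop} subjects")
        all_ids = [s.subject_id for s in self.population]
        rows = []
        for r in range(repetitions):
            rep = self.repetition(seed, r)
            subset_rng = np.random.default_rng(np.random.SeedSequence([int(seed), r, 907]))
            for size in sizes:
                subset = list(subset_rng.choice(all_ids, size=size, replace=False))
                for scenario in scenarios:
                    decisions = [
                        (true, outcome.decided)
                        for true, outcome in self.decide(rep, scenario, subset)
                    ]
                    ccr, frr, far = identification_metrics(decisions)
                    rows.append(
                        {
                            "scenario": scenario,
                            "n_subjects": size,
                            "repetition": r,
                            "ccr": ccr,
                            "frr": frr,
                            "far": far,
                            "n_probes": len(decisions),
                        }
                    )
        return pd.DataFrame(rows)


def run_scenario(
    scenario: str,
    population: Sequence[SubjectParams],
    sizes: Sequence[int],
    repetitions: int = 10,
    seed: int = 0,
    config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Identification report for one scenario over population sizes.

    Returns one row per size with CCR/FRR/FAR averaged over the seeded
    repetitions, rounded to 2 decimals.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    lab = ScenarioLab(population, config)
    detail = lab.evaluate([scenario], sizes, repetitions=repetitions, seed=seed)
    report = (
        detail.groupby("n_subjects", as_index=False)[["ccr", "frr", "far"]]
        .mean()
        .round(2)
    )
    report.insert(0, "scenario", scenario)
    return report


def compare_scenarios(
    population: Sequence[SubjectParams],
    scenarios: Sequence[str],
    size: int,
    repetitions: int = 10,
    seed: int = 0,
    config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Paired scenario comparison at one population size (unrounded means)."""
    lab = ScenarioLab(population, config)
    detail = lab.evaluate(scenarios, [size], repetitions=repetitions, seed=seed)
    return detail.groupby("scenario", as_index=False)[["ccr", "frr", "far"]].mean()
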