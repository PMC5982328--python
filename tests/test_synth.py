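"""Generator tests: determinism, morphology and calibration."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import argrelmax

import gaitid
from gaitid import PopulationConfig, sample_population, synth_grf_stride, synth_skeleton_stream
from gaitid.synth import SCENARIO_PLANS, FootwearPlan, build_dataset
from gaitid.types import HEELS, SPORT


def _noise_free(config: PopulationConfig) -> PopulationConfig:
    from gaitid.synth import WithinStrideNoise

    return dataclasses.replace(
        config,
        within=WithinStrideNoise(0.0, 0.0, 0.0, 0.0),
        sensor_noise_sd_cm=0.0,
        dropout_prob=0.0,
    )


class TestSamplePopulation:
    def test_seeded_determinism(self):
        a = sample_population(PopulationConfig(n_subjects=4, seed=7))
        b = sample_population(PopulationConfig(n_subjects=4, seed=7))
        for sa, sb in zip(a, b):
            assert sa.body_weight_n == sb.body_weight_n
            assert sa.heel_delta_cm == sb.heel_delta_cm
            for key in sa.grf_shape:
                np.testing.assert_array_equal(sa.grf_shape[key], sb.grf_shape[key])

    def test_zero_between_variation_gives_identical_shapes(self):
        from gaitid.synth import ShapeVariation

        cfg = PopulationConfig(n_subjects=5, seed=3, between=ShapeVariation(0.0, 0.0))
        pop = sample_population(cfg)
        for key in pop[0].grf_shape:
            for s in pop[1:]:
                np.testing.assert_array_equal(s.grf_shape[key], pop[0].grf_shape[key])

    def test_heel_delta_law(self):
        pop = sample_population(PopulationConfig(n_subjects=10_000, seed=1))
        deltas = np.array([s.heel_delta_cm for s in pop])
        se = 0.7504 / np.sqrt(deltas.size)
        assert abs(deltas.mean() - 4.988) < 3 * se
        assert deltas.std(ddof=1) == pytest.approx(0.7504, rel=0.05)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_subjects=0)
        with pytest.raises(ValueError):
            PopulationConfig(dropout_prob=1.0)


class TestSynthGrfStride:
    def test_zero_noise_determinism(self, population):
        cfg = _noise_free(PopulationConfig(n_subjects=1, seed=5))
        subject = sample_population(cfg)[0]
        a = synth_grf_stride(subject, SPORT, 9)
        b = synth_grf_stride(subject, SPORT, 9)
        c = synth_grf_stride(subject, SPORT, 10)
        np.testing.assert_array_equal(a.forces, b.forces)
        np.testing.assert_array_equal(a.forces, c.forces)  # no within noise at all

    def test_vertical_component_morphology(self, sport_stride):
        fy = sport_stride.column("L", "fy") / sport_stride.body_weight_n
        peaks = argrelmax(fy)[0]
        assert len(peaks) == 2
        assert fy[peaks[0]] == pytest.approx(1.2, abs=0.25)
        assert fy[peaks[1]] == pytest.approx(1.2, abs=0.25)
        mid = fy[peaks[0] : peaks[1]].min()
        assert mid < 1.0  # unloading dips below body weight
        assert fy[0] == pytest.approx(0.0, abs=1e-9)
        assert fy[-1] == pytest.approx(0.0, abs=1e-9)

    def test_anterior_posterior_biphasic(self, sport_stride):
        fx = sport_stride.column("R", "fx") / sport_stride.body_weight_n
        n = len(fx)
        assert fx[: n // 3].min() < -0.1  # braking
        assert fx[2 * n // 3 :].max() > 0.1  # propulsion
        # one sign change in the interior
        interior = fx[n // 10 : -n // 10]
        assert np.sum(np.diff(np.sign(interior[interior != 0])) != 0) == 1

    def test_lateral_sign_convention(self, sport_stride):
        from gaitid.phases import phase_window

        w = phase_window(sport_stride.n_samples, "MSt")
        fz_l = sport_stride.column("L", "fz")[w.start_index : w.end_index]
        fz_r = sport_stride.column("R", "fz")[w.start_index : w.end_index]
        assert (fz_l > 0).all()
        assert (fz_r < 0).all()

    def test_heels_raise_extremes_and_shorten_stance(self, subject):
        sport = synth_grf_stride(subject, SPORT, 77)
        heels = synth_grf_stride(subject, HEELS, 77)
        assert heels.stance_duration_s < sport.stance_duration_s
        for limb in ("L", "R"):
            assert np.abs(heels.column(limb, "fy")).max() > np.abs(sport.column(limb, "fy")).max()
            assert np.abs(heels.column(limb, "fx")).max() > np.abs(sport.column(limb, "fx")).max()

    def test_unknown_footwear_rejected(self, subject):
        with pytest.raises(ValueError):
            synth_grf_stride(subject, "barefoot", 1)

    def test_calibration_batch(self):
        """200 default sport strides: Fy peaks ~120% BW, |Fx| ~20%, |Fz| ~10%."""
        pop = sample_population(PopulationConfig(n_subjects=20, seed=1))
        peaks, fx_ext, fz_mid = [], [], []
        rng = np.random.default_rng(1)
        for subject in pop:
            for _ in range(10):
                s = synth_grf_stride(subject, SPORT, int(rng.integers(2**31)))
                fy = s.column("L", "fy") / s.body_weight_n
                peaks.append(fy[argrelmax(fy)[0][0]])
                fx_ext.append(np.abs(s.column("L", "fx")).max() / s.body_weight_n)
                fz_mid.append(abs(s.column("L", "fz")[s.n_samples // 2]) / s.body_weight_n)
        assert np.mean(peaks) * 100 == pytest.approx(120.0, abs=5.0)
        assert np.mean(fx_ext) * 100 == pytest.approx(20.0, abs=3.0)
        assert np.mean(fz_mid) * 100 == pytest.approx(10.0, abs=3.0)

    def test_stance_fraction_calibration(self):
        pop = sample_population(PopulationConfig(n_subjects=20, seed=2))
        rng = np.random.default_rng(2)
        fractions = [
            s.stance_duration_s / s.cycle_duration_s
            for subject in pop
            for s in [synth_grf_stride(subject, SPORT, int(rng.integers(2**31)))]
        ]
        assert np.mean(fractions) * 100 == pytest.approx(60.0, abs=2.0)


class TestSkeletonStream:
    def test_noise_free_chain_equals_true_height(self):
        cfg = _noise_free(PopulationConfig(n_subjects=1, seed=9, osc_ptp_mean_cm=0.0, osc_ptp_sd_cm=0.0))
        subject = sample_population(cfg)[0]
        log = synth_skeleton_stream(subject, SPORT, 2, 3)
        rec = gaitid.estimate_body_height(log)
        assert rec.bh_measured_cm == pytest.approx(subject.true_height_sport_cm, abs=1e-9)

    def test_heel_delta_is_additive(self):
        cfg = _noise_free(PopulationConfig(n_subjects=1, seed=9, osc_ptp_mean_cm=0.0, osc_ptp_sd_cm=0.0))
        subject = sample_population(cfg)[0]
        sport = gaitid.estimate_body_height(synth_skeleton_stream(subject, SPORT, 2, 3))
        heels = gaitid.estimate_body_height(synth_skeleton_stream(subject, HEELS, 2, 3))
        assert heels.bh_measured_cm - sport.bh_measured_cm == pytest.approx(
            subject.heel_delta_cm, abs=1e-9
        )

    def test_oscillation_peak_to_trough_bounded(self):
        pop = sample_population(PopulationConfig(n_subjects=30, seed=13))
        worst = 0.0
        for subject in pop:
            log = synth_skeleton_stream(subject, SPORT, 5, 17)
            osc = log.true_heights["height_cm"].to_numpy() - log.base_height_cm
            t = log.true_heights["timestamp"].to_numpy()
            cycles = (t // log.cycle_duration_s).astype(int)
            for c in np.unique(cycles):
                chunk = osc[cycles == c]
                worst = max(worst, chunk.max() - chunk.min())
        assert worst <= 9.5

    def test_requires_positive_cycles(self, subject):
        with pytest.raises(ValueError):
            synth_skeleton_stream(subject, SPORT, 0, 1)


class TestBuildDataset:
    def test_sport_only_plan_has_no_heels(self, population):
        ds = build_dataset(population[:4], 6, SCENARIO_PLANS["a"], seed=5)
        assert all(s.footwear == SPORT for s in ds.gallery + ds.probe)
        assert len(ds.gallery) == 4 * 3  # half of 6, rounded up
        assert len(ds.probe) == 4 * 3

    def test_mixed_plan_keeps_heels_out_of_gallery(self, population):
        ds = build_dataset(population[:4], 5, SCENARIO_PLANS["b"], seed=5)
        assert all(s.footwear == SPORT for s in ds.gallery)
        assert any(s.footwear == HEELS for s in ds.probe)
        # 5 sport strides: 3 enroll + 2 probe; 5 heels strides all probe
        assert len(ds.gallery) == 4 * 3
        assert len(ds.probe) == 4 * (2 + 5)

    def test_stride_count_bookkeeping(self, population):
        ds = build_dataset(population[:2], 14, SCENARIO_PLANS["b"], seed=1)
        per_subject = {}
        for s in ds.gallery + ds.probe:
            per_subject.setdefault((s.subject_id, s.footwear), 0)
            per_subject[(s.subject_id, s.footwear)] += 1
        assert set(per_subject.values()) == {14}

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            FootwearPlan(gallery=("sport",), probe=("flipflops",))
        with pytest.raises(ValueError):
            FootwearPlan(gallery=(), probe=("sport",))
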