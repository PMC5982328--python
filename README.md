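# gaitid

Footwear-aware human gait identification from ground reaction forces and
body height.

Gait is a usable biometric — but it degrades badly when people change
shoes, and the worst case is women switching between sport shoes and high
heels, which alters both the ground reaction forces (GRF) and the apparent
body height. `gaitid` implements a two-stage pipeline that fuses
force-plate stride recordings with depth-sensor skeleton measurements to
keep identification accurate across footwear changes:

1. **Footwear recognition.** The loading-response (LR) portions of the
   vertical and anterior–posterior GRF of both limbs are each summarized
   by the six least-squares coefficients of a degree-5 polynomial
   (24 features per stride) and classified as sport shoes (*y* = 0) or
   high heels (*y* = 1) with an SVM.
2. **Height-gated ensemble identification.** The body height *BH* is
   estimated by summing skeleton segment lengths along a fixed joint
   chain, averaged over the frames of a walk and over two sensors, with
   tracking-state fallbacks. Heels inflate the measurement by a roughly
   constant offset, so the corrected height is
   `BH_norm = BH_measured − 5·y` (cm). The enrolled gallery is reduced to
   subjects whose sport-shoe height is within ±2 cm of `BH_norm`. Five
   stride dissimilarities are then computed by dynamic time warping (DTW):

   `ρ_{v,s} = Σ_m DTW_m` over the M = 3 force components for phase
   *v* ∈ {MSt, TSt} and limb *s* ∈ {L, R}, plus the whole-stride distance
   (M = 6). Each distance drives a k-nearest-neighbor voter (k = 5) over
   the reduced gallery; a neighbor at rank *R* contributes weight
   `w_R = (k + 1 − R)/k` to its subject. The identity with the largest
   total wins unless the top totals tie or fall below a rejection
   threshold *Th*, in which case the answer is **NONE** (open-set
   rejection).

Because no stride/skeleton corpus is publicly released for this problem,
the package ships a seeded synthetic gait generator
(`gaitid.sample_population`, `gaitid.synth_grf_stride`,
`gaitid.synth_skeleton_stream`) that emulates the documented gait
structure: double-peaked vertical GRF near 120 % of body weight, biphasic
anterior–posterior GRF near 20 %, lateral GRF near 10 % (positive left,
negative right), stance ≈ 60 % of the gait cycle, a heel-height effect of
4.988 ± 0.7504 cm, and a within-cycle head-height oscillation bounded by
9.5 cm. Every downstream stage is tested against this generator.

## Worked example

```python
import gaitid

population = gaitid.sample_population(gaitid.PopulationConfig(n_subjects=10, seed=1))
subject = population[0]

gallery = gaitid.Gallery(
    strides=[gaitid.synth_grf_stride(s, "sport", 100 + 10 * i + j, 240.0)
             for i, s in enumerate(population) for j in range(3)],
    heights_cm={s.subject_id: s.true_height_sport_cm for s in population},
)
probe = gaitid.synth_grf_stride(subject, "sport", 999, 240.0)
outcome = gaitid.identify(probe, gallery,
                          bh_measured_cm=subject.true_height_sport_cm, footwear_y=0)
print("decided:", outcome.decided)
print("totals:", {k: round(v, 2) for k, v in sorted(outcome.totals.items())})
```

prints

```
decided: S001
totals: {'S001': 11.0, 'S002': 0.2, 'S005': 0.6, 'S006': 1.2, 'S007': 2.0}
```

The probe is decided as `S001`: out of the 5 × 3 = 15 rank weights the
five voters distribute, 11.0 accumulate on the true subject, far ahead of
every height-compatible competitor. Evaluation scenarios reproduce the
harder settings — `b` enrolls sport-shoe gait only and probes with mixed
footwear using forces alone, while `d` adds footwear recognition and
height gating (the full pipeline):

```python
for scenario in ("b", "d"):
    print(gaitid.run_scenario(scenario, population, sizes=[10], repetitions=3, seed=1))
```

```
scenario  n_subjects  ccr  frr   far
       b          10 61.9 4.29 33.81
scenario  n_subjects   ccr  frr   far
       d          10 70.95  0.0 29.05
```

CCR/FRR/FAR are the percentages of probes identified correctly, rejected
as NONE, and accepted under a wrong identity; they always sum to 100.
Height gating (scenario d) recovers a substantial part of the accuracy
that footwear change costs the force-only system (scenario b).

The same pipeline is scriptable from the shell:

```sh
gaitid simulate --subjects 10 --seed 1 --out data/
gaitid train-footwear --data data/strides --out clf.joblib
gaitid enroll --data data/ --out gallery/
gaitid identify --gallery gallery/ --probe data/strides/S001_sport_000.csv
gaitid evaluate --scenario d --subjects 10 --repetitions 3 --seed 1
```

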