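# Methods

This note documents the models, conventions and numerical choices behind
`gaitid`, in the order data flows through the pipeline.

## Gait-cycle model and phase segmentation

The gait cycle runs heel strike to heel strike of the same limb. The
support (stance) phase occupies about 60 % of the cycle and decomposes
into loading response (0–10 % of cycle), mid stance (10–30 %), terminal
stance (30–50 %) and pre-swing (50–60 %). A force plate records stance
only, so cycle percentages are mapped onto stance fractions under the
nominal stance = 60 % assumption, giving boundaries at 0, 1/6, 1/2, 5/6
and 1 of the stance samples. Whether per-subject measured stance ratios
would be preferable is an open question; the nominal value is adopted
because the plate gives no access to the swing phase. Boundaries are
placed at `round(fraction · n)` with ties rounded away from zero;
windows are 0-based half-open and always tile `[0, n)` exactly. A stance
must contain at least 12 samples (two per sub-phase).

## DTW dissimilarity

Strides differ in length, so similarity is measured by classic dynamic
time warping with local cost `|a_i − b_j|` (L1), the symmetric
unit-weight step set {(1,0), (0,1), (1,1)}, anchored endpoints and no
window by default (an optional Sakoe–Chiba band is exposed but unused by
the defaults — stance series are short enough for exact alignment). The
accumulated cost is **not** normalized by path length: the per-phase
distance is a plain sum of the three per-component costs, and the
whole-stride distance a plain sum over six component/limb series, each
aligned independently (no multivariate joint alignment). Forces are
normalized to fraction of body weight before alignment so heavier
subjects do not dominate the cost. DTW here is a dissimilarity, not a
metric: nonnegative, symmetric, zero iff the aligned series are equal,
but without the triangle inequality. The dynamic program is verified in
the test suite against exhaustive enumeration of all monotone warping
paths for short series.

## Footwear recognition

Heel geometry changes the loading response most, so each stride is
summarized by least-squares degree-5 polynomial fits to the LR window of
the vertical and anterior–posterior components of both limbs. Time is
rescaled to [0, 1] before fitting (coefficients comparable across stance
durations); forces are in fraction of body weight (features invariant to
body weight); coefficients are ordered by descending degree in the block
order (x, L), (x, R), (y, L), (y, R), giving 24 features. Degree 5
balances curve fidelity against input-space size; an LR window shorter
than 6 samples is rejected as underdetermined.

The default classifier is an RBF-kernel soft-margin SVM (C = 10,
`gamma="scale"`) on standardized features; a city-block 3-NN alternative
is selectable. The SVM hyperparameters are package defaults, not claimed
to match any external system. Training rows are canonically sorted
before fitting so predictions are invariant to row order.
Cross-validation is grouped by subject — strides of one person never
span folds — because within-subject correlation would otherwise leak
identity into the footwear estimate. High heels are the positive class
for sensitivity/specificity.

## Body height from skeletons

Height is the sum of segment lengths along head → neck → spine shoulder
→ spine mid → spine base, plus the mean of the two hip → knee → ankle →
foot chains, plus a 12 cm head-top offset (the head joint is not the
skull vertex; the generator and the estimator share the constant so
noise-free round trips are exact). The exact joint chain of the original
acquisition setup is only documented graphically; this chain is a
reconstruction and is stated as such. A segment counts only when both
endpoint joints are fully tracked. A failed leg segment is replaced
segment-wise by the contralateral segment; segments available from both
sensors are averaged, from one sensor taken as-is. Frames with an
unresolvable segment are skipped and counted. The per-walk estimate is
the mean over usable frames; walks should span at least two gait cycles
so the within-cycle height oscillation averages out.

Heels raise the measured height by a nearly constant offset, so the
correction `BH_norm = BH_measured − 5·y` cm is applied before gating
(5 cm is the rounded mean heel effect). The gallery gate keeps subjects
with `|enrolled − BH_norm| ≤ 2` cm; the boundary is inclusive because
only subjects differing by *more* than 2 cm are excluded. Enrolled
heights are sport-shoe walk estimates, since galleries are built from
sport-shoe sessions in the footwear-change scenarios.

## Ensemble voting and open-set rejection

Neighbors are individual enrolled strides; the class is the subject.
Each of the five distances drives one kNN voter with k = 5 by default;
with a reduced gallery smaller than k, all its strides are ranked. Rank
weights are `w_R = (k + 1 − R)/k`, so each voter distributes exactly
`(k + 1)/2` total weight. A subject occupying several ranks within one
voter accumulates all of those ranks' weights (the alternative reading —
only a class's best rank counts — was considered and rejected because
every neighbor, not every class, carries a decision). Distance ties
break by enrollment order (stable sort). The decision is the largest
total unless at least two classes tie (within 1e-9, totals being sums of
k-denominator fractions) or the winning total is below Th, in which case
the probe is rejected as NONE. Th = 0 by default — the most liberal
strategy; sweeping Th produces the ROC (FAR vs CCR fractions, anchored
at (0,0) and (1,1), trapezoidal AUC).

## Synthetic data generator

**What it emulates.** Each force component is a shape-preserving
piecewise cubic (PCHIP) through five control points (time as fraction of
stance, amplitude as fraction of body weight). PCHIP is monotone between
knots, so the curve's extremes are exactly the control amplitudes — the
calibration targets are honored by construction, not by fitting.
Defaults: Fy peaks 1.20 BW at 0.25/0.75 of stance with a 0.75 BW trough
at 0.50; Fx −0.20 BW at 0.22 (braking, just before the first Fy peak)
and +0.20 BW at 0.78 (propulsion, just after the second), zero crossing
at 0.50; Fz plateau 0.10 BW (positive left, negative right). Contact
boundaries are pinned to zero force.

Cohort anthropometrics default to an adult-female study group: body mass
61.90 ± 11.07 kg, height 166.41 ± 5.74 cm, cycle duration 1.05 ± 0.05 s,
stance fraction 0.60 ± 0.01, heel delta N(4.988, 0.7504²) cm. The native
sampling rate is 960 Hz, skeleton frame rate 30 Hz.

**Separability.** Between-subject variation multiplies interior control
amplitudes by `1 + N(0, 0.06)` and shifts interior knot times by
N(0, 0.015), independently per limb and component; within-subject noise
repeats this per stride with sd 0.02 / 0.005 plus cycle-duration
(relative sd 0.02) and stance-fraction (sd 0.005) jitter. All normal
perturbations are clipped at ±3 sd to keep knots ordered. No published
within- vs between-subject GRF variance exists for this setting, so the
ratio is a free knob; evaluation therefore asserts orderings between
scenarios, never absolute rates.

**Heels effect.** Wearing heels multiplies interior control amplitudes
by 1.10 (all components), stance duration by 0.95, and the time of the
first interior knot of Fx and Fy by 0.90. The timing term models the
sharper heel-strike transient of a rigid high heel. It also matters for
identifiability of the footwear itself: a purely multiplicative
amplitude change of 10 % against 6 % between-subject amplitude sd would
leave footwear classification of unseen subjects close to chance,
whereas real heels gait differs in shape, not just scale; the earlier
loading peak supplies that shape difference and brings subject-disjoint
footwear accuracy into the mid-90 % range that force-based footwear
classifiers achieve in practice.

**Skeleton streams.** The noise-free instantaneous height is the walking
height (sport height, plus the heel delta when in heels) plus a sinusoid
at stride frequency with per-subject peak-to-trough N(4.0, 0.8) cm
clipped to [0, 9.5] cm. Each sensor observes it with independent
N(0, 1 cm) noise per frame; joints lie on per-chain vertical lines with
fixed proportions so the chain sum reproduces the observed height
exactly; each joint independently degrades to "inferred" with
probability 0.02 per sensor per frame.

**What it does not emulate.** No musculoskeletal dynamics, no
ground-contact events (strides arrive pre-cut), no gait maturation or
session-to-session drift, no correlated sensor failures, no
heel-height-dependent heel delta, no depth-image artifacts. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the assumed statistical structure — not field performance on real
recordings.

## Evaluation harness

Scenarios: (a) sport-only gallery and probes, forces only; (b) sport
gallery, mixed probes, forces only; (c) = (a) plus footwear recognition
and height gating; (d) = (b) plus both (the full pipeline); (e) = (d)
with the true footwear label substituted for the classifier. Per
repetition each subject contributes 6 sport strides (half enroll,
rounded up) and 4 heels probes; the footwear classifier trains on a
disjoint set of 2 strides per footwear per subject, mirroring a model
built on a separate corpus; heights come from 3-cycle walks. The five
distances are computed once per repetition for all probe/gallery pairs
and sliced per scenario and subject subset, so scenario comparisons are
paired. Subject subsets are drawn per repetition and size, shared across
scenarios. CCR/FRR/FAR are computed over enrolled probes (closed cohort
plus NONE, so the three sum to 100); an impostor mode is not reported
because the default cohorts contain no unenrolled probes. Reports round
to 2 decimals.

The harness samples strides at 120 Hz rather than the generator's native
960 Hz: the synthetic curves are smooth PCHIP splines, so alignment
costs at 120 Hz preserve the neighbor ordering while DTW's quadratic
cost stays proportionate to the study sizes used (50 subjects,
10 repetitions for the ordering checks). On those defaults the observed
orderings are: scenario (a) CCR > 95 %, (d) well above (b), and
(e) ≥ (d); absolute synthetic rates are not comparable to real-data
rates and are not asserted.

## Numerical conventions and degenerate inputs

All randomness derives from explicit integer seeds via
`numpy.random.SeedSequence` substreams; identical configuration and
seeds reproduce outputs bit for bit. Empty reduced galleries yield NONE,
not an error. Vote-total ties compare within 1e-9. Stride CSV files
must have a uniform time step (relative tolerance 1e-6) and positive
body weight; skeleton CSVs with out-of-order timestamps are sorted with
a warning; unknown tracking states, sensor ids outside {1, 2}, missing
columns and empty files are errors that name the fault.
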