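# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `surgilearn`.

## Study design emulated

The pipeline targets a training study in which participants at four
skill levels (pre-medical student, resident, fellow, faculty) perform
laparoscopic and robot-assisted tasks five times each while wearing a
124-channel EEG headset sampled at 500 Hz and eye-tracking glasses
sampled at 50 Hz. Performance on each attempt is scored on a structured
rubric: GOALS (5 domains × 1–5, total 5–25) for the peg-transfer and
pattern-cut tasks, OSAT (8 domains × 1–5, total 8–40) for suturing, and
GEARS (6 domains × 1–5, total 6–30) for the robotic tasks. The learning
rate is the OLS slope of a participant's scores on the 1-based attempt
index.

## Gaze features

Gaze directions are stored as horizontal/vertical visual angles in
degrees; angular velocity between consecutive valid samples is the
Euclidean angular displacement divided by the time step, so the I-VT
threshold applies in °/s. Choices the underlying measurement chain
leaves open, and how they are resolved here:

- **Smoothing**: 3-point centered moving average with truncated edge
  windows, applied to gaze and pupil series before everything else.
- **I-VT boundary**: a velocity exactly at 30 °/s is a saccade
  (below-threshold defines fixation). A relative tolerance of 1e-9
  keeps this stable under float rounding of time steps.
- **Pupil entropy** is not a standard quantity; it is computed as the
  Shannon entropy (base 2) of a 16-equal-width-bin histogram spanning
  [min, max] of the smoothed series. A constant series has entropy 0.
  The bin count is a parameter.
- **Fixation/saccade rates** are dimensionless fractions of classified
  samples (they sum to 1), not events per second.
- **Direction-change rate** counts sign reversals of consecutive
  nonzero displacements along one axis, divided by elapsed time; zero
  displacements are skipped so a pause does not reset the direction.
- **Trajectory length** is the summed Euclidean displacement of the
  smoothed gaze trace, in degrees, per eye.
- **Validity**: invalid samples are excluded everywhere; a recording
  with under 50% valid samples triggers a warning.
- Classification runs on the dominant eye; per-eye statistics are
  reported for the dominant and nondominant eye (ocular dominance, not
  left/right, is the meaningful axis for skill analysis).

## EEG network features

The artifact-decontamination chain used on real recordings is out of
scope; preprocessing here is a zero-phase 4th-order Butterworth
band-pass (default 4–30 Hz) followed by per-channel z-scoring with a
variance floor of 1e-12 (flat channels come out identically zero).

Connectivity layers are absolute Pearson correlations over
non-overlapping windows (default 2 s), diagonal zeroed, one symmetric
matrix in [0,1] per window. The connectivity estimator, band, and
windowing are configurable; they are reasonable defaults, not an
assertion about any particular study's unpublished settings.

**Multilayer modularity.** The quality function couples temporally
adjacent layers with a uniform ω (ordinal coupling — the standard
choice for temporal networks) and uses the Newman–Girvan null model per
layer with resolution γ = 1. The optimizer is a generalized-Louvain
heuristic: starting from singleton node-layer communities, randomized
sweeps of single node-layer moves (ties broken toward the lowest
community index) alternate with greedy community merges until the
partition is stable. An ensemble of seeded restarts (default 100 for
standalone extraction; 20 in the study generator, 8 in the compact
pipeline profile) gives the partitions from which flexibility and the
allegiance matrix are computed. Zero-noise planted bipartitions are
recovered exactly (verified in tests).

**Search information** is computed per layer as
SI(i→j) = −log₂ Π w_uv/s_u along the shortest path on edge lengths 1/w.
Implementation: all-pairs Dijkstra distances (scipy), then a
lexicographic next-hop matrix (the smallest-index neighbor consistent
with the distances, which reconstructs the lexicographically smallest
shortest path — a deterministic tie-break) and per-target dynamic
programming to accumulate the step costs. This is algebraically
identical to the per-pair path product and is verified against
exhaustive path enumeration on small graphs. Unreachable pairs get +∞
and are excluded from averages.

**Cortex averaging.** Strength and SI are computed per layer, averaged
over layers, then over each cortex's channels; SI is averaged over
ordered pairs with the source in the cortex and any other node as
target (the within-cortex-only alternative is available). Flexibility,
recruitment, and integration are averaged per cortex from the ensemble.
Channel→cortex assignment uses 10-5 label prefixes (Fp/AF/F/FC →
frontal, FT/TP/T → temporal, CP/P → parietal, PO/O → occipital; central
C channels unassigned) and is fully user-overridable via a channel-map
CSV.

## Performance models (GLMM-LASSO)

The model is y = β₀ + Xβ + Zb + ε with b ~ N(0, τ²) per participant and
ε ~ N(0, σ²). The objective is the penalized marginal log-likelihood
−ℓ(β, τ², σ²) + λ‖β‖₁ (intercept unpenalized), minimized by
alternating:

1. coordinate-wise soft-thresholding of β on the GLS-whitened design
   (the random-intercept structure admits a closed-form V^{-1/2} per
   group), and
2. exact ML variance-component updates: σ² is profiled out in closed
   form and the ratio ρ = τ²/σ² maximized in 1-D. (EM was rejected: it
   stalls geometrically near the τ² → 0 boundary.)

Convergence is declared when the penalized objective changes by less
than 1e-8 relative. Features are standardized (ddof = 1) before
fitting so the penalty treats them symmetrically; coefficients are
reported on the standardized scale.

λ is selected on a 20-point geometric grid from the full-shrinkage
point λ_max = max_j |X_jᵀ(y − ȳ)| down to λ_max/1000, traversed with
warm starts; the minimum-BIC fit wins, ties toward the larger (sparser)
penalty. BIC = −2ℓ + k·log n with k = |support| + 2 (intercept and τ²);
the degrees-of-freedom convention is configurable. The winning support
is refit unpenalized with statsmodels `MixedLM` (REML) for Wald SEs and
p-values; exactly collinear selected pairs (e.g. the fixation rate and
its complement, which the L1 fit tolerates) are reduced to a maximal
independent subset for the refit, with a warning. These are naive
post-selection quantities — no selective-inference correction — which
matches how such tables are usually reported but overstates certainty;
a stated limitation.

## Learning-rate models (forward selection + LOOCV)

Candidates are the first-attempt features plus the baseline
(first-attempt) score, standardized; rows are screened with LOF
(k = 10, exclusion threshold 1.5 — the threshold is a package choice,
configurable). From the intercept-only model, each step adds the
candidate with the lowest leave-one-out RMSE (computed exactly via the
hat-matrix identity) among those that (a) improve the current LOOCV
RMSE and (b) pass a partial F-test at α = 0.01. The F-to-enter gate is
essential: the minimum LOOCV error over ~36 candidates keeps improving
by chance on pure noise, so an improvement-only rule selects ~10
spurious predictors at n = 25. With the gate, pure-noise supports stay
empty or near-empty while planted 3-predictor models are still
recovered in the large majority of runs (rates recomputed by
`scripts/acceptance.py`). The gate can be disabled
(`enter_alpha=None`) for the improvement-only behavior.

LOF itself is delegated to scikit-learn and cross-checked in the tests
against a direct implementation of the k-distance/reachability formula;
the two agree to ~1e-10 on tie-free data (with exact duplicate rows the
textbook neighbor set is ambiguous and conventions differ).

## Skill-level comparison

Score ~ level (fixed, treatment-coded in the canonical order) with a
participant random intercept, REML via statsmodels. The omnibus test is
a Wald F on the level effects with containment denominator df
= n_participants − n_levels — the skill factor is between-participant,
so this equals the Satterthwaite value in the balanced design and keeps
the test calibrated (type-I error ≈ 0.05 over 500 null replicates,
recomputed by the acceptance script). LSMs are the model-based marginal
means; pairwise contrasts use the studentized-range (Tukey HSD)
adjustment by default, with unadjusted Wald p-values as an option since
the adjustment convention in published tables of this kind is often
unstated. A zero-variance response yields a flagged degenerate result
rather than a crash.

## Synthetic-data generator

The generator is first-class code: it defines the conditions under
which every downstream guarantee is tested.

- **Cohort**: default 25 participants in an 11/2/6/6
  pre-med/resident/fellow/faculty mix, five attempts. Experience
  covariates are sampled uniformly from per-level ranges (pre-medical
  students exactly zero in all four covariates; faculty the widest
  ranges, e.g. up to 1000 h of RAS experience and 250 laparoscopic
  cases). The ranges are plausible approximations to a real training
  cohort, not measured quantities.
- **Gaze**: alternating fixation (0.2–0.5 s, speed 2–10 °/s, random
  walk) and saccade (0.04–0.1 s, speed 90–300 °/s, consistent
  direction) segments; reflection keeps gaze within ±25°. Pupils follow
  a bounded AR(1) around a per-recording mean (3–4.5 mm) with an
  independent per-eye baseline offset (sd 0.3 mm, i.e. physiological
  anisocoria) — without that offset the two eyes' average-pupil
  features are duplicates and jointly unidentifiable. Both eyes share
  the gaze path up to 0.02° jitter, as real eyes do; consequently the
  two trajectory-length features are near-collinear by design.
- **EEG**: each planted community within a layer window shares a latent
  sinusoid (communities get well-separated 4–30 Hz frequencies, random
  phase) plus white noise; the amplitude/noise ratio sets the
  clustering strength. A configurable fraction of channels switches
  community at each layer transition, which sets the planted
  flexibility.
- **Scores**: base (rubric midpoint) + Σ β_f·z(feature) + participant
  random intercept (sd 1) + slope·(attempt−1) + N(0, 1), clipped to the
  rubric range; the generator warns when more than 5% of scores clip,
  since clipping attenuates planted slopes. Default planted score
  effects: avg_pupil_dom 2.0, recruitment_parietal 1.5,
  entropy_pupil_nondom 1.0 (standardized scale). They sit on
  attempt-varying features deliberately: a participant-constant
  covariate is absorbed by the random intercept and is not a fair
  recovery target. Slopes are slope_mean 0.8 + planted dependence on
  standardized first-attempt features (avg_pupil_dom −0.4,
  flexibility_frontal +0.3) + N(0, 0.2), so the learning-rate family
  also has ground truth to recover; effect sizes come from a power
  calculation (≈2× the combined slope-estimate sd at 25 participants).

What the generator does **not** emulate: volume conduction and
realistic EEG spectra, blinks/EMG artifacts, Tobii gap-fill heuristics,
rater noise in rubric scores, or correlation between skill level and
the planted physiologic effects. Passing tests therefore demonstrate
correctness of the computations and recoverability under controlled
conditions — not clinical validity on real recordings.

## Problem sizes and determinism

The default end-to-end profile used by the test suite and the
acceptance script runs 25 participants × 5 attempts with 32 EEG
channels, 12 s recordings, 6 layers, and 8 Louvain restarts — large
enough that all planted structure is recoverable, small enough to run
the whole chain in seconds per cohort on one CPU. Standalone extraction
defaults (124 channels, 100 restarts) remain the study-scale settings.
All randomness flows from a single integer seed through
`numpy.random.Generator`; model fitting itself is deterministic given
the data, and two pipeline runs with the same configuration and seed
produce byte-identical manifests.

## Known limitations

- Post-selection inference is naive (no selective correction).
- BIC uses the total observation count n, ignoring within-participant
  correlation in the effective sample size; the df convention is
  configurable.
- The connectivity estimator (|r| on windowed band-passed signals) is a
  stand-in; coherence/PLV alternatives are not implemented.
- Search information on disconnected layers yields +∞ pairs which are
  dropped from cortex averages (with a warning at the call site).
- Rubric totals are modelled as continuous Gaussians, not ordinal sums.
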