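# surgilearn

Objective evaluation of surgical-task performance and learning rate from
EEG dynamic-network features, eye-gaze features, and surgical-experience
covariates.

Surgical skill assessment in laparoscopic (FLS) and robot-assisted (RAS)
training traditionally relies on human raters scoring structured rubrics
(GOALS, OSAT, GEARS), which is costly and subjective. This package
implements, as a tested and reusable pipeline, an alternative: predict a
trainee's rubric score and learning rate from physiological signals
recorded while they perform the task. It is aimed at researchers in
surgical-skill analytics and neuroergonomics who want the full chain —
signal-level feature extraction, sparse mixed-effects modelling, and
skill-level comparison — with a synthetic-data generator that provides
ground truth for every stage.

## What it computes

**Eye-gaze features (12).** From a binocular 50 Hz gaze/pupil stream:
average and entropy of pupil diameter per eye, the fraction of fixation
and saccade samples under an I-VT velocity-threshold filter
(v_i = angular displacement × rate, fixation iff v < 30°/s), horizontal
and vertical gaze direction-change rates per eye, and gaze trajectory
length per eye. A 3-point moving average is applied first.

**EEG dynamic-network features (20).** From a multichannel 500 Hz EEG
recording: band-pass (4–30 Hz) and z-score, build windowed
|Pearson-correlation| connectivity layers, then compute per channel

- *strength* s_i = Σ_j w_ij,
- *search information* SI(i→j) = −log₂ Π_{(u,v)∈π*} w_uv / s_u over the
  shortest weighted path π* (lengths 1/w),
- *temporal network flexibility* — the fraction of layer transitions in
  which a node changes community under a multilayer-modularity partition
  Q = (1/2μ) Σ [(A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω] δ(g_il, g_jr),
  optimized by a seeded generalized-Louvain ensemble,
- *recruitment* and *integration* — module-allegiance probabilities
  P_ij = Pr[g_i = g_j] averaged within and across cortices,

each averaged over the channels of four cortices (frontal, parietal,
occipital, temporal).

**Performance models.** GLMM-LASSO: a Gaussian mixed model with a
participant random intercept and an L1 penalty on the 36 standardized
fixed effects (12 gaze + 20 EEG + 4 experience), estimated by penalized
marginal likelihood; the penalty λ is chosen on a grid by minimum
BIC = −2ℓ + (|support| + 2)·log n, and the selected support is refit
unpenalized for Wald SEs and p-values.

**Learning-rate models.** The learning rate is the OLS slope of a
participant's scores across attempts. After Local-Outlier-Factor
screening (10 neighbors), first-attempt features plus the baseline score
are forward-selected by leave-one-out cross-validation, and the final
linear model reports estimates, 95% CIs, and LOOCV MAE/RMSE.

**Skill-level comparison.** A mixed model of score on the four-level
skill factor with participant random intercept, an omnibus ANOVA F-test,
least-squares means per level, and Tukey-adjusted pairwise contrasts.

## Worked example

```bash
python examples/04_performance_model.py
```

simulates a 25-participant cohort (5 attempts each), extracts all
features, and fits the BIC-selected GLMM-LASSO. It prints:

```
minimum-BIC penalty: lambda=10.3 (BIC=544.6)
planted support: ['avg_pupil_dom', 'entropy_pupil_nondom', 'recruitment_parietal']
selected support: ['avg_pupil_dom', 'entropy_pupil_nondom', 'recruitment_parietal', 'search_information_frontal', 'search_information_occipital']
random-intercept sd: 1.31 (planted 1.0)
                   predictor  estimate  std_error  p_value
                   intercept    19.404      0.308    0.000
               avg_pupil_dom     2.347      0.156    0.000
        entropy_pupil_nondom     0.675      0.157    0.000
  search_information_frontal    -0.207      0.260    0.427
        recruitment_parietal     1.327      0.149    0.000
search_information_occipital    -0.213      0.264    0.418
{'r_squared': 0.608, 'mae': 1.651, 'rmse': 2.079}
```

The three planted predictors are all selected with estimates near their
planted values (2.0, 1.0, 1.5 on the standardized scale); the two extra
predictors are shrunk small and non-significant in the refit. The other
examples cover the cohort generator, the gaze and EEG extractors, the
learning-rate model, and the skill-level comparison.

A thin CLI mirrors the library
(`surgilearn simulate|features|fit|compare-levels|run`); run
`surgilearn --help`.

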