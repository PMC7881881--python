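# Methods

`gazephysio` analyses synchronized eye-gaze and physiological recordings of
the kind collected in contemplative-landscape viewing studies: a seated
observer free-views a scene for 15 minutes after a 3-minute baseline, while
a scene-camera eye tracker samples gaze at 60 Hz and a physiological
amplifier records ECG (2048 Hz) and skin conductance (256 Hz).  The package
implements the full analysis chain — gaze descriptors, a two-state scanpath
HMM with gaze transition entropy, Pan-Tompkins-based autonomic metrics, and
the windowed correlation / factorial-ANOVA stages — together with a
synthetic-data generator that provides ground truth for every stage.

## Gaze descriptors

**Heatmap.** Writing the gaze sample at time *t* as g_t ∈ R², the heatmap
places an isotropic Gaussian kernel of SD σ = 10 px at every valid sample on
the pixel grid x ∈ Z² and normalizes the accumulated mass to 1.  Kernels are
truncated at ±4σ (tail mass ~1e-4 of a kernel, absorbed by the final
normalization).  Invalid samples (blinks, look-aways) are excluded.
Coordinates are 0-based pixel indices, origin top-left, x rightward, y
downward; grids are indexed `grid[y, x]`.

**Spatial entropy.** The Shannon entropy of the heatmap in base 2,
H = −Σ_x p(x) log₂ p(x) with 0·log 0 ≡ 0, bounded by log₂(W·H) bits.
Higher values mean more spatially distributed viewing.

**Fixation/saccade segmentation.** Speeds between adjacent valid samples
are decoded by a two-state velocity HMM (fixation ≈ zero speed, saccade ≈
high speed; half-normal emissions) via the Viterbi path.  Emission scales
are set adaptively from the speed distribution (fixation scale 1.5× the
median speed; saccade scale the 99th percentile, floored at 8× the fixation
scale).  Transitions are asymmetric — the fixation state is sticky (0.95),
the saccade state is not (0.5) — because at 60 Hz a saccade occupies only
one or two inter-sample segments and a sticky saccade state would
over-penalize legitimate single-segment jumps.  Two refinements:

* a fixation never bridges an invalid run longer than 75 ms, and a bridged
  shorter gap still breaks the run when gaze re-appears displaced by more
  than 30 px (a blink that hid a saccade);
* each candidate fixation run is recursively tested for an internal
  change point: if splitting the run maximizes the distance between the
  left/right sub-centroids above 12 px, the run is split.  Small
  re-fixations move the eye by less than the single-sample velocity test
  can resolve against jitter (≈3 px SD per sample); averaging the samples
  on each side of the candidate change point recovers them at much better
  signal-to-noise.  The 12 px threshold is 4× the within-fixation jitter
  scale.

Fixations shorter than 100 ms are discarded.  Each inter-fixation jump
yields one saccade whose amplitude is the Euclidean distance between the
adjacent fixation centroids (reported in pixels).  Mean fixation duration
indexes focus; mean saccade amplitude indexes spatial exploration.

## The scanpath HMM and gaze transition entropy

The scanpath model assumes the observation at step *t* is emitted by a
hidden state s_t ∈ {1, 2} — a *central* state for gaze concentrated near
the scene center and a *peripheral* state for gaze distributed over the
margins — with state-dependent Gaussian-mixture emissions

p(g_t | s_t = i) = Σ_m c_im N(g_t; m_im, Σ_im),  Σ_m c_im = 1,

and a first-order Markov chain over states with transition matrix
A = [a_ij], a_ij = p(s_t = j | s_{t−1} = i), initial probabilities p_i, and
stationary distribution π satisfying πA = π (computed from the null space
of Aᵀ − I; for a 2×2 chain, π = (a₂₁, a₁₂)/(a₁₂ + a₂₁)).  A reducible
chain has no unique stationary distribution; the absorbing-state point mass
is returned with a warning.

The **gaze transition entropy**

H = −Σ_i π_i Σ_j a_ij log₂ a_ij   (0·log 0 ≡ 0)

is the stationary-weighted entropy rate of the chain, in [0, 1] bit for two
states: 1 bit for uniform transition probabilities (rapid central↔
peripheral alternation), 0 bits for deterministic rows (no transitions).
It is the only descriptor here that couples the spatial and temporal
structure of the scanpath; lower values indicate more deliberative,
focused scanning.

**Observation granularity.** By default the model is fit at
fixation-centroid granularity — one observation per detected fixation — so
the chain describes transitions between fixation targets rather than
autocorrelated raw samples.  A per-sample mode
(`ScanpathHMM.from_trajectory(..., granularity="sample")`) is available.

**Training.** Baum-Welch (EM) with a scaled forward-backward pass
(per-step normalization, numerically equivalent to the log-space
recursion).  Emission means and covariances are seeded by k-means run
separately on a central and a peripheral shell of the observations — the
shells are found by 2-means on the distances from the data centroid (a
median split would drown the peripheral shell in central mass whenever the
central state dominates occupancy).  Mixture weights, transition and
initial-state probabilities are initialized randomly from the seed.
Per-state component counts default to (4, 9) for the courtyard-like scene
and (3, 12) for the garden-like scene and are configurable; a robustness
sweep over ±25% component counts is provided
(`stats.robustness_sweep`).  Convergence is declared when the
*per-observation* log-likelihood change falls below 1e-5 (or at 500
iterations); log-likelihood is monotone non-decreasing and this is checked at every
iteration.  Covariance eigenvalues are floored at 1 px².  After fitting,
states are ordered so index 0 is the central state (smaller weighted mean
distance of emission means from the data centroid).

**Constrained re-estimation.** Two frozen-parameter operations implement
the group/window comparisons:

* `reestimate_transitions` — EM over A only, with emissions and initial
  state probabilities frozen (bit-identical before/after).  Used to obtain
  per-3-minute-window transition matrices from the subject-independent
  model; window entropy is the stationary-weighted entropy of the
  re-estimated A.  If a state's expected occupancy in a window is below one
  observation, its row is kept from the subject-independent model and a
  warning issued.
* `reweight_mixture` — EM over mixture weights only, with means and
  covariances frozen.  Used to compare groups over a shared set of
  regions of interest.

**ROI mixtures and spread.** `fit_gmm_bic` selects the number of
regions-of-interest mixtures by minimizing BIC = −2 log L + k ln n over a
candidate range (EM fits via scikit-learn, collapsed components rejected
and refit).  The spatial spread of a weighted set of cluster means is
summarized by det(Σ_b), Σ_b = Σ_i π_i (m_i − m̄)(m_i − m̄)ᵀ,
m̄ = Σ_i π_i m_i — zero for coincident or (in 2-D) collinear means.

**Model adequacy.** The heatmap of an HMM-generated scanpath is compared
with the measured heatmap by the Kullback-Leibler divergence
KL(p‖q) = Σ p log₂(p/q) in bits, with q floored at 1e-12 and renormalized
so supp(p) ⊆ supp(q).

## Physiological metrics

**Beat localization** uses the Pan-Tompkins chain: 5-15 Hz band-pass
(2nd-order Butterworth; zero-phase forward-backward by default to avoid
beat-time bias, the original causal filters behind `zero_phase=False`),
differentiation, squaring, 150 ms moving-window integration, then adaptive
dual-threshold peak selection (running signal/noise estimates,
THR = N + 0.25(S − N)) with a 200 ms refractory period and a search-back
pass at half threshold when the gap since the last beat exceeds 1.66× the
running RR average.  Detections are refined to the local maximum of the
band-passed signal within ±100 ms.  A maximum-RR-jump rejection filter is
available behind an option (`max_rr_jump`) but off by default — no
artifact/ectopic rejection is applied unless requested.

**Windowed metrics.**  An RR interval belongs to a half-open window
[start, end) iff both bounding beats fall inside it.  Per window:
HR = 60 · n_RR / Σ RR (bpm); RMSSD = √(mean ΔRR²) in ms over successive RR
pairs (a time-domain vagal index); SCL = the arithmetic mean of the skin
conductance samples (µS).  HR needs ≥2 beats and RMSSD ≥3 beats in the
window, otherwise the value is flagged undefined (NaN) and propagates as
missing.  All metrics are reported relative to the 3-minute baseline
averages as ΔHR, ΔRMSSD, ΔSCL.  BVP is ingested and stored but not
analysed.  No frequency-domain HRV and no phasic SCR decomposition.

## Statistical stages

Per-window gaze metrics and physiology deltas are joined into one row per
subject × scene × modality × window (`build_window_table`); rows with any
flagged metric are excluded and the count logged.

**Pooled correlations.** Pearson r over pooled windows — each 3-minute
window is one observation, matching the scatter-plot convention of one dot
per window — with a two-sided p from the t distribution on n−2 df.  A
subject-level aggregation mode exists but is not the default; pooled
windows from the same subject are not independent, so the default p-values
are anti-conservative to the extent that within-subject correlation exists
(the synthetic cohort generates exchangeable rows, where they are exact).

**2×2 ANOVA.** Type-III sums of squares with sum-to-zero contrasts
(statsmodels OLS + `anova_lm`), well defined for unbalanced cells such as
11 female vs 27 male subjects.  Per effect: F = MS_effect/MS_error, p from
the F distribution, and partial η² = SS_effect/(SS_effect + SS_error) with
0.01/0.06/0.14 conventionally read as small/medium/large.  The factorial
is treated as plain between-cells (no repeated-measures structure).
Significance threshold 0.05; no multiple-testing correction by default,
Holm step-down available behind a flag.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Session geometry**: 960×720 px scene image, 60 Hz gaze, 2048 Hz ECG,
  256 Hz GSR, 180 s baseline + 900 s viewing, 20% gaze dropout.
* **Gaze**: a fixation-granularity state path from a two-state chain; per
  fixation one centroid draw from the state's emission GMM (redrawn into
  the frame), gamma-distributed durations (shape 4, mean 350 ms — a
  realistic mean and coefficient of variation; no generative law for
  durations is established, so this is a modelling convention), isotropic
  within-fixation jitter of SD 3 px, instantaneous one-sample jumps
  between fixations.  Dropout is placed in contiguous blink-like runs
  (gamma lengths, mean 200 ms) alternating with gamma-distributed valid
  gaps scaled to the requested dropout fraction — blinks, not i.i.d.
  sample loss.
* **Scene models**: the courtyard-like scene uses (4, 9) central/peripheral
  components and base chain [[0.80, 0.20], [0.35, 0.65]]; the garden-like
  scene (3, 12) components and a stickier chain [[0.90, 0.10],
  [0.20, 0.80]] — lower transition entropy, matching the qualitative
  contrast the design is meant to produce.
* **ECG**: RR intervals are mean_rr plus zero-mean Gaussian perturbations
  rescaled so the realized RMSSD of the RR series equals the target
  exactly; a PQRST template (sum of five Gaussians) is placed at each
  beat; exact beat times are returned.
* **GSR**: tonic level + linear drift + low-amplitude white noise
  (0.02 µS SD).
* **Cohorts** are generated at the per-window metrics level: per-window
  transition entropy comes from simulating the fixation-granularity chain
  (~514 fixations per 3-minute window) with per-subject jitter of the
  transition logits (SD 0.25, a stable scanning style), and ΔHR is
  coupled to the entropy as ΔHR = β(H − H̄) + ε with ε Gaussian
  (SD 2.5 bpm).  Passing `target_r` calibrates β against the realized
  entropy spread so the population pooled correlation equals the target;
  the expected r is returned as ground truth.  Factor shifts
  (scene/gender/modality) are injected additively at the second level.
  Metric noise is i.i.d. across rows apart from the designed coupling —
  the calibration properties (type-I rate at α, designed pooled r) are
  stated and validated under that exchangeable regime.  Raw-signal cohorts
  are not generated at this scale; full sessions (gaze + ECG + GSR) come
  from `simulate_session`.

**What the generator does not emulate.** Real gaze has smooth pursuit,
drift, saccade dynamics and calibration error; real ECG has baseline
wander, muscle noise and ectopy; real cohorts have repeated-measures
correlation across scenes and windows beyond the injected scanning style.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative assumptions, not robustness to
every artifact of real recordings.

## Known biases and numerical choices

* **Missing-fixation inflation.** With 20% blink-like dropout and the
  100 ms minimum duration, ~12% of true fixations are unobserved (blink-
  obliterated or too short).  Adjacent observed fixations then reflect
  multi-step chain transitions, whose cross-probabilities exceed the
  one-step values — e.g. (A²)₁₂ = 0.16 vs a₁₂ = 0.10 for the reference
  chain — biasing windowed transition entropy upward by ≈ +0.02 bits under
  the default study conditions.  This is a property of the measurement
  process, not of the estimator: given the true observation set, the
  constrained EM reproduces each session's realized chain entropy to
  within ~0.001 bits.  No correction is applied.
* **Session-level chain noise.** A single 15-minute session yields ~2550
  fixation transitions; the realized empirical chain deviates from the
  generating matrix with SD ≈ 0.02 bits of entropy (observed deviations up
  to 0.06 bits).  Recovery of design values is therefore asserted on
  across-seed aggregates, while per-seed estimates are compared to each
  session's realized chain.
* Heatmap kernels truncated at ±4σ; entropy uses 0·log 0 ≡ 0; KL and both
  entropies are reported in bits.
* EM: covariance eigenvalue floor 1 px²; scaled forward-backward;
  per-observation log-likelihood tolerance 1e-5, max 500 iterations;
  identical seeds give bit-identical fits.
* Problem sizes in the validation suites: ten 15-minute sessions for
  pipeline recovery; 1,000 metric-level cohort replicates for type-I
  calibration; 100 seeds for the designed-correlation band; 120-300 s ECG
  segments for detector fidelity.  These sizes make every check
  reproducible on a single CPU in minutes while keeping Monte-Carlo
  standard errors well inside the asserted tolerances.

## Limitations

* Exactly two gaze states; no semantic ROI labels, no smooth-pursuit
  detection, no eye-tracker calibration or scene-camera registration.
* The pooled-correlation default ignores within-subject dependence (by
  design, to match the one-dot-per-window convention).
* The Pan-Tompkins implementation targets clean-to-moderately-noisy ECG;
  heavy artifact regimes would need the optional RR-jump filter and/or
  upstream cleaning.
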