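# gazephysio

Synchronized gaze-behavior and physiological-response analysis for
free-viewing studies: scanpath hidden Markov models with gaze transition
entropy, heatmap/spatial-entropy descriptors, Pan-Tompkins-based autonomic
metrics (HR, RMSSD, SCL), and the windowed correlation / factorial-ANOVA
stages that link them — plus a synthetic-data generator with known ground
truth so the whole pipeline is testable end to end without any recordings.

## Who this is for

Researchers analysing eye-tracking + biosignal sessions of the kind used in
restorative-environment and contemplative-landscape studies: an observer
free-views a scene for 15 minutes after a 3-minute baseline while gaze is
sampled at 60 Hz in scene-camera pixel coordinates, ECG at 2048 Hz and
galvanic skin response at 256 Hz.  The package turns those channels into
per-3-minute-window metrics and the inferential summaries built on them.

## The model at the core

Gaze at step *t* is emitted by a hidden state s_t ∈ {central, peripheral}
with Gaussian-mixture emissions p(g_t | s_t = i) = Σ_m c_im N(g_t; m_im, Σ_im)
and a Markov chain over states, A = [a_ij].  With π the stationary
distribution (πA = π), the **gaze transition entropy**

    H = − Σ_i π_i Σ_j a_ij log₂ a_ij        (bits)

is 1 bit for uniform transitions (rapid central↔peripheral alternation) and
0 bits for deterministic rows (no transitions); lower H means more focused,
deliberative scanning.  It is the only gaze descriptor here that couples the
spatial and temporal structure of the scanpath.  A subject-independent model
is trained by Baum-Welch on pooled fixation centroids; per-window transition
matrices are then re-estimated with emissions frozen, giving one entropy
value per 3-minute window that can be correlated with the baseline-relative
physiology deltas ΔHR, ΔRMSSD, ΔSCL.

## Worked example

```python
import gazephysio as gp
from gazephysio.model import ScanpathHMM

# a 5-minute synthetic viewing session of the garden-like scene
cfg = gp.SessionConfig(viewing_duration=300.0)
hmm = gp.default_scene_hmm(cfg, "garden", seed=0)
traj, truth = gp.simulate_gaze(hmm, cfg, seed=42)

fs = gp.segment_fixations(traj)
dur, amp = gp.gaze_summary(fs)
hmap = gp.compute_heatmap(traj, sigma=10.0)
print(f"fixations: {len(fs.fixations)}, mean duration {dur:.0f} ms, "
      f"mean saccade amplitude {amp:.0f} px")
print(f"spatial entropy: {gp.spatial_entropy(hmap):.2f} bits")

res = ScanpathHMM.from_trajectory(traj, n_components=(3, 12)).fit(seed=0)
print(res.summary())
print(f"generating-chain entropy: {gp.transition_entropy(truth.hmm.transmat):.4f} bits")
```

prints

```
fixations: 772, mean duration 279 ms, mean saccade amplitude 220 px
spatial entropy: 17.33 bits
Two-state scanpath HMM
======================================================
observations:        772
components (C, P):   (3, 12)
log-likelihood:      -9203.486
EM iterations:       31 (converged: True)
------------------------------------------------------
transition matrix A (rows: from central, peripheral):
  [0.8811  0.1189]
  [0.2195  0.7805]
stationary distribution pi: [0.6485  0.3515]
transition entropy:  0.6082 bits
======================================================
generating-chain entropy: 0.5533 bits
```

The 772 detected fixations have a shorter mean duration than the
generator's 350 ms because 20 % of samples are lost in blink-like runs that
split fixations.  The fitted chain is sticky (a₁₁ ≈ 0.88, a₂₂ ≈ 0.78) and
its entropy, 0.61 bits, sits near the generating chain's 0.55 bits — the
gap reflects both the 5-minute session's sampling noise and the upward bias
from fixations hidden by blinks (see `docs/methods.md`).

Cohort-level inference works the same way on generated metrics:

```python
df, truth = gp.simulate_cohort(n_subjects=38, scenes=("courtyard",),
                               target_r=0.25, seed=3)
r, p, n = gp.pooled_correlation(df["transition_entropy"], df["delta_hr"])
print(f"pooled entropy-vs-dHR correlation: r={r:.2f}, p={p:.4f}, n={n}")
# pooled entropy-vs-dHR correlation: r=0.29, p=0.0000, n=190
```

Here 38 subjects × 5 windows give 190 pooled observations and the designed
entropy↔ΔHR coupling (population r = 0.25) is recovered at r = 0.29.

A command-line pipeline wraps the same stages:

```bash
gazephysio simulate --seed 7 --out session/
gazephysio gaze    --gaze session/gaze.csv
gazephysio physio  --ecg session/ecg.csv --gsr session/gsr.csv
gazephysio report  --table metrics.csv --out report.md
```

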