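# Methods

## The indicator

Consciousness is treated as two binary components: **arousal**
(wakefulness) and **awareness** (subjective experience).  Each recording
state carries a fixed label pair — wakefulness (high, high), REM sleep
(low, high), NREM sleep (low, low), ketamine (low, high), propofol/xenon
(low, low), MCS and MCS\* (high, high), UWS (high, low) — so the two
components dissociate: REM and ketamine are low-arousal yet high-awareness,
UWS the reverse.  Two classifiers with identical architecture are trained
on the same feature tensors, one per component.

For a session *j* with *N* trials, the indicator on a component is the mean
high-class probability

    C_j = (1/N) * sum_{i=1..N} p_i ,

so C_j ∈ [0, 1], is invariant to trial order, and damps single-trial
outliers.  The pair (C^aro, C^awa) is classified against the cutoff 0.5 —
the mean probability of a two-class decision; an exact tie is reported as
*indeterminate* rather than silently assigned, since real sessions
essentially never average to exactly 0.5.

## Preprocessing

The chain follows standard evoked-EEG practice: polyphase downsampling to
362.5 Hz; zero-phase (forward–backward) band-pass 0.5–45 Hz with an
order-2 Butterworth design; segmentation to −400..1000 ms around the pulse
(resting data keep their 1-s segments); baseline correction by the mean of
the 400 ms pre-pulse window; spherical-spline interpolation of an
*explicitly listed* set of bad channels (never auto-detected); rejection of
any trial whose absolute amplitude exceeds 100 μV on a retained channel;
and common-average re-referencing.  Zero-phase filtering was chosen so the
200–400 ms analysis window is not latency-shifted; the filter's attenuation
is what an order-2 Butterworth provides (the 60 Hz / 10 Hz amplitude ratio
after the zero-phase pass is 13.7 dB, matching the design's squared
transfer function — tests assert agreement with `sosfreqz` rather than a
steeper roll-off this filter cannot deliver).  Ocular ICA cleanup is a
pluggable hook (`ChainOptions.ica_hook`), not built in.

**Window convention.**  Sample times are t_k = k/srate relative to the
alignment origin.  A window [start, end) keeps samples from the first one
at or ≥ start, and an *interior* window of duration d keeps at most
⌊d·srate⌋ samples, so equal durations always yield equal counts regardless
of grid alignment: 200 ms at 362.5 Hz is exactly 72 samples both for the
evoked 200–400 ms window (whose first in-window sample is at 201.38 ms) and
for the resting 0–200 ms window (whose start sits exactly on the grid).
When the requested end reaches past the last recorded sample the cap is
moot and everything from start is kept, so a window covering the whole
epoch is the identity.  This convention is fixed; changing it changes the
tensor depth and therefore the network input.

## Mesh features

Each trial's channels × samples matrix is scattered onto a 10 × 11 scalp
grid (anterior rows first, left columns first).  The channel → cell map
projects each electrode's standard 10-05 position through an
azimuthal-equidistant flattening and rank-bins the anteroposterior and
lateral coordinates **against the full standard reference montage** — not
against the channels present — so the map is stable across montage subsets
and a lone Cz still lands centrally.  Cell collisions go to the nearest
free cell in a deterministic scan, processing channels in sorted-label
order so the layout is independent of channel order.  The layout is
versioned (`grid-rankbin-1`); no equivalence with any historical grid is
claimed, and classifier behavior depends on it.  Grid cells without an
electrode ("null electrodes") are exactly zero at every depth plane and
receive exactly zero relevance.

Depth is either the 72 window samples (spatiotemporal) or five band powers
(spatio-spectral): delta 1.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–40 Hz, computed as a magnitude-squared FFT periodogram zero-padded to
1024 points and summed over in-band bins (half-open edges).  A 200 ms
window resolves only ~5 Hz, so the delta band is dominated by spectral
leakage and is computed for structural completeness only; a pure 10 Hz
tone concentrates 76% of its five-band power in alpha under this estimator,
with the remainder leaking into the neighbors.

## Network and training

The classifier is a small valid-padding CNN over the mesh:

    conv 100 @ 3×3 /(1,1) → conv 80 @ 2×2 /(1,1) → maxpool 2×2 /(1,2)
    → conv F3 @ 3×3 /(1,1) → conv F4 @ 2×2 /(2,1) → maxpool 2×1 /(2,1)
    → conv 2 @ 1×1 → flatten → softmax

with ReLU after every convolution except the final 1×1.  Strides are
(rows, cols); under valid padding the stack collapses 10×11 → 8×9 → 7×8 →
6×4 → 4×2 → 2×1 → 1×1, leaving a length-2 softmax — the only padding
convention under which this kernel/stride sequence is dimension-exact.
F3/F4 taper the filter counts 100 → 80 → 60 → 40 → 2 and are configurable.
The engine (valid convolution, overlapping max-pooling, Adam, epsilon-rule
relevance) is implemented in NumPy with channels-last im2col matrix
multiplication; analytic gradients are verified against central finite
differences in the test suite.

Training uses Adam (lr₀ = 0.005, β₁ = 0.9, β₂ = 0.999), batch size 25, and
a budget of five presentations per training sample (≈5 epochs; a literal
"iterations = 5 × n_train" reading is available via
`TrainSpec.budget_mode="iterations"`).  The learning rate decays
sublinearly, lr_t = lr₀/√(1+t) per evaluation step (one per epoch).  An
inner 80/20 split, stratified by class, provides the validation set; the
checkpoint with the best validation accuracy is kept.  Loss is two-class
cross-entropy; weights start from variance-scaled uniform init with a
seeded generator, so training is bit-reproducible.

Generalization to unseen people is estimated leave-one-participant-out:
each fold trains on every other participant and scores the held-out one, so
train and test trials never overlap.  Training data may pool several
recording domains (sleep, anesthesia, disorders of consciousness); the
default pool policy uses {sleep, anesthesia} for evoked sleep/anesthesia
targets, {doc, anesthesia} for DoC targets, anesthesia alone for resting
anesthesia — and a `distance_rank` policy orders candidate domains by the
cosine distance between domain-average evoked responses,
D(A,B) = 1 − f_Aᵀf_B/(‖f_A‖‖f_B‖) ∈ [0, 2].  A pool whose states carry
only one label for a component (e.g., arousal within DoC alone) is
rejected as untrainable.  A participant-level 0.75/0.25 hold-out harness
covers the "new patient without retraining" use case.

## Relevance propagation

Relevance starts at the target class's **pre-softmax** score f(x) (the
decision actually made — by default each trial's predicted class) and is
propagated backward: an ε-stabilized proportional rule through
convolutions (R_i = Σ_j x_i w_ij/(z_j + ε·sign z_j) · R_j), winner-take-all
through max-pooling, identity through ReLU and flatten.  With ε = 0 and
zero biases the decomposition is conservative, Σ_p R_p = f(x), which the
tests verify to 1e-6 relative on fixture networks and exactly on a single
linear layer (R_p = w_p x_p).  On trained networks biases absorb a share of
relevance and ε (default 10⁻² × mean |pre-activation| per layer) trades
conservation for numerical stability; leakage grows smoothly with ε.

Region scores sum relevance over depth per cell, map cells back to
electrodes, average over a participant's trials, then average over each
region's electrodes — frontal (Fp1-2, Fpz, AF1-2, AFz, F1-8, Fz), temporal
(FT9-10, T7-8, TP9-10), parietal (CP1-6, CPz, P1-4, P7-8, Pz).  Signed
means are the default (a positive-part variant sits behind a flag);
electrodes outside the three lists (central row, occipital) are not part of
the region statistics.  Group differences use Kruskal–Wallis across the
three regions with pairwise two-sided t-tests under Fisher's LSD logic —
pairwise calls count only when the omnibus rejects at α = 0.05, with no
further correction.

## Synthetic cohorts

The generator emulates a 60-channel TMS-compatible montage sampled at
1450 Hz, epochs −400..1000 ms (evoked) or 0..1000 ms (resting).  Evoked
archetypes: low-awareness states respond with a single high-amplitude slow
(2.5 Hz) damped transient confined to 0–300 ms; high-awareness states with
a sustained low-amplitude 8–40 Hz oscillation persisting past 300 ms.  A
second, temporally/spectrally distinct signature (18 Hz vs 5 Hz bursts
around 300–350 ms) separates high from low arousal, so the same trials
support both classifiers with different labels.  All class kernels are
scaled by `effect_size`, weighted `parietal_gain`× on the parietal
electrodes, and modulated by random effects at two levels: per participant
(lognormal amplitude SD 0.3, latency SD 15 ms) and per trial (lognormal
amplitude SD 0.6, latency SD 20 ms) — single-trial evoked responses
fluctuate strongly in real recordings, and this variability is what keeps
single-trial classification away from the ceiling.  The background is
per-channel 1/f Gaussian noise (exponent 1, RMS 9 μV).  Kernel amplitudes
and noise were calibrated once so that the default cohort lands in the
single-trial accuracy regime reported for real evoked recordings
(fold accuracies near 0.9 rather than 1.0), which also leaves the
electrode-ablation contrast resolvable instead of saturated.  Resting
cohorts replace the pulse-locked kernels with stationary oscillatory
mixtures whose spectral content differs by state, at amplitudes chosen so
clean trials stay within the ±100 μV rejection bound.

Defaults — 6 participants per domain, 40 trials per session, effect size 3,
parietal gain 4 — are the standard conditions of every recovery analysis in
this package.  What the generator does **not** emulate: spatially
correlated noise, TMS decay artifacts, ocular/muscle artifacts, sleep
microstructure, volume-conduction-consistent topographies, or any
biophysical forward model.  Passing recovery tests therefore demonstrates
that the pipeline recovers the structure it assumes — parietal-dominant,
time-frequency-distinct class effects — not that it would classify real
clinical recordings at the same accuracy.

## Problem sizes and numerics

The recovery study runs 6 LOPO folds on 720 trials (600 training, ≈5 s per
fold on one CPU), two ablation reruns, a balanced two-state null cohort
(wake vs NREM, effect 0 — balanced so chance is exactly 0.5 regardless of
any class-prior bias the trained network acquires), and a trial-count curve
with 100 resamples per n ∈ 1..40 (without replacement; at n = max every
resample is the full set, so the curve endpoint equals the full-data ROC
exactly).  ROC uses the tie-corrected rank (Mann–Whitney) AUC, verified
against exhaustive pairwise enumeration; sensitivity/specificity are
reported at the fixed 0.5 cutoff and at the Youden-optimal point.  External
complexity indices (e.g., a perturbational complexity value with its
published 0.31 cutoff) are consumed as inputs for correlation, never
computed.

## Known limitations

* The exact channel→cell grid of any particular historical study is not
  recoverable; equivalence with previously published trained models is not
  claimed.
* The delta band power of a 200 ms window is leakage-dominated (see above).
* Session-level AUC over a handful of synthetic sessions is coarsely
  quantized; the ablation comparison therefore reports single-trial AUC
  alongside it.
* Relevance explains the classifier's decision surface, not physiology:
  a high parietal score means the model used parietal signal, nothing more.
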