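# eci — explainable consciousness indicator from EEG epochs

Clinical assessment of consciousness conflates two things that can
dissociate: **arousal** (wakefulness — eyes open, sleep/wake physiology)
and **awareness** (subjective experience).  REM sleep and ketamine
anesthesia are low-arousal yet high-awareness; unresponsive wakefulness
syndrome (UWS) is the reverse.  Indices built on evoked-response
complexity separate conscious from unconscious states but collapse the two
components into one number.

This package implements a two-dimensional, classifier-based indicator for
researchers working with TMS-evoked or resting-state EEG.  Epoched
recordings are preprocessed (362.5 Hz, 0.5–45 Hz zero-phase Butterworth,
baseline correction, ±100 μV trial rejection, average reference), the
200–400 ms post-pulse window is rearranged onto a 10 × 11 electrode mesh
(10 × 11 × 72 spatiotemporal or 10 × 11 × 5 band-power tensors), and a
small CNN is trained per component under leave-one-participant-out (LOPO)
transfer, optionally pooling training data across recording domains by the
cosine distance between domain-average evoked responses.  The indicator of
a session *j* with *N* trials is, per component,

> C_j = (1/N) Σᵢ pᵢ ,  pᵢ = softmax probability of the *high* class on trial *i*,

classified against the 0.5 cutoff.  Decisions are explained by layer-wise
relevance propagation (Σₚ Rₚ = f(x) under the ε-rule at ε = 0), aggregated
over frontal / temporal / parietal scalp regions.  A synthetic-cohort
generator with the statistical structure the classifier assumes
(state-specific evoked archetypes, parietal-dominant effects, 1/f noise,
participant random effects) makes every stage testable without clinical
data.  See `docs/methods.md` for the model details and the generator's
limitations.

## Worked example

`examples/04_train_and_indicator.py` simulates a 4-participant sleep
cohort (NREM / REM / wake, 20 trials per session), trains both component
classifiers LOPO, and prints the per-session indicator pairs:

```
participant session state  n_trials  eci_awa      eci_aro
    sleep01    nrem  nrem        20 0.724894 2.981797e-01
    sleep01     rem   rem        19 0.760337 2.578799e-01
    sleep01    wake  wake        20 0.883025 4.939897e-01
    sleep02    nrem  nrem        20 0.276058 3.195341e-07
    sleep02     rem   rem        20 0.829321 2.402464e-02
    sleep02    wake  wake        20 0.910745 9.340126e-01
    sleep03    nrem  nrem        18 0.021703 5.971961e-02
    sleep03     rem   rem        17 0.935346 1.224647e-01
    sleep03    wake  wake        16 0.999976 9.994380e-01
    sleep04    nrem  nrem        19 0.108271 6.106545e-02
    sleep04     rem   rem        16 0.727466 1.379538e-01
    sleep04    wake  wake        16 0.916669 9.998709e-01

awareness: session AUC 1.000, mean fold accuracy 0.851
arousal:   session AUC 1.000, mean fold accuracy 0.882
```

Each row is one session's indicator pair, scored by a model that never saw
that participant: NREM sits low on both axes, REM low-arousal /
high-awareness, wakefulness high on both.  Single trials are noisy
(per-trial accuracy ≈ 0.85), so the ranking separates states perfectly
(AUC 1.0) while a couple of sessions sit near the 0.5 cutoff — the first
participant's NREM awareness is miscalled, and their wake arousal is
borderline, which is exactly why the indicator averages trials rather than
trusting any single one.  The other examples cover simulation,
preprocessing, mesh features, relevance maps with region statistics, and
the trial-count curve.  The same pipeline is scriptable from the shell:

```sh
eci simulate -c cfg.yaml --out run/      # then: preprocess, featurize,
eci train --out run/ --component both    # eci, explain, report
```

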