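"""Train the two component classifiers LOPO and compute the 2-D indicator.

Each held-out participant is scored by a model that never saw their data;
per-trial high-class probabilities are averaged within each session into
the (arousal, awareness) indicator pair, classified against the 0.5 cutoff.
REM sessions should land in the low-arousal / high-awareness quadrant.
"""

from eci.model import TrainSpec
from eci.workflows import cohort_tensor, lopo_indicator
from eci.synthetic import SimConfig

# a small, moderately clean demo cohort; the package-default noise level is
# the harder regime used by the recovery analyses
tensors = cohort_tensor(SimConfig(n_participants_per_domain=4, trials_per_session=20,
                                  noise_rms_uv=6.0, seed=5))
spec = TrainSpec(seed=5)

awa = lopo_indicator(tensors, "awareness", spec, keep_models=False)
aro = lopo_indicator(tensors, "arousal", spec, keep_models=False)

frame = awa.session_frame[["participant", "session", "state", "n_trials", "eci_awa"]].copy()
frame["eci_aro"] = aro.session_frame["eci_aro"]
print(frame.to_string(index=False))
print(f"\nawareness: session AUC {awa.roc.auc:.3f}, "
      f"mean fold accuracy {awa.lopo.mean_accuracy:.3f}")
print(f"arousal:   session AUC {aro.roc.auc:.3f}, "
      f"mean fold accuracy {aro.lopo.mean_accuracy:.3f}")
# an indicator pair > 0.5 means the model calls the component "high";
# NREM should sit low on both axes, REM low arousal but high awareness.
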