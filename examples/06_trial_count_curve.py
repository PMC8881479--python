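"""How many trials does a reliable indicator need?

The session indicator is a trial average, so its discriminability grows
with the number of trials averaged.  This resamples n trials per session
(n = 1..max), recomputes the indicator and its ROC each time, and prints
the AUC as a function of n — the practical question being how quickly the
curve saturates.
"""

from eci.indicator import trial_curve
from eci.model import TrainSpec
from eci.workflows import cohort_tensor, lopo_indicator, session_truth
from eci.synthetic import SimConfig

tensors = cohort_tensor(SimConfig(n_participants_per_domain=3, trials_per_session=12,
                                  noise_rms_uv=6.0, seed=5))
run = lopo_indicator(tensors, "awareness", TrainSpec(seed=5), keep_models=False)

truth = session_truth(tensors.trial_meta, "awareness")
curve = trial_curve(tensors.trial_meta, run.lopo.trial_p_high, truth,
                    n_max=12, n_boot=50, seed=5)
auc = curve[curve["metric"] == "auc"]
print(auc.to_string(index=False))
print(f"\nfull-data session AUC: {run.roc.auc:.3f} "
      "(the curve should approach this as n grows)")
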