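"""Convenience orchestration: LOPO -> session indicator -> ROC in one call.

These helpers glue the library modules together the way the command-line
runs and the worked examples use them; nothing here adds behavior of its
own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTensor
from .indicator import RocResult, rank_auc, roc_analysis, session_eci, sessions_to_frame
from .labels import HIGH, label_for_state
from .model import CNNSpec, LopoResult, TrainSpec, lopo_evaluate


def session_truth(trial_meta: pd.DataFrame, component: str) -> dict[str, int]:
    """participant/session -> 1 if the session's state is high on the component."""
    key = trial_meta["participant_id"].astype(str) + "/" + trial_meta["session_id"].astype(str)
    out: dict[str, int] = {}
    for sk in dict.fromkeys(key):
        state = trial_meta[(key == sk).to_numpy()].iloc[0]["state"]
        out[sk] = int(label_for_state(state).component(component) == HIGH)
    return out


@dataclass
class ComponentRun:
    """One component's LOPO evaluation with session-level aggregation."""

    component: str
    lopo: LopoResult
    session_frame: pd.DataFrame = field(repr=False)
    session_scores: np.ndarray
    session_truth: np.ndarray
    roc: RocResult
    trial_auc: float


def cohort_tensor(config=None, seed: int | None = None) -> FeatureTensor:
    """Simulate a cohort, run the standard chain, window it, and mesh it."""
    from .features import build_layout, to_spatiotemporal
    from .preprocess import standard_chain, window
    from .synthetic import SimConfig, generate_cohort

    if config is None:
        config = SimConfig() if seed is None else SimConfig(seed=seed)
    cohort = generate_cohort(config)
    clean, _log = standard_chain(cohort)
    evoked = config.modality == "tms"
    win = window(clean, 200.0, 400.0) if evoked else window(clean, 0.0, 200.0)
    layout = build_layout(win.channel_labels)
    return to_spatiotemporal(win, layout)


def recovery_study(seed: int = 1, include_arousal: bool = True,
                   include_holdout: bool = True,
                   trial_curve_boot: int = 100) -> dict:
    """Full structure-recovery analysis on the default synthetic cohort.

    Simulates the standard cohort (6 participants x {NREM, REM, wake} x 40
    evoked trials, effect size 3, parietal gain 4), runs LOPO training,
    session aggregation and ROC, relevance-based region scoring, frontal and
    parietal electrode ablations, and the trial-count performance curve.
    Returns a flat dict of the quantities plus the underlying tables.
    """
    from scipy import stats as _stats

    from .explain import electrode_ablation, lrp, region_scores, region_stats
    from .indicator import roc_analysis, trial_curve
    from .model import holdout_evaluate

    base = int(seed) % (2 ** 31)
    tensors = cohort_tensor(seed=base)
    spec = TrainSpec(seed=base)

    awa = lopo_indicator(tensors, "awareness", spec)
    out: dict = {
        "tensors": tensors,
        "awareness": awa,
        "awareness_session_auc": awa.roc.auc,
        "awareness_sensitivity": awa.roc.sensitivity,
        "awareness_specificity": awa.roc.specificity,
        "awareness_trial_auc": awa.trial_auc,
        "awareness_fold_accuracy": awa.lopo.mean_accuracy,
        "n_trials": tensors.n_trials,
    }

    if include_arousal:
        aro = lopo_indicator(tensors, "arousal", TrainSpec(seed=(base + 101) % (2 ** 31)),
                             keep_models=False)
        out.update({
            "arousal": aro,
            "arousal_session_auc": aro.roc.auc,
            "arousal_trial_auc": aro.trial_auc,
            "arousal_fold_accuracy": aro.lopo.mean_accuracy,
        })

    # relevance of each held-out participant under its own fold model
    pid_col = tensors.trial_meta["participant_id"].to_numpy()
    maps = [lrp(awa.lopo.models[pid], tensors.select_trials(pid_col == pid))
            for pid in awa.lopo.models]
    from .explain import RelevanceMap

    combined = RelevanceMap(
        values=np.concatenate([m.values for m in maps]),
        target_class="predicted",
        f_x=np.concatenate([m.f_x for m in maps]),
        layout=tensors.layout,
        trial_meta=pd.concat([m.trial_meta for m in maps], ignore_index=True),
    )
    scores = region_scores(combined)
    stats_out = region_stats(scores)
    out["region_scores"] = scores
    out["region_means"] = scores.group_means()
    out["region_kruskal_h"] = stats_out.h
    out["region_kruskal_p"] = stats_out.p

    for region in ("frontal", "parietal"):
        abl = electrode_ablation(tensors, "awareness", region, spec)
        out[f"ablate_{region}_session_auc"] = abl.roc.auc
        out[f"ablate_{region}_trial_auc"] = abl.trial_auc

    truth = session_truth(tensors.trial_meta, "awareness")
    curve = trial_curve(tensors.trial_meta, awa.lopo.trial_p_high, truth,
                        n_max=40, n_boot=trial_curve_boot, seed=base)
    out["trial_curve"] = curve
    auc_curve = curve[curve["metric"] == "auc"].sort_values("n")
    ns = auc_curve["n"].to_numpy()
    means = auc_curve["mean"].to_numpy()
    out["curve_auc_n1"] = float(means[0])
    out["curve_auc_nmax"] = float(means[-1])
    if np.ptp(means) == 0:
        out["curve_trend_tau"], out["curve_trend_p_decreasing"] = 0.0, 1.0
    else:
        tau, p_two = _stats.kendalltau(ns, means)
        p_dec = p_two / 2 if tau < 0 else 1 - p_two / 2
        out["curve_trend_tau"], out["curve_trend_p_decreasing"] = float(tau), float(p_dec)

    if include_holdout:
        hold = holdout_evaluate(tensors, "awareness", 0.75, spec)
        held = tensors.select_trials(hold.test_index)
        from .indicator import correlate, session_eci

        hold_sessions = session_eci(held.trial_meta, p_awareness=hold.test_p_high)
        hold_vals = {f"{s.participant_id}/{s.session_id}": s.eci_awa for s in hold_sessions}
        keys = awa.session_frame["participant"].astype(str) + "/" + awa.session_frame["session"].astype(str)
        paired = [(hold_vals[k], v) for k, v in zip(keys, awa.session_frame["eci_awa"])
                  if k in hold_vals]
        hx = np.array([a for a, _ in paired])
        hy = np.array([b for _, b in paired])
        if len(paired) >= 3 and np.std(hx) > 0 and np.std(hy) > 0:
            r, p = correlate(hx, hy)
            out["holdout_vs_lopo_r"] = r
            out["holdout_vs_lopo_p"] = p
    return out


def null_control_study(seed: int = 1) -> dict:
    """Balanced two-state cohort with zero effect: fold accuracy must sit
    inside the binomial 95% chance band around 0.5."""
    from .synthetic import SimConfig

    base = (int(seed) + 977) % (2 ** 31)
    config = SimConfig(states=("nrem", "wake"), effect_size=0.0, seed=base)
    tensors = cohort_tensor(config=config)
    res = lopo_evaluate(tensors, "awareness", TrainSpec(seed=base), keep_models=False)
    n_test_total = int(res.accuracy_table["n_test"].sum())
    half_width = 1.96 * np.sqrt(0.25 / n_test_total)
    return {
        "null_fold_accuracy": res.mean_accuracy,
        "null_chance_half_width": float(half_width),
        "null_n_test": n_test_total,
        "accuracy_table": res.accuracy_table,
    }


def lopo_indicator(tensors: FeatureTensor, component: str,
                   spec: TrainSpec | None = None,
                   cnn_spec: CNNSpec | None = None,
                   keep_models: bool = True) -> ComponentRun:
    """LOPO-evaluate one component, aggregate to sessions, and run ROC."""
    lopo = lopo_evaluate(tensors, component, spec, cnn_spec, keep_models=keep_models)
    meta = tensors.trial_meta
    kw = {"p_arousal" if component == "arousal" else "p_awareness": lopo.trial_p_high}
    sessions = session_eci(meta, **kw)
    frame = sessions_to_frame(sessions, meta)
    col = "eci_aro" if component == "arousal" else "eci_awa"
    scores = frame[col].to_numpy(dtype=float)
    truth_map = session_truth(meta, component)
    keys = frame["participant"].astype(str) + "/" + frame["session"].astype(str)
    truth = np.array([truth_map[k] for k in keys])
    roc = roc_analysis(scores, truth)
    trial_truth = tensors.component_labels(component)
    trial_auc = rank_auc(lopo.trial_p_high, trial_truth)
    return ComponentRun(
        component=component, lopo=lopo, session_frame=frame,
        session_scores=scores, session_truth=truth, roc=roc, trial_auc=trial_auc,
    )
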