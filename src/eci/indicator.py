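"""Session-level consciousness indicator and its evaluation analyses.

A session's indicator on a component is the arithmetic mean of its trials'
high-class probabilities,

    C_j = (1/N) * sum_i p_i,

so it lives in [0, 1], is invariant to trial order, and damps single-trial
outliers.  The pair (arousal, awareness) values form the 2-D indicator; the
classification cutoff is 0.5, the mean probability of a two-class decision.
ROC analysis uses the rank (Mann-Whitney) AUC with tie correction.

An external complexity index (e.g., a perturbational complexity value with
its published cutoff 0.31) can be correlated against the awareness
indicator; it is consumed as a column, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PCI_CUTOFF = 0.31   # published empirical consciousness cutoff; plotting constant
CUTOFF = 0.5


@dataclass
class SessionECI:
    """One session's indicator pair and the trial probabilities behind it."""

    session_id: str
    participant_id: str
    eci_aro: float | None
    eci_awa: float | None
    n_trials: int
    p_aro: np.ndarray | None = field(default=None, repr=False)
    p_awa: np.ndarray | None = field(default=None, repr=False)


def _mean_prob(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty session: no trial probabilities")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("trial probabilities must lie in [0, 1]")
    return float(p.mean())


def session_eci(trial_meta: pd.DataFrame,
                p_arousal: np.ndarray | None = None,
                p_awareness: np.ndarray | None = None) -> list[SessionECI]:
    """Average per-trial high-class probabilities within each session.

    Sessions are participant/session pairs from the metadata; each trial
    belongs to exactly one.  Either component may be absent (None).
    """
    if p_arousal is None and p_awareness is None:
        raise ValueError("at least one component's probabilities are required")
    if len(trial_meta) == 0:
        raise ValueError("empty session: no trials to aggregate")
    key = trial_meta["participant_id"].astype(str) + "/" + trial_meta["session_id"].astype(str)
    out = []
    for sk in dict.fromkeys(key):
        sel = (key == sk).to_numpy()
        pid, sid = sk.split("/", 1)
        pa = None if p_arousal is None else np.asarray(p_arousal)[sel]
        pw = None if p_awareness is None else np.asarray(p_awareness)[sel]
        out.append(SessionECI(
            session_id=sid,
            participant_id=pid,
            eci_aro=None if pa is None else _mean_prob(pa),
            eci_awa=None if pw is None else _mean_prob(pw),
            n_trials=int(sel.sum()),
            p_aro=pa, p_awa=pw,
        ))
    return out


def classify_eci(e: SessionECI, cutoff: float = CUTOFF) -> tuple[str, str]:
    """Call each component low/high against the cutoff; exact ties are
    flagged 'indeterminate' rather than silently assigned."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")

    def call(v):
        if v is None:
            return "n/a"
        if v > cutoff:
            return "high"
        if v < cutoff:
            return "low"
        return "indeterminate"

    return call(e.eci_aro), call(e.eci_awa)


@dataclass
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    youden_cutoff: float | None = None
    youden_sensitivity: float | None = None
    youden_specificity: float | None = None


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (midranks)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both truth classes")
    ranks = stats.rankdata(scores)
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_analysis(scores, truth, cutoff: float = CUTOFF) -> RocResult:
    """AUC plus sensitivity/specificity at the fixed cutoff and at the
    Youden-optimal operating point."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    auc = rank_auc(scores, truth)
    pos, neg = scores[truth == 1], scores[truth == 0]
    sens = float((pos > cutoff).mean())
    spec = float((neg <= cutoff).mean())

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(truth, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    return RocResult(
        auc=auc, sensitivity=sens, specificity=spec, cutoff=cutoff,
        youden_cutoff=float(thr[k]), youden_sensitivity=float(tpr[k]),
        youden_specificity=float(1 - fpr[k]),
    )


def trial_curve(trial_meta: pd.DataFrame, p_high: np.ndarray, truth_by_session: dict,
                n_max: int = 80, n_boot: int = 100, seed: int = 0,
                cutoff: float = CUTOFF) -> pd.DataFrame:
    """Performance of the session indicator as a function of trial count.

    For each n from 1 to n_max, draw ``n_boot`` subsamples of min(n, N_s)
    trials per session s (without replacement), average them into indicator
    values, and run ROC across sessions.  Returns a tidy table
    (n, metric, mean, sd).  Sessions shorter than n contribute all their
    trials, so once n reaches every session's trial count each resample is
    the full data and the curve equals the full-data ROC exactly.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    key = trial_meta["participant_id"].astype(str) + "/" + trial_meta["session_id"].astype(str)
    sessions = list(dict.fromkeys(key))
    probs = {sk: np.asarray(p_high)[(key == sk).to_numpy()] for sk in sessions}
    truth = np.array([int(truth_by_session[sk]) for sk in sessions])
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(1, n_max + 1):
        metrics = np.empty((n_boot, 3))
        for b in range(n_boot):
            eci = np.array([
                probs[sk][rng.choice(len(probs[sk]), size=min(n, len(probs[sk])),
                                     replace=False)].mean()
                for sk in sessions
            ])
            r = roc_analysis(eci, truth, cutoff=cutoff)
            metrics[b] = (r.auc, r.sensitivity, r.specificity)
        for m, name in enumerate(("auc", "sensitivity", "specificity")):
            rows.append({
                "n": n, "metric": name,
                "mean": float(metrics[:, m].mean()),
                "sd": float(metrics[:, m].std(ddof=1)) if n_boot > 1 else 0.0,
            })
    return pd.DataFrame(rows)


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p (e.g., awareness indicator vs an
    external complexity index, or evoked vs resting indicators)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def sessions_to_frame(sessions: list[SessionECI], trial_meta: pd.DataFrame | None = None,
                      cutoff: float = CUTOFF) -> pd.DataFrame:
    """Tidy per-session table: ids, metadata, trial count, indicator pair, calls."""
    rows = []
    meta_by_session = {}
    if trial_meta is not None:
        key = trial_meta["participant_id"].astype(str) + "/" + trial_meta["session_id"].astype(str)
        for sk in dict.fromkeys(key):
            first = trial_meta[(key == sk).to_numpy()].iloc[0]
            meta_by_session[sk] = (first["domain"], first["state"])
    for s in sessions:
        call_aro, call_awa = classify_eci(s, cutoff)
        domain, state = meta_by_session.get(
            f"{s.participant_id}/{s.session_id}", (None, None)
        )
        rows.append({
            "participant": s.participant_id, "session": s.session_id,
            "domain": domain, "state": state, "n_trials": s.n_trials,
            "eci_aro": s.eci_aro, "eci_awa": s.eci_awa,
            "call_aro": call_aro, "call_awa": call_awa,
        })
    return pd.DataFrame(rows)
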