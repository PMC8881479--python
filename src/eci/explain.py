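"""Layer-wise relevance propagation and scalp-region relevance statistics.

Relevance is initialized at the target class's pre-softmax score f(x) and
propagated backward through the network: an epsilon-stabilized proportional
rule through convolutions, winner-take-all through max-pooling, identity
through ReLU and flatten.  With epsilon = 0 and bias-free layers the
decomposition is conservative,

    sum_p R_p = f(x),

which the tests verify on fixture networks.  Grid cells with no electrode
receive exactly zero relevance (their input is zero, and the rule multiplies
by the input).

Region scores aggregate relevance over the frontal, temporal and parietal
electrode groups; electrodes outside the three groups (central, occipital)
are not part of the region statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTensor, MeshLayout
from .model import CNNSpec, TrainSpec, predict_logits, TrainedModel

REGION_NAMES = ("frontal", "temporal", "parietal")


@dataclass
class RelevanceMap:
    """Per-trial, per-input-cell relevance for one target class."""

    values: np.ndarray                   # trial x rows x cols x depth
    target_class: str
    f_x: np.ndarray                      # propagated pre-softmax scores, per trial
    layout: MeshLayout
    trial_meta: pd.DataFrame = field(repr=False)

    def conservation_error(self) -> np.ndarray:
        """|sum_p R_p - f(x)| / |f(x)| per trial (exact conservation only for
        epsilon = 0 on bias-free networks)."""
        tot = self.values.reshape(len(self.values), -1).sum(axis=1)
        return np.abs(tot - self.f_x) / np.maximum(np.abs(self.f_x), 1e-30)


def lrp(m: TrainedModel, t: FeatureTensor, target_class: str = "predicted",
        eps: float | None = None) -> RelevanceMap:
    """Relevance decomposition of the model's decision on each trial.

    ``target_class`` is ``"high"``, ``"low"`` or ``"predicted"`` (each
    trial's argmax decision — the decision one wants explained).  ``eps``
    defaults to an adaptive stabilizer of 1e-2 times each layer's mean
    absolute pre-activation; pass 0 for exact conservation on bias-free
    fixtures.
    """
    if t.depth != m.depth:
        raise ValueError(f"tensor depth {t.depth} does not match model depth {m.depth}")
    x = np.ascontiguousarray(t.values, dtype=np.float32)
    logits = predict_logits(m.net, x)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite activations in the forward pass")
    if target_class == "predicted":
        tgt = logits.argmax(axis=1)
    elif target_class in ("low", "high"):
        tgt = np.full(len(x), 0 if target_class == "low" else 1)
    else:
        raise ValueError(f"target_class must be low, high or predicted, got {target_class!r}")

    values = np.empty_like(x, dtype=np.float64)
    f_x = np.empty(len(x))
    batch = 256
    for lo in range(0, len(x), batch):
        xb = x[lo:lo + batch]
        lg = m.net.forward(xb)          # re-forward so layer caches match
        R = np.zeros_like(lg)
        idx = np.arange(len(xb))
        R[idx, tgt[lo:lo + batch]] = lg[idx, tgt[lo:lo + batch]]
        f_x[lo:lo + batch] = lg[idx, tgt[lo:lo + batch]]
        values[lo:lo + batch] = m.net.relevance(R, eps)
    return RelevanceMap(values=values, target_class=str(target_class), f_x=f_x,
                        layout=t.layout, trial_meta=t.trial_meta)


def write_relevance(path, rmap: RelevanceMap) -> None:
    """Persist a relevance map to the package HDF5 container."""
    import h5py

    from .epochs import META_COLUMNS

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rmap.values, track_times=False)
        f.create_dataset("f_x", data=rmap.f_x, track_times=False)
        g = f.create_group("meta")
        for col in META_COLUMNS:
            g.create_dataset(col, data=rmap.trial_meta[col].astype(str).to_numpy(dtype="S64"),
                             track_times=False)
        f.attrs["target_class"] = rmap.target_class
        f.attrs["layout"] = rmap.layout.to_json()


def read_relevance(path) -> RelevanceMap:
    import h5py

    from .epochs import META_COLUMNS

    with h5py.File(path, "r") as f:
        meta = pd.DataFrame(
            {col: [v.decode() for v in f["meta"][col][()]] for col in META_COLUMNS}
        )
        return RelevanceMap(
            values=f["values"][()], f_x=f["f_x"][()],
            target_class=str(f.attrs["target_class"]),
            layout=MeshLayout.from_json(str(f.attrs["layout"])),
            trial_meta=meta,
        )


@dataclass
class RegionScores:
    """Participant x region mean relevance (tidy frame, one row per participant)."""

    table: pd.DataFrame                  # columns: participant, frontal, temporal, parietal
    signed: bool
    skipped_electrodes: dict[str, tuple[str, ...]]

    def group_means(self) -> dict[str, float]:
        return {r: float(self.table[r].mean()) for r in REGION_NAMES if r in self.table}


def region_scores(rmap: RelevanceMap, signed: bool = True) -> RegionScores:
    """Average relevance per participant over each scalp region.

    Relevance is summed over depth per grid cell, mapped back to electrodes
    through the layout, averaged over the participant's trials, then
    averaged over the region's electrodes.  ``signed=False`` averages the
    positive part only.
    """
    layout = rmap.layout
    cellsum = rmap.values.sum(axis=3)    # trial x rows x cols
    if not signed:
        cellsum = np.clip(rmap.values, 0, None).sum(axis=3)
    pid = rmap.trial_meta["participant_id"].to_numpy()
    skipped: dict[str, tuple[str, ...]] = {}
    region_cells: dict[str, list[tuple[int, int]]] = {}
    for region in REGION_NAMES:
        electrodes = layout.region_sets.get(region, ())
        present = [ch for ch in electrodes if ch in layout.mapping]
        skipped[region] = tuple(ch for ch in electrodes if ch not in layout.mapping)
        if not present:
            raise ValueError(f"region {region!r} has no electrodes mapped in the layout")
        region_cells[region] = [layout.mapping[ch] for ch in present]
    rows = []
    for p in dict.fromkeys(pid):
        sel = pid == p
        per_cell = cellsum[sel].mean(axis=0)      # rows x cols, mean over trials
        row = {"participant": p}
        for region, cells in region_cells.items():
            row[region] = float(np.mean([per_cell[r, c] for r, c in cells]))
        rows.append(row)
    return RegionScores(table=pd.DataFrame(rows), signed=signed, skipped_electrodes=skipped)


@dataclass
class RegionStats:
    h: float
    p: float
    alpha: float
    pairwise: pd.DataFrame               # region_a, region_b, t, p, significant


def region_stats(scores: RegionScores, alpha: float = 0.05) -> RegionStats:
    """Kruskal-Wallis omnibus across the three regions, with pairwise
    two-sided t-tests under Fisher's least-significant-difference logic:
    pairwise calls count as significant only when the omnibus rejects, and
    no further multiplicity correction is applied."""
    cols = [r for r in REGION_NAMES if r in scores.table.columns]
    if len(cols) < 2:
        raise ValueError("region statistics need at least 2 region columns")
    if len(scores.table) < 2:
        raise ValueError("region statistics need at least 2 participants")
    groups = [scores.table[c].to_numpy(dtype=float) for c in cols]
    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0                  # identical values carry no rank information
    else:
        h, p = stats.kruskal(*groups)
    rows = []
    for a, b in combinations(cols, 2):
        tstat, tp = stats.ttest_ind(scores.table[a], scores.table[b])
        rows.append({
            "region_a": a, "region_b": b, "t": float(tstat), "p": float(tp),
            "significant": bool(p < alpha and tp < alpha),
        })
    return RegionStats(h=float(h), p=float(p), alpha=alpha, pairwise=pd.DataFrame(rows))


@dataclass
class AblationResult:
    dropped: tuple[str, ...]
    roc: "RocResult"
    trial_auc: float
    session_frame: pd.DataFrame = field(repr=False)


def drop_electrodes(t: FeatureTensor, electrodes) -> FeatureTensor:
    """Zero the mesh cells of the given electrodes (all depth planes)."""
    out = t.select_trials(np.arange(t.n_trials))
    for ch in electrodes:
        if ch in t.layout.mapping:
            r, c = t.layout.mapping[ch]
            out.values[:, r, c, :] = 0.0
    return out


def electrode_ablation(tensors: FeatureTensor, component: str, region_to_drop,
                       spec: TrainSpec | None = None,
                       cnn_spec: CNNSpec | None = None) -> AblationResult:
    """Re-run LOPO -> indicator -> ROC with a scalp region's electrodes zeroed.

    ``region_to_drop`` is a region name, an iterable of electrode labels, or
    empty (the baseline).  Electrodes are zeroed in training and test
    tensors alike.  Returns the session-level ROC and, because a handful of
    sessions quantizes session-level AUC coarsely, the single-trial AUC as a
    higher-resolution readout of the degradation.
    """
    from .indicator import RocResult  # noqa: F401  (dataclass annotation)
    from .workflows import lopo_indicator

    if isinstance(region_to_drop, str):
        electrodes = tensors.layout.region_sets.get(region_to_drop)
        if electrodes is None:
            raise ValueError(f"unknown region {region_to_drop!r}")
    else:
        electrodes = tuple(region_to_drop)
    mapped = set(tensors.layout.mapping)
    if electrodes and mapped.issubset(set(electrodes)):
        raise ValueError("cannot drop every mapped electrode")
    ablated = drop_electrodes(tensors, electrodes)
    run = lopo_indicator(ablated, component, spec, cnn_spec, keep_models=False)
    return AblationResult(
        dropped=tuple(electrodes), roc=run.roc, trial_auc=run.trial_auc,
        session_frame=run.session_frame,
    )
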