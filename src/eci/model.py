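"""The mesh CNN, its training regimen, and the cross-validation harnesses.

Two independent binary classifiers share one architecture: one distinguishes
low from high arousal, the other low from high awareness, both trained on
the same feature tensors but with different labels.  Generalization to
unseen people is estimated with leave-one-participant-out (LOPO)
cross-validation; pooling of training data across recording domains (sleep,
anesthesia, disorders of consciousness) follows either the fixed default
policy or the cosine-distance ranking between domain-average evoked
potentials.

Architecture (valid padding throughout; ReLU after every convolution except
the final 1x1):

    conv 100 @ 3x3 /1x1 -> conv 80 @ 2x2 /1x1 -> pool 2x2 /1x2
    -> conv F3 @ 3x3 /1x1 -> conv F4 @ 2x2 /2x1 -> pool 2x1 /2x1
    -> conv 2 @ 1x1 -> flatten -> softmax

which collapses a 10 x 11 x D input to a length-2 probability vector:
10x11 -> 8x9 -> 7x8 -> 6x4 -> 4x2 -> 2x1 -> 1x1.  Strides are (rows, cols).
F3/F4 default to 60/40, tapering 100 -> 80 -> 60 -> 40 -> 2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .epochs import EpochSet
from .features import FeatureTensor
from .labels import DOMAINS, STATE_LABELS, domain_for_state

MESH_SHAPE = (10, 11)   # grid the architecture's dimension arithmetic assumes


@dataclass
class CNNSpec:
    """Filter counts of the five convolutions (kernels/strides are fixed)."""

    f1: int = 100
    f2: int = 80
    f3: int = 60
    f4: int = 40

    def build(self, depth: int, rng: np.random.Generator, dtype=np.float32) -> _nn.Sequential:
        C = _nn.Conv2D
        return _nn.Sequential([
            C(3, 3, depth, self.f1, (1, 1), rng, dtype), _nn.ReLU(),
            C(2, 2, self.f1, self.f2, (1, 1), rng, dtype), _nn.ReLU(),
            _nn.MaxPool2D(2, 2, (1, 2)),
            C(3, 3, self.f2, self.f3, (1, 1), rng, dtype), _nn.ReLU(),
            C(2, 2, self.f3, self.f4, (2, 1), rng, dtype), _nn.ReLU(),
            _nn.MaxPool2D(2, 1, (2, 1)),
            C(1, 1, self.f4, 2, (1, 1), rng, dtype),
            _nn.Flatten(),
        ])


@dataclass
class TrainSpec:
    """Optimization regimen: Adam(0.005, 0.9, 0.999), batch 25, a budget of
    five presentations per training sample, sublinear lr decay
    lr_t = lr0 / sqrt(1 + t) per evaluation step, 80/20 inner split."""

    lr0: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 25
    budget_multiplier: int = 5
    budget_mode: str = "presentations"   # or "iterations" (literal batch count)
    val_fraction: float = 0.2
    seed: int = 0

    def with_seed(self, seed: int) -> "TrainSpec":
        d = asdict(self)
        d["seed"] = int(seed) % (2 ** 31)
        return TrainSpec(**d)


@dataclass
class TrainedModel:
    """A fitted component classifier plus its training provenance."""

    net: _nn.Sequential
    component: str
    depth: int
    cnn_spec: CNNSpec
    train_spec: TrainSpec
    source_domains: tuple[str, ...]
    log: pd.DataFrame = field(repr=False)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", *self.net.state())
        (d / "spec.json").write_text(json.dumps({
            "component": self.component,
            "depth": self.depth,
            "cnn": asdict(self.cnn_spec),
            "train": asdict(self.train_spec),
            "source_domains": list(self.source_domains),
        }, indent=2))
        self.log.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        d = Path(directory)
        meta = json.loads((d / "spec.json").read_text())
        cnn = CNNSpec(**meta["cnn"])
        net = cnn.build(meta["depth"], np.random.default_rng(0))
        with np.load(d / "weights.npz") as z:
            net.load_state([z[k] for k in z.files])
        return cls(
            net=net, component=meta["component"], depth=meta["depth"],
            cnn_spec=cnn, train_spec=TrainSpec(**meta["train"]),
            source_domains=tuple(meta["source_domains"]),
            log=pd.read_csv(d / "training_log.csv"),
        )


@dataclass
class DomainProfile:
    """Domain fingerprint: the channel x time average evoked response, flattened."""

    domain: str
    f: np.ndarray


def domain_profile(e: EpochSet, domain: str) -> DomainProfile:
    sel = (e.trial_meta["domain"] == domain).to_numpy()
    if not sel.any():
        raise ValueError(f"no trials in domain {domain!r}")
    return DomainProfile(domain=domain, f=e.data[sel].mean(axis=0).ravel().astype(float))


def domain_distance(a: DomainProfile, b: DomainProfile) -> float:
    """Cosine distance D(A, B) = 1 - f_A.f_B / (||f_A|| ||f_B||), in [0, 2]."""
    fa, fb = np.asarray(a.f, float), np.asarray(b.f, float)
    if fa.shape != fb.shape:
        raise ValueError(f"profile lengths differ: {fa.size} vs {fb.size}")
    na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero-norm profile")
    return float(1.0 - float(fa @ fb) / (na * nb))


_DEFAULT_POOLS = {
    ("tms", "sleep"): ("sleep", "anesthesia"),
    ("tms", "anesthesia"): ("sleep", "anesthesia"),
    ("tms", "doc"): ("doc", "anesthesia"),
    ("resting", "anesthesia"): ("anesthesia",),
    ("resting", "doc"): ("doc", "anesthesia"),
}


def _component_trainable(domains, component: str) -> bool:
    labels = {
        STATE_LABELS[s][0 if component == "arousal" else 1]
        for s in STATE_LABELS
        if domain_for_state(s) in set(domains)
    }
    return len(labels) == 2


def pool_sources(target_domain: str, available, policy: str = "paper_default",
                 modality: str = "tms", component: str | None = None,
                 profiles: dict[str, DomainProfile] | None = None) -> list[str]:
    """Choose the source-domain pool for a given target domain.

    ``paper_default`` applies the fixed policy: sleep and anesthesia targets
    pool {sleep, anesthesia} (evoked); DoC targets pool {doc, anesthesia};
    resting anesthesia uses anesthesia alone.  ``distance_rank`` orders the
    available candidates by cosine distance to the target (ties broken by
    declaration order in ``available``).  ``explicit`` returns ``available``.
    """
    available = list(available)
    if target_domain not in DOMAINS:
        raise ValueError(f"unknown target domain {target_domain!r}")
    if policy == "explicit":
        pool = available
    elif policy == "paper_default":
        key = (modality, target_domain)
        if key not in _DEFAULT_POOLS:
            raise ValueError(f"no default pool for target {target_domain!r} with modality {modality!r}")
        pool = [d for d in _DEFAULT_POOLS[key] if d in available]
        if target_domain not in pool and target_domain in available:
            pool.insert(0, target_domain)
    elif policy == "distance_rank":
        if profiles is None:
            raise ValueError("distance_rank needs domain profiles")
        tgt = profiles[target_domain]
        others = [d for d in available if d != target_domain]
        ranked = sorted(
            others, key=lambda d: (domain_distance(tgt, profiles[d]), available.index(d))
        )
        pool = [target_domain] + ranked
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if component is not None and not _component_trainable(pool, component):
        raise ValueError(
            f"component untrainable on this pool: {component!r} has a single class "
            f"across domains {pool}"
        )
    return pool


def _lr_schedule(lr0: float, t: int) -> float:
    return lr0 / np.sqrt(1.0 + t)


def train_component(tensors: FeatureTensor, component: str,
                    spec: TrainSpec | None = None,
                    cnn_spec: CNNSpec | None = None) -> TrainedModel:
    """Fit one component classifier on a pooled tensor set.

    An inner 80/20 split (stratified by class) provides the validation set;
    the checkpoint with the best validation accuracy is returned.  Fully
    reproducible for a fixed ``spec.seed``.
    """
    spec = spec or TrainSpec()
    cnn_spec = cnn_spec or CNNSpec()
    y = tensors.component_labels(component)
    if len(np.unique(y)) < 2:
        raise ValueError(f"single-class pool: cannot train {component!r}")
    x = np.ascontiguousarray(tensors.values, dtype=np.float32)

    rng = np.random.default_rng(spec.seed)
    val_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        perm = rng.permutation(cls_idx)
        n_val = max(1, int(round(spec.val_fraction * len(cls_idx))))
        val_idx.extend(perm[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)
    if len(np.unique(y[tr_idx])) < 2:
        raise ValueError("inner training split lost a class; pool too small")

    net = cnn_spec.build(tensors.depth, rng)
    opt = _nn.Adam(net.params(), lr0=spec.lr0, beta1=spec.beta1, beta2=spec.beta2)

    n_train = len(tr_idx)
    if spec.budget_mode == "presentations":
        n_epochs = max(1, int(np.ceil(spec.budget_multiplier)))
    elif spec.budget_mode == "iterations":
        total_batches = spec.budget_multiplier * n_train
        n_epochs = max(1, int(np.ceil(total_batches * spec.batch_size / n_train)))
    else:
        raise ValueError(f"unknown budget_mode {spec.budget_mode!r}")

    best = (-1.0, None)
    rows = []
    evaluations = 0
    opt.set_lr(_lr_schedule(spec.lr0, 0))
    for epoch in range(n_epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for lo in range(0, n_train, spec.batch_size):
            batch = order[lo:lo + spec.batch_size]
            logits = net.forward(x[batch])
            loss, dlogits = _nn.cross_entropy(logits, y[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {lo // spec.batch_size}; "
                    f"lr={opt.lr:.2g}, component={component}"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = float((predict_logits(net, x[va_idx]).argmax(axis=1) == y[va_idx]).mean())
        evaluations += 1
        rows.append({
            "epoch": epoch, "mean_loss": float(np.mean(losses)),
            "val_accuracy": val_acc, "lr": opt.lr,
        })
        if val_acc > best[0]:
            best = (val_acc, net.state())
        opt.set_lr(_lr_schedule(spec.lr0, evaluations))
    net.load_state(best[1])

    domains = tuple(sorted(tensors.trial_meta["domain"].unique()))
    return TrainedModel(
        net=net, component=component, depth=tensors.depth,
        cnn_spec=cnn_spec, train_spec=spec, source_domains=domains,
        log=pd.DataFrame(rows),
    )


def predict_logits(net: _nn.Sequential, x: np.ndarray, batch: int = 512) -> np.ndarray:
    out = [net.forward(np.ascontiguousarray(x[lo:lo + batch], dtype=x.dtype))
           for lo in range(0, len(x), batch)]
    return np.concatenate(out, axis=0)


def predict_proba(m: TrainedModel, t: FeatureTensor) -> np.ndarray:
    """Per-trial (p_low, p_high); rows sum to one.  p_high is the p_i that
    session averaging turns into the indicator."""
    if t.depth != m.depth:
        raise ValueError(f"tensor depth {t.depth} does not match model depth {m.depth}")
    x = np.ascontiguousarray(t.values, dtype=np.float32)
    return _nn.softmax(predict_logits(m.net, x))


@dataclass
class LopoResult:
    """Per-participant folds: held-out probabilities and fold accuracies."""

    component: str
    trial_p_high: np.ndarray            # aligned with the input tensor's trials
    trial_meta: pd.DataFrame = field(repr=False)
    accuracy_table: pd.DataFrame = field(repr=False)
    models: dict[str, TrainedModel] = field(repr=False, default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy_table["accuracy"].mean())


def _fold_seed(base: int, k: int) -> int:
    return (int(base) * 1000003 + 7919 * (k + 1)) % (2 ** 31)


def lopo_evaluate(tensors: FeatureTensor, component: str,
                  spec: TrainSpec | None = None,
                  cnn_spec: CNNSpec | None = None,
                  keep_models: bool = True) -> LopoResult:
    """Leave-one-participant-out transfer evaluation.

    Each fold trains on every other participant's trials and predicts the
    held-out participant, so test and training trials never overlap; the
    held-out probabilities partition the cohort.
    """
    spec = spec or TrainSpec()
    participants = list(dict.fromkeys(tensors.trial_meta["participant_id"]))
    if len(participants) < 2:
        raise ValueError("LOPO needs at least 2 participants")
    y = tensors.component_labels(component)
    p_high = np.full(tensors.n_trials, np.nan)
    rows = []
    models: dict[str, TrainedModel] = {}
    pid_col = tensors.trial_meta["participant_id"].to_numpy()
    for k, target in enumerate(participants):
        test_mask = pid_col == target
        train_mask = ~test_mask
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError(f"training fold for {target!r} contains a single class")
        fold_spec = spec.with_seed(_fold_seed(spec.seed, k))
        model = train_component(tensors.select_trials(train_mask), component,
                                fold_spec, cnn_spec)
        probs = predict_proba(model, tensors.select_trials(test_mask))
        p_high[test_mask] = probs[:, 1]
        acc = float(((probs[:, 1] > 0.5).astype(int) == y[test_mask]).mean())
        rows.append({"participant": target, "n_test": int(test_mask.sum()), "accuracy": acc})
        if keep_models:
            models[target] = model
    return LopoResult(
        component=component, trial_p_high=p_high, trial_meta=tensors.trial_meta,
        accuracy_table=pd.DataFrame(rows), models=models,
    )


@dataclass
class HoldoutResult:
    component: str
    train_participants: tuple[str, ...]
    test_participants: tuple[str, ...]
    test_index: np.ndarray
    test_p_high: np.ndarray
    model: TrainedModel


def holdout_evaluate(tensors: FeatureTensor, component: str,
                     train_frac: float = 0.75,
                     spec: TrainSpec | None = None,
                     cnn_spec: CNNSpec | None = None) -> HoldoutResult:
    """Single participant-level split: train on a fraction, score the rest."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    spec = spec or TrainSpec()
    participants = list(dict.fromkeys(tensors.trial_meta["participant_id"]))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(participants))
    n_train = int(round(train_frac * len(participants)))
    n_train = min(max(n_train, 1), len(participants) - 1)
    train_p = tuple(participants[i] for i in sorted(perm[:n_train]))
    test_p = tuple(participants[i] for i in sorted(perm[n_train:]))
    pid_col = tensors.trial_meta["participant_id"].to_numpy()
    train_mask = np.isin(pid_col, train_p)
    model = train_component(tensors.select_trials(train_mask), component, spec, cnn_spec)
    test_idx = np.flatnonzero(~train_mask)
    probs = predict_proba(model, tensors.select_trials(~train_mask))
    return HoldoutResult(
        component=component, train_participants=train_p, test_participants=test_p,
        test_index=test_idx, test_p_high=probs[:, 1], model=model,
    )
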