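"""Training loop, stratified cross-validation and bag-level metrics.

Bags are trained in padded mini-batches under binary cross-entropy between
the pooled bag probability and the bag label, optimized with Adam.  With
augmentation enabled, every epoch re-crops each bag longer than the crop
threshold to a random 3/4-length fragment before instancing, so the signal
does not always appear at the same position.  Model selection is by
validation average precision with early stopping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .bagging import Bag, InstanceConfig, batch_pad, make_instances, random_crop
from .model import MILModel

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 5e-3
    augment: bool = True
    seed: int = 0
    early_stop_patience: int = 15

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class MetricsReport:
    """Held-out classification metrics (accuracy at the 0.5 threshold).

    AUROC/AP are ``None`` when the evaluation set has a single class.  For
    cross-validated runs, ``per_fold`` holds one report per fold and the
    top-level values are fold means with standard deviations alongside.
    """

    auroc: float | None
    ap: float | None
    accuracy: float
    n_pos: int
    n_neg: int
    auroc_sd: float | None = None
    ap_sd: float | None = None
    accuracy_sd: float | None = None
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "auroc": self.auroc, "ap": self.ap, "accuracy": self.accuracy,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }
        if self.per_fold:
            out.update(auroc_sd=self.auroc_sd, ap_sd=self.ap_sd, accuracy_sd=self.accuracy_sd)
            out["per_fold"] = [f.to_dict() for f in self.per_fold]
        return out


def kfold_split(
    bags: Sequence[Bag], k: int = 10, rng: np.random.Generator | None = None
) -> list[list[int]]:
    """Stratified k-fold partition of bag indices.

    Positives and negatives are shuffled separately and dealt round-robin, so
    per-fold class counts differ by at most one; deterministic given the rng.
    """
    rng = rng or np.random.default_rng(0)
    pos = [i for i, b in enumerate(bags) if b.label == 1]
    neg = [i for i, b in enumerate(bags) if b.label == 0]
    if len(pos) < k or len(neg) < k:
        raise ValueError(
            f"need at least k={k} bags of each class, got {len(pos)} positive "
            f"and {len(neg)} negative"
        )
    pos = list(rng.permutation(pos))
    neg = list(rng.permutation(neg))
    folds: list[list[int]] = [[] for _ in range(k)]
    for j, i in enumerate(pos):
        folds[j % k].append(int(i))
    for j, i in enumerate(neg):
        folds[j % k].append(int(i))
    return folds


def split_bags(
    bags: Sequence[Bag], fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng: np.random.Generator | None = None,
) -> tuple[list[Bag], list[Bag], list[Bag]]:
    """Stratified train/validation/test split (default ratio 8:1:1)."""
    rng = rng or np.random.default_rng(0)
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    parts: tuple[list[Bag], list[Bag], list[Bag]] = ([], [], [])
    for label in (1, 0):
        idx = [i for i, b in enumerate(bags) if b.label == label]
        idx = list(rng.permutation(idx))
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        if fractions[1] > 0 and n_va == 0 and n > 1:
            n_va = 1  # keep the validation split populated on tiny inputs
            n_tr = min(n_tr, n - n_va)
        chunks = (idx[:n_tr], idx[n_tr : n_tr + n_va], idx[n_tr + n_va :])
        for part, chunk in zip(parts, chunks):
            part.extend(bags[i] for i in chunk)
    return parts


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def predict_bags(
    model: MILModel, bags: Sequence[Bag], inst_cfg: InstanceConfig, batch_size: int = 64
) -> np.ndarray:
    """Eval-mode bag probabilities, batched with padding."""
    probs = np.empty(len(bags))
    for lo in range(0, len(bags), batch_size):
        chunk = bags[lo : lo + batch_size]
        x, mask, _ = batch_pad([make_instances(b, inst_cfg) for b in chunk])
        p, _ = model.predict(x, mask)
        probs[lo : lo + len(chunk)] = p
    return probs


def evaluate(
    model: MILModel,
    bags: Sequence[Bag],
    inst_cfg: InstanceConfig,
    threshold: float = 0.5,
) -> MetricsReport:
    """AUROC / AP / accuracy on held-out bags (ties at the threshold count
    as positive calls)."""
    probs = predict_bags(model, bags, inst_cfg)
    labels = np.array([b.label for b in bags])
    return metrics_from_scores(probs, labels, threshold)


def metrics_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("cannot compute metrics on an empty evaluation set")
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    acc = float(((scores >= threshold).astype(int) == labels).mean())
    if n_pos == 0 or n_neg == 0:
        return MetricsReport(auroc=None, ap=None, accuracy=acc, n_pos=n_pos, n_neg=n_neg)
    return MetricsReport(
        auroc=float(roc_auc_score(labels, scores)),
        ap=float(average_precision_score(labels, scores)),
        accuracy=acc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def train(
    model: MILModel,
    train_bags: Sequence[Bag],
    val_bags: Sequence[Bag],
    cfg: TrainConfig,
    inst_cfg: InstanceConfig | None = None,
) -> tuple[MILModel, list[dict]]:
    """Fit the model by mini-batch Adam on binary cross-entropy.

    Returns the model restored to its best-validation-AP parameters plus a
    per-epoch history (loss, validation AUROC/AP).  Fully reproducible given
    ``cfg.seed``; aborts with diagnostics on a non-finite loss.
    """
    inst_cfg = inst_cfg or InstanceConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate)
    labels_all = np.array([b.label for b in train_bags], dtype=float)

    best_score, best_params, best_epoch, since_best = -np.inf, model.copy_params(), -1, 0
    history: list[dict] = []
    plain_sets = None  # instancing cache for the unaugmented path

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_bags))
        if cfg.augment:
            sets = [make_instances(random_crop(b, inst_cfg, rng), inst_cfg) for b in train_bags]
        else:
            if plain_sets is None:
                plain_sets = [make_instances(b, inst_cfg) for b in train_bags]
            sets = plain_sets
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            x, mask, _ = batch_pad([sets[i] for i in idx])
            y = labels_all[idx]
            prob, _, cache = model.forward(x, mask, train=True, rng=rng)
            p = np.clip(prob, _EPS, 1.0 - _EPS)
            loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}: "
                    f"loss={loss}, prob range [{prob.min()}, {prob.max()}]"
                )
            dprob = (p - y) / (p * (1.0 - p)) / len(y)
            grads, _ = model.backward(cache, dprob)
            opt.step(model.params, grads)
            losses.append(loss)

        val = evaluate(model, val_bags, inst_cfg)
        score = val.ap if val.ap is not None else -np.inf
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "val_auroc": val.auroc, "val_ap": val.ap}
        )
        if score > best_score:
            best_score, best_params, best_epoch, since_best = score, model.copy_params(), epoch, 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break

    model.params = best_params
    return model, history


def cross_validate(
    bags: Sequence[Bag],
    k: int,
    model_factory: Callable[[int], MILModel],
    cfg: TrainConfig,
    inst_cfg: InstanceConfig | None = None,
) -> MetricsReport:
    """k-fold cross-validation: k independently trained models, held-out
    metrics aggregated as mean with standard deviation."""
    inst_cfg = inst_cfg or InstanceConfig()
    rng = np.random.default_rng(cfg.seed)
    folds = kfold_split(bags, k, rng)
    reports: list[MetricsReport] = []
    for fi, fold in enumerate(folds):
        test = [bags[i] for i in fold]
        rest = [bags[i] for f in folds[:fi] + folds[fi + 1 :] for i in f]
        tr, va, _ = split_bags(rest, (0.9, 0.1, 0.0), np.random.default_rng(cfg.seed + fi))
        model = model_factory(cfg.seed + fi)
        fold_cfg = TrainConfig(
            epochs=cfg.epochs, batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            augment=cfg.augment, seed=cfg.seed + fi, early_stop_patience=cfg.early_stop_patience,
        )
        model, _ = train(model, tr, va, fold_cfg, inst_cfg)
        reports.append(evaluate(model, test, inst_cfg))

    def agg(vals):
        vals = [v for v in vals if v is not None]
        return (float(np.mean(vals)), float(np.std(vals))) if vals else (None, None)

    auroc, auroc_sd = agg([r.auroc for r in reports])
    ap, ap_sd = agg([r.ap for r in reports])
    acc, acc_sd = agg([r.accuracy for r in reports])
    return MetricsReport(
        auroc=auroc, ap=ap, accuracy=acc,
        n_pos=sum(r.n_pos for r in reports), n_neg=sum(r.n_neg for r in reports),
        auroc_sd=auroc_sd, ap_sd=ap_sd, accuracy_sd=acc_sd, per_fold=reports,
    )
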