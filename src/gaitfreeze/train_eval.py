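"""Training regimen, cross-validation harness and the full metric suite.

Training follows the published regimen: Adam at an initial learning rate of
0.001, held constant through epoch 100 and decayed by a factor of 0.1 per
10-epoch block thereafter; batch size 128; MSE loss on one-hot targets
(cross-entropy available); per-epoch loss and RMSE curves recorded.

Evaluation reports everything a confusion matrix supports: per-class
precision, sensitivity, specificity, accuracy and F-score, their macro
(unweighted over classes) and micro (pooled counts) averages, Cohen's
kappa, ROC AUC and RMSE — rates in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .cba_bilstm import CbaBilstm, CbaBilstmConfig, build_model
from typing import TYPE_CHECKING

from .channel_select import score_auc
from .signal_io import (
    LabeledDataset,
    ValidationError,
    apply_sequence_norm,
    fit_sequence_norm,
)

if TYPE_CHECKING:  # pragma: no cover
    from .channel_select import SelectionResult

logger = logging.getLogger("gaitfreeze")

HARD_EPOCH_CAP = 300


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    initial_lr: float = 0.001
    lr_constant_until_epoch: int = 100
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    lr_decay_mode: str = "multiplicative"  # or "subtractive"
    batch_size: int = 128
    max_epochs: int = 200
    loss: str = "mse"  # or "cross_entropy"
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs > HARD_EPOCH_CAP:
            raise ValidationError(f"max_epochs must be <= {HARD_EPOCH_CAP}")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be >= 1")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.lr_decay_mode not in ("multiplicative", "subtractive"):
            raise ValidationError(f"unknown lr_decay_mode {self.lr_decay_mode!r}")


def lr_at_epoch(epoch: int, cfg: TrainConfig | None = None) -> float:
    """Learning rate for a 1-based epoch under the constant-then-decay rule.

    The rate stays at ``initial_lr`` through ``lr_constant_until_epoch``,
    then shrinks once per ``lr_decay_every``-epoch block.  The default
    multiplicative reading multiplies by ``lr_decay_factor`` per block; the
    subtractive reading subtracts it, floored at zero.
    """
    cfg = cfg or TrainConfig()
    if epoch < 1:
        raise ValidationError("epoch must be >= 1")
    if epoch <= cfg.lr_constant_until_epoch:
        return cfg.initial_lr
    blocks = int(np.ceil((epoch - cfg.lr_constant_until_epoch) / cfg.lr_decay_every))
    if cfg.lr_decay_mode == "multiplicative":
        return cfg.initial_lr * cfg.lr_decay_factor**blocks
    return max(cfg.initial_lr - blocks * cfg.lr_decay_factor, 0.0)


def one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((y.shape[0], n_classes))
    out[np.arange(y.shape[0]), y] = 1.0
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    model: CbaBilstm, dataset: LabeledDataset, cfg: TrainConfig
) -> tuple[CbaBilstm, list[float], list[float]]:
    """Mini-batch training; returns (model, loss_curve, rmse_curve).

    Shuffling is driven by ``cfg.seed`` so a run is reproducible; training
    aborts with a diagnostic if the loss turns non-finite.
    """
    if len(dataset) == 0 or len(np.unique(dataset.y)) < 2:
        raise ValidationError("training requires a nonempty two-class dataset")
    n_classes = model.config.n_classes
    targets = one_hot(dataset.y, n_classes)
    x_all = dataset.X
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    n = len(dataset)
    loss_curve: list[float] = []
    rmse_curve: list[float] = []
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        sq_sum = 0.0
        loss_sum = 0.0
        count = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = Tensor(x_all[idx])
            tb = Tensor(targets[idx])
            probs = model.forward(xb, training=True)
            diff = probs - tb
            if cfg.loss == "mse":
                loss = (diff**2).mean()
            else:
                loss = -(tb * ad.log(probs + 1e-12)).sum(axis=1).mean()
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss.value!r})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            b = idx.size
            loss_sum += float(loss.value) * b
            sq_sum += float((diff.value**2).mean()) * b
            count += b
        loss_curve.append(loss_sum / count)
        rmse_curve.append(float(np.sqrt(sq_sum / count)))
    return model, loss_curve, rmse_curve


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, defined as 0")
        return 0.0
    return num / den


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 2) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def confusion_metrics(cm: np.ndarray) -> dict:
    """All tabulated rates (percent) from a K x K confusion matrix.

    Rows are true classes, columns predictions.  Per-class accuracy is the
    overall accuracy (single-label problem); macroAVG is the unweighted mean
    over classes; microAVG pools one-vs-rest counts, so micro precision =
    micro sensitivity = accuracy.  Zero denominators yield 0 with a flag.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any() or cm.sum() == 0:
        raise ValidationError("cm must be square, nonnegative, with a nonzero entry")
    k = cm.shape[0]
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    flags: list[str] = []
    per_class = []
    pooled = {"tp": 0.0, "fp": 0.0, "fn": 0.0, "tn": 0.0}
    for i in range(k):
        tp = float(cm[i, i])
        fp = float(cm[:, i].sum() - tp)
        fn = float(cm[i, :].sum() - tp)
        tn = float(total - tp - fp - fn)
        p = _safe_div(tp, tp + fp, flags, f"class{i}.precision")
        r = _safe_div(tp, tp + fn, flags, f"class{i}.sensitivity")
        s = _safe_div(tn, tn + fp, flags, f"class{i}.specificity")
        f1 = _safe_div(2 * p * r, p + r, flags, f"class{i}.f_score")
        per_class.append(
            {
                "precision": 100 * p,
                "sensitivity": 100 * r,
                "specificity": 100 * s,
                "accuracy": 100 * accuracy,
                "f_score": 100 * f1,
            }
        )
        for key, val in zip(("tp", "fp", "fn", "tn"), (tp, fp, fn, tn)):
            pooled[key] += val
    macro = {
        m: float(np.mean([c[m] for c in per_class]))
        for m in ("precision", "sensitivity", "specificity", "accuracy", "f_score")
    }
    mp = _safe_div(pooled["tp"], pooled["tp"] + pooled["fp"], flags, "micro.precision")
    mr = _safe_div(pooled["tp"], pooled["tp"] + pooled["fn"], flags, "micro.sensitivity")
    ms = _safe_div(pooled["tn"], pooled["tn"] + pooled["fp"], flags, "micro.specificity")
    mf = _safe_div(2 * mp * mr, mp + mr, flags, "micro.f_score")
    micro = {
        "precision": 100 * mp,
        "sensitivity": 100 * mr,
        "specificity": 100 * ms,
        "accuracy": 100 * accuracy,
        "f_score": 100 * mf,
    }
    return {
        "per_class": per_class,
        "macroAVG": macro,
        "microAVG": micro,
        "accuracy": 100 * accuracy,
        "flags": flags,
    }


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix, in percent."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        logger.warning("cohens_kappa: chance agreement is 1; kappa defined as 0")
        return 0.0
    return float(100.0 * (p_o - p_e) / (1.0 - p_e))


def roc_curve_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Empirical ROC by threshold sweep; AUC by the trapezoid rule.

    Returns (curve, auc) where ``curve`` is an array of (fpr, tpr) points.
    Agrees with the Mann-Whitney AUC estimator to floating-point precision,
    ties included (tied scores produce diagonal segments).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_curve_auc requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(np.float64)
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(1.0 - sorted_pos)
    # keep only the last point of each tied-score block
    last_of_block = np.append(np.diff(sorted_scores) != 0, True)
    tpr = np.concatenate(([0.0], tp[last_of_block] / n_pos))
    fpr = np.concatenate(([0.0], fp[last_of_block] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def rmse(predictions, targets) -> float:
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape or p.size == 0:
        raise ValidationError("rmse requires equal-length nonempty inputs")
    return float(np.sqrt(np.mean((p - t) ** 2)))


# ---------------------------------------------------------------------------
# Reports and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix plus every tabulated metric for one evaluation."""

    confusion: np.ndarray
    metrics: dict
    kappa: float
    auc: float
    rmse_value: float
    loss_curve: list[float] = field(default_factory=list)
    rmse_curve: list[float] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.tolist(),
            **self.metrics,
            "kappa": self.kappa,
            "auc": self.auc,
            "rmse": self.rmse_value,
            "loss_curve": self.loss_curve,
            "rmse_curve": self.rmse_curve,
        }


def evaluate_model(
    model: CbaBilstm,
    dataset: LabeledDataset,
    loss_curve: list[float] | None = None,
    rmse_curve: list[float] | None = None,
) -> EvalReport:
    """Inference on ``dataset`` and the complete metric suite."""
    probs = model.predict_proba(dataset.X)
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(dataset.y, preds, model.config.n_classes)
    metrics = confusion_metrics(cm)
    if len(np.unique(dataset.y)) == 2:
        _, auc = roc_curve_auc(probs[:, 1], dataset.y)
    else:
        auc = float("nan")
    targets = one_hot(dataset.y, model.config.n_classes)
    return EvalReport(
        confusion=cm,
        metrics=metrics,
        kappa=cohens_kappa(cm),
        auc=auc,
        rmse_value=rmse(probs, targets),
        loss_curve=loss_curve or [],
        rmse_curve=rmse_curve or [],
    )


def train_and_evaluate(
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    model_config: CbaBilstmConfig,
    cfg: TrainConfig,
) -> tuple[CbaBilstm, EvalReport]:
    """Normalize on the training split, train, evaluate on the held-out split.

    The fitted normalization is attached to the returned model, so it (and
    any checkpoint saved from it) scores raw sequences correctly.
    """
    lo, hi = fit_sequence_norm(train_set.X)
    tr = LabeledDataset(
        X=apply_sequence_norm(train_set.X, lo, hi),
        y=train_set.y,
        channel_ids=train_set.channel_ids,
        provenance=list(train_set.provenance),
    )
    model = build_model(model_config)
    model, loss_curve, rmse_curve = train(model, tr, cfg)
    model.input_norm = (lo, hi)
    return model, evaluate_model(model, test_set, loss_curve, rmse_curve)


def kfold_evaluate(
    dataset: LabeledDataset,
    cfg: TrainConfig,
    model_config: CbaBilstmConfig,
    seeds: list[int] | None = None,
) -> tuple[list[EvalReport], dict]:
    """Stratified k-fold CV, a fresh model per fold; optional repeated runs.

    ``seeds`` replaces the single ``cfg.seed`` to emulate repeated
    experiments; the aggregate reports the mean and standard deviation of
    accuracy, kappa and AUC over all (repeat, fold) evaluations.
    """
    if len(dataset) < cfg.folds:
        raise ValidationError("dataset smaller than the number of folds")
    seeds = seeds or [cfg.seed]
    reports: list[EvalReport] = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed)
        for fold_no, (tr_idx, te_idx) in enumerate(skf.split(dataset.X[:, 0, 0], dataset.y)):
            sub = lambda idx: LabeledDataset(  # noqa: E731
                X=dataset.X[idx],
                y=dataset.y[idx],
                channel_ids=dataset.channel_ids,
                provenance=[dataset.provenance[i] for i in idx] if dataset.provenance else [],
            )
            fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": seed + fold_no})
            fold_model_cfg = CbaBilstmConfig(
                **{**model_config.to_dict(), "conv_groups": model_config.conv_groups,
                   "seed": seed + fold_no}
            )
            _, report = train_and_evaluate(sub(tr_idx), sub(te_idx), fold_model_cfg, fold_cfg)
            reports.append(report)
    agg = {}
    for name, values in (
        ("accuracy", [r.accuracy for r in reports]),
        ("kappa", [r.kappa for r in reports]),
        ("auc", [r.auc for r in reports]),
    ):
        agg[name] = {"mean": float(np.mean(values)), "std": float(np.std(values))}
    return reports, agg


def end_to_end_synthetic(
    seed: int = 0,
    epochs: int = 40,
    syn_config=None,
    select_k: int = 5,
    select_folds: int = 10,
) -> tuple["SelectionResult", EvalReport]:
    """Full pipeline on synthetic data: simulate, select, train, evaluate.

    Channel selection runs on the training recordings only; the model is
    then trained on the selected channels and evaluated on held-out
    recordings never seen by selection or training.
    """
    from .channel_select import select_channels
    from .synthetic_data import SyntheticConfig, train_test_datasets

    syn = syn_config or SyntheticConfig(seed=seed)
    train_set, test_set = train_test_datasets(syn)
    selection = select_channels(train_set, k=select_k, folds=select_folds, fold_seed=seed)
    tr = train_set.subset_channels(selection.selected)
    te = test_set.subset_channels(selection.selected)
    model_cfg = CbaBilstmConfig(
        n_channels=len(selection.selected),
        sequence_length=tr.sequence_length,
        seed=seed,
    )
    cfg = TrainConfig(max_epochs=epochs, seed=seed)
    _, report = train_and_evaluate(tr, te, model_cfg, cfg)
    return selection, report


# cross-check hook: the two AUC routes must agree
def auc_agreement(scores, labels) -> float:
    """|trapezoid ROC AUC - Mann-Whitney AUC|; used as a self-diagnostic."""
    _, a1 = roc_curve_auc(scores, labels)
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    a2 = score_auc(scores[labels == 1], scores[labels == 0])
    return abs(a1 - a2)
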