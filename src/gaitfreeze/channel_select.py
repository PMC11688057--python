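"""Ensemble filter-based channel selection with a k-NN wrapper.

Each of the nine sensor-axis streams is scored by three filter statistics
computed on its per-timestep values pooled by class:

* empirical ROC AUC (Mann-Whitney estimator, orientation-free via
  max(AUC, 1 - AUC)),
* the standardized two-sample rank-sum statistic z (midranks, tie-corrected
  variance; |z| used for ranking),
* a signal-to-noise contrast (mu1 - mu2) / (sigma1 + sigma2).

The three per-metric rankings are fused by a Borda count and candidate
channel subsets (prefixes of the vote order) are compared by stratified
k-fold cross-validated k-NN accuracy on per-sequence mean/sd features; the
smallest prefix achieving the maximum accuracy is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .signal_io import ChannelId, LabeledDataset, ValidationError

logger = logging.getLogger("gaitfreeze")

DEFAULT_K = 5
DEFAULT_FOLDS = 10
DEFAULT_FOLD_SEED = 42

METRICS = ("auc", "wilcoxon", "snr")


# ---------------------------------------------------------------------------
# Filter scores
# ---------------------------------------------------------------------------

def score_auc(pos, neg) -> float:
    """Empirical ROC AUC: P(X_pos > X_neg) + 0.5 P(X_pos = X_neg).

    Computed exactly (ties included) through midranks, equivalent to the
    Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("score_auc requires both classes nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_informativeness(auc: float) -> float:
    """Orientation-free informativeness: max(AUC, 1 - AUC)."""
    return max(auc, 1.0 - auc)


def score_wilcoxon(group1, group2) -> float:
    """Standardized two-sample rank-sum statistic z with tie correction.

    z = (W - E[W]) / sd[W] where W is the midrank sum of ``group1`` over the
    pooled sample, E[W] = n1 (n1 + n2 + 1) / 2 and Var[W] is the rank-sum
    variance with the standard tie correction.  All pooled values identical
    gives zero variance; z is then defined as 0 with a warning.
    """
    g1 = np.asarray(group1, dtype=np.float64)
    g2 = np.asarray(group2, dtype=np.float64)
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("score_wilcoxon requires both groups nonempty")
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    expect = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum() / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        logger.warning("score_wilcoxon: zero variance (all pooled values tied); z = 0")
        return 0.0
    return float((w - expect) / np.sqrt(var))


def score_snr(pos, neg, ddof: int = 0) -> float:
    """Signal-to-noise contrast (mu1 - mu2) / (sigma1 + sigma2).

    Population standard deviations (ddof=0) are used so the score is exactly
    invariant under duplicating the sample.  A zero denominator with
    distinct means returns signed infinity (ranked top, with a warning);
    with equal means the score is 0.
    """
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("score_snr requires >= 2 values per class")
    num = pos.mean() - neg.mean()
    den = pos.std(ddof=ddof) + neg.std(ddof=ddof)
    if den == 0.0:
        if num == 0.0:
            return 0.0
        logger.warning("score_snr: zero pooled spread; returning signed infinity")
        return float(np.sign(num) * np.inf)
    return float(num / den)


# ---------------------------------------------------------------------------
# Per-channel score table and vote fusion
# ---------------------------------------------------------------------------

@dataclass
class ChannelScoreTable:
    """Three filter metrics and per-metric ranks for every candidate channel."""

    channel_ids: tuple[ChannelId, ...]
    auc: np.ndarray
    wilcoxon_z: np.ndarray
    snr: np.ndarray
    ranks: dict[str, np.ndarray] = field(default_factory=dict)  # metric -> midranks, 1=best

    def informativeness(self, metric: str) -> np.ndarray:
        """Orientation-free effect size used for ranking a metric."""
        if metric == "auc":
            return np.maximum(self.auc, 1.0 - self.auc)
        if metric == "wilcoxon":
            return np.abs(self.wilcoxon_z)
        if metric == "snr":
            return np.abs(self.snr)
        raise ValidationError(f"unknown metric {metric!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "channel": [c.index for c in self.channel_ids],
                "site_axis": [f"{c.site}/{c.axis}" for c in self.channel_ids],
                "auc": self.auc,
                "wilcoxon_z": self.wilcoxon_z,
                "snr": self.snr,
            }
        )
        for m, r in self.ranks.items():
            df[f"rank_{m}"] = r
        return df


def score_channels(dataset: LabeledDataset, metrics=METRICS) -> ChannelScoreTable:
    """Score every channel of ``dataset`` with the three filter metrics.

    The per-timestep values of each channel are pooled by class (FoG
    sequences vs normal sequences) and fed to the scorers; ranks are
    assigned per metric on the orientation-free informativeness, midranks
    on ties, rank 1 = most informative.
    """
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValidationError("score_channels requires both classes present")
    pos = dataset.X[y == 1]  # FoG
    neg = dataset.X[y == 0]
    n_ch = len(dataset.channel_ids)
    auc = np.empty(n_ch)
    wz = np.empty(n_ch)
    snr = np.empty(n_ch)
    for c in range(n_ch):
        p = pos[:, :, c].ravel()
        n = neg[:, :, c].ravel()
        auc[c] = score_auc(p, n)
        wz[c] = score_wilcoxon(p, n)
        snr[c] = score_snr(p, n)
    table = ChannelScoreTable(
        channel_ids=dataset.channel_ids, auc=auc, wilcoxon_z=wz, snr=snr
    )
    for m in metrics:
        info = table.informativeness(m)
        # rank 1 = largest informativeness; midranks on ties; +/-inf handled by order
        table.ranks[m] = rankdata(-info)
    return table


def ensemble_vote(table: ChannelScoreTable) -> tuple[list[ChannelId], np.ndarray]:
    """Fuse the per-metric rankings by a Borda count.

    Each metric awards a channel (C - rank) points; votes are summed over
    metrics.  Ties are broken by the mean min-max-normalized
    informativeness across metrics, then by channel index.
    """
    n_ch = len(table.channel_ids)
    metrics = list(table.ranks)
    votes = np.zeros(n_ch)
    for m in metrics:
        votes += n_ch - table.ranks[m]
    norm_scores = np.zeros(n_ch)
    for m in metrics:
        info = table.informativeness(m)
        finite = np.isfinite(info)
        if finite.any():
            lo, hi = info[finite].min(), info[finite].max()
        else:
            lo, hi = 0.0, 0.0
        info = np.clip(info, lo, hi)  # infinities pinned to the extremes
        norm_scores += (info - lo) / (hi - lo) if hi > lo else np.zeros(n_ch)
    norm_scores /= max(len(metrics), 1)
    order = sorted(
        range(n_ch),
        key=lambda c: (-votes[c], -norm_scores[c], table.channel_ids[c].index),
    )
    return [table.channel_ids[c] for c in order], votes


# ---------------------------------------------------------------------------
# k-NN cross-validation wrapper
# ---------------------------------------------------------------------------

def _sequence_features(dataset: LabeledDataset, channels) -> np.ndarray:
    """Per-example summary: mean and sd of each channel over the sequence."""
    idx = [dataset.channel_ids.index(c) for c in channels]
    x = dataset.X[:, :, idx]
    return np.concatenate([x.mean(axis=1), x.std(axis=1)], axis=1)


def _knn_predict(train_x, train_y, test_x, k: int) -> np.ndarray:
    """Majority-vote k-NN with a distance-weighted tie-break."""
    nn = NearestNeighbors(n_neighbors=k).fit(train_x)
    dist, ind = nn.kneighbors(test_x)
    labels = train_y[ind]  # (n_test, k)
    pred = np.empty(labels.shape[0], dtype=np.int64)
    inv = 1.0 / np.maximum(dist, 1e-12)
    for i in range(labels.shape[0]):
        counts = np.bincount(labels[i], minlength=2)
        top = np.flatnonzero(counts == counts.max())
        if top.size == 1:
            pred[i] = top[0]
        else:  # tie: sum of inverse neighbour distances decides
            weights = np.bincount(labels[i], weights=inv[i], minlength=2)
            pred[i] = int(np.argmax(weights))
    return pred


def knn_cv_accuracy(
    dataset: LabeledDataset,
    channels,
    k: int = DEFAULT_K,
    folds: int = DEFAULT_FOLDS,
    fold_seed: int = DEFAULT_FOLD_SEED,
) -> float:
    """Mean stratified k-fold CV accuracy of k-NN on mean/sd features.

    Deterministic given ``fold_seed``.  Raises if ``k`` exceeds the smallest
    training fold.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(dataset) < folds:
        raise ValidationError("dataset smaller than the number of folds")
    feats = _sequence_features(dataset, channels)
    y = dataset.y
    min_train = len(dataset) - int(np.ceil(len(dataset) / folds))
    if k > min_train:
        raise ValidationError(f"k={k} exceeds smallest training fold ({min_train})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    accs = []
    for tr, te in skf.split(feats, y):
        pred = _knn_predict(feats[tr], y[tr], feats[te], k)
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


@dataclass
class SelectionResult:
    """Outcome of the full selection stage."""

    ordered_channels: list[ChannelId]
    votes: np.ndarray
    subset_trace: list[tuple[tuple[ChannelId, ...], float]]
    selected: tuple[ChannelId, ...]
    k: int
    folds: int
    table: ChannelScoreTable | None = None

    def to_dict(self) -> dict:
        return {
            "ordered_channels": [c.index for c in self.ordered_channels],
            "votes": {str(c.index): float(v) for c, v in zip(self.ordered_channels, self.votes)},
            "subset_trace": [
                {"channels": [c.index for c in subset], "cv_accuracy": acc}
                for subset, acc in self.subset_trace
            ],
            "selected": [c.index for c in self.selected],
            "k": self.k,
            "folds": self.folds,
            "scores": self.table.to_frame().to_dict(orient="records") if self.table else None,
        }


def select_channels(
    dataset: LabeledDataset,
    k: int = DEFAULT_K,
    folds: int = DEFAULT_FOLDS,
    fold_seed: int = DEFAULT_FOLD_SEED,
    metrics=METRICS,
) -> SelectionResult:
    """Full selection: score, vote, then evaluate incremental prefixes.

    Prefixes of the vote order of sizes 1..C are scored by k-NN CV accuracy;
    the smallest prefix achieving the maximum accuracy is selected.
    """
    table = score_channels(dataset, metrics=metrics)
    ordered, votes_raw = ensemble_vote(table)
    votes = np.array(
        [votes_raw[table.channel_ids.index(c)] for c in ordered]
    )
    trace = []
    for size in range(1, len(ordered) + 1):
        subset = tuple(ordered[:size])
        acc = knn_cv_accuracy(dataset, subset, k=k, folds=folds, fold_seed=fold_seed)
        trace.append((subset, acc))
    best_acc = max(acc for _, acc in trace)
    selected = next(subset for subset, acc in trace if acc == best_acc)
    return SelectionResult(
        ordered_channels=ordered,
        votes=votes,
        subset_trace=trace,
        selected=selected,
        k=k,
        folds=folds,
        table=table,
    )
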