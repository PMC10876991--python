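"""The semi-supervised core: out-of-fold prediction, consistency
filtering, threshold pseudo-labeling, grid search and retraining.

The labeled training set is partitioned into k (default 5) folds; a model
trained on each leave-one-fold-out subset scores the whole unlabeled
pool, giving each pool variant k probabilities. Variants whose k
probabilities are consistently away from the 0.5 decision boundary (a
two-sided one-sample Student's t-test against 0.5 at p < 0.05) are kept.
Symmetric thresholds 0.5 +/- delta then turn the mean probability into a
pseudo-label: above the upper cut -> positive, below the lower cut ->
negative, in between -> discarded. The delta is chosen by grid search
(delta in {0, 0.1, 0.2, 0.3, 0.4}) on held-out AUC after retraining on
the merged labeled + pseudo-labeled set; of the k retrained fold models
the one with the best held-out-fold AUC is the final model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cnn import ArchitectureSpec, TrainConfig, TrainedModel, score, train
from .evaluate import roc_auc
from .features import AnnotationMatrix

__all__ = [
    "FoldPredictions", "ThresholdPair", "PseudoLabelSet",
    "crossval_fold_predictions", "ttest_consistency_filter",
    "assign_pseudo_labels", "threshold_grid_search", "augment_and_retrain",
]

_SEED_MOD = 2**31 - 1


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 100_003 + fold + 1) % _SEED_MOD


@dataclass
class FoldPredictions:
    """Per-pool-variant out-of-fold probabilities (variants x k folds)."""

    variant_keys: list[str]
    probs: np.ndarray
    fold_assignment: np.ndarray  # labeled-set partition used for training

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != len(self.variant_keys):
            raise ValueError("probs must be (n_variants, k)")
        if self.probs.size and ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.probs.shape[1]

    def __len__(self) -> int:
        return len(self.variant_keys)

    def mean_probs(self) -> np.ndarray:
        return self.probs.mean(axis=1)

    def subset(self, mask: np.ndarray) -> "FoldPredictions":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return FoldPredictions(
            [self.variant_keys[i] for i in idx],
            self.probs[idx],
            self.fold_assignment,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probs, columns=[f"p{j + 1}" for j in range(self.k)]
        )
        df.insert(0, "variant", self.variant_keys)
        df["mean"] = self.mean_probs()
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ThresholdPair:
    """Symmetric pseudo-labeling cuts 0.5 +/- delta."""

    upper: float
    lower: float
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= 0.5 <= self.upper <= 1.0):
            raise ValueError("need 0 <= lower <= 0.5 <= upper <= 1")
        if not (
            np.isclose(self.upper, 0.5 + self.delta)
            and np.isclose(self.lower, 0.5 - self.delta)
        ):
            raise ValueError("pair must be 0.5 +/- delta")

    @classmethod
    def from_delta(cls, delta: float) -> "ThresholdPair":
        if not (0.0 <= delta <= 0.5):
            raise ValueError("delta must lie in [0, 0.5]")
        return cls(round(0.5 + delta, 12), round(0.5 - delta, 12), delta)


@dataclass
class PseudoLabelSet:
    """Pool variants that received a pseudo-label, with provenance."""

    variant_keys: list[str]
    pseudo_labels: np.ndarray
    mean_probs: np.ndarray
    n_discarded: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pseudo_labels = np.asarray(self.pseudo_labels, dtype=int)
        self.mean_probs = np.asarray(self.mean_probs, dtype=float)
        if not (
            len(self.variant_keys)
            == len(self.pseudo_labels)
            == len(self.mean_probs)
        ):
            raise ValueError("keys, labels and means must align")

    def __len__(self) -> int:
        return len(self.variant_keys)

    @property
    def n_pos(self) -> int:
        return int((self.pseudo_labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.pseudo_labels == 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_keys,
                "mean": self.mean_probs,
                "label": self.pseudo_labels,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_labeled(labeled: AnnotationMatrix, k: int) -> np.ndarray:
    if labeled.labels is None:
        raise ValueError("labeled matrix must carry labels")
    if len(np.unique(labeled.labels)) < 2:
        raise ValueError("labeled set must contain both classes")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > labeled.n_variants:
        raise ValueError(f"k = {k} exceeds labeled-set size {labeled.n_variants}")
    return labeled.labels


def crossval_fold_predictions(
    labeled: AnnotationMatrix,
    unlabeled: AnnotationMatrix,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> FoldPredictions:
    """Score the whole pool with each of k leave-one-fold-out models.

    The labeled set is split into k seeded, stratified folds; the model
    trained without fold j contributes probability column j for every
    pool variant.
    """
    spec = spec or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    y = _check_labeled(labeled, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
    probs = np.empty((unlabeled.n_variants, k), dtype=float)
    assignment = np.empty(labeled.n_variants, dtype=int)
    for j, (train_idx, held_idx) in enumerate(skf.split(labeled.values, y)):
        assignment[held_idx] = j
        fold_cfg = TrainConfig(
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=_fold_seed(seed, j),
            beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps,
        )
        model = train(labeled.subset_rows(train_idx), spec, fold_cfg)
        probs[:, j] = score(model, unlabeled)
    return FoldPredictions(list(unlabeled.row_keys), probs, assignment)


def ttest_consistency_filter(
    fp: FoldPredictions, alpha: float = 0.05, null_mean: float = 0.5
) -> FoldPredictions:
    """Keep variants whose fold probabilities sit consistently off 0.5.

    Two-sided one-sample Student's t-test of each variant's k
    probabilities against ``null_mean``; retained iff p < ``alpha``.
    Zero-variance rows (all k probabilities identical) are maximally
    consistent, so they are retained iff their common value differs from
    ``null_mean``.
    """
    if fp.k < 2:
        raise ValueError("need at least 2 folds for a t-test")
    means = fp.probs.mean(axis=1)
    sds = fp.probs.std(axis=1, ddof=1)
    retained = np.zeros(len(fp), dtype=bool)
    degenerate = sds == 0.0
    retained[degenerate] = means[degenerate] != null_mean
    if (~degenerate).any():
        res = stats.ttest_1samp(fp.probs[~degenerate], null_mean, axis=1)
        retained[~degenerate] = res.pvalue < alpha
    return fp.subset(retained)


def assign_pseudo_labels(
    fp: FoldPredictions, pair: ThresholdPair
) -> PseudoLabelSet:
    """Label by mean probability: above upper -> 1, below lower -> 0.

    Variants with mean probability inside [lower, upper] are discarded;
    retained plus discarded always equals the input count.
    """
    means = fp.mean_probs()
    pos = means > pair.upper
    neg = means < pair.lower
    keep = pos | neg
    idx = np.flatnonzero(keep)
    return PseudoLabelSet(
        variant_keys=[fp.variant_keys[i] for i in idx],
        pseudo_labels=pos[idx].astype(int),
        mean_probs=means[idx],
        n_discarded=int((~keep).sum()),
        provenance={"upper": pair.upper, "lower": pair.lower, "delta": pair.delta},
    )


def _merge(
    labeled: AnnotationMatrix, pseudo: PseudoLabelSet, pool: AnnotationMatrix
) -> AnnotationMatrix:
    overlap = set(pseudo.variant_keys) & set(labeled.row_keys)
    if overlap:
        raise ValueError(f"pseudo-labeled keys overlap the labeled set: {sorted(overlap)[:5]}")
    if list(pool.feature_names) != list(labeled.feature_names):
        raise ValueError("pool and labeled matrices must share feature columns")
    pos_of = {k: i for i, k in enumerate(pool.row_keys)}
    idx = [pos_of[k] for k in pseudo.variant_keys]
    values = np.vstack([labeled.values, pool.values[idx]])
    labels = np.r_[labeled.labels, pseudo.pseudo_labels]
    keys = list(labeled.row_keys) + list(pseudo.variant_keys)
    return AnnotationMatrix(keys, list(labeled.feature_names), values, labels)


def augment_and_retrain(
    labeled: AnnotationMatrix,
    pseudo: PseudoLabelSet,
    pool: AnnotationMatrix,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Retrain on labeled + pseudo-labeled variants under k-fold CV.

    The merged set (pseudo-labeled examples weighted equally with labeled
    ones) is trained k-fold; of the k fold models the one with the
    highest held-out-fold AUC is returned as the final model. An empty
    pseudo set degenerates to plain k-fold training on the labeled data.
    """
    spec = spec or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    merged = _merge(labeled, pseudo, pool) if len(pseudo) else labeled
    y = _check_labeled(merged, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
    best_model, best_auc = None, -np.inf
    for j, (train_idx, held_idx) in enumerate(skf.split(merged.values, y)):
        fold_cfg = TrainConfig(
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=_fold_seed(seed, j),
            beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps,
        )
        model = train(merged.subset_rows(train_idx), spec, fold_cfg)
        held = merged.subset_rows(held_idx)
        try:
            auc = roc_auc(score(model, held), held.labels)
        except ValueError:  # held-out fold single-class at tiny n
            auc = 0.5
        model.provenance["heldout_fold_auc"] = auc
        model.provenance["fold"] = j
        if auc > best_auc:
            best_model, best_auc = model, auc
    assert best_model is not None
    best_model.provenance["n_merged"] = merged.n_variants
    return best_model


def threshold_grid_search(
    labeled_train: AnnotationMatrix,
    unlabeled: AnnotationMatrix,
    test_set: AnnotationMatrix,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    deltas: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
    k: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[ThresholdPair, pd.DataFrame]:
    """Pick the threshold pair whose retrained model maximizes test AUC.

    For every delta: t-test-filter the out-of-fold pool predictions,
    pseudo-label at 0.5 +/- delta, merge with the labeled training set,
    retrain under k-fold CV and evaluate the resulting model's AUC on
    ``test_set``. Returns the best pair (ties broken toward larger delta,
    i.e. stricter labels) and the full per-delta report.
    """
    if len(deltas) == 0:
        raise ValueError("deltas grid must be non-empty")
    if test_set.labels is None:
        raise ValueError("test_set must carry labels")
    overlap = (set(test_set.row_keys) & set(labeled_train.row_keys)) | (
        set(test_set.row_keys) & set(unlabeled.row_keys)
    )
    if overlap:
        raise ValueError(f"test set overlaps training inputs: {sorted(overlap)[:5]}")
    fp = crossval_fold_predictions(labeled_train, unlabeled, spec, cfg, k=k, seed=seed)
    retained = ttest_consistency_filter(fp, alpha=alpha)
    rows = []
    best_pair, best_auc = None, -np.inf
    for delta in sorted(deltas):
        pair = ThresholdPair.from_delta(delta)
        pseudo = assign_pseudo_labels(retained, pair)
        model = augment_and_retrain(
            labeled_train, pseudo, unlabeled, spec, cfg, k=k, seed=seed
        )
        auc = roc_auc(score(model, test_set), test_set.labels)
        rows.append(
            {
                "delta": delta, "upper": pair.upper, "lower": pair.lower,
                "n_pos": pseudo.n_pos, "n_neg": pseudo.n_neg,
                "n_discarded": pseudo.n_discarded, "auc": auc,
            }
        )
        if auc >= best_auc:  # >= so equal AUC prefers the larger delta
            best_pair, best_auc = pair, auc
    assert best_pair is not None
    return best_pair, pd.DataFrame(rows)
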