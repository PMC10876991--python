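"""Model/Results facade over the pipeline.

:class:`SscNova` bundles a labeled annotation matrix and (optionally) an
unlabeled pool; :meth:`SscNova.fit` runs either plain supervised training
or the full semi-supervised procedure (out-of-fold pool prediction,
t-test consistency filter, threshold pseudo-labeling, retraining) and
returns a :class:`SscNovaResults` carrying the fitted network, the
pseudo-label set, held-out metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cnn import (
    ArchitectureSpec, TrainConfig, TrainedModel, choose_threshold, score, train,
)
from .evaluate import MetricsReport, classification_metrics
from .features import AnnotationMatrix
from .pseudolabel import (
    PseudoLabelSet, ThresholdPair, assign_pseudo_labels, augment_and_retrain,
    crossval_fold_predictions, threshold_grid_search, ttest_consistency_filter,
)

__all__ = ["SscNova", "SscNovaResults", "split_matrix"]


def split_matrix(
    m: AnnotationMatrix, test_frac: float = 0.2, seed: int = 0
) -> tuple[AnnotationMatrix, AnnotationMatrix]:
    """Uniform shuffled row split; test size is round-half-up."""
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must lie in (0, 1)")
    n = m.n_variants
    n_test = int(np.floor(test_frac * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return m.subset_rows(perm[n_test:]), m.subset_rows(perm[:n_test])


class SscNova:
    """Semi-supervised regulatory-variant classifier.

    Parameters
    ----------
    labeled
        Annotation matrix with binary labels (1 = functional/positive).
    unlabeled
        Optional pool matrix sharing the labeled feature columns; when
        present, :meth:`fit` runs the semi-supervised procedure.
    spec, train_config
        Network architecture and optimization settings; defaults follow
        the reference configuration (input 141, two conv blocks, dense
        16, dropout 0.1; Adam lr 0.001, 50 epochs).
    """

    def __init__(
        self,
        labeled: AnnotationMatrix,
        unlabeled: AnnotationMatrix | None = None,
        spec: ArchitectureSpec | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        if labeled.labels is None:
            raise ValueError("labeled matrix must carry labels")
        if unlabeled is not None and list(unlabeled.feature_names) != list(
            labeled.feature_names
        ):
            raise ValueError("unlabeled pool must share the labeled feature columns")
        self.labeled = labeled
        self.unlabeled = unlabeled
        self.spec = spec or ArchitectureSpec(input_len=labeled.n_features)
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        variant_col: str = "variant",
        unlabeled: pd.DataFrame | None = None,
        **kwargs,
    ) -> "SscNova":
        """Build from DataFrames with a variant-key column and, for the
        labeled frame, a binary label column."""

        def to_matrix(frame: pd.DataFrame, with_labels: bool) -> AnnotationMatrix:
            frame = frame.copy()
            labels = frame.pop(label_col).to_numpy() if with_labels else None
            keys = frame.pop(variant_col).astype(str).tolist()
            return AnnotationMatrix(
                keys, list(frame.columns), frame.to_numpy(dtype=float), labels
            )

        pool = None if unlabeled is None else to_matrix(unlabeled, False)
        return cls(to_matrix(df, True), pool, **kwargs)

    def fit(
        self,
        delta: float = 0.4,
        deltas: Sequence[float] | None = None,
        eval_frac: float = 0.2,
        k: int = 5,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> "SscNovaResults":
        """Train and evaluate on an internal held-out split.

        With no unlabeled pool this is plain supervised training. With a
        pool, the pool is pseudo-labeled at the pair 0.5 +/- ``delta``
        (default 0.4, i.e. the 0.9/0.1 rule) — or, if ``deltas`` is
        given, the pair is chosen by grid search on held-out AUC — and
        the model is retrained on the augmented set.
        """
        train_m, eval_m = split_matrix(self.labeled, eval_frac, seed)
        pseudo: PseudoLabelSet | None = None
        grid_report: pd.DataFrame | None = None
        pair: ThresholdPair | None = None
        if self.unlabeled is None:
            cfg = TrainConfig(
                learning_rate=self.train_config.learning_rate,
                epochs=self.train_config.epochs,
                batch_size=self.train_config.batch_size,
                seed=seed,
                beta1=self.train_config.beta1,
                beta2=self.train_config.beta2,
                eps=self.train_config.eps,
            )
            model = train(train_m, self.spec, cfg)
        elif deltas is not None:
            pair, grid_report = threshold_grid_search(
                train_m, self.unlabeled, eval_m, self.spec, self.train_config,
                deltas=deltas, k=k, alpha=alpha, seed=seed,
            )
            fp = crossval_fold_predictions(
                train_m, self.unlabeled, self.spec, self.train_config, k=k, seed=seed
            )
            pseudo = assign_pseudo_labels(ttest_consistency_filter(fp, alpha), pair)
            model = augment_and_retrain(
                train_m, pseudo, self.unlabeled, self.spec, self.train_config,
                k=k, seed=seed,
            )
        else:
            pair = ThresholdPair.from_delta(delta)
            fp = crossval_fold_predictions(
                train_m, self.unlabeled, self.spec, self.train_config, k=k, seed=seed
            )
            pseudo = assign_pseudo_labels(ttest_consistency_filter(fp, alpha), pair)
            model = augment_and_retrain(
                train_m, pseudo, self.unlabeled, self.spec, self.train_config,
                k=k, seed=seed,
            )
        eval_scores = score(model, eval_m)
        threshold = choose_threshold(eval_scores, eval_m.labels)
        metrics = classification_metrics(eval_scores, eval_m.labels, threshold)
        return SscNovaResults(
            model=model,
            spec=self.spec,
            pair=pair,
            pseudo=pseudo,
            grid_report=grid_report,
            threshold=threshold,
            eval_metrics=metrics,
            n_labeled_train=train_m.n_variants,
            n_eval=eval_m.n_variants,
            seed=seed,
        )


@dataclass
class SscNovaResults:
    """Fit results: the network, the pseudo-label audit trail and metrics."""

    model: TrainedModel
    spec: ArchitectureSpec
    pair: ThresholdPair | None
    pseudo: PseudoLabelSet | None
    grid_report: pd.DataFrame | None
    threshold: float
    eval_metrics: MetricsReport
    n_labeled_train: int
    n_eval: int
    seed: int
    _extra: dict = field(default_factory=dict)

    def predict(self, m: AnnotationMatrix | np.ndarray) -> np.ndarray:
        """Functional-significance score (positive-class probability) per row."""
        return score(self.model, m)

    def classify(self, m: AnnotationMatrix | np.ndarray) -> np.ndarray:
        """Binary call at the held-out-optimal threshold (score > t)."""
        return (self.predict(m) > self.threshold).astype(int)

    def summary(self) -> str:
        mode = "semi-supervised" if self.pseudo is not None else "supervised"
        lines = [
            "sscNOVA fit results".center(58),
            "=" * 58,
            f"{'Mode:':<28}{mode}",
            f"{'Labeled (train/eval):':<28}{self.n_labeled_train} / {self.n_eval}",
            f"{'Input features:':<28}{self.spec.input_len}",
            f"{'Training epochs:':<28}{len(self.model.training_history)}",
            f"{'Seed:':<28}{self.seed}",
        ]
        if self.pseudo is not None and self.pair is not None:
            lines += [
                f"{'Threshold pair (delta):':<28}"
                f"{self.pair.upper:.2f} / {self.pair.lower:.2f} ({self.pair.delta:.2f})",
                f"{'Pseudo-labels (+/-/drop):':<28}"
                f"{self.pseudo.n_pos} / {self.pseudo.n_neg} / {self.pseudo.n_discarded}",
            ]
        m = self.eval_metrics
        lines += [
            "-" * 58,
            "Held-out evaluation",
            f"{'AUC:':<28}{m.auc:.4f}",
            f"{'AUPRC:':<28}{m.auprc:.4f}",
            f"{'Accuracy:':<28}{m.accuracy:.4f}",
            f"{'Precision:':<28}{m.precision:.4f}",
            f"{'Recall:':<28}{m.recall:.4f}",
            f"{'F1:':<28}{m.f1:.4f}",
            f"{'Specificity:':<28}{m.specificity:.4f}",
            f"{'Decision threshold:':<28}{self.threshold:.4f}",
            "=" * 58,
        ]
        return "\n".join(lines)
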