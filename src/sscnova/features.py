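"""Annotation matrices and feature selection.

A wide per-variant annotation matrix (e.g. thousands of chromatin-profile
features) is reduced to an informative subset in two stages: a name-based
filter (e.g. keep features derived from immune cell types), then a ranking
by either mutual information with the label or random-forest impurity
importance, keeping the top k columns (k = 141 by default downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif

__all__ = [
    "AnnotationMatrix", "FeatureSubset", "EmptySelectionError",
    "subset_features_by_name", "mutual_information_scores",
    "rf_importance_scores", "select_top_k",
]


class EmptySelectionError(ValueError):
    """A name predicate matched no features."""


@dataclass
class AnnotationMatrix:
    """Variants x named numeric features, with optional binary labels.

    ``row_keys`` are opaque per-variant identifiers (strings); values must
    be a dense float matrix with no missing entries.
    """

    row_keys: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.row_keys) != n:
            raise ValueError(f"{len(self.row_keys)} row keys for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("values must not contain missing entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != n:
                raise ValueError(f"{len(self.labels)} labels for {n} rows")
            if self.labels.size and not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary 0/1")

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "AnnotationMatrix":
        idx = np.asarray(idx)
        return AnnotationMatrix(
            [self.row_keys[i] for i in idx],
            list(self.feature_names),
            self.values[idx],
            None if self.labels is None else self.labels[idx],
        )

    def subset_columns(self, names: Sequence[str]) -> "AnnotationMatrix":
        pos = {n: i for i, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return AnnotationMatrix(
            list(self.row_keys), list(names), self.values[:, idx], self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "variant", self.row_keys)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AnnotationMatrix":
        df = pd.read_csv(path, sep="\t")
        if "variant" not in df.columns:
            raise ValueError("matrix TSV must have a 'variant' column")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        keys = df.pop("variant").astype(str).tolist()
        return cls(keys, list(df.columns), df.to_numpy(dtype=float), labels)


@dataclass
class FeatureSubset:
    """An ordered feature selection: names with their ranking scores."""

    names: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores must align")

    def __len__(self) -> int:
        return len(self.names)

    def write_tsv(self, path) -> None:
        pd.DataFrame({"feature": self.names, "score": self.scores}).to_csv(
            path, sep="\t", index=False
        )


def subset_features_by_name(
    m: AnnotationMatrix, predicate: Callable[[str], bool] | Sequence[str]
) -> AnnotationMatrix:
    """Column-filter a matrix by feature name.

    ``predicate`` is either a boolean function over names or an explicit
    collection of names to keep. Row order and relative column order are
    preserved. Raises :class:`EmptySelectionError` if nothing matches.
    """
    if callable(predicate):
        keep = [n for n in m.feature_names if predicate(n)]
    else:
        wanted = set(predicate)
        keep = [n for n in m.feature_names if n in wanted]
    if not keep:
        raise EmptySelectionError("feature-name predicate matched no columns")
    return m.subset_columns(keep)


def _check_two_classes(m: AnnotationMatrix) -> np.ndarray:
    if m.labels is None:
        raise ValueError("matrix has no labels")
    if len(np.unique(m.labels)) < 2:
        raise ValueError("labels must contain both classes")
    return m.labels


def mutual_information_scores(
    m: AnnotationMatrix, n_neighbors: int = 3, seed: int = 0
) -> FeatureSubset:
    """Estimate mutual information (nats) between each feature and the label.

    Uses a nearest-neighbor estimator for continuous features; scores are
    nonnegative, zero for features independent of the label.
    """
    y = _check_two_classes(m)
    scores = mutual_info_classif(
        m.values, y, n_neighbors=n_neighbors, random_state=seed
    )
    return FeatureSubset(list(m.feature_names), scores, "mutual_information")


def rf_importance_scores(
    m: AnnotationMatrix, n_trees: int = 500, seed: int = 0
) -> FeatureSubset:
    """Gini impurity importances from a random forest (sum to 1)."""
    y = _check_two_classes(m)
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        random_state=seed, n_jobs=1,
    )
    forest.fit(m.values, y)
    return FeatureSubset(
        list(m.feature_names), forest.feature_importances_, "forest_importance"
    )


def select_top_k(scores: FeatureSubset, k: int) -> FeatureSubset:
    """Keep the k highest-scoring features; ties keep the earlier column."""
    if not (1 <= k <= len(scores)):
        raise ValueError(f"k must lie in [1, {len(scores)}], got {k}")
    order = np.argsort(-scores.scores, kind="stable")[:k]
    return FeatureSubset(
        [scores.names[i] for i in order], scores.scores[order], scores.method
    )
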