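"""Synthetic inputs for the whole pipeline.

Real inputs to this kind of variant-prioritization pipeline are large
downloads (association catalogues, eQTL tables, chromatin-model
annotations). This module generates structurally equivalent stand-ins so
every downstream stage can be exercised and audited offline:

* labeled annotation matrices drawn from two class-conditional Gaussians,
  where a configurable number of "signal" columns is mean-shifted by
  ``effect`` in the positive class and everything else is pure noise —
  this makes the Bayes-optimal AUC analytic (``Phi(d / sqrt(2))`` with
  ``d = effect * sqrt(n_informative) / noise_sd``), which the tests use
  as an oracle;
* mock eQTL association tables (a significant table nested inside a full
  table) with a planted number of rows passing the negative-selection
  filter P > 0.1 and AF > 0.3;
* toy VCF files;
* an unlabeled pool from the same generative process, whose ground-truth
  class is returned out-of-band so pseudo-label precision can be audited
  without leaking truth into the pipeline.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import AnnotationMatrix
from .variants import VariantRecord, write_vcf

__all__ = [
    "SimulationConfig", "simulate_annotation_dataset", "simulate_eqtl_tables",
    "simulate_vcf", "simulate_unlabeled_pool", "bayes_auc",
]

# distinct substream tags so the labeled set, tables and pool are
# independent draws under one config seed
_TAG_LABELED, _TAG_TABLES, _TAG_POOL = 1, 2, 3


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the synthetic study.

    ``effect`` is the mean shift (in feature units) of each informative
    column in the positive class; ``noise_sd`` the common within-class
    standard deviation; ``unlabeled_prevalence`` the fraction of hidden
    positives in the unlabeled pool.
    """

    n_pos: int = 500
    n_neg: int = 500
    n_features: int = 141
    n_informative: int = 20
    effect: float = 3.0
    noise_sd: float = 1.0
    n_unlabeled: int = 2000
    unlabeled_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_features", "n_informative", "n_unlabeled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds "
                f"n_features ({self.n_features})"
            )
        if not (0.0 <= self.unlabeled_prevalence <= 1.0):
            raise ValueError("unlabeled_prevalence must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def feature_names(self) -> list[str]:
        """Column names; ``signal_*`` columns carry the planted class shift."""
        width = max(4, len(str(self.n_features)))
        names = [f"signal_{i + 1:0{width}d}" for i in range(self.n_informative)]
        names += [
            f"noise_{i + 1:0{width}d}"
            for i in range(self.n_features - self.n_informative)
        ]
        return names

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def bayes_auc(config: SimulationConfig) -> float:
    """Analytic AUC of the Bayes-optimal classifier for this configuration."""
    from scipy.stats import norm

    d = config.effect * np.sqrt(config.n_informative) / config.noise_sd
    return float(norm.cdf(d / np.sqrt(2.0)))


def _draw_class_matrix(
    rng: np.random.Generator, n: int, config: SimulationConfig, positive: bool
) -> np.ndarray:
    x = rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    if positive and config.n_informative:
        x[:, : config.n_informative] += config.effect
    return x


def simulate_annotation_dataset(config: SimulationConfig) -> AnnotationMatrix:
    """Labeled annotation matrix: ``n_pos`` positives then ``n_neg`` negatives."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_LABELED]))
    xp = _draw_class_matrix(rng, config.n_pos, config, positive=True)
    xn = _draw_class_matrix(rng, config.n_neg, config, positive=False)
    keys = [f"pos_{i + 1:05d}" for i in range(config.n_pos)]
    keys += [f"neg_{i + 1:05d}" for i in range(config.n_neg)]
    labels = np.r_[np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    return AnnotationMatrix(keys, config.feature_names, np.vstack([xp, xn]), labels)


def simulate_unlabeled_pool(
    config: SimulationConfig,
) -> tuple[AnnotationMatrix, np.ndarray]:
    """Unlabeled pool plus its hidden ground truth (returned out-of-band).

    Rows are drawn from the same two class-conditional distributions as
    :func:`simulate_annotation_dataset`, with the hidden class Bernoulli
    (``unlabeled_prevalence``). The matrix itself carries no labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_POOL]))
    hidden = (rng.random(config.n_unlabeled) < config.unlabeled_prevalence).astype(int)
    x = rng.normal(0.0, config.noise_sd, size=(config.n_unlabeled, config.n_features))
    if config.n_informative:
        x[hidden == 1, : config.n_informative] += config.effect
    keys = [f"pool_{i + 1:05d}" for i in range(config.n_unlabeled)]
    return AnnotationMatrix(keys, config.feature_names, x), hidden


def simulate_eqtl_tables(
    config: SimulationConfig,
    n_significant: int = 50,
    n_other: int = 50,
    n_filter_pass: int = 20,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mock eQTL association tables: (significant_table, full_table).

    The full table contains every significant row (P drawn below 0.05)
    plus ``n_other`` non-significant rows, of which exactly
    ``n_filter_pass`` are constructed to pass the negative-selection
    filter P > 0.1 and AF > 0.3 and the rest to fail it.
    """
    if n_filter_pass > n_other:
        raise ValueError(
            f"n_filter_pass ({n_filter_pass}) exceeds the number of "
            f"non-significant rows ({n_other})"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, _TAG_TABLES])
    )
    n_total = n_significant + n_other
    pos = rng.choice(np.arange(10_000, 10_000_000), size=n_total, replace=False)
    bases = np.array(list("ACGT"))

    def alleles(k: int) -> tuple[list[str], list[str]]:
        pairs = [rng.choice(bases, size=2, replace=False) for _ in range(k)]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    ref, alt = alleles(n_total)
    p = np.empty(n_total)
    af = rng.uniform(0.01, 0.99, size=n_total)
    # significant associations: P below 0.05 (never pass the P > 0.1 filter)
    p[:n_significant] = rng.uniform(1e-8, 0.05, size=n_significant)
    # planted filter passes: strict P > 0.1 and AF > 0.3
    sl = slice(n_significant, n_significant + n_filter_pass)
    p[sl] = rng.uniform(0.101, 1.0, size=n_filter_pass)
    af[sl] = rng.uniform(0.301, 0.99, size=n_filter_pass)
    # remaining rows fail: low P, or high P with low AF
    for i in range(n_significant + n_filter_pass, n_total):
        if rng.random() < 0.5:
            p[i] = rng.uniform(1e-8, 0.1)
        else:
            p[i] = rng.uniform(0.101, 1.0)
            af[i] = rng.uniform(0.01, 0.3)
    full = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "id": [f"rs{i + 1}" for i in range(n_total)],
            "p_value": p,
            "af": af,
        }
    ).sort_values("pos", kind="stable", ignore_index=True)
    significant = full[full["p_value"] <= 0.05].reset_index(drop=True)
    return significant, full


def simulate_vcf(variants: Sequence[VariantRecord], path) -> None:
    """Write variants as a minimal VCF 4.2 file (header always emitted)."""
    write_vcf(variants, path)
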