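"""Out-of-fold prediction, t-test filtering, thresholding, retraining."""

import numpy as np
import pytest
from scipy import stats

from sscnova import (
    FoldPredictions,
    SimulationConfig,
    ThresholdPair,
    TrainConfig,
    assign_pseudo_labels,
    augment_and_retrain,
    crossval_fold_predictions,
    simulate_annotation_dataset,
    simulate_unlabeled_pool,
    threshold_grid_search,
    ttest_consistency_filter,
)


def _fp(rows):
    rows = np.asarray(rows, dtype=float)
    return FoldPredictions(
        [f"v{i}" for i in range(len(rows))], rows, np.zeros(0, dtype=int)
    )


@pytest.fixture(scope="module")
def small_pipeline_data():
    cfg = SimulationConfig(n_pos=30, n_neg=30, n_features=20, n_informative=4,
                           effect=4.0, n_unlabeled=40, unlabeled_prevalence=0.5,
                           seed=17)
    labeled = simulate_annotation_dataset(cfg)
    pool, hidden = simulate_unlabeled_pool(cfg)
    test_cfg = SimulationConfig(n_pos=15, n_neg=15, n_features=20, n_informative=4,
                                effect=4.0, seed=18)
    test = simulate_annotation_dataset(test_cfg)
    test.row_keys = [f"t_{k}" for k in test.row_keys]
    return labeled, pool, hidden, test


class TestCrossvalFoldPredictions:
    def test_shape_partition_determinism(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, _ = small_pipeline_data
        fp = crossval_fold_predictions(labeled, pool, tiny_spec, fast_cfg, k=5, seed=1)
        assert fp.probs.shape == (40, 5)
        assert ((fp.probs >= 0) & (fp.probs <= 1)).all()
        # each labeled record sits in exactly one fold
        assert sorted(np.unique(fp.fold_assignment)) == [0, 1, 2, 3, 4]
        assert len(fp.fold_assignment) == labeled.n_variants
        fp2 = crossval_fold_predictions(labeled, pool, tiny_spec, fast_cfg, k=5, seed=1)
        assert np.array_equal(fp.probs, fp2.probs)

    def test_k_too_large_errors(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, _ = small_pipeline_data
        with pytest.raises(ValueError, match="exceeds"):
            crossval_fold_predictions(labeled, pool, tiny_spec, fast_cfg, k=100)


class TestTtestFilter:
    def test_confident_variant_retained(self):
        """(0.90, 0.92, 0.91, 0.90, 0.93) sits far from 0.5: |t| >> t_crit."""
        probs = [0.90, 0.92, 0.91, 0.90, 0.93]
        t, p = stats.ttest_1samp(probs, 0.5)
        assert p < 0.05 and t > 60  # hand check: 0.412 / (0.01304/sqrt(5))
        fp = _fp([probs])
        assert len(ttest_consistency_filter(fp)) == 1

    def test_mean_at_null_discarded(self):
        """(0.45, 0.55, 0.50, 0.60, 0.40) has mean exactly 0.5 -> t = 0."""
        fp = _fp([[0.45, 0.55, 0.50, 0.60, 0.40]])
        assert len(ttest_consistency_filter(fp)) == 0

    def test_zero_variance_retained_iff_off_null(self):
        fp = _fp([[0.9] * 5, [0.5] * 5])
        kept = ttest_consistency_filter(fp)
        assert kept.variant_keys == ["v0"]

    def test_single_fold_errors(self):
        with pytest.raises(ValueError, match="2 folds"):
            ttest_consistency_filter(_fp(np.ones((3, 1)) * 0.9))

    def test_matches_scipy_row_scan(self, rng):
        probs = rng.random((50, 5))
        kept = ttest_consistency_filter(_fp(probs), alpha=0.05)
        brute = [
            i for i in range(50)
            if (np.std(probs[i], ddof=1) == 0 and probs[i].mean() != 0.5)
            or (np.std(probs[i], ddof=1) > 0
                and stats.ttest_1samp(probs[i], 0.5).pvalue < 0.05)
        ]
        assert kept.variant_keys == [f"v{i}" for i in brute]


class TestThresholdPair:
    def test_from_delta(self):
        p = ThresholdPair.from_delta(0.4)
        assert (p.upper, p.lower) == (0.9, 0.1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ThresholdPair(0.7, 0.2, 0.2)
        with pytest.raises(ValueError):
            ThresholdPair.from_delta(0.6)


class TestAssignPseudoLabels:
    def test_final_rule_examples(self):
        fp = _fp([[0.95] * 5, [0.05] * 5, [0.5] * 5, [0.85] * 5])
        ps = assign_pseudo_labels(fp, ThresholdPair.from_delta(0.4))
        by_key = dict(zip(ps.variant_keys, ps.pseudo_labels))
        assert by_key == {"v0": 1, "v1": 0}
        assert ps.n_discarded == 2
        assert len(ps) + ps.n_discarded == len(fp)

    def test_delta_zero_labels_everything_off_half(self):
        fp = _fp([[0.51] * 5, [0.49] * 5])
        ps = assign_pseudo_labels(fp, ThresholdPair.from_delta(0.0))
        assert ps.n_discarded == 0 and len(ps) == 2

    def test_monotone_in_delta(self, rng):
        fp = _fp(rng.random((100, 5)))
        counts = [
            len(assign_pseudo_labels(fp, ThresholdPair.from_delta(d)))
            for d in (0.0, 0.1, 0.2, 0.3, 0.4)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestAugmentAndRetrain:
    def test_merged_size_and_disjointness(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, _ = small_pipeline_data
        fp = crossval_fold_predictions(labeled, pool, tiny_spec, fast_cfg, k=5, seed=1)
        ps = assign_pseudo_labels(
            ttest_consistency_filter(fp), ThresholdPair.from_delta(0.3)
        )
        model = augment_and_retrain(labeled, ps, pool, tiny_spec, fast_cfg, k=5, seed=1)
        assert model.provenance["n_merged"] == labeled.n_variants + len(ps)

    def test_overlap_rejected(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, _ = small_pipeline_data
        ps_bad = assign_pseudo_labels(
            _fp([[0.95] * 5]), ThresholdPair.from_delta(0.4)
        )
        ps_bad.variant_keys = [labeled.row_keys[0]]
        pool_bad = pool
        pool_bad.row_keys = [labeled.row_keys[0]] + pool.row_keys[1:]
        with pytest.raises(ValueError, match="overlap"):
            augment_and_retrain(labeled, ps_bad, pool_bad, tiny_spec, fast_cfg)

    def test_empty_pseudo_is_plain_crossval(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, _ = small_pipeline_data
        empty = assign_pseudo_labels(
            _fp(np.full((3, 5), 0.5)), ThresholdPair.from_delta(0.4)
        )
        assert len(empty) == 0
        model = augment_and_retrain(labeled, empty, pool, tiny_spec, fast_cfg, seed=2)
        assert model.provenance["n_merged"] == labeled.n_variants


class TestGridSearch:
    def test_report_contract(self, small_pipeline_data, tiny_spec):
        labeled, pool, _, test = small_pipeline_data
        cfg = TrainConfig(epochs=2, batch_size=16, seed=0)
        deltas = (0.0, 0.2, 0.4)
        pair, report = threshold_grid_search(
            labeled, pool, test, tiny_spec, cfg, deltas=deltas, k=3, seed=3
        )
        assert list(report["delta"]) == sorted(deltas)
        assert set(report.columns) >= {
            "delta", "upper", "lower", "n_pos", "n_neg", "n_discarded", "auc"
        }
        assert report["auc"].max() == report.loc[report["delta"] == pair.delta, "auc"].max()
        # conservation within each row of the report
        fp = crossval_fold_predictions(labeled, pool, tiny_spec, cfg, k=3, seed=3)
        retained = ttest_consistency_filter(fp)
        for _, row in report.iterrows():
            assert row["n_pos"] + row["n_neg"] + row["n_discarded"] == len(retained)

    def test_empty_grid_errors(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, test = small_pipeline_data
        with pytest.raises(ValueError, match="non-empty"):
            threshold_grid_search(labeled, pool, test, tiny_spec, fast_cfg, deltas=())

    def test_test_set_isolation_enforced(self, small_pipeline_data, tiny_spec, fast_cfg):
        labeled, pool, _, _ = small_pipeline_data
        with pytest.raises(ValueError, match="overlap"):
            threshold_grid_search(
                labeled, pool, labeled, tiny_spec, fast_cfg, deltas=(0.4,)
            )
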