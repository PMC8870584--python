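"""Fold construction, metric formulas against oracles, CV driver behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scalonet.evaluation import (
    classification_metrics,
    confusion_matrix,
    cross_validate,
    audit_no_leakage,
    make_subject_folds,
    quadratic_weighted_kappa,
    roc_and_auc,
)
from scalonet.model import CnnSpec, ConvBlock, TrainConfig
from scalonet.timefreq import TileSet

# printed 4-fold confusion matrices of the reference study (rows = truth
# HC/PD, columns = prediction)
TABLE4 = {
    "Fp1": np.array([[3042, 38], [19, 2967]]),
    "CP5": np.array([[3077, 3], [2, 2984]]),
    "Fp2": np.array([[3021, 37], [18, 2990]]),
}


class TestSubjectFolds:
    def test_31_subjects_4_folds_sizes(self):
        labels = {f"hc{i}": 0 for i in range(16)}
        labels.update({f"pd{i}": 1 for i in range(15)})
        split = make_subject_folds(labels, k=4, seed=0)
        sizes = [len(split.subjects_in_fold(f)) for f in range(4)]
        assert sorted(sizes) in ([7, 8, 8, 8],)
        assert sum(sizes) == 31

    def test_leave_one_subject_out(self):
        labels = {f"s{i}": i % 2 for i in range(6)}
        split = make_subject_folds(labels, k=6, seed=0)
        assert sorted(len(split.subjects_in_fold(f)) for f in range(6)) == [1] * 6

    def test_partition_property(self):
        labels = {f"s{i}": i % 3 for i in range(20)}
        split = make_subject_folds(labels, k=5, seed=1)
        seen = [s for f in range(5) for s in split.subjects_in_fold(f)]
        assert sorted(seen) == sorted(labels)

    def test_class_stratification(self):
        labels = {f"hc{i}": 0 for i in range(16)}
        labels.update({f"pd{i}": 1 for i in range(15)})
        split = make_subject_folds(labels, k=4, seed=0)
        for f in range(4):
            members = split.subjects_in_fold(f)
            classes = {labels[s] for s in members}
            assert classes == {0, 1}

    def test_k_exceeding_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_subject_folds({"a": 0, "b": 1}, k=3)

    def test_seeded_determinism(self):
        labels = {f"s{i}": i % 2 for i in range(10)}
        a = make_subject_folds(labels, k=3, seed=7)
        b = make_subject_folds(labels, k=3, seed=7)
        assert a.assignment == b.assignment

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(4, 40), k=st.integers(2, 4), seed=st.integers(0, 10))
    def test_partition_property_randomized(self, n, k, seed):
        labels = {f"s{i}": i % 2 for i in range(n)}
        split = make_subject_folds(labels, k=k, seed=seed)
        assert sorted(split.assignment) == sorted(labels)
        assert set(split.assignment.values()) <= set(range(k))


class TestConfusionMatrix:
    def test_all_correct_single_class_column(self):
        m = confusion_matrix([1] * 10, [1] * 10, 2)
        assert m.tolist() == [[0, 0], [0, 10]]

    def test_empty_input_gives_zero_matrix(self):
        assert confusion_matrix([], [], 3).tolist() == [[0] * 3] * 3

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 2], [0, 1], 2)

    def test_table4_fixture_ingestible(self):
        m = TABLE4["CP5"]
        assert m.sum() == 6066
        assert classification_metrics(m).confusion.tolist() == m.tolist()


class TestClassificationMetrics:
    def test_exhaustive_small_binary_matrices_against_counting(self):
        # oracle: rebuild the label vectors and count directly
        for tn in range(5):
            for fp in range(5):
                for fn in range(5):
                    for tp in range(5):
                        if tn + fp + fn + tp == 0:
                            continue
                        y_true = [0] * (tn + fp) + [1] * (fn + tp)
                        y_pred = [0] * tn + [1] * fp + [0] * fn + [1] * tp
                        conf = confusion_matrix(y_true, y_pred, 2)
                        rep = classification_metrics(conf)
                        acc = np.mean(np.array(y_true) == np.array(y_pred))
                        assert rep.accuracy == pytest.approx(acc)
                        if tp + fn:
                            assert rep.sensitivity == pytest.approx(
                                tp / (tp + fn))
                        else:
                            assert np.isnan(rep.sensitivity)
                        if tn + fp:
                            assert rep.specificity == pytest.approx(
                                tn / (tn + fp))
                        else:
                            assert np.isnan(rep.specificity)

    def test_table4_cp5_rounds_to_printed_values(self):
        rep = classification_metrics(TABLE4["CP5"])
        assert round(100 * rep.accuracy, 1) == 99.9
        assert round(100 * rep.sensitivity, 1) == 99.9
        assert round(100 * rep.specificity, 1) == 99.9

    @pytest.mark.parametrize("channel,misclassified", [("CP5", 5),
                                                       ("Fp1", 57)])
    def test_misclassified_counts(self, channel, misclassified):
        m = TABLE4[channel]
        assert int(m.sum() - np.trace(m)) == misclassified

    def test_perfect_diagonal(self):
        rep = classification_metrics(np.diag([7, 9]))
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0

    def test_three_class_per_class_one_vs_rest(self):
        conf = np.array([[5, 1, 0], [0, 6, 2], [1, 0, 7]])
        rep = classification_metrics(conf)
        assert rep.per_class is not None
        assert rep.per_class[0]["sensitivity"] == pytest.approx(5 / 6)
        # class 0 one-vs-rest: TN = sum of non-row-0 non-col-0 cells
        assert rep.per_class[0]["specificity"] == pytest.approx(15 / 16)
        assert rep.accuracy == pytest.approx(18 / 22)

    def test_undefined_metric_is_nan_not_zero(self):
        rep = classification_metrics(np.array([[5, 2], [0, 0]]))
        assert np.isnan(rep.sensitivity)
        assert rep.specificity == pytest.approx(5 / 7)


def _kappa_bruteforce(conf, power):
    conf = np.asarray(conf, float)
    n = conf.sum()
    c = conf / n
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    num = 0.0
    den = 0.0
    L = conf.shape[0]
    for i in range(L):
        for j in range(L):
            w = (i - j) ** power
            num += w * c[i, j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        assert quadratic_weighted_kappa(np.diag([4, 5, 6])) == 1.0

    def test_independence_with_matched_marginals_is_zero(self):
        # counts proportional to the outer product of one distribution
        m = np.outer([0.6, 0.4], [0.6, 0.4]) * 100
        assert quadratic_weighted_kappa(m) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("channel", list(TABLE4))
    def test_agrees_with_bruteforce_on_table4(self, channel):
        ours = quadratic_weighted_kappa(TABLE4[channel])
        ref = _kappa_bruteforce(TABLE4[channel], 2)
        assert ours == pytest.approx(ref, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.integers(0, 50), min_size=9, max_size=9),
        st.sampled_from([2, 3]),
    )
    def test_agrees_with_bruteforce_randomized(self, cells, L):
        conf = np.array(cells[: L * L]).reshape(L, L)
        if conf.sum() == 0:
            conf[0, 1] = 1
        ours = quadratic_weighted_kappa(conf)
        if np.isnan(ours):  # degenerate: all mass in one class
            return
        assert ours == pytest.approx(_kappa_bruteforce(conf, 2), abs=1e-12)

    def test_agrees_with_sklearn_cohen_kappa(self):
        from sklearn.metrics import cohen_kappa_score

        conf = TABLE4["Fp1"]
        y_true = np.repeat([0, 0, 1, 1], conf.ravel())
        y_pred = np.tile([0, 1], 2).repeat(conf.ravel())
        ours = quadratic_weighted_kappa(conf)
        ref = cohen_kappa_score(y_true, y_pred, weights="quadratic")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_degenerate_single_cell_is_undefined(self):
        assert np.isnan(quadratic_weighted_kappa(np.array([[10, 0], [0, 0]])))

    def test_signed_linear_variant_available(self):
        m = TABLE4["CP5"]
        lin = quadratic_weighted_kappa(m, weights="linear_signed")
        quad = quadratic_weighted_kappa(m)
        assert lin != quad

    def test_moving_mass_off_diagonal_lowers_kappa(self):
        base = np.array([[40, 10], [10, 40]])
        worse = np.array([[35, 15], [10, 40]])
        assert quadratic_weighted_kappa(worse) < quadratic_weighted_kappa(base)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_equal_scores_give_half(self):
        r = roc_and_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("n,seed", [(20, 0), (50, 1)])
    def test_equals_pairwise_rank_oracle(self, n, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.uniform(0, 1, n), 2)  # force some ties
        labels = r.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_and_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert res.auc == pytest.approx(wins / (pos.size * neg.size),
                                        abs=1e-12)

    def test_single_class_is_undefined(self):
        r = roc_and_auc([0.2, 0.7], [1, 1])
        assert not r.defined
        assert np.isnan(r.auc)


def _toy_tileset(n_subjects=8, tiles_per_subject=8, size=32, classes=(0, 1),
                 seed=0):
    """Tiny synthetic tiles whose mean intensity encodes the class."""
    r = np.random.default_rng(seed)
    images, rows = [], []
    for s in range(n_subjects):
        label = classes[s % len(classes)]
        level = 0.2 + 0.6 * classes.index(label) / max(len(classes) - 1, 1)
        for t in range(tiles_per_subject):
            images.append(np.clip(r.normal(level, 0.05, (size, size)), 0, 1))
            rows.append({"subject_id": f"s{s:02d}", "channel": "CP5",
                         "class_label": label, "tile_index": t})
    return TileSet(np.stack(images), pd.DataFrame(rows))


TOY_SPEC = CnnSpec(input_size=32, blocks=(ConvBlock(3, 2, 1),
                                          ConvBlock(3, 4, 1)), head=(8,))
TOY_CFG = TrainConfig(batch_size=8, learning_rate=0.05, epochs=8, seed=0,
                      dtype="float32")


class TestCrossValidate:
    def test_separable_toy_and_report_schema(self):
        tiles = _toy_tileset()
        res = cross_validate(tiles, "hc-vs-off", k=4, cnn_spec=TOY_SPEC,
                             train_config=TOY_CFG, seed=0)
        assert res.pooled.accuracy >= 0.9
        summary = res.summary()
        assert set(summary["mean_of_folds"]) == {
            "accuracy", "sensitivity", "specificity", "kappa", "auc"
        }
        assert "pooled" in summary and len(summary["per_fold"]) == 4
        assert len(res.predictions) == len(tiles)

    def test_validation_subjects_disjoint_from_training(self):
        tiles = _toy_tileset()
        res = cross_validate(tiles, "hc-vs-off", k=4, cnn_spec=TOY_SPEC,
                             train_config=TOY_CFG, seed=0)
        assert audit_no_leakage(res)
        for fold in range(res.folds.k):
            val_subjects = set(
                res.predictions.loc[res.predictions["fold"] == fold,
                                    "subject_id"]
            )
            train_subjects = set(res.folds.assignment) - val_subjects
            assert val_subjects.isdisjoint(train_subjects)
            assert val_subjects == set(res.folds.subjects_in_fold(fold))

    def test_missing_experiment_class_rejected(self):
        tiles = _toy_tileset(classes=(0,), n_subjects=4)
        with pytest.raises(ValueError, match="absent"):
            cross_validate(tiles, "hc-vs-off", k=2, cnn_spec=TOY_SPEC,
                           train_config=TOY_CFG)

    def test_off_vs_on_relabels_to_binary(self):
        tiles = _toy_tileset(classes=(1, 2))
        res = cross_validate(tiles, "off-vs-on", k=2, cnn_spec=TOY_SPEC,
                             train_config=TOY_CFG, seed=0)
        assert set(res.predictions["true"]) <= {0, 1}
        assert res.pooled.confusion.shape == (2, 2)

    def test_three_class_reports_per_class_metrics(self):
        tiles = _toy_tileset(n_subjects=9, classes=(0, 1, 2))
        res = cross_validate(tiles, "three-class", k=3, cnn_spec=TOY_SPEC,
                             train_config=TOY_CFG, seed=0)
        assert res.pooled.per_class is not None
        assert set(res.pooled.per_class) == {0, 1, 2}
        for v in res.pooled.per_class.values():
            assert {"sensitivity", "specificity"} <= set(v)

    def test_label_permutation_destroys_signal(self):
        # chance-level accuracy when subject labels are shuffled
        tiles = _toy_tileset(n_subjects=8, tiles_per_subject=8)
        meta = tiles.meta.copy()
        r = np.random.default_rng(5)
        subjects = sorted(set(tiles.subjects))
        orig = meta.groupby("subject_id")["class_label"].first()
        perm = dict(zip(subjects, r.permutation(orig[subjects].to_numpy())))
        meta["class_label"] = meta["subject_id"].map(perm)
        res = cross_validate(TileSet(tiles.images, meta), "hc-vs-off", k=4,
                             cnn_spec=TOY_SPEC, train_config=TOY_CFG, seed=0)
        se = np.sqrt(0.25 / len(subjects))
        assert abs(res.pooled.accuracy - 0.5) <= 3 * se
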