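"""Balancing, classifier contract, LOSO / intra-subject / scalability."""

import numpy as np
import pytest

import eegaffect.evaluation as ev
from eegaffect import balance, classify, intra_subject_run, loso_run, scalability_curve, suggest_k
from conftest import make_table


def unbalanced_table(counts, n_features=3, seed=0):
    """counts: dict subject -> (n_negative, n_positive)."""
    rng = np.random.default_rng(seed)
    rows, subs, trials, ys = [], [], [], []
    for subj, (n0, n1) in counts.items():
        for j, y in enumerate([0] * n0 + [1] * n1):
            rows.append(rng.normal(size=n_features))
            subs.append(subj)
            trials.append(f"{subj}_t{j}")
            ys.append(float(y))
    from eegaffect import FeatureTable
    y_arr = np.array(ys)
    return FeatureTable(
        values=np.vstack(rows), feature_names=[f"f{j}" for j in range(n_features)],
        subject_ids=np.array(subs, dtype=object), trial_ids=np.array(trials, dtype=object),
        valence=y_arr, arousal=y_arr.copy(),
    )


class TestBalance:
    def test_exact_counts_kept(self):
        table = unbalanced_table({"A": (6, 10)})
        data = balance(table, "valence", 6, seed=0)
        assert data.table.n_trials == 12

    def test_short_subject_discarded(self):
        table = unbalanced_table({"A": (3, 5), "B": (6, 6)})
        data = balance(table, "valence", 4, seed=0)
        assert data.discarded_subjects == ["A"]
        assert data.table.subjects == ["B"]

    def test_retained_counts_by_exhaustive_tally(self):
        table = unbalanced_table({"A": (9, 4), "B": (5, 12), "C": (4, 4)}, seed=3)
        data = balance(table, "valence", 4, seed=1)
        labels = data.table.labels("valence")
        for subj in data.table.subjects:
            mask = data.table.subject_ids == subj
            tally = {c: int(np.sum(mask & (labels == c))) for c in (0, 1)}
            assert tally == {0: 4, 1: 4}

    def test_all_discarded_suggests_smaller_k(self):
        table = unbalanced_table({"A": (2, 2)})
        with pytest.raises(ValueError, match="smaller k"):
            balance(table, "valence", 5, seed=0)

    def test_deterministic_under_seed(self):
        table = unbalanced_table({"A": (9, 9), "B": (9, 9)})
        d1 = balance(table, "valence", 5, seed=7)
        d2 = balance(table, "valence", 5, seed=7)
        assert list(d1.table.trial_ids) == list(d2.table.trial_ids)

    def test_suggest_k_respects_discard_budget(self):
        table = unbalanced_table({"A": (10, 10), "B": (10, 10), "C": (2, 10), "D": (10, 10)})
        assert suggest_k(table, "valence", max_discard_frac=0.25) == 10
        assert suggest_k(table, "valence", max_discard_frac=0.0) == 2


class TestClassify:
    def threshold_data(self):
        train_X = np.array([[0.0], [0.1], [0.2], [0.9], [1.0], [1.1]])
        train_y = np.array([0, 0, 0, 1, 1, 1])
        test_X = np.array([[0.05], [1.05]])
        return train_X, train_y, test_X

    @pytest.mark.parametrize("spec", ev.CLASSIFIERS)
    def test_threshold_separable_perfect(self, spec):
        train_X, train_y, test_X = self.threshold_data()
        assert np.array_equal(classify(train_X, train_y, test_X, spec), [0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            classify(np.ones((4, 2)), np.zeros(4), np.ones((1, 2)), "svm_rbf")

    def test_unknown_spec_lists_supported(self):
        with pytest.raises(ValueError, match="svm_cubic"):
            classify(np.ones((4, 2)), np.array([0, 0, 1, 1]), np.ones((1, 2)), "forest")

    def test_naive_bayes_constant_features_no_crash(self):
        """All-constant binary features carry no signal; naive Bayes falls
        back to the majority class instead of dividing by zero variance."""
        train_X = np.ones((5, 3))
        train_y = np.array([0, 0, 1, 1, 1])
        pred = classify(train_X, train_y, np.ones((2, 3)), "naive_bayes")
        assert np.array_equal(pred, [1, 1])

    def test_rbf_predictions_match_hand_kernel_arithmetic(self):
        """Recompute the fitted RBF decision function from support vectors
        with an independent kernel implementation on a 20-row fixture."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=20) > 0).astype(int)
        test_X = rng.normal(size=(10, 4))
        pred = classify(X, y, test_X, "svm_rbf")

        clf = SVC(kernel="rbf", random_state=0).fit(X, y)
        gamma = 1.0 / (4 * X.var())  # sklearn's 'scale' default
        sv = clf.support_vectors_
        d2 = ((test_X[:, None, :] - sv[None, :, :]) ** 2).sum(-1)
        decision = (np.exp(-gamma * d2) @ clf.dual_coef_.ravel()) + clf.intercept_[0]
        assert np.array_equal(pred, (decision > 0).astype(int))


class TestLoso:
    def test_record_count_24_subjects_20_reps(self):
        table = make_table(24, 2, 3, seed=0)
        data = balance(table, "valence", 2, seed=0)
        records = loso_run(data, ["none"], "naive_bayes", reps=20, seed=0)
        assert len(records) == 480

    def test_record_count_16_subjects_20_reps(self):
        table = make_table(16, 2, 3, seed=0)
        data = balance(table, "arousal", 2, seed=0)
        records = loso_run(data, ["none"], "naive_bayes", reps=20, seed=0)
        assert len(records) == 320

    def test_training_rows_are_90pct_of_other_subjects(self, monkeypatch):
        """Per repetition, round(0.9 * rows of the other subjects) are drawn."""
        seen = []
        real = ev.classify

        def spy(train_X, train_y, test_X, spec, seed=0):
            seen.append(train_X.shape[0])
            return real(train_X, train_y, test_X, spec, seed)

        monkeypatch.setattr(ev, "classify", spy)
        table = make_table(5, 3, 3, seed=1)  # 6 rows/subject, pool = 24 rows
        data = balance(table, "valence", 3, seed=0)
        loso_run(data, ["none"], "naive_bayes", reps=2, seed=0)
        assert set(seen) == {round(0.9 * 24)}

    def test_no_test_subject_leakage(self, monkeypatch):
        """The held-out subject's rows never enter the training matrix."""
        table = make_table(4, 3, 3, seed=2)
        # tag each subject's rows with a distinctive constant in feature 0
        for i, subj in enumerate(table.subjects):
            table.values[table.subject_ids == subj, 0] = 1000.0 * (i + 1)
        data = balance(table, "valence", 3, seed=0)
        held_out = []

        real = ev.classify

        def spy(train_X, train_y, test_X, spec, seed=0):
            held_out.append((set(np.unique(train_X[:, 0])), test_X[0, 0]))
            return real(train_X, train_y, test_X, spec, seed)

        monkeypatch.setattr(ev, "classify", spy)
        loso_run(data, ["none"], "naive_bayes", reps=3, seed=0)
        for train_tags, test_tag in held_out:
            assert test_tag not in train_tags

    def test_identical_seeds_identical_records(self):
        table = make_table(4, 3, 4, seed=3)
        data = balance(table, "valence", 3, seed=1)
        r1 = loso_run(data, ["zscore", "binarize"], "naive_bayes", reps=3, seed=5)
        r2 = loso_run(data, ["zscore", "binarize"], "naive_bayes", reps=3, seed=5)
        assert [(r.test_subject, r.repetition, r.accuracies) for r in r1] == [
            (r.test_subject, r.repetition, r.accuracies) for r in r2
        ]

    def test_methods_share_one_split_per_record(self):
        """The identity transform and z-score see the same split, so a
        scale-invariant classifier scores them identically."""
        table = make_table(4, 4, 3, seed=4, effect=np.full(3, 2.0))
        data = balance(table, "valence", 4, seed=0)
        records = loso_run(data, ["none", "zscore"], "naive_bayes", reps=2, seed=0)
        assert all(set(r.accuracies) == {"none", "zscore"} for r in records)

    def test_needs_two_subjects(self):
        table = make_table(1, 3, 3)
        data = balance(table, "valence", 3, seed=0)
        with pytest.raises(ValueError, match="2 subjects"):
            loso_run(data, ["none"], "naive_bayes", reps=1, seed=0)

    def test_unknown_specs_rejected(self):
        table = make_table(3, 2, 3)
        data = balance(table, "valence", 2, seed=0)
        with pytest.raises(ValueError, match="supported"):
            loso_run(data, ["none"], "deep_net", reps=1, seed=0)
        with pytest.raises(ValueError, match="supported"):
            loso_run(data, ["quantile"], "naive_bayes", reps=1, seed=0)


class TestIntraSubject:
    def test_judgment_count_is_2_m_reps(self):
        m, reps = 3, 10
        table = make_table(m, 4, 3, seed=5)
        data = balance(table, "valence", 4, seed=0)
        records = intra_subject_run(data, ["none"], "naive_bayes", reps=reps, seed=0)
        assert len(records) == m * reps  # 2 judgments per record = 2*m*reps total

    def test_always_positive_classifier_scores_half(self, monkeypatch):
        """One positive and one negative held out per repetition, so a
        constant classifier scores exactly 0.5."""
        monkeypatch.setattr(
            ev, "classify", lambda trX, trY, teX, spec, seed=0: np.ones(teX.shape[0])
        )
        table = make_table(3, 3, 3, seed=6)
        data = balance(table, "valence", 3, seed=0)
        records = intra_subject_run(data, ["none"], "naive_bayes", reps=5, seed=0)
        assert all(r.accuracies["none"] == 0.5 for r in records)

    def test_separable_data_perfect_accuracy(self, separable_table):
        data = balance(separable_table, "valence", 4, seed=0)
        records = intra_subject_run(data, ["none"], "naive_bayes", reps=5, seed=0)
        assert all(r.accuracies["none"] == 1.0 for r in records)

    def test_subject_with_one_row_per_class_rejected(self):
        table = make_table(2, 1, 3)
        data = balance(table, "valence", 1, seed=0)
        with pytest.raises(ValueError, match="2 rows per class"):
            intra_subject_run(data, ["none"], "naive_bayes", reps=1, seed=0)


class TestScalability:
    def test_p_out_of_range_rejected(self):
        table = make_table(4, 2, 3)
        data = balance(table, "valence", 2, seed=0)
        with pytest.raises(ValueError, match="n_subjects"):
            scalability_curve(data, ["none"], "naive_bayes", [4], seed=0)

    def test_identical_seeds_identical_curves(self):
        table = make_table(5, 3, 4, seed=7)
        data = balance(table, "valence", 3, seed=0)
        c1 = scalability_curve(data, ["zscore", "binarize"], "naive_bayes", [1, 3], seed=2)
        c2 = scalability_curve(data, ["zscore", "binarize"], "naive_bayes", [1, 3], seed=2)
        assert c1 == c2

    def test_full_p_equals_loso_with_full_training(self):
        """p = n_subjects - 1 trains on all other rows, definitionally a
        LOSO run with train_fraction 1.0 and a single repetition."""
        table = make_table(5, 3, 4, seed=8, effect=np.full(4, 1.0))
        data = balance(table, "valence", 3, seed=0)
        curve = scalability_curve(data, ["zscore"], "naive_bayes", [4], seed=0)
        records = loso_run(data, ["zscore"], "naive_bayes", reps=1, train_fraction=1.0, seed=0)
        loso_mean = np.mean([r.accuracies["zscore"] for r in records])
        assert curve["zscore"][4] == pytest.approx(loso_mean)
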