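"""Experimental protocols for subject-independent affect classification.

Implements class balancing, leave-one-subject-out (LOSO) evaluation with
repeated 90% training draws, the intra-subject protocol (hold out one
positive and one negative trial per repetition), and the scalability curve
(accuracy as a function of the number of training subjects).

All protocols evaluate every requested feature transform on the *same*
train/test split, producing paired :class:`ComparisonRecord` rows suitable
for a Friedman rank comparison.  The test subject contributes no training
rows, and its labels are never visible to any transform fit: subject-based
transforms (binarization, max-min) fit the test subject's profile from its
feature rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .features import FeatureTable
from .transforms import (
    fit_profile_from_matrix,
    binarize,
    maxmin_scale,
    zscore_apply,
    zscore_fit,
)

__all__ = [
    "BalancedDataset",
    "ComparisonRecord",
    "CLASSIFIERS",
    "TRANSFORMS",
    "balance",
    "suggest_k",
    "classify",
    "apply_transform_loso",
    "loso_run",
    "intra_subject_run",
    "scalability_curve",
]

CLASSIFIERS = ("svm_cubic", "svm_rbf", "naive_bayes")
TRANSFORMS = ("none", "zscore", "binarize", "maxmin")


@dataclass
class BalancedDataset:
    """A class-balanced subset: every retained subject contributes exactly
    ``k`` rows per class of ``label_dim``."""

    table: FeatureTable
    label_dim: str
    k: int
    discarded_subjects: list
    seed: int

    @property
    def subjects(self) -> list:
        return self.table.subjects

    @property
    def n_subjects(self) -> int:
        return len(self.table.subjects)


@dataclass
class ComparisonRecord:
    """Paired accuracies of the compared methods on one
    (test subject, repetition, classifier) cell -- the Friedman test's unit.

    One identical train/test split underlies every method's accuracy.
    """

    test_subject: object
    repetition: int
    classifier: str
    label_dim: str
    accuracies: dict[str, float]
    dataset: str = ""

    def __post_init__(self) -> None:
        for m, a in self.accuracies.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"accuracy for {m!r} out of [0, 1]: {a}")


def balance(table: FeatureTable, label_dim: str, k: int, seed: int) -> BalancedDataset:
    """Randomly select the same number ``k`` of trials per class per subject.

    Sampling is uniform without replacement within each (subject, class)
    group; subjects with fewer than ``k`` trials in their minority class
    are discarded.  Deterministic under ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = table.labels(label_dim)
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    discarded: list = []
    for subj in table.subjects:
        mask = table.subject_ids == subj
        ok = True
        chosen: list[np.ndarray] = []
        for cls in (0, 1):
            idx = np.flatnonzero(mask & (labels == cls))
            if len(idx) < k:
                ok = False
                break
            chosen.append(rng.choice(idx, size=k, replace=False))
        if ok:
            keep_idx.extend(np.sort(np.concatenate(chosen)))
        else:
            discarded.append(subj)
    if not keep_idx:
        raise ValueError(
            f"balancing with k={k} discarded every subject; try a smaller k"
        )
    return BalancedDataset(
        table=table.subset(np.array(keep_idx)),
        label_dim=label_dim,
        k=k,
        discarded_subjects=discarded,
        seed=seed,
    )


def suggest_k(table: FeatureTable, label_dim: str, max_discard_frac: float = 0.25) -> int:
    """Largest per-class count ``k`` that discards at most
    ``max_discard_frac`` of the subjects.

    Balancing trades training-set size against the number of subjects that
    must be dropped for lacking minority-class trials; this helper picks
    the largest k compatible with a discard budget.
    """
    labels = table.labels(label_dim)
    minority: list[int] = []
    for subj in table.subjects:
        mask = table.subject_ids == subj
        counts = [int(np.sum(mask & (labels == c))) for c in (0, 1)]
        minority.append(min(counts))
    minority_arr = np.array(minority)
    m = len(minority_arr)
    best = 0
    for k in range(1, int(minority_arr.max()) + 1):
        discarded = int(np.sum(minority_arr < k))
        if discarded / m <= max_discard_frac:
            best = k
    if best == 0:
        raise ValueError("no k retains enough subjects under the discard budget")
    return best


def _majority_label(y: np.ndarray) -> int:
    vals, counts = np.unique(y, return_counts=True)
    return int(vals[np.argmax(counts)])


def classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    spec: str,
    seed: int = 0,
) -> np.ndarray:
    """Train a classifier and predict test labels.

    Thin contract over scikit-learn: ``svm_cubic`` is an SVM with a
    degree-3 polynomial kernel, ``svm_rbf`` an SVM with a Gaussian kernel,
    ``naive_bayes`` a Gaussian naive Bayes.  Deterministic given seed and
    inputs.  A training matrix whose features are all constant carries no
    information; naive Bayes then predicts the majority training class
    rather than failing.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    test_X = np.asarray(test_X, dtype=float)
    if spec not in CLASSIFIERS:
        raise ValueError(f"unknown classifier spec {spec!r}; supported: {CLASSIFIERS}")
    if len(np.unique(train_y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    if spec == "svm_cubic":
        clf = SVC(kernel="poly", degree=3, random_state=seed)
    elif spec == "svm_rbf":
        clf = SVC(kernel="rbf", random_state=seed)
    else:
        if np.var(train_X, axis=0).max() == 0.0:
            return np.full(test_X.shape[0], _majority_label(train_y))
        clf = GaussianNB()
    clf.fit(train_X, train_y)
    return clf.predict(test_X)


def _per_subject_transform(fn, X: np.ndarray, subject_ids: np.ndarray,
                           profiles: dict) -> np.ndarray:
    out = np.empty_like(X)
    for subj, prof in profiles.items():
        mask = subject_ids == subj
        if mask.any():
            out[mask] = fn(X[mask], prof)
    return out


def apply_transform_loso(
    method: str,
    train_X: np.ndarray,
    train_subjects: np.ndarray,
    test_X: np.ndarray,
    test_subject: object,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a transform per its leakage contract and apply to train and test.

    * ``zscore``: standardizer fitted on the training rows only.
    * ``binarize`` / ``maxmin``: one profile per training subject from that
      subject's training rows; the test subject's profile is fitted from
      the test feature rows alone (no labels involved).
    * ``none``: identity.
    """
    if method == "none":
        return train_X, test_X
    if method == "zscore":
        std = zscore_fit(train_X)
        return zscore_apply(train_X, std), zscore_apply(test_X, std)
    if method in ("binarize", "maxmin"):
        fn = binarize if method == "binarize" else maxmin_scale
        profiles = {
            subj: fit_profile_from_matrix(train_X[train_subjects == subj], subj)
            for subj in dict.fromkeys(train_subjects)
        }
        test_profile = fit_profile_from_matrix(test_X, test_subject)
        out_train = _per_subject_transform(fn, train_X, train_subjects, profiles)
        out_test = fn(test_X, test_profile)
        return out_train, out_test
    raise ValueError(f"unknown transform spec {method!r}; supported: {TRANSFORMS}")


def loso_run(
    data: BalancedDataset,
    methods: list[str],
    classifier: str,
    reps: int = 20,
    train_fraction: float = 0.9,
    seed: int = 0,
    dataset_name: str = "",
) -> list[ComparisonRecord]:
    """Leave-one-subject-out evaluation with repeated training draws.

    For each held-out subject and each repetition, ``train_fraction`` of
    the remaining subjects' rows are drawn uniformly without replacement,
    each transform in ``methods`` is fitted on that identical split, the
    classifier trained, and accuracy scored on *all* of the held-out
    subject's rows.  Yields ``reps * n_subjects`` records.
    """
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier spec {classifier!r}; supported: {CLASSIFIERS}")
    for m in methods:
        if m not in TRANSFORMS:
            raise ValueError(f"unknown transform spec {m!r}; supported: {TRANSFORMS}")
    table = data.table
    subjects = table.subjects
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    labels = table.labels(data.label_dim)
    rng = np.random.default_rng(seed)
    records: list[ComparisonRecord] = []
    for subj in subjects:
        test_mask = table.subject_ids == subj
        pool = np.flatnonzero(~test_mask)
        test_X = table.values[test_mask]
        test_y = labels[test_mask]
        n_train = int(round(train_fraction * len(pool)))
        for rep in range(reps):
            chosen = rng.choice(pool, size=n_train, replace=False) if n_train < len(pool) else pool
            train_X = table.values[chosen]
            train_y = labels[chosen]
            train_subj = table.subject_ids[chosen]
            accs: dict[str, float] = {}
            for method in methods:
                Xtr, Xte = apply_transform_loso(method, train_X, train_subj, test_X, subj)
                pred = classify(Xtr, train_y, Xte, classifier, seed=seed)
                accs[method] = float(np.mean(pred == test_y))
            records.append(
                ComparisonRecord(
                    test_subject=subj,
                    repetition=rep,
                    classifier=classifier,
                    label_dim=data.label_dim,
                    accuracies=accs,
                    dataset=dataset_name,
                )
            )
    return records


def intra_subject_run(
    data: BalancedDataset,
    methods: list[str],
    classifier: str,
    reps: int = 100,
    seed: int = 0,
    dataset_name: str = "",
) -> list[ComparisonRecord]:
    """Subject-dependent evaluation: per repetition, hold out one positive
    and one negative trial of the subject, train on the rest of that
    subject's trials.

    Produces ``reps`` records per subject (2 judgments each, so a run over
    m subjects totals 2*m*reps judgments); per-subject mean accuracy comes
    from averaging a subject's records.  Transforms are fitted on the
    subject's training rows only.
    """
    table = data.table
    labels = table.labels(data.label_dim)
    rng = np.random.default_rng(seed)
    records: list[ComparisonRecord] = []
    for subj in table.subjects:
        mask = table.subject_ids == subj
        pos = np.flatnonzero(mask & (labels == 1))
        neg = np.flatnonzero(mask & (labels == 0))
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError(
                f"subject {subj!r} needs >= 2 rows per class for the "
                f"intra-subject protocol (has {len(pos)} positive, {len(neg)} negative)"
            )
        for rep in range(reps):
            test_idx = np.array([rng.choice(pos), rng.choice(neg)])
            train_idx = np.setdiff1d(np.flatnonzero(mask), test_idx)
            train_X, train_y = table.values[train_idx], labels[train_idx]
            test_X, test_y = table.values[test_idx], labels[test_idx]
            accs: dict[str, float] = {}
            for method in methods:
                if method == "none":
                    Xtr, Xte = train_X, test_X
                elif method == "zscore":
                    std = zscore_fit(train_X)
                    Xtr, Xte = zscore_apply(train_X, std), zscore_apply(test_X, std)
                elif method in ("binarize", "maxmin"):
                    fn = binarize if method == "binarize" else maxmin_scale
                    prof = fit_profile_from_matrix(train_X, subj)
                    Xtr, Xte = fn(train_X, prof), fn(test_X, prof)
                else:
                    raise ValueError(
                        f"unknown transform spec {method!r}; supported: {TRANSFORMS}"
                    )
                pred = classify(Xtr, train_y, Xte, classifier, seed=seed)
                accs[method] = float(np.mean(pred == test_y))
            records.append(
                ComparisonRecord(
                    test_subject=subj,
                    repetition=rep,
                    classifier=classifier,
                    label_dim=data.label_dim,
                    accuracies=accs,
                    dataset=dataset_name,
                )
            )
    return records


def scalability_curve(
    data: BalancedDataset,
    methods: list[str],
    classifier: str,
    p_values: list[int],
    seed: int = 0,
) -> dict[str, dict[int, float]]:
    """Accuracy as a function of the number of training subjects ``p``.

    For every test subject and every ``p``, ``p`` other subjects are drawn
    at random (the identical draw is reused across methods) and all their
    rows form the training set; the reported accuracy per (method, p) is
    the mean over test subjects.
    """
    table = data.table
    subjects = table.subjects
    labels = table.labels(data.label_dim)
    for p in p_values:
        if p < 1 or p >= len(subjects):
            raise ValueError(
                f"p={p} must satisfy 1 <= p < n_subjects ({len(subjects)})"
            )
    rng = np.random.default_rng(seed)
    sums: dict[str, dict[int, float]] = {m: {p: 0.0 for p in p_values} for m in methods}
    for subj in subjects:
        others = [s for s in subjects if s != subj]
        test_mask = table.subject_ids == subj
        test_X = table.values[test_mask]
        test_y = labels[test_mask]
        for p in p_values:
            train_subjects = rng.choice(np.array(others, dtype=object), size=p, replace=False)
            train_mask = np.isin(table.subject_ids, train_subjects)
            train_X = table.values[train_mask]
            train_y = labels[train_mask]
            train_subj = table.subject_ids[train_mask]
            for method in methods:
                Xtr, Xte = apply_transform_loso(method, train_X, train_subj, test_X, subj)
                pred = classify(Xtr, train_y, Xte, classifier, seed=seed)
                sums[method][p] += float(np.mean(pred == test_y))
    n = len(subjects)
    return {m: {p: sums[m][p] / n for p in p_values} for m in methods}
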