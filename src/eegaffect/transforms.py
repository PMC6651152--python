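"""Subject-aware and global feature transforms.

Three normalisations used when pooling EEG features across subjects:

* **median binarization** -- each feature becomes 1 iff it strictly exceeds
  that subject's per-feature median, else 0.  Because the median is an
  order statistic, the output is invariant to any strictly increasing
  per-feature, per-subject distortion of the raw features, which is what
  makes it effective at cancelling subject-specific baselines.
* **z-score** -- global standardisation with mean/sd fitted on the training
  set only.
* **max-min scaling** -- per-subject linear rescaling of each feature to
  [0, 1], clipped for unseen out-of-range values.

Subject profiles are fitted from feature rows only; labels are never
consulted, so a test subject's profile can be computed from unlabeled data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureTable

__all__ = [
    "SubjectProfile",
    "GlobalStandardizer",
    "fit_subject_profile",
    "fit_profile_from_matrix",
    "binarize",
    "maxmin_scale",
    "zscore_fit",
    "zscore_apply",
]


@dataclass
class SubjectProfile:
    """Per-subject, per-feature order statistics (median, min, max).

    Fitted from one subject's feature rows only; labels are not part of
    the interface.  For an even number of rows the median is the midpoint
    of the two central order statistics.
    """

    subject_id: object
    median: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.vmin = np.asarray(self.vmin, dtype=float)
        self.vmax = np.asarray(self.vmax, dtype=float)
        if not (self.median.shape == self.vmin.shape == self.vmax.shape):
            raise ValueError("median/min/max vectors must share one shape")
        if np.any(self.vmin > self.median) or np.any(self.median > self.vmax):
            raise ValueError("profile must satisfy min <= median <= max per feature")

    @property
    def n_features(self) -> int:
        return self.median.shape[0]

    def to_text(self, path) -> None:
        """Serialise to a small tab-delimited key-value file."""
        lines = [f"subject_id\t{self.subject_id}", f"n_samples\t{self.n_samples}"]
        for key, vec in (("median", self.median), ("min", self.vmin), ("max", self.vmax)):
            lines.append(key + "\t" + "\t".join(repr(float(v)) for v in vec))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "SubjectProfile":
        fields = {}
        for line in Path(path).read_text().splitlines():
            key, _, rest = line.partition("\t")
            fields[key] = rest
        return cls(
            subject_id=fields["subject_id"],
            median=np.array([float(v) for v in fields["median"].split("\t")]),
            vmin=np.array([float(v) for v in fields["min"].split("\t")]),
            vmax=np.array([float(v) for v in fields["max"].split("\t")]),
            n_samples=int(fields["n_samples"]),
        )


@dataclass
class GlobalStandardizer:
    """Per-feature mean and standard deviation fitted on training rows."""

    mean: np.ndarray
    std: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must share one shape")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be nonnegative")

    def to_text(self, path) -> None:
        lines = [f"n_samples\t{self.n_samples}"]
        for key, vec in (("mean", self.mean), ("std", self.std)):
            lines.append(key + "\t" + "\t".join(repr(float(v)) for v in vec))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "GlobalStandardizer":
        fields = {}
        for line in Path(path).read_text().splitlines():
            key, _, rest = line.partition("\t")
            fields[key] = rest
        return cls(
            mean=np.array([float(v) for v in fields["mean"].split("\t")]),
            std=np.array([float(v) for v in fields["std"].split("\t")]),
            n_samples=int(fields["n_samples"]),
        )


def fit_profile_from_matrix(X: np.ndarray, subject_id: object = None) -> SubjectProfile:
    """Fit a :class:`SubjectProfile` directly from a rows x features matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("cannot fit a subject profile from zero rows")
    return SubjectProfile(
        subject_id=subject_id,
        median=np.median(X, axis=0),
        vmin=X.min(axis=0),
        vmax=X.max(axis=0),
        n_samples=X.shape[0],
    )


def fit_subject_profile(table: FeatureTable, subject_id: object) -> SubjectProfile:
    """Fit per-feature median/min/max from one subject's rows of ``table``.

    Only the feature values are visible to the fit; labels never are.
    """
    mask = table.subject_ids == subject_id
    if not mask.any():
        raise ValueError(f"no rows for subject {subject_id!r} in feature table")
    return fit_profile_from_matrix(table.values[mask], subject_id=subject_id)


def _check_length(u: np.ndarray, profile_len: int, what: str) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != profile_len:
        raise ValueError(
            f"{what}: input has {u.shape[-1]} features but profile has {profile_len}"
        )
    return u


def binarize(u: np.ndarray, profile: SubjectProfile) -> np.ndarray:
    """Median binarization: 1 where ``u[k]`` strictly exceeds the subject
    median, 0 otherwise (ties map to 0).

    Accepts a single vector or a rows x features matrix; output has the
    same shape with values in {0, 1}.
    """
    u = _check_length(u, profile.n_features, "binarize")
    return (u > profile.median).astype(float)


def maxmin_scale(u: np.ndarray, profile: SubjectProfile) -> np.ndarray:
    """Per-subject scaling of each feature to [0, 1].

    ``(u - min) / (max - min)`` per feature, clipped to [0, 1] for values
    outside the fitted range; constant features (max == min) map to 0.
    """
    u = _check_length(u, profile.n_features, "maxmin_scale")
    span = profile.vmax - profile.vmin
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (u - profile.vmin) / span
    scaled = np.where(span == 0, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0)


def zscore_fit(X: np.ndarray) -> GlobalStandardizer:
    """Fit per-feature mean and sample standard deviation (ddof=1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("z-score fit needs at least 2 training rows")
    return GlobalStandardizer(
        mean=X.mean(axis=0),
        std=X.std(axis=0, ddof=1),
        n_samples=X.shape[0],
    )


def zscore_apply(x: np.ndarray, standardizer: GlobalStandardizer) -> np.ndarray:
    """Standardise ``(x - mean) / std`` elementwise; zero-sd features map to 0."""
    x = _check_length(x, standardizer.mean.shape[-1], "zscore_apply")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - standardizer.mean) / standardizer.std
    return np.where(standardizer.std == 0, 0.0, z)
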