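import numpy as np
import pytest
from hypothesis import settings

from eegaffect import FeatureTable

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


def make_table(n_subjects, rows_per_class, n_features, seed=0, subject_scale=0.0,
               effect=None):
    """Small balanced feature table with optional subject offsets / class effect."""
    rng = np.random.default_rng(seed)
    rows, subs, trials, ys = [], [], [], []
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        base = rng.normal(0, subject_scale, n_features) if subject_scale else np.zeros(n_features)
        for j in range(2 * rows_per_class):
            y = j % 2
            x = base + rng.normal(0, 1, n_features)
            if effect is not None and y == 1:
                x = x + effect
            rows.append(x)
            subs.append(sid)
            trials.append(f"{sid}_t{j}")
            ys.append(float(y))
    y_arr = np.array(ys)
    return FeatureTable(
        values=np.vstack(rows),
        feature_names=[f"f{j}" for j in range(n_features)],
        subject_ids=np.array(subs, dtype=object),
        trial_ids=np.array(trials, dtype=object),
        valence=y_arr,
        arousal=y_arr.copy(),
    )


@pytest.fixture
def small_table():
    """6 subjects x 4 rows/class x 8 features, no structure."""
    return make_table(6, 4, 8, seed=1)


@pytest.fixture
def separable_table():
    """Strongly class-separable table (large effect, no subject offsets)."""
    return make_table(4, 4, 5, seed=2, effect=np.full(5, 8.0))
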