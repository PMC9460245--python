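import numpy as np
import pytest

from harpipe import FeatureMatrix, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_subject_recordings():
    """Two short hand-built recordings with contiguous label bouts."""
    rng = np.random.default_rng(7)
    recs = []
    for sid in ("A", "B"):
        t = np.arange(1000) / 50.0
        walk = np.sin(2 * np.pi * 2.0 * t[:500])[:, None] + rng.normal(0, 0.1, (500, 2))
        idle = rng.normal(0, 0.05, (500, 2))
        samples = np.vstack([walk, idle])
        labels = np.array(["walk"] * 500 + ["idle"] * 500)
        recs.append(
            Recording(
                subject_id=sid,
                sample_rate_hz=50.0,
                channel_names=["x", "y"],
                samples=samples,
                labels=labels,
            )
        )
    return recs


def make_feature_matrix(values, names=None, subjects=None, labels=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureMatrix(
        feature_names=names or [f"f{i:02d}" for i in range(p)],
        values=values,
        subject_ids=np.asarray(subjects if subjects is not None else ["s"] * n),
        labels=np.asarray(labels if labels is not None else ["c0"] * n),
    )
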