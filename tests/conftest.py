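"""Shared fixtures: printed agreement tables, fast synthetic feature clusters,
and one session-scoped signal cohort reused by the expensive end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from somnoscore import features, simulate
from somnoscore.core import Hypnogram

# Published inter-scorer confusion rows (percent of each reference stage) and
# the per-stage epoch totals of the 72-night test set they accompany. These
# are printed inputs to the reconstruction checks, not values we compute.
TABLE1_ROW_PERCENT = np.array(
    [
        [94.0, 2.4, 2.2, 0.1, 1.3],
        [2.8, 83.9, 10.9, 0.1, 2.3],
        [1.1, 3.5, 89.0, 3.7, 2.7],
        [0.14, 0.21, 7.1, 92.0, 0.55],
        [1.2, 2.1, 3.6, 0.1, 93.0],
    ]
)
TABLE2_STAGE_EPOCHS = np.array([14662, 6577, 33319, 4548, 10485])
TABLE2_TOTAL_EPOCHS = 69591


@pytest.fixture(scope="session")
def table_counts() -> np.ndarray:
    """Pooled 5×5 count matrix reconstructed from the printed tables."""
    return TABLE1_ROW_PERCENT / 100.0 * TABLE2_STAGE_EPOCHS[:, None]


def make_cluster_subjects(
    n_subjects: int,
    epochs: int,
    seed: int = 0,
    n_features: int = 24,
    separation: float = 4.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Fast stage-separable synthetic features: Gaussian clusters around
    fixed per-stage means, labels from the sticky Markov stage model."""
    base = np.random.default_rng(12345)
    means = base.normal(0.0, separation, size=(5, n_features))
    out = {}
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i])
        h = simulate.generate_hypnogram(simulate.DEFAULT_STAGE_PROPORTIONS, epochs, rng)
        y = h.to_indices()
        X = means[y] + rng.standard_normal((epochs, n_features))
        out[f"c{i:02d}"] = (X, y)
    return out


@pytest.fixture(scope="session")
def cohort30():
    """Default 30-subject signal cohort with extracted features (shared; ~3 min)."""
    cfg = simulate.CohortConfig(seed=2024)
    cohort = simulate.generate_cohort(cfg)
    data = {}
    truths: dict[str, Hypnogram] = {}
    for rec, h in cohort:
        data[rec.subject_id] = (features.extract_features(rec), h)
        truths[rec.subject_id] = h
    return {"config": cfg, "data": data, "truths": truths}
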