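import numpy as np
import pytest

from chemgroup.descriptors import FeatureMatrix
from chemgroup.fixtures import make_labeled_features


@pytest.fixture(scope="session")
def planted_fm():
    """Labeled feature table: 5 informative + 15 noise columns, n=200."""
    X, y = make_labeled_features(200, 5, 15, 2.0, "binary", seed=0)
    fm = FeatureMatrix(
        row_ids=[f"r{i}" for i in range(200)],
        column_names=[f"inf{i}" for i in range(5)] + [f"noise{i}" for i in range(15)],
        values=X,
    )
    return fm, y


@pytest.fixture(scope="session")
def smiles_dataset():
    from chemgroup.fixtures import make_smiles_families

    return make_smiles_families(3, 15, salt_fraction=0.1, duplicate_fraction=0.1, seed=3)


def brute_force_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Independent double-loop silhouette: SI = (b - a) / max(a, b)."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    keep = labels != -1
    points, labels = points[keep], labels[keep]
    clusters = sorted(set(labels.tolist()))
    assert len(clusters) >= 2
    scores = []
    for i in range(len(points)):
        own = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if own:
            a = float(np.mean([np.linalg.norm(points[i] - points[j]) for j in own]))
        else:
            a = 0.0
        b = min(
            float(
                np.mean(
                    [
                        np.linalg.norm(points[i] - points[j])
                        for j in range(len(points))
                        if labels[j] == c
                    ]
                )
            )
            for c in clusters
            if c != labels[i]
        )
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))
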