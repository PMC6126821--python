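"""Synthetic labeled echo corpora for the classifier.

Glue between the scene generators, the echo synthesizer and the feature
extractor: build a balanced diffuse-vs-glint echo set, synthesize one
binaural recording per object at a random (gated, < 3 m) placement, and
extract the six 483-dimensional feature vectors per echo.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from . import acoustics, classify, scene as scene_mod
from .config import RunConfig


def make_echo_feature_dataset(n_per_class: int, config: RunConfig,
                              seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Features X (n, 6, 483) and labels y (1 = plant) for a balanced set.

    Each object is placed at a range uniform in [0.8, 2.5] m (inside the
    3 m classification gate) and azimuth uniform in +/- 20 degrees, and
    observed from the origin with the 0-degree heading.
    """
    rng = np.random.default_rng(seed)
    population = scene_mod.make_object_echo_population(n_per_class, seed)
    X, y = [], []
    for k, (obj, label) in enumerate(population):
        r = rng.uniform(0.8, 2.5)
        az = rng.uniform(-20.0, 20.0)
        sc = scene_mod.place_object_scene(obj, r, az)
        rec = acoustics.synthesize_echoes(sc, (0.0, 0.0, 0.0), 0.0,
                                          config.sonar, seed=seed + 31 * k)
        X.append(classify.features_for_recording(rec, config.sonar, config.classify))
        y.append(1.0 if label == scene_mod.PLANT else 0.0)
    return np.stack(X), np.asarray(y)


def train_test_split_echoes(X: np.ndarray, y: np.ndarray, test_fraction: float = 0.25,
                            seed: int = 0):
    """Stratified shuffle split (default 75/25)."""
    rng = np.random.default_rng(seed)
    test_idx = []
    train_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    return X[train_idx], y[train_idx], X[test_idx], y[test_idx]
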