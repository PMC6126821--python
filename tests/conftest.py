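"""Shared fixtures: expensive simulations run once per session."""

from __future__ import annotations

import numpy as np
import pytest

import echonav as en
from echonav.datasets import make_echo_feature_dataset, train_test_split_echoes
from echonav.scene import NON_PLANT, PLANT, Reflector, Scene, SceneObject


@pytest.fixture(scope="session")
def run_config() -> en.RunConfig:
    return en.RunConfig(seed=1)


@pytest.fixture(scope="session")
def chirp(run_config) -> np.ndarray:
    return en.generate_chirp(run_config.sonar)


@pytest.fixture(scope="session")
def corridor_scene() -> Scene:
    return en.make_corridor_scene(10.0, 3.0, 0.25)


@pytest.fixture(scope="session")
def corridor_mission(corridor_scene, run_config):
    """A full 10 m corridor traverse with the three-heading protocol."""
    return en.run_mission(corridor_scene, (0.3, 0.3, 0.0), run_config, max_steps=25)


@pytest.fixture(scope="session")
def summed_corridor_mission(corridor_scene, run_config):
    """The same corridor traversed in summed (wide-beam) mode."""
    return en.run_mission(corridor_scene, (0.3, 0.3, 0.0), run_config,
                          max_steps=25, summed_beam=True)


@pytest.fixture(scope="session")
def cylinder_mission(run_config):
    """Corridor with a 0.8 m cylinder in the path; the robot must detour."""
    obstacle = en.make_cylinder_object((5.0, 0.0), 0.8)
    scene = en.make_corridor_scene(10.0, 4.0, 0.25, obstacle=obstacle)
    result = en.run_mission(scene, (0.3, 0.0, 0.0), run_config, max_steps=40)
    return scene, result


def three_reflector_scene() -> Scene:
    """Three reflectors in one beam, separated by >0.7 m in range.

    Strengths increase with range so all three echoes clear the relative
    amplitude threshold under two-way spreading.
    """
    import math

    targets = [(1.0, 0.0, 0.30), (1.8, 5.0, 0.60), (2.6, -5.0, 1.0)]
    objects = []
    for i, (r, az, s) in enumerate(targets):
        a = math.radians(az)
        p = (r * math.cos(a), r * math.sin(a))
        objects.append(SceneObject(
            footprint=[(p[0] - 0.05, p[1] - 0.05), (p[0] + 0.05, p[1] - 0.05),
                       (p[0] + 0.05, p[1] + 0.05), (p[0] - 0.05, p[1] + 0.05)],
            reflectors=[Reflector(p, s)], id=f"target_{i}"))
    return Scene(objects=objects, bounds=(-1, -4, 4, 4))


def localization_sweep(config: en.RunConfig, n_trials: int = 100, seed: int = 1):
    """Single-reflector trials: ranges U(0.3, 3) m, azimuths U(-50, 50) deg."""
    chirp_ = en.generate_chirp(config.sonar)
    rng = np.random.default_rng(seed)
    trials = []
    misses = 0
    for k in range(n_trials):
        r = float(rng.uniform(0.3, 3.0))
        az = float(rng.uniform(-50.0, 50.0))
        scene = en.make_single_reflector_scene(r, az)
        rec = en.synthesize_echoes(scene, (0.0, 0.0, 0.0), 0.0, config.sonar,
                                   seed=seed * 1000 + k)
        dets = en.process_acquisition([rec], chirp_, config.sonar, config.detection)
        if not dets:
            misses += 1
            continue
        best = min(dets, key=lambda d: abs(d.range_m - r))
        trials.append(((r, az), best))
    return trials, misses


@pytest.fixture(scope="session")
def echo_classifier(run_config):
    """Dataset, split, trained ensemble and its held-out balanced accuracy."""
    X, y = make_echo_feature_dataset(40, run_config, seed=7)
    Xtr, ytr, Xte, yte = train_test_split_echoes(X, y, seed=7)
    model = en.train_ensemble(Xtr, ytr, run_config.classify, seed=7)
    labels = [PLANT if v else NON_PLANT for v in yte]
    preds = [en.predict(model, x)[0] for x in Xte]
    ba = en.balanced_accuracy(preds, labels)
    return {
        "X_train": Xtr, "y_train": ytr, "X_test": Xte, "labels_test": labels,
        "model": model, "balanced_accuracy": ba,
    }


@pytest.fixture(scope="session")
def permutation_result(echo_classifier, run_config):
    """The 100-permutation significance test (shared: it retrains 600 nets)."""
    return en.permutation_test(
        echo_classifier["X_train"], echo_classifier["y_train"],
        echo_classifier["X_test"], echo_classifier["labels_test"],
        observed_ba=echo_classifier["balanced_accuracy"],
        n_perm=100, config=run_config.classify, seed=11)
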