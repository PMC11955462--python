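"""Shared fixtures: the toy color task and its trained model.

The toy task — solid red vs solid blue 224x224 patches with mild pixel
noise — is linearly separable in color, so the reduced backbone must
learn it; the trained model is reused by classifier, Grad-CAM and
acceptance tests.
"""

import numpy as np
import pytest

from hemil.classifier import (BackboneConfig, TrainConfig, build_backbone, train)
from hemil.patches import normalize_patch

RED = (200, 40, 40)
BLUE = (40, 40, 200)

# hot-and-short: from-scratch training nails the separable color task within
# two epochs, and the best checkpoint is already sharp
TOY_TRAIN = TrainConfig(learning_rate=0.05, epochs=2, batch_size=4, seed=2)


def solid_patches(color, n, rng):
    out = []
    for _ in range(n):
        img = np.clip(np.array(color) + rng.integers(-20, 21, size=(224, 224, 3)),
                      0, 255).astype(np.uint8)
        out.append(normalize_patch(img))
    return np.stack(out).astype(np.float32)


def make_toy_data(seed=0, n_per_class=20):
    rng = np.random.default_rng(seed)
    red = solid_patches(RED, n_per_class, rng)
    blue = solid_patches(BLUE, n_per_class, rng)
    x = np.concatenate([red, blue])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    idx = rng.permutation(len(x))
    n_train = int(0.75 * len(x))
    return {"x": x, "y": y, "red": red, "blue": blue,
            "train_idx": idx[:n_train], "val_idx": idx[n_train:]}


@pytest.fixture(scope="session")
def toy_data():
    return make_toy_data()


@pytest.fixture(scope="session")
def toy_model(toy_data):
    """Reduced backbone trained to perfection on the red-vs-blue task."""
    d = toy_data
    model = build_backbone(BackboneConfig(stages=2, base_width=16), seed=1)
    model, records = train(model, d["x"][d["train_idx"]], d["y"][d["train_idx"]],
                           d["x"][d["val_idx"]], d["y"][d["val_idx"]], TOY_TRAIN)
    return {"model": model, "records": records}
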