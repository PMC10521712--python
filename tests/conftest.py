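import numpy as np
import pytest

from joshua_seg import (HistogramBlockConfig, ModelSpec, SyntheticSpec,
                        TrainConfig, build_model, render_synthetic_pair,
                        train_one)

# Desk-scale study conditions: 32 synthetic H&E-like 64x64 images, a tiny
# multiply-fusion histogram network (depth 2, 8 base channels, 4 bins),
# up to 20 epochs, three random initializations.
DESK_SYNTH = SyntheticSpec(n_images=32, height=64, width=64, seed=42)
DESK_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def blob_pairs():
    rng = np.random.default_rng(DESK_SYNTH.seed)
    return [render_synthetic_pair(DESK_SYNTH, rng)
            for _ in range(DESK_SYNTH.n_images)]


@pytest.fixture(scope="session")
def tiny_spec():
    return ModelSpec(variant="joshua_plus", depth=2, base_channels=8,
                     histogram=HistogramBlockConfig(8, 4, 2))


@pytest.fixture(scope="session")
def desk_train_config():
    return TrainConfig(epochs=20, patience=5, repeats_per_epoch=1,
                       batch_size=8)


@pytest.fixture(scope="session")
def smoke_runs(blob_pairs, tiny_spec, desk_train_config):
    """Three seeded desk-scale training runs of the tiny JOSHUA+ model.

    Returns a list of (model, record) pairs; shared across the suite so
    training happens once."""
    train, val = blob_pairs[:24], blob_pairs[24:]
    runs = []
    for seed in DESK_SEEDS:
        model = build_model(tiny_spec, seed)
        rec = train_one(model, train, val, desk_train_config, seed)
        runs.append((model, rec))
    return runs


@pytest.fixture(scope="session")
def smoke_model(smoke_runs):
    return smoke_runs[0][0]
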