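"""Shared fixtures: synthetic datasets and (expensive) trained models.

The benchmark fixtures run on a dense, boundary-ambiguous regime —
most cells touch or overlap a neighbor, per-cell brightness is nearly
uniform, and a faint membrane seam marks each border — because that is
the regime where separating touching cells (the hard part of the
problem) dominates accuracy.  Both training arms (with and without the
boundary auxnet) are trained for several seeds and reused across
tests; session scope keeps the total cost to a few CPU-minutes.
"""

import numpy as np
import pytest

from loiseg.metrics import evaluate_instances
from loiseg.network import ModelConfig
from loiseg.synthetic import SynthConfig, generate_scene
from loiseg.training import TrainConfig, TrainSample, train

# desk-scale study conditions: 96x96 scenes, 9-13 cells, 70% of cells
# exempt from the spacing constraint (touching/overlapping), narrow
# per-cell brightness spread, 1-px darker membrane seams
SCENE_KW = dict(
    image_size=96,
    n_cells_range=(9, 13),
    contact_fraction=0.7,
    min_center_spacing=16.0,
    cell_intensity_range=(0.62, 0.74),
    rim_shade=0.22,
    noise_sigma=0.06,
)
N_TRAIN = 32
N_VAL = 16
EPOCHS = 15
SEEDS = (0, 1, 2)


def _scene(seed):
    return generate_scene(SynthConfig(**SCENE_KW, seed=seed))


@pytest.fixture(scope="session")
def train_scenes():
    return [_scene(i) for i in range(N_TRAIN)]


@pytest.fixture(scope="session")
def val_scenes():
    return [_scene(1000 + i) for i in range(N_VAL)]


def _run_training(train_scenes, val_scenes, mode, seed):
    ds = [TrainSample(image=s.image, weak=s.weak) for s in train_scenes]
    val = [(s.image, s.instances) for s in val_scenes]
    return train(
        ModelConfig(seed=seed),
        TrainConfig(mode=mode, epochs=EPOCHS, seed=seed, val_every=3),
        ds,
        val_dataset=val,
    )


@pytest.fixture(scope="session")
def trained_weak_runs(train_scenes, val_scenes):
    """Weak-supervision arm (auxnet co-training), one run per seed."""
    return [
        _run_training(train_scenes, val_scenes, "weak", seed=s) for s in SEEDS
    ]


@pytest.fixture(scope="session")
def trained_no_auxnet_runs(train_scenes, val_scenes):
    """Ablation arm: identical data and schedule, auxnet terms absent."""
    return [
        _run_training(train_scenes, val_scenes, "weak_no_auxnet", seed=s)
        for s in SEEDS
    ]


@pytest.fixture(scope="session")
def trained_weak(trained_weak_runs):
    """Best weak run selected by validation AP50 (rerun-selection protocol)."""
    return max(trained_weak_runs, key=lambda r: r.best_val_ap50 or 0.0)


def evaluate_model(model, scenes):
    """Segment held-out scenes and compute the full report."""
    from loiseg.inference import segment_image

    per_image = []
    label_maps = []
    for s in scenes:
        res = segment_image(s.image, model)
        per_image.append(
            (
                [p.hard_mask(res.image_shape) for p in res.instances],
                [p.score for p in res.instances],
                s.instances,
            )
        )
        label_maps.append(res.label_map)
    return evaluate_instances(per_image, label_maps=label_maps)
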