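"""Shared fixtures: small phantom datasets and one desk-scale trained run.

The ``desk_run`` fixture trains the full framework once per session under
the reference desk-scale conditions (200 training images at 64x64, pooled
lesion:background ratio about 1:100, K=3 discriminators with mae/cce/dice,
N=5 MC samples, 5 epochs) and evaluates it on held-out in-distribution and
domain-shifted batches; several tests assert different properties of the
same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from uqgan import (ClassFrequencySpec, DiscriminatorSpec, DropoutConfig,
                   GeneratorSpec, ObjectiveConfig, TrainConfig, desk_spec,
                   apply_domain_shift, build_generator, compute_moments,
                   generate_segmentation_dataset, train)
from uqgan.synthetic_data import ShiftSpec

DESK_SEED = 7


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """20 small (32x32) phantoms for fast training tests."""
    return generate_segmentation_dataset(desk_spec((32, 32)), 20, seed=5)


@pytest.fixture(scope="session")
def tiny_specs():
    gs = GeneratorSpec(stacks=1, base_channels=6, n_classes=3, noise_dim=8,
                       n_down=2)
    ds = DiscriminatorSpec(patch_receptive_field=8, base_channels=6,
                           loss_type="cce")
    return gs, ds


@dataclass
class DeskRun:
    generator: object
    params: object
    freq: ClassFrequencySpec
    dropout: DropoutConfig
    history: object
    gspec: GeneratorSpec
    train_set: list
    test_set: list
    ood_set: list
    moments_id: list
    moments_ood: list


@pytest.fixture(scope="session")
def desk_run() -> DeskRun:
    spec = desk_spec((64, 64))
    all_imgs = generate_segmentation_dataset(spec, 250, seed=1000 + DESK_SEED)
    train_set, test_set = all_imgs[:200], all_imgs[200:]
    ood_set = apply_domain_shift(test_set, ShiftSpec(), seed=2000 + DESK_SEED)

    gspec = GeneratorSpec()
    dspecs = [DiscriminatorSpec(loss_type=l) for l in ("mae", "cce", "dice")]
    dropout = DropoutConfig(sigma=0.1, n_samples=5, seed=DESK_SEED)
    cfg = TrainConfig(epochs=5, seed=DESK_SEED, dropout=dropout,
                      objective=ObjectiveConfig())
    params, history = train(train_set, None, gspec, dspecs, cfg)

    G = build_generator(gspec, seed=DESK_SEED)
    freq = ClassFrequencySpec.from_masks([s.mask for s in train_set], 3)
    zr = np.random.default_rng([DESK_SEED, 15])
    moments_id = []
    moments_ood = []
    for s in test_set:
        z = zr.normal(size=gspec.noise_dim)
        moments_id.append(compute_moments(G, params, s.image, z, dropout, freq))
    for s in ood_set:
        z = zr.normal(size=gspec.noise_dim)
        moments_ood.append(compute_moments(G, params, s.image, z, dropout, freq))
    return DeskRun(generator=G, params=params, freq=freq, dropout=dropout,
                   history=history, gspec=gspec, train_set=train_set,
                   test_set=test_set, ood_set=ood_set,
                   moments_id=moments_id, moments_ood=moments_ood)
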