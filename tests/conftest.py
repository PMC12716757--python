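"""Shared fixtures: default LGN front-end and a small trained network.

The ``tiny_trainer`` fixture trains a deliberately small network (16 E / 4 I,
8x8 patches, short schedule) once per session; tests that need a trained
model (probes, resume-equivalence baselines, transform) reuse it.
"""

import numpy as np
import pytest

import sparsev1 as s


@pytest.fixture(scope="session")
def lgn():
    return s.LgnConfig()


@pytest.fixture(scope="session")
def lgn8():
    return s.LgnConfig(patch_size=8)


def tiny_config(**overrides):
    base = dict(
        patch_size=8, n_x=128, n_e=16, n_i=4,
        l1_ex=25.0, l1_ee=0.4, l1_ei=4.8, l1_ix=20.0, l1_ie=9.6, l1_ii=4.8,
        eta_ex=3.2e-3, eta_ee=1.6e-3, eta_ei=1.44, eta_ix=4.8e-2,
        eta_ie=0.64, eta_ii=0.96,
        n_batches=20, batch_size=10, warmup_batches=3,
        presentation_ms=200.0, pool_size=100, n_images=20, image_size=32,
    )
    base.update(overrides)
    return s.RunConfig(**base).validate()


@pytest.fixture(scope="session")
def tiny_trainer():
    return s.train(tiny_config(), seed=11)
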