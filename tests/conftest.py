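"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from aslica.asl_io import AslAcquisition, ImageSeries
from aslica.preprocess import AslSub, subtract_pairs, tissue_masks
from aslica.synthgen import (
    NoiseComponentSpec,
    make_phantom,
    noise_profile,
    simulate_dataset,
)

PAPER_PLDS = (0.4, 0.8, 1.2, 1.6, 2.0)


@pytest.fixture(scope="session")
def acq() -> AslAcquisition:
    return AslAcquisition(plds=PAPER_PLDS)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom((32, 32, 8), seed=1)


def build_subtracted(phantom, acq, noise, seed):
    """Simulate, subtract and attach masks; returns (sub, m0, truth)."""
    raw, m0, motion, truth = simulate_dataset(
        phantom, acq, noise=noise, seed=seed
    )
    sub = subtract_pairs(raw, acq, motion=motion)
    gm, nonbrain = tissue_masks(
        ImageSeries(phantom.pve_gm, np.eye(4), (1.0, 1.0, 1.0)),
        ImageSeries(phantom.brain_mask.astype(float), np.eye(4), (1.0, 1.0, 1.0)),
    )
    sub.gm_mask = gm
    sub.brain_mask = phantom.brain_mask
    sub.nonbrain_mask = nonbrain
    return sub, m0, truth


@pytest.fixture(scope="session")
def clean_dataset(phantom, acq):
    """Noiseless dataset: the difference series is exactly the kinetic dM."""
    return build_subtracted(phantom, acq, noise=[], seed=1)


@pytest.fixture(scope="session")
def full_noise_dataset(phantom, acq):
    """Default full-noise profile (motion-edge + drift + CSF + thermal)."""
    noise = noise_profile("full", phantom, acq, seed=3)
    return build_subtracted(phantom, acq, noise=noise, seed=3)


@pytest.fixture(scope="session")
def thermal_dataset(phantom, acq):
    """Thermal-only noise at the default sigma."""
    noise = [NoiseComponentSpec(kind="thermal", amplitude=2.0)]
    return build_subtracted(phantom, acq, noise=noise, seed=5)
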