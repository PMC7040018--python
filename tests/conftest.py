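"""Shared fixtures: small rendered droplets and cached study features."""

from __future__ import annotations

import numpy as np
import pytest

from dropsig.pipeline import (
    RunConfig,
    default_class_effect,
    default_two_condition_design,
    matched_sigma,
    study_features,
)
from dropsig.synthetic import DropletPhenotype, StudyDesign, generate_study, render_droplet


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    return StudyDesign(n_participants=2, conditions=("baseline", "rec6"), master_seed=0)


@pytest.fixture(scope="session")
def droplet(small_design):
    """One default crack-bearing droplet render with ground truth."""
    return render_droplet(small_design, DropletPhenotype(), rotation=0.3, seed=42)


@pytest.fixture(scope="session")
def study_sigma(small_design) -> float:
    return matched_sigma(small_design.droplet_radius_px)


@pytest.fixture(scope="session")
def strong_study_features():
    """Per-seed cached features of the full strong-effect study (30 x 2 x 10).

    Returns a callable seed -> (cfg, features); images are released after
    feature extraction to keep memory flat.
    """
    cache: dict[int, tuple[RunConfig, dict]] = {}

    def get(seed: int):
        if seed not in cache:
            cfg = RunConfig(design=default_two_condition_design(master_seed=seed))
            study = generate_study(cfg.design, default_class_effect(1.0))
            cache[seed] = (cfg, study_features(study, cfg))
        return cache[seed]

    return get


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
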