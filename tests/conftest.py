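"""Shared fixtures: tiny smoke cohorts and the desk-scale benchmark runs."""

from __future__ import annotations

import numpy as np
import pytest

from daaemil.backbone import BackboneConfig, build_backbone
from daaemil.daae import MilModel, TrainConfig, train_stage1
from daaemil.synthetic import CohortConfig, generate_cohort

SMOKE_SHAPE = (12, 12, 6)


def smoke_cohort_config(seed: int = 0, n: int = 16) -> CohortConfig:
    return CohortConfig(n_patients=n, prevalence=0.5, volume_shape=SMOKE_SHAPE,
                        key_slice_range=(1, 1), lesion_effect=4.0,
                        n_radiomics=30, n_radiomics_informative=4,
                        radiomics_effect=1.5, seed=seed)


def smoke_backbone_config(seed: int = 0) -> BackboneConfig:
    return BackboneConfig(widths=(4, 8), pools=((2, 2, 1), (2, 2, 1)),
                          feature_dim=8, seed=seed)


@pytest.fixture(scope="session")
def smoke_cohort():
    return generate_cohort(smoke_cohort_config(n=40))


@pytest.fixture(scope="session")
def trained_smoke_model(smoke_cohort):
    """A quickly trained dual-attention model on the tiny smoke cohort."""
    volumes, _, _, truth = smoke_cohort
    extractor = build_backbone(smoke_backbone_config(),
                               input_shape=volumes.shape[1:])
    model = MilModel(extractor, pooling="daae", attention_dim=8, proj_dim=8,
                     seed=0)
    model, log = train_stage1(volumes, truth.bag_labels, model,
                              TrainConfig(lr=3e-3, max_epochs=30, patience=30,
                                          seed=0))
    return model, log


@pytest.fixture(scope="session")
def benchmark_results():
    """Full recovery benchmark, one dict of headline numbers per seed."""
    from daaemil.benchmark import run_benchmark_seed
    return {seed: run_benchmark_seed(seed) for seed in (1, 2, 3)}
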