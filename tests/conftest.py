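"""Shared fixtures: small generator configs and one cached default study.

The "default study" — ten synthetic datasets at the default generator
conditions, preprocessed and cross-validated leave-three-batches-out —
is computed once per session and shared by the end-to-end, variance and
acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import sersid

N_STUDY_SEEDS = 10


@pytest.fixture(scope="session")
def default_config() -> sersid.GeneratorConfig:
    return sersid.default_class_templates()


@pytest.fixture(scope="session")
def small_config(default_config) -> sersid.GeneratorConfig:
    """Reduced replicate count for fast per-module tests."""
    return dataclasses.replace(default_config, n_per_batch=4)


@dataclasses.dataclass
class StudyRun:
    seed: int
    preprocessed: sersid.SpectrumSet
    summed: sersid.ConfusionMatrix
    per_split: list
    report: sersid.MetricsReport
    variance_4pc: float


def run_study(config: sersid.GeneratorConfig, seed: int) -> StudyRun:
    """Generate, preprocess and leave-three-batches-out validate one dataset."""
    cfg = dataclasses.replace(config, seed=seed)
    sset, dark = sersid.generate_dataset(cfg)
    pre = sersid.preprocess_set(sset, dark)
    pca = sersid.pca_fit(pre.to_matrix(), 4)
    plan = sersid.enumerate_splits(cfg.n_batches, 3)
    summed, per_split = sersid.cross_validate(pre, plan, n_pcs=4, cost_C=1.0)
    report = sersid.compute_metrics(summed, per_split)
    return StudyRun(
        seed=seed,
        preprocessed=pre,
        summed=summed,
        per_split=per_split,
        report=report,
        variance_4pc=float(pca.explained_variance_ratio.sum()),
    )


@pytest.fixture(scope="session")
def default_study(default_config) -> list[StudyRun]:
    """Ten full pipeline runs at the default study conditions."""
    return [run_study(default_config, seed) for seed in range(N_STUDY_SEEDS)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
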