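"""Shared fixtures: small simulated cohorts and a trained pipeline.

The trained pipeline is session-scoped because numpy training, while quick,
is the dominant cost; interpretation and robustness tests reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dismir.model import SMALL_CONFIG
from dismir.pipeline import train_pipeline
from dismir.simulate import SimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

TRAIN_DESIGN = (
    [("healthy_plasma", 0.0, 1500)] * 18 + [("tumor_tissue", 1.0, 3000)] * 9
)


@pytest.fixture(scope="session")
def default_scenario():
    """Default-signal cohort: 18 healthy plasma + 9 tumor tissue samples."""
    cfg = SimConfig(seed=7)
    reference, samples = simulate_cohort(cfg, TRAIN_DESIGN, seed=7)
    return cfg, reference, samples


@pytest.fixture(scope="session")
def cohort_reads(default_scenario):
    _, _, samples = default_scenario
    healthy = [r for s in samples if s.meta.class_label == "healthy_plasma"
               for r in s.reads]
    tumor = [r for s in samples if s.meta.class_label == "tumor_tissue"
             for r in s.reads]
    return healthy, tumor


@pytest.fixture(scope="session")
def trained(default_scenario, cohort_reads):
    """A 2-member ensemble trained on the default scenario."""
    _, reference, _ = default_scenario
    healthy, tumor = cohort_reads
    return train_pipeline(
        healthy, tumor, reference.chrom_sizes,
        model_cfg=SMALL_CONFIG, n_members=2, seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
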