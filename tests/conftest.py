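"""Shared fixtures.

Two cohort scales are used: a "fast" configuration with a high pump rate
and short records for unit-level checks (same physiology, compressed
timeline), and full protocol-scale cohorts (default configuration) for
the cohort-level statistical checks, shared session-wide because they
are expensive to build.
"""

from __future__ import annotations

import numpy as np
import pytest

from blvest.cohort import SimConfig, generate_cohort
from blvest.features import extract_cohort_features


def fast_config(**overrides) -> SimConfig:
    """Compressed-timeline configuration: ~2-3 min baseline, ~10 min bleed
    at 150 mL/min, so full records take seconds to synthesize."""
    cfg = SimConfig(
        baseline_min_s=120.0,
        baseline_max_s=180.0,
        pump_rate_ml_min=150.0,
        bleed_total_min_s=480.0,
        bleed_total_max_s=720.0,
        max_bleed_total_s=1500.0,
        n_segments_range=(2, 3),
        refill_tau_s=240.0,
        hct_refill_tau_s=300.0,
        hct_draw_interval_s=240.0,
        artifact_fraction=0.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def fast_cohort():
    return generate_cohort(4, fast_config(), seed=11)


@pytest.fixture(scope="session")
def fast_features(fast_cohort):
    return extract_cohort_features(fast_cohort)


@pytest.fixture(scope="session")
def cohort10():
    """Ten subjects under the default (protocol-scale) configuration."""
    return generate_cohort(10, SimConfig(), seed=5)


@pytest.fixture(scope="session")
def features10(cohort10):
    return extract_cohort_features(cohort10)


@pytest.fixture(scope="session")
def cohort40():
    """The default 40-subject cohort used for cohort-level statistics."""
    return generate_cohort(40, SimConfig(), seed=7)


@pytest.fixture(scope="session")
def features40(cohort40):
    return extract_cohort_features(cohort40)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
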