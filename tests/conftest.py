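"""Shared fixtures: small epoch sets and reduced-size synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from icf_histology.preprocess import EpochSet
from icf_histology.synthetic_data import (
    ArtifactSpec,
    ExprFixtureConfig,
    SynthConfig,
    generate_expression_fixture,
    generate_tep_dataset,
)


def make_epochs(
    data: np.ndarray,
    sfreq: float = 1000.0,
    t0: float = -600.0,
    ch_names: list[str] | None = None,
) -> EpochSet:
    """EpochSet with a time axis starting at ``t0`` ms."""
    data = np.asarray(data, dtype=float)
    n_t = data.shape[2]
    times = t0 + np.arange(n_t) * 1000.0 / sfreq
    if ch_names is None:
        from icf_histology.atlas import CHANNELS_64

        ch_names = list(CHANNELS_64[: data.shape[1]])
    return EpochSet(data=data, ch_names=ch_names, sfreq=sfreq, times=times)


def noise_epochs(
    rng: np.random.Generator,
    n_trials: int = 8,
    n_channels: int = 16,
    sfreq: float = 1000.0,
    t0: float = -600.0,
    n_t: int = 801,
    sd: float = 10.0,
) -> EpochSet:
    return make_epochs(
        sd * rng.standard_normal((n_trials, n_channels, n_t)), sfreq, t0
    )


#: Small cohort settings used throughout the unit tests: full atlas, one
#: source per region, short epochs, modest trial/channel counts.
SMALL_COHORT = SynthConfig(
    n_trd=4,
    n_hc=3,
    n_trials_per_condition=6,
    n_channels=16,
    sampling_rate=1000.0,
    epoch_window=(-600.0, 200.0),
    n_sources_per_region=1,
    seed=11,
)

ARTIFACT_COHORT = SynthConfig(
    n_trd=1,
    n_hc=1,
    n_trials_per_condition=12,
    n_channels=16,
    sampling_rate=3000.0,
    epoch_window=(-600.0, 400.0),
    n_sources_per_region=1,
    artifact_spec=ArtifactSpec(
        n_bad_channels=1, n_bad_epochs=3, n_tms_transients=2
    ),
    seed=5,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_tep_dataset(SMALL_COHORT)


@pytest.fixture(scope="session")
def artifact_dataset():
    return generate_tep_dataset(ARTIFACT_COHORT)


@pytest.fixture(scope="session")
def expression_fixture():
    cfg = ExprFixtureConfig(planted_correlation=0.6, seed=7)
    return generate_expression_fixture(cfg)


@pytest.fixture(scope="session")
def null_expression_fixture():
    cfg = ExprFixtureConfig(planted_correlation=0.0, seed=3)
    return generate_expression_fixture(cfg)
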