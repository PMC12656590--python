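import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bcgaf import RhythmLabel, SensorPlacement, SynthParams
from bcgaf.preprocess import featurize_recordings
from bcgaf.synth import generate_cohort
from bcgaf.types import SpectrumSetting

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def hr60_params() -> SynthParams:
    """Fixed 60 bpm so the harmonic comb sits exactly at 1, 2, 3 Hz."""
    return SynthParams(mean_hr_bpm=60.0, hr_jitter_bpm=0.0)


@pytest.fixture(scope="session")
def bcg2_cohort(default_params):
    """Small labelled cohort, chest-level channel only, with artifacts."""
    return generate_cohort(
        3, 4, default_params, seed=101, placements=[SensorPlacement.BCG2]
    )


@pytest.fixture(scope="session")
def bcg2_features(bcg2_cohort):
    """Featurized chest-channel cohort under two grid settings."""
    settings_ = [SpectrumSetting(0.0, 10.0, 30), SpectrumSetting(100.0, 250.0, 10)]
    return featurize_recordings(bcg2_cohort, None, settings_)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
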