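import numpy as np
import pytest
from hypothesis import settings

import swnc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_scenario():
    """Default 5-sensor, 9-class scenario at a reduced desk scale."""
    return swnc.default_paper_scenario(
        n_subjects=3, windows_per_pair=3, rate=25.0, window_duration=4.0
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    cfg, profiles, placements = small_scenario
    return swnc.generate_dataset(cfg, profiles, placements)


def make_tiny_scenario(m=2, n=3, **overrides):
    """A hand-rolled M-sensor, N-class scenario for counting/contract tests."""
    placements = [
        swnc.SensorPlacement(i + 1, f"s{i + 1}", mobility=1.0 + 0.2 * i)
        for i in range(m)
    ]
    profiles = []
    for cls in range(1, n + 1):
        angle = cls * np.pi / (2 * n)
        static = {p.sensor_id: (np.sin(angle), np.cos(angle)) for p in placements}
        dynamic = {p.sensor_id: (0.1 * cls, 0.8 * cls, 2) for p in placements}
        profiles.append(
            swnc.ActivityProfile(cls, f"act{cls}", static, dynamic, jitter=0.05)
        )
    cfg = swnc.SyntheticDatasetConfig(
        n_sensors=m,
        n_classes=n,
        n_subjects=overrides.pop("n_subjects", 2),
        rate=overrides.pop("rate", 20.0),
        window_duration=overrides.pop("window_duration", 2.0),
        windows_per_pair=overrides.pop("windows_per_pair", 4),
        noise_floor=overrides.pop("noise_floor", 0.01),
        seed=overrides.pop("seed", 7),
        **overrides,
    )
    return cfg, profiles, placements


@pytest.fixture()
def tiny_scenario():
    return make_tiny_scenario()


@pytest.fixture()
def tiny_dataset(tiny_scenario):
    return swnc.generate_dataset(*tiny_scenario)
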