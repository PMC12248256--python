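import numpy as np
import pytest

from pape.synthetic import (ParticipantProfile, ScenarioConfig,
                            generate_session)


@pytest.fixture(scope="session")
def profile():
    return ParticipantProfile("P01", sex_code=1, age=25.0, height=179.0,
                              weight=70.0, fvc=5.0)


@pytest.fixture(scope="session")
def small_config():
    """Campaign scenario trimmed for test speed: short transits and a 2 Hz
    physiological stream (the cadence itself is exercised separately)."""
    return ScenarioConfig(transit_min=2.0, physio_rate_hz=2.0, rng_seed=7)


@pytest.fixture(scope="session")
def session(profile, small_config):
    return generate_session(profile, small_config, seed=11)


def constant_scenario(level: float = 25.0, rr: float = 15.0, pr: float = 90.0,
                      **kwargs) -> ScenarioConfig:
    """Zero-variance scenario: every label shares one concentration level
    (PM fractions ordered level-1/level/level+1) and constant physiology,
    so downstream results have closed forms."""
    regimes = {}
    physio = {}
    from pape.synthetic import STATIC_LABELS, default_regimes
    base = default_regimes()
    for lbl in STATIC_LABELS:
        regimes[lbl] = {**{ch: (m, 0.0) for ch, (m, _) in base[lbl].items()},
                        "pm1": (level - 1.0, 0.0), "pm2_5": (level, 0.0),
                        "pm10": (level + 1.0, 0.0), "co2": (level, 0.0),
                        "tvoc": (level, 0.0)}
        physio[lbl] = {"rr": (rr, 0.0), "pr": (pr, 0.0)}
    kwargs.setdefault("transit_min", 2.0)
    kwargs.setdefault("physio_rate_hz", 2.0)
    return ScenarioConfig(regime_params=regimes, physio_params=physio, **kwargs)
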