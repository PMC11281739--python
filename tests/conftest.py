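import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from backvalue import SimulationConfig, generate_episodes, generate_registers

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """A modest 12-practice, two-year simulated dataset for generic tests."""
    cfg = SimulationConfig(
        seed=7, n_practices=12, register_size_range=(2_000, 4_000),
        years=("2018/19", "2019/20"),
    )
    registers = generate_registers(cfg)
    episodes = generate_episodes(cfg, registers)
    return cfg, registers, episodes


@pytest.fixture(scope="session")
def null_sim():
    """Exchangeable practices: no practice effect and no deprivation
    gradient, large registers — every systematic source of between-practice
    variation switched off."""
    cfg = SimulationConfig(
        seed=0, n_practices=40, register_size_range=(8_000, 8_000),
        years=("2019/20",), practice_sigma=0.0, decile_rate_ratio=1.0,
    )
    registers = generate_registers(cfg)
    episodes = generate_episodes(cfg, registers)
    return cfg, registers, episodes


@pytest.fixture(scope="session")
def gradient_sim():
    """A two-fold deprivation gradient with no practice effects, sized to
    exceed 1e5 person-years in every IMD decile."""
    cfg = SimulationConfig(
        seed=1, n_practices=40, register_size_range=(60_000, 60_000),
        years=("2019/20",), practice_sigma=0.0, decile_rate_ratio=2.0,
    )
    registers = generate_registers(cfg)
    episodes = generate_episodes(cfg, registers)
    return cfg, registers, episodes


@pytest.fixture()
def tiny_tables():
    """Hand-built two-practice registers and episodes for exact oracles."""
    registers = pd.DataFrame({
        "practice_id": ["pA"] * 4 + ["pB"] * 4,
        "age_band": ["40-44", "40-44", "60-64", "60-64"] * 2,
        "sex": ["F", "M", "F", "M"] * 2,
        "imd_decile": [2, 2, 2, 2, 9, 9, 9, 9],
        "count": [500, 500, 250, 250, 400, 400, 200, 200],
        "deprivation_score": [2.0] * 4 + [9.0] * 4,
    })
    episodes = pd.DataFrame({
        "patient_id": [f"pt{i}" for i in range(10)],
        "age": [42, 43, 61, 62, 44, 41, 63, 60, 42, 62],
        "sex": ["F", "M", "F", "M", "F", "M", "F", "M", "F", "M"],
        "practice_id": ["pA"] * 6 + ["pB"] * 4,
        "imd_decile": [2] * 6 + [9] * 4,
        "fiscal_year": ["2019/20"] * 10,
        "event_class": ["procedure", "attendance"] * 5,
        "intervention_id": [""] * 10,
    })
    return registers, episodes
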