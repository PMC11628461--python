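import pytest

from ventpower import RespiratoryMechanics, SearchSpace, minimize_total_power


@pytest.fixture(scope="session")
def normal_lung() -> RespiratoryMechanics:
    """Normal lung with an 8-mm endotracheal tube: E=10 mbar/L, R=1+7 mbar/L/s."""
    return RespiratoryMechanics(
        elastance=10.0, airway_resistance=1.0, tube_resistance=7.0, dead_space=0.2
    )


@pytest.fixture(scope="session")
def stiff_lung() -> RespiratoryMechanics:
    """Stiff (ARDS-like) lung with a 7-mm tube: E=20 mbar/L, R=1+12 mbar/L/s."""
    return RespiratoryMechanics(
        elastance=20.0, airway_resistance=1.0, tube_resistance=12.0, dead_space=0.2
    )


@pytest.fixture(scope="session")
def panel_mechanics() -> list[RespiratoryMechanics]:
    """The four (elastance, tube-resistance) panels: {10, 20} x {7, 12}."""
    return [
        RespiratoryMechanics(elastance=e, airway_resistance=1.0, tube_resistance=rt,
                             dead_space=0.2)
        for e in (10.0, 20.0)
        for rt in (7.0, 12.0)
    ]


@pytest.fixture(scope="session")
def total_optimum(normal_lung):
    """Full-resolution (1-mL) total-power minimization for the normal lung at
    10 L/min alveolar ventilation; shared because it is the slowest call."""
    return minimize_total_power(normal_lung, 10.0, objective="total")


@pytest.fixture(scope="session")
def coarse_space() -> SearchSpace:
    """5-mL grid for qualitative curve/panel tests."""
    return SearchSpace(vt_min=0.21, vt_max=2.0, vt_step=0.005)
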