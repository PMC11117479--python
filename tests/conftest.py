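import pytest

from gradchip import (
    ChamberGeometry,
    SolverConfig,
    default_geometry,
    default_layout,
    default_profile,
)


@pytest.fixture
def geometry() -> ChamberGeometry:
    return default_geometry()


@pytest.fixture
def layout():
    return default_layout()


@pytest.fixture
def profile():
    return default_profile()


@pytest.fixture
def solver_config() -> SolverConfig:
    return SolverConfig()


@pytest.fixture
def duct_geometry() -> ChamberGeometry:
    """Uniform straight-duct degenerate geometry for analytic comparisons:
    the exchange window spans the whole chamber and the cavity matches the
    channel width, so the chamber is just a widened duct section."""
    return ChamberGeometry(
        chamber_width_um=125.0,
        chamber_length_um=6400.0,
        exchange_window_width_um=125.0,
        exchange_window_length_um=6400.0,
    )


@pytest.fixture
def duct_config() -> SolverConfig:
    return SolverConfig(
        channel_width_um=125.0,
        window_transmissibility=1.0,
        diffusivity_m2_s=1e-12,
        grid_cells_per_chamber=5,
        entry_length_um=500.0,
        channel_segment_length_um=500.0,
    )
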