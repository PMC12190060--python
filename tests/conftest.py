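import numpy as np
import pytest

from squidhab import (
    FieldConfig,
    GridSpec,
    RasterField,
    TruthParams,
    generate_env_fields,
    generate_vessel_records,
)


@pytest.fixture
def small_grid() -> GridSpec:
    """4 x 4 degree box at 0.1 degrees (40 x 40 cells), nesting 0.5 and 1."""
    return GridSpec(110.0, 114.0, 6.0, 10.0, 0.1)


@pytest.fixture
def tiny_grid() -> GridSpec:
    """1 x 1 degree box at 0.1 degrees (10 x 10 cells)."""
    return GridSpec(110.0, 111.0, 7.0, 8.0, 0.1)


@pytest.fixture
def planar_field(tiny_grid) -> RasterField:
    lon, lat = np.meshgrid(tiny_grid.lon_centers, tiny_grid.lat_centers)
    return RasterField(tiny_grid, "2016-03", "sst", "degC", lat + lon)


@pytest.fixture(scope="session")
def seasonal_env():
    """One representative month per season on a small grid, fixed seed."""
    grid = GridSpec(110.0, 114.0, 6.0, 10.0, 0.1)
    return generate_env_fields(
        grid, ["2016-03", "2016-06", "2016-09", "2016-12"], FieldConfig(), seed=7
    )


@pytest.fixture(scope="session")
def seasonal_records(seasonal_env):
    return generate_vessel_records(seasonal_env, TruthParams(), seed=7)
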