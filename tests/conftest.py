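import numpy as np
import pytest

from pearlclim import synthetic
from pearlclim.morphometry import PopulationSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


#: compact world used across tests: full latitude span (so the MST gradient
#: covers the calibration range) but a narrow longitude band for speed
SMALL_WORLD_SPEC = synthetic.WorldSpec(seed=7, lon_range=(5.0, 10.0))


@pytest.fixture(scope="session")
def world_spec():
    return SMALL_WORLD_SPEC


@pytest.fixture(scope="session")
def world_grid(world_spec):
    return synthetic.generate_climate(world_spec)


@pytest.fixture(scope="session")
def world(world_spec, world_grid):
    populations, shells, truth = synthetic.generate_populations(world_spec, world_grid)
    return {
        "spec": world_spec,
        "grid": world_grid,
        "populations": populations,
        "shells": shells,
        "truth": truth,
    }


def make_population(
    i,
    mean_sci,
    *,
    status="viable",
    period="recent",
    lat=60.0,
    lon=10.0,
    altitude=50.0,
    mean_length=100.0,
    mean_width=None,
    n_shells=20,
    year=2000,
):
    """Hand-built population sample for statistical unit tests."""
    if mean_width is None:
        mean_width = mean_sci / 100.0 * mean_length
    return PopulationSample(
        population_id=f"p{i}",
        n_shells=n_shells,
        mean_sci=mean_sci,
        sem_sci=0.5,
        mean_length_mm=mean_length,
        mean_height_mm=0.5 * mean_length,
        mean_width_mm=mean_width,
        status=status,
        period=period,
        latitude_deg=lat,
        longitude_deg=lon,
        altitude_m=altitude,
        year_collected=year,
    )
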