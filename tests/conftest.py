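import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from duckscape.grids import Grid
from duckscape.simdata import LandscapeStack, SimConfig, YearState

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_config():
    """A fast desk-top configuration: 16 x 16 km, 2 strata, 3-year horizon."""
    return SimConfig(
        grid_ncols=40,
        grid_nrows=40,
        cell_size_m=400.0,
        n_strata=2,
        transect_spacing_km=2.4,
        segment_length_km=8.0,
        n_years=3,
        population_series=(3000, 4000, 3500),
        seed=7,
    )


def uniform_grid(value, nrows=4, ncols=5, cell_size=400.0):
    return Grid(np.full((nrows, ncols), float(value)), cell_size=cell_size)


def tiny_landscape(nrows=4, ncols=5, wetland=2.0, grass=0.3, crop=0.3):
    """A uniform hand-built landscape for settling/observation unit tests."""
    g = lambda v: uniform_grid(v, nrows, ncols)
    return LandscapeStack(
        wetland_count=g(wetland),
        wetland_area=g(wetland * 0.01),
        elevation=g(600.0),
        dd5=g(1400.0),
        ami=g(3.0),
        sspb=g(1.1),
        crop=g(crop),
        grass=g(grass),
        forest=g(0.05),
        country=g(0.0),
    )


def tiny_states(landscape, n_total_years, ponds_value=None):
    """Year states with ponds = wetland_count (or a constant) and zero moisture."""
    base = landscape.grid()
    states = []
    for year in range(n_total_years):
        ponds = landscape.wetland_count.data.copy() if ponds_value is None else np.full_like(
            landscape.wetland_count.data, float(ponds_value)
        )
        states.append(
            YearState(
                year=year,
                ponds=base.like(ponds),
                moisture_index=base.like(np.zeros_like(ponds)),
                ndwi=base.like(np.zeros_like(ponds)),
                gpp=base.like(np.full_like(ponds, 800.0)),
            )
        )
    return states


def config_for(landscape, n_years=1, **kwargs):
    """A SimConfig consistent with a hand-built landscape's grid."""
    nrows, ncols = landscape.grid().data.shape
    defaults = dict(
        grid_ncols=ncols,
        grid_nrows=nrows,
        cell_size_m=landscape.grid().cell_size,
        n_strata=1,
        transect_spacing_km=100.0,
        segment_length_km=1.0,
        n_years=n_years,
        population_series=tuple([1000] * n_years),
        seed=3,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def with_seed(config, seed):
    return dataclasses.replace(config, seed=seed)
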