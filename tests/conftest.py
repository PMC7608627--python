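import dataclasses

import numpy as np
import pytest

from soiltau import (Grid, ModelRun, AnnualSeries, PipelineConfig, Scenario,
                     default_ensemble_configs, default_truth_config,
                     make_ensemble, make_pseudo_obs, run_pipeline)


@pytest.fixture(scope="session")
def grid46():
    """Default 4x5-degree analysis grid."""
    return Grid.regular(46, 72)


@pytest.fixture(scope="session")
def small_grid():
    return Grid.regular(12, 24)


@pytest.fixture(scope="session")
def obs_bundle(grid46):
    """Default pseudo-observations (truth relation at seed 0)."""
    return make_pseudo_obs(default_truth_config(0), grid46)


@pytest.fixture(scope="session")
def small_ensemble(grid46):
    """Six pseudo-models, two scenarios: quick but statistically non-trivial."""
    cfgs = default_ensemble_configs(0, 6)
    return make_ensemble(cfgs, grid46,
                         (Scenario("mid", 2.8), Scenario("high", 5.0)))


@pytest.fixture(scope="session")
def noise_free_ensemble(grid46):
    """Models that obey their own quadratics exactly, warming uniformly."""
    cfgs = [dataclasses.replace(c, scatter_sd=0.0, polar_amp=0.0,
                                t_noise_sd=0.0, rh_noise_sd=0.0)
            for c in default_ensemble_configs(0, 6)]
    return make_ensemble(cfgs, grid46,
                         (Scenario("mid", 2.8), Scenario("high", 5.0)))


@pytest.fixture(scope="session")
def default_report():
    """Full pipeline on the default 16-model ensemble at seed 0."""
    return run_pipeline(PipelineConfig(seed=0))


def constant_run(grid, cs=10.0, rh=1.0, tas=15.0, years=(1995, 2030),
                 model_id="const", scenario_id="test"):
    """A run whose fields never change; handy analytic baseline."""
    yr = np.arange(years[0], years[1] + 1)
    shape = (yr.size, *grid.shape)
    return ModelRun(
        model_id=model_id, scenario_id=scenario_id,
        cs=AnnualSeries(grid, yr, np.full(shape, cs), "kg m-2"),
        rh=AnnualSeries(grid, yr, np.full(shape, rh), "kg m-2 yr-1"),
        tas=AnnualSeries(grid, yr, np.full(shape, tas), "degC"),
        reference_period=(1995, 2005),
    )
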