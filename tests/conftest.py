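"""Shared fixtures: small synthetic worlds, a virtual species with known
limits, training sets, and one session-scoped end-to-end pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from marinesdm import pipeline, sampling, synthetic
from marinesdm.models import DEFAULT_MONOTONE

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_world() -> synthetic.SyntheticWorld:
    """80x80 world with the default predictors and a warming scenario."""
    return synthetic.make_world(
        n_rows=80,
        n_cols=80,
        seed=7,
        scenario_offsets={
            "ssp585": {"ocean_temperature_max": 5.0, "ocean_temperature_min": 5.0}
        },
    )


@pytest.fixture(scope="session")
def thermal_species(small_world) -> synthetic.VirtualSpecies:
    """Species limited above by maximum temperature, below by salinity."""
    t = small_world.predictors["ocean_temperature_max"]
    upper = float(np.nanmean(t))
    return synthetic.make_virtual_species(
        small_world,
        {
            "ocean_temperature_max": (-np.inf, -np.inf, upper - 1.0, upper),
            "salinity": (34.5, 35.0, np.inf, np.inf),
        },
        max_depth_m=300.0,
    )


@pytest.fixture(scope="session")
def training_set(small_world, thermal_species) -> sampling.TrainingSet:
    """One presence/pseudo-absence run with hexagonal folds assigned."""
    occ = synthetic.sample_occurrences(thermal_species, 400, seed=3)
    thinned = sampling.thin_occurrences(occ, 60.0, seed=4)
    tsets = sampling.generate_pseudoabsences(
        small_world.stack(), thinned, exclusion_km=30.0, seed=5, kmeans_restarts=2
    )
    ts = tsets[0]
    ts.fold = sampling.assign_hex_folds(ts.lon, ts.lat, 80.0, 5, seed=6).fold
    return ts


@pytest.fixture(scope="session")
def monotone_map(training_set) -> dict[str, int]:
    return {n: DEFAULT_MONOTONE[n] for n in training_set.features.columns}


@pytest.fixture(scope="session")
def end_to_end(tmp_path_factory):
    """Full pipeline run on a 200x200 world with a known thermal limit.

    Shared by the acceptance-level tests: threshold behaviour, parameter
    recovery, CV performance, and range contraction under warming.
    """
    out = tmp_path_factory.mktemp("endtoend")
    world = synthetic.make_world(
        n_rows=200,
        n_cols=200,
        seed=1,
        scenario_offsets={
            "ssp585": {"ocean_temperature_max": 5.0, "ocean_temperature_min": 5.0}
        },
    )
    t = world.predictors["ocean_temperature_max"]
    upper = float(np.nanmean(t))
    species = synthetic.make_virtual_species(
        world,
        {
            "ocean_temperature_max": (-np.inf, -np.inf, upper - 1.0, upper),
            "salinity": (34.5, 35.0, np.inf, np.inf),
        },
        max_depth_m=300.0,
    )
    occ = synthetic.sample_occurrences(species, 500, bias_exponent=1.0, seed=2)
    config = pipeline.SpeciesConfig(
        species_id="virtual",
        group="seagrass",
        max_depth_m=300.0,
        seed=11,
        predictors=list(world.predictors),
        output_dir=str(out),
        scenarios=["baseline", "ssp585"],
    )
    stacks = {s: world.stack(s) for s in config.scenarios}
    manifest = pipeline.run_species(
        config,
        stacks=stacks,
        bathymetry=world.bathymetry_grid(),
        occurrences=occ,
    )
    return {
        "world": world,
        "species": species,
        "true_upper_limit": upper,
        "occurrences": occ,
        "config": config,
        "manifest": manifest,
        "out_dir": out / config.group / config.species_id,
    }
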