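"""Synthetic worlds and virtual species for desk-scale pipeline testing.

Generates spatially autocorrelated predictor fields on a lon/lat grid with a
land mask and bathymetry, future scenarios as additive shifts of the dynamic
predictors, and virtual species with known piecewise-trapezoidal response
limits from which biased occurrence samples are drawn.  Everything is a pure
function of its inputs and an integer seed, so the whole modelling pipeline
can be exercised against known truth without downloading any real layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geo_io import KM_PER_DEGREE, OccurrenceTable, PredictorStack, RasterGrid, write_raster

__all__ = [
    "PREDICTOR_VOCABULARY",
    "STATIC_PREDICTORS",
    "PredictorSpec",
    "SyntheticWorld",
    "VirtualSpecies",
    "make_world",
    "make_virtual_species",
    "sample_occurrences",
    "trapezoid_response",
]

#: Predictor names the pipeline understands (benthic climatologies plus
#: static terrain layers), with bathymetry handled separately.
PREDICTOR_VOCABULARY = frozenset(
    {
        "ocean_temperature_max",
        "ocean_temperature_min",
        "sea_ice_cover",
        "nitrate",
        "salinity",
        "ph",
        "phytoplankton",
        "oxygen",
        "sea_water_speed",
        "slope",
        "ruggedness",
        "wave_energy",
        "silicate",
    }
)

#: Terrain-derived layers that do not change between climate scenarios.
STATIC_PREDICTORS = frozenset({"slope", "ruggedness", "wave_energy"})

SCENARIOS = ("baseline", "ssp119", "ssp370", "ssp585")


@dataclass(frozen=True)
class PredictorSpec:
    """How one synthetic predictor field is built.

    The field is ``mean + sd * Z + lat_gradient * (lat - mid_lat)`` where Z
    is a unit-variance smoothed noise field.
    """

    name: str
    mean: float = 0.0
    sd: float = 1.0
    lat_gradient: float = 0.0


@dataclass
class SyntheticWorld:
    """A self-consistent synthetic study region.

    All layers share one grid; masked (land) cells are masked in every
    layer.  ``scenario_offsets`` maps a scenario label to additive shifts of
    dynamic predictors; static predictors are identical across scenarios.
    """

    n_rows: int
    n_cols: int
    west: float
    north: float
    cell_deg: float
    predictors: dict[str, np.ndarray]
    bathymetry: np.ndarray
    land_mask: np.ndarray
    scenario_offsets: dict[str, dict[str, float]]
    seed: int

    def _grid(self, values: np.ndarray) -> RasterGrid:
        vals = values.copy()
        vals[self.land_mask] = np.nan
        return RasterGrid(vals, self.land_mask.copy(), self.west, self.north, self.cell_deg)

    def stack(self, scenario: str = "baseline") -> PredictorStack:
        """Predictor stack for one scenario (baseline plus additive offsets)."""
        if scenario != "baseline" and scenario not in self.scenario_offsets:
            raise KeyError(f"unknown scenario {scenario!r}")
        offs = self.scenario_offsets.get(scenario, {}) if scenario != "baseline" else {}
        grids = {}
        for name, vals in self.predictors.items():
            shift = 0.0 if name in STATIC_PREDICTORS else offs.get(name, 0.0)
            grids[name] = self._grid(vals + shift)
        return PredictorStack(scenario=scenario, grids=grids)

    def bathymetry_grid(self) -> RasterGrid:
        return self._grid(self.bathymetry)

    def write(self, directory: str | Path) -> list[Path]:
        """One GeoTIFF per predictor per scenario, plus bathymetry.tif."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        scenarios = ["baseline"] + sorted(self.scenario_offsets)
        for scen in scenarios:
            st = self.stack(scen)
            for name, grid in st.grids.items():
                p = directory / f"{scen}_{name}.tif"
                write_raster(grid, p)
                written.append(p)
        p = directory / "bathymetry.tif"
        write_raster(self.bathymetry_grid(), p)
        written.append(p)
        return written


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to zero mean, unit variance."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def make_world(
    n_rows: int = 200,
    n_cols: int = 200,
    cell_deg: float = 0.05,
    predictor_specs: list[PredictorSpec] | None = None,
    autocorr_length_km: float = 50.0,
    scenario_offsets: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    west: float = -5.0,
    north: float = 45.0,
    land_fraction: float = 0.1,
    mean_depth_m: float = 120.0,
    depth_sd_m: float = 80.0,
) -> SyntheticWorld:
    """Build a synthetic study region of smoothed random predictor fields.

    The smoothing kernel sd in cells is ``autocorr_length_km /
    (111.32 * cell_deg)``; ``autocorr_length_km = 0`` gives white noise.
    The land mask is carved from an independent smooth field so it forms
    contiguous patches covering roughly ``land_fraction`` of the grid.
    Bathymetry is positive-down, clipped at 1 m minimum depth.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8 x 8 cells")
    if cell_deg <= 0:
        raise ValueError("cell size must be positive")
    if autocorr_length_km < 0:
        raise ValueError("autocorrelation length must be non-negative")
    if predictor_specs is None:
        predictor_specs = [
            PredictorSpec("ocean_temperature_max", mean=18.0, sd=4.0, lat_gradient=-0.1),
            PredictorSpec("ocean_temperature_min", mean=10.0, sd=3.0, lat_gradient=-0.1),
            PredictorSpec("salinity", mean=35.0, sd=1.0),
            PredictorSpec("nitrate", mean=8.0, sd=3.0),
            PredictorSpec("wave_energy", mean=30.0, sd=10.0),
        ]
    for spec in predictor_specs:
        if spec.name not in PREDICTOR_VOCABULARY:
            raise ValueError(f"unknown predictor name {spec.name!r}")
    scenario_offsets = scenario_offsets or {}
    for scen, offs in scenario_offsets.items():
        for name in offs:
            if name not in PREDICTOR_VOCABULARY:
                raise ValueError(f"unknown predictor name {name!r} in scenario {scen!r}")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    sigma_cells = autocorr_length_km / (KM_PER_DEGREE * cell_deg)

    # land mask from an always-smooth independent field (keeps land contiguous)
    mask_field = _smooth_unit_field(rng, shape, max(sigma_cells, 3.0))
    if land_fraction > 0:
        thresh = np.quantile(mask_field, 1.0 - land_fraction)
        land_mask = mask_field > thresh
    else:
        land_mask = np.zeros(shape, dtype=bool)

    lat_centers = north - (np.arange(n_rows) + 0.5) * cell_deg
    lat_dev = (lat_centers - lat_centers.mean())[:, None]

    predictors = {}
    for spec in predictor_specs:
        z = _smooth_unit_field(rng, shape, sigma_cells)
        predictors[spec.name] = spec.mean + spec.sd * z + spec.lat_gradient * lat_dev

    depth = mean_depth_m + depth_sd_m * _smooth_unit_field(rng, shape, max(sigma_cells, 3.0))
    bathymetry = np.clip(depth, 1.0, None)

    return SyntheticWorld(
        n_rows=n_rows,
        n_cols=n_cols,
        west=west,
        north=north,
        cell_deg=cell_deg,
        predictors=predictors,
        bathymetry=bathymetry,
        land_mask=land_mask,
        scenario_offsets=scenario_offsets,
        seed=seed,
    )


def trapezoid_response(x: np.ndarray, knots: tuple[float, float, float, float]) -> np.ndarray:
    """Piecewise-trapezoidal response in [0, 1].

    ``knots = (lower_limit, lower_optimum, upper_optimum, upper_limit)``
    must be non-decreasing; infinite knots flatten the corresponding ramp
    (e.g. ``(-inf, -inf, t_opt, t_max)`` is a pure upper-limit response).
    """
    z1, z2, z3, z4 = knots
    if not (z1 <= z2 <= z3 <= z4):
        raise ValueError(f"trapezoid knots must be non-decreasing: {knots}")
    x = np.asarray(x, dtype=float)
    if np.isfinite(z1):
        left = np.clip((x - z1) / (z2 - z1), 0.0, 1.0) if z2 > z1 else (x >= z1).astype(float)
    else:
        left = np.ones_like(x)
    if np.isfinite(z4):
        right = np.clip((z4 - x) / (z4 - z3), 0.0, 1.0) if z4 > z3 else (x <= z4).astype(float)
    else:
        right = np.ones_like(x)
    return left * right


@dataclass
class VirtualSpecies:
    """A species with known environmental limits on a synthetic world.

    ``tipping_points`` records, per predictor, the trapezoid limit a
    correctly recovered tolerance limit should match: the upper limit
    (side "max") for predictors acting negatively at the margin and the
    lower limit (side "min") otherwise.
    """

    species_id: str
    world: SyntheticWorld
    response_params: dict[str, tuple[float, float, float, float]]
    suitability: RasterGrid
    tipping_points: dict[str, tuple[float, str]]
    max_depth_m: float


def make_virtual_species(
    world: SyntheticWorld,
    response_params: dict[str, tuple[float, float, float, float]],
    max_depth_m: float = 1000.0,
    species_id: str = "virtual_species",
) -> VirtualSpecies:
    """Build a virtual species whose true suitability is the cell-wise
    product of per-predictor trapezoid responses on the baseline fields."""
    suit = np.ones((world.n_rows, world.n_cols))
    tipping: dict[str, tuple[float, str]] = {}
    for name, knots in response_params.items():
        if name not in world.predictors:
            raise KeyError(f"predictor {name!r} not present in world")
        suit *= trapezoid_response(world.predictors[name], tuple(knots))
        z1, _, _, z4 = knots
        if np.isfinite(z4):
            tipping[name] = (float(z4), "max")
        elif np.isfinite(z1):
            tipping[name] = (float(z1), "min")
    suit[world.land_mask] = np.nan
    grid = RasterGrid(suit, world.land_mask.copy(), world.west, world.north, world.cell_deg)
    return VirtualSpecies(
        species_id=species_id,
        world=world,
        response_params={k: tuple(v) for k, v in response_params.items()},
        suitability=grid,
        tipping_points=tipping,
        max_depth_m=float(max_depth_m),
    )


def sample_occurrences(
    species: VirtualSpecies,
    n: int,
    bias_exponent: float = 1.0,
    seed: int = 0,
) -> OccurrenceTable:
    """Draw ``n`` occurrence records (with replacement) from unmasked cells
    with probability proportional to ``suitability ** bias_exponent``;
    coordinates snap to cell centers."""
    if n < 1:
        raise ValueError("at least one occurrence must be requested")
    grid = species.suitability
    rows, cols = grid.unmasked_indices()
    suit = grid.values[rows, cols]
    positive = suit > 0
    if not positive.any():
        raise ValueError("no unmasked cell has positive suitability")
    rows, cols, suit = rows[positive], cols[positive], suit[positive]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0**0 == 1 is intended
        w = suit**bias_exponent
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=True, p=p)
    lon, lat = grid.cell_center(rows[idx], cols[idx])
    return OccurrenceTable(species_id=species.species_id, lon=lon, lat=lat)
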