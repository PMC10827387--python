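"""Weighted-average ensembles, uncertainty layers, and binary range maps
with depth and dispersal clipping.

The three algorithms' suitability maps are combined as a weighted average
with weights proportional to cross-validated skill above random
expectation.  Ensemble suitability is reclassified to presence/absence at
the minimum-training-area threshold, restricted to cells no deeper than
the species' maximum reported depth, and finally clipped to cells
reachable from occupied habitat by chained dispersal steps of at most a
fixed distance (default 200 km) through suitable cells — an unsuitable gap
wider than one step cannot be crossed unless occurrence records
demonstrate the species is already beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geo_io import (
    EARTH_RADIUS_KM,
    KM_PER_DEGREE,
    OccurrenceTable,
    PredictorStack,
    RasterGrid,
)
from .models import FittedModel, predict_map

__all__ = [
    "DISPERSAL_KM",
    "EnsembleModel",
    "RangeMap",
    "build_ensemble",
    "ensemble_predict",
    "reclassify",
    "clip_depth",
    "clip_dispersal",
    "project_scenarios",
]

#: Fixed maximum dispersal step between suitable cells, km.
DISPERSAL_KM = 200.0


@dataclass
class EnsembleModel:
    """Fitted members (per algorithm, possibly several runs each) plus
    normalized skill weights and the species' reclassification threshold."""

    members: dict[str, list[FittedModel]]
    weights: dict[str, float]
    threshold: float | None = None
    max_depth_m: float | None = None

    def __post_init__(self) -> None:
        if set(self.members) != set(self.weights):
            raise ValueError("weights must cover exactly the member algorithms")
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("weights must sum to 1")


@dataclass
class RangeMap:
    """Binary presence/absence raster with provenance of how it was made."""

    grid: RasterGrid
    scenario: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.grid.values[~self.grid.mask]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("range map values must be 0 or 1 on unmasked cells")

    @property
    def presence_mask(self) -> np.ndarray:
        return (self.grid.values == 1.0) & ~self.grid.mask

    @property
    def n_presence_cells(self) -> int:
        return int(self.presence_mask.sum())


def build_ensemble(
    models: dict[str, list[FittedModel]] | dict[str, FittedModel],
    cv_metric: dict[str, float],
    weight_metric: str = "auc",
    threshold: float | None = None,
    max_depth_m: float | None = None,
) -> EnsembleModel:
    """Weight members by cross-validated skill above random expectation.

    Weight_i is proportional to max(metric_i - floor, 0), with floor 0.5
    for AUC (random ranking skill) and 0 for Boyce; if every member sits
    at or below the floor, equal weights are used with a warning.
    """
    if not models:
        raise ValueError("ensemble needs at least one member model")
    members = {
        a: (m if isinstance(m, list) else [m]) for a, m in models.items()
    }
    floor = 0.5 if weight_metric == "auc" else 0.0
    raw = {a: max(float(cv_metric[a]) - floor, 0.0) for a in members}
    total = sum(raw.values())
    if total <= 0:
        warnings.warn("all members at or below random skill; using equal weights")
        weights = {a: 1.0 / len(members) for a in members}
    else:
        weights = {a: r / total for a, r in raw.items()}
    return EnsembleModel(members=members, weights=weights, threshold=threshold, max_depth_m=max_depth_m)


def ensemble_predict(
    ensemble: EnsembleModel, stack: PredictorStack
) -> tuple[RasterGrid, RasterGrid]:
    """(suitability, uncertainty) over a scenario's predictor stack.

    Suitability is the weighted mean of per-algorithm maps (runs averaged
    within an algorithm first); uncertainty is the unweighted sample
    standard deviation (n-1) across the per-algorithm maps, zero where the
    members agree exactly or when there is a single member.
    """
    algo_maps = {}
    for algo, models in ensemble.members.items():
        maps = [predict_map(m, stack).values for m in models]
        algo_maps[algo] = np.mean(maps, axis=0)
    ref = stack.grid
    stackd = np.stack(list(algo_maps.values()))
    suit = np.zeros(ref.shape)
    for algo, vals in algo_maps.items():
        suit = suit + ensemble.weights[algo] * vals
    if stackd.shape[0] > 1:
        unc = np.std(stackd, axis=0, ddof=1)
    else:
        unc = np.zeros(ref.shape)
    suit[ref.mask] = np.nan
    unc[ref.mask] = np.nan
    mk = lambda v: RasterGrid(v, ref.mask.copy(), ref.west, ref.north, ref.cell_deg)
    return mk(suit), mk(unc)


def reclassify(suitability: RasterGrid, threshold: float, scenario: str = "baseline") -> RangeMap:
    """Binary map: presence iff suitability >= threshold; nodata untouched."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    vals = np.where(suitability.values >= threshold, 1.0, 0.0)
    vals[suitability.mask] = np.nan
    grid = suitability.copy(values=vals)
    return RangeMap(grid=grid, scenario=scenario, provenance={"threshold": float(threshold), "clips": []})


def clip_depth(range_map: RangeMap, bathymetry: RasterGrid, max_depth_m: float) -> RangeMap:
    """Remove predicted presence from cells deeper than the species'
    maximum reported depth (bathymetry positive down, metres)."""
    if max_depth_m <= 0:
        raise ValueError("maximum depth must be positive")
    if not range_map.grid.same_grid(bathymetry):
        raise ValueError("bathymetry is not co-registered with the range map")
    vals = range_map.grid.values.copy()
    too_deep = (bathymetry.values > max_depth_m) & ~range_map.grid.mask
    vals[too_deep] = 0.0
    prov = dict(range_map.provenance)
    prov["clips"] = list(prov.get("clips", [])) + [("depth", float(max_depth_m))]
    return RangeMap(grid=range_map.grid.copy(values=vals), scenario=range_map.scenario, provenance=prov)


def _chord(max_step_km: float) -> float:
    """3-D chord length equivalent to a great-circle arc of max_step_km."""
    return 2.0 * EARTH_RADIUS_KM * np.sin(max_step_km / (2.0 * EARTH_RADIUS_KM))


def _unit_xyz(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lon, lat = np.radians(lon), np.radians(lat)
    return EARTH_RADIUS_KM * np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def clip_dispersal(
    range_map: RangeMap,
    occurrences: OccurrenceTable | None,
    max_step_km: float = DISPERSAL_KM,
    seed_points: tuple[np.ndarray, np.ndarray] | None = None,
) -> RangeMap:
    """Keep only presence cells reachable from occupied habitat by chained
    steps of at most ``max_step_km`` between suitable cells.

    Seeds are the occurrence cells (whatever their predicted state); a
    presence cell joins the reached set when it lies within one step of any
    reached cell, repeated to fixpoint, so an unsuitable gap wider than one
    step is impassable unless occurrences demonstrate otherwise.
    ``seed_points`` (lon, lat arrays) may replace occurrences as seeds,
    e.g. to seed a future scenario from the baseline clipped range.
    """
    if max_step_km <= 0:
        raise ValueError("maximum dispersal step must be positive")
    if seed_points is not None:
        seed_lon, seed_lat = (np.asarray(a, dtype=float) for a in seed_points)
    elif occurrences is not None and len(occurrences) > 0:
        seed_lon, seed_lat = occurrences.lon, occurrences.lat
    else:
        warnings.warn("no occurrences to seed dispersal clipping; map returned unchanged")
        return RangeMap(
            grid=range_map.grid.copy(),
            scenario=range_map.scenario,
            provenance=dict(range_map.provenance),
        )
    grid = range_map.grid
    pres = range_map.presence_mask
    if seed_lon.size == 0:
        # an explicitly empty seed set means nothing is reachable
        vals = grid.values.copy()
        vals[pres] = 0.0
        prov = dict(range_map.provenance)
        prov["clips"] = list(prov.get("clips", [])) + [("dispersal", float(max_step_km))]
        return RangeMap(grid=grid.copy(values=vals), scenario=range_map.scenario, provenance=prov)

    # cells of one 8-connected presence patch are mutually reachable as
    # long as one diagonal cell step is within the dispersal step
    diag_km = grid.cell_deg * KM_PER_DEGREE * np.sqrt(2.0)
    if diag_km > max_step_km:
        raise ValueError("cell size exceeds the dispersal step; grid too coarse")
    labels, n_comp = ndimage.label(pres, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        out = grid.copy()
    else:
        comp_cells = []
        trees = []
        for c in range(1, n_comp + 1):
            r, cc = np.nonzero(labels == c)
            lon, lat = grid.cell_center(r, cc)
            xyz = _unit_xyz(lon, lat)
            comp_cells.append((r, cc))
            trees.append(cKDTree(xyz))
        chord = _chord(max_step_km)
        seed_xyz = _unit_xyz(seed_lon, seed_lat)
        reached = np.zeros(n_comp, dtype=bool)
        for c in range(n_comp):
            d, _ = trees[c].query(seed_xyz, k=1)
            if np.min(d) <= chord:
                reached[c] = True
        # pairwise component adjacency (min inter-cell distance within one
        # step), then breadth-first expansion over the component graph
        adjacent = np.zeros((n_comp, n_comp), dtype=bool)
        for a in range(n_comp):
            for b in range(a + 1, n_comp):
                d, _ = trees[b].query(trees[a].data, k=1)
                if np.min(d) <= chord:
                    adjacent[a, b] = adjacent[b, a] = True
        frontier = list(np.nonzero(reached)[0])
        while frontier:
            c = frontier.pop()
            for o in np.nonzero(adjacent[c] & ~reached)[0]:
                reached[o] = True
                frontier.append(o)
        vals = grid.values.copy()
        for c in range(n_comp):
            if not reached[c]:
                r, cc = comp_cells[c]
                vals[r, cc] = 0.0
        out = grid.copy(values=vals)
    prov = dict(range_map.provenance)
    prov["clips"] = list(prov.get("clips", [])) + [("dispersal", float(max_step_km))]
    return RangeMap(grid=out, scenario=range_map.scenario, provenance=prov)


def project_scenarios(
    ensemble: EnsembleModel,
    stacks: dict[str, PredictorStack],
    occurrences: OccurrenceTable,
    bathymetry: RasterGrid | None = None,
    max_step_km: float = DISPERSAL_KM,
) -> dict[str, dict[str, object]]:
    """Suitability, uncertainty, and clipped range map for every scenario.

    The reclassification threshold is the ensemble's (fixed from baseline
    training) and is reused unchanged for future scenarios.  Future
    dispersal clipping is seeded from the baseline clipped range, so
    colonization is limited to cells reachable from currently occupied or
    reachable habitat.
    """
    if "baseline" not in stacks:
        raise ValueError("a baseline stack is required")
    if ensemble.threshold is None:
        raise ValueError("ensemble has no reclassification threshold set")
    out: dict[str, dict[str, object]] = {}

    def _clipped(scenario: str, seeds) -> dict[str, object]:
        suit, unc = ensemble_predict(ensemble, stacks[scenario])
        rng_map = reclassify(suit, ensemble.threshold, scenario=scenario)
        if bathymetry is not None and ensemble.max_depth_m is not None:
            rng_map = clip_depth(rng_map, bathymetry, ensemble.max_depth_m)
        rng_map = clip_dispersal(rng_map, occurrences if seeds is None else None,
                                 max_step_km=max_step_km, seed_points=seeds)
        return {"suitability": suit, "uncertainty": unc, "range": rng_map}

    out["baseline"] = _clipped("baseline", None)
    base_range: RangeMap = out["baseline"]["range"]
    r, c = np.nonzero(base_range.presence_mask)
    seed_lon, seed_lat = base_range.grid.cell_center(r, c)
    for scenario in stacks:
        if scenario == "baseline":
            continue
        out[scenario] = _clipped(scenario, (seed_lon, seed_lat))
    return out
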