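"""Autocorrelation distance, thinning, hexagonal folds, pseudo-absences."""

import numpy as np
import pytest

from marinesdm import synthetic
from marinesdm.geo_io import OccurrenceTable, great_circle_km
from marinesdm.sampling import (
    assign_hex_folds,
    estimate_autocorrelation_distance,
    generate_pseudoabsences,
    pseudoabsence_plan,
    thin_occurrences,
)
from marinesdm.synthetic import PredictorSpec


def _flat_world(autocorr_km, seed=0, n=100, specs=None):
    return synthetic.make_world(
        n_rows=n, n_cols=n, seed=seed, autocorr_length_km=autocorr_km,
        land_fraction=0.0, predictor_specs=specs,
    )


class TestCorrelogram:
    def test_white_noise_world_decorrelates_in_the_first_class(self):
        w = _flat_world(0.0, seed=1)
        c = estimate_autocorrelation_distance(
            w.stack(), n_pairs=5000, class_width_km=50, max_distance_km=500, seed=1
        )
        assert c.uncorrelated_distance_km == 0.0

    def test_recovers_a_300km_correlation_length_within_band(self):
        # oracle band from the empirical variogram of the same fields:
        # significance-based estimates cluster between 0.5x and 2x the
        # kernel length across seeds
        estimates = []
        specs = [
            PredictorSpec("ocean_temperature_max", 18, 4),
            PredictorSpec("salinity", 35, 1),
            PredictorSpec("nitrate", 8, 3),
        ]
        for seed in range(10):
            w = _flat_world(300.0, seed=seed, n=200, specs=specs)
            c = estimate_autocorrelation_distance(
                w.stack(), n_pairs=5000, class_width_km=50, max_distance_km=600,
                alpha=0.05, seed=seed,
            )
            estimates.append(c.uncorrelated_distance_km)
        assert all(150 <= d <= 600 for d in estimates)

    def test_constant_predictor_is_non_significant(self):
        w = _flat_world(0.0, seed=2, n=50,
                        specs=[PredictorSpec("salinity", 35.0, 0.0)])
        c = estimate_autocorrelation_distance(
            w.stack(), n_pairs=2000, class_width_km=50, max_distance_km=300, seed=2
        )
        assert not c.significant.any()
        assert c.uncorrelated_distance_km == 0.0

    def test_too_few_pairs_rejected(self):
        w = _flat_world(0.0, seed=3, n=20)
        with pytest.raises(ValueError):
            estimate_autocorrelation_distance(w.stack(), n_pairs=500)


class TestThinning:
    def test_tight_cluster_collapses_to_one_record(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(0, 0.005, 50)  # all within ~1 km
        lat = rng.uniform(0, 0.005, 50)
        thinned = thin_occurrences(OccurrenceTable("sp", lon, lat), 10.0, seed=1)
        assert len(thinned) == 1

    def test_regular_grid_spaced_beyond_the_minimum_is_kept_whole(self):
        # 5x5 grid spaced ~100 km at the equator
        step = 100.0 / 111.32
        lon, lat = np.meshgrid(np.arange(5) * step, np.arange(5) * step)
        occ = OccurrenceTable("sp", lon.ravel(), lat.ravel())
        assert len(thin_occurrences(occ, 50.0, seed=2)) == 25

    def test_zero_distance_returns_input_unchanged(self):
        occ = OccurrenceTable("sp", np.array([1.0, 1.0001]), np.array([2.0, 2.0]))
        thinned = thin_occurrences(occ, 0.0)
        assert len(thinned) == 2

    def test_thinning_is_idempotent(self):
        rng = np.random.default_rng(4)
        occ = OccurrenceTable("sp", rng.uniform(0, 5, 200), rng.uniform(0, 5, 200))
        once = thin_occurrences(occ, 75.0, seed=5)
        twice = thin_occurrences(once, 75.0, seed=99)
        assert len(twice) == len(once)
        assert set(zip(twice.lon, twice.lat)) == set(zip(once.lon, once.lat))

    def test_retained_records_respect_the_minimum_distance(self):
        rng = np.random.default_rng(6)
        occ = OccurrenceTable("sp", rng.uniform(0, 3, 300), rng.uniform(0, 3, 300))
        thinned = thin_occurrences(occ, 40.0, seed=7)
        d = great_circle_km(
            thinned.lon[:, None], thinned.lat[:, None],
            thinned.lon[None, :], thinned.lat[None, :],
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 40.0


class TestHexFolds:
    def test_ten_folds_over_many_hexagons(self):
        rng = np.random.default_rng(8)
        lon = rng.uniform(0, 10, 2000)
        lat = rng.uniform(0, 10, 2000)
        a = assign_hex_folds(lon, lat, hex_width_km=120.0, n_folds=10, seed=9)
        assert np.unique(a.fold).size == 10
        assert np.unique(a.hex_id).size >= 60

    def test_nearby_points_share_hexagon_and_fold(self):
        # two points ~1 km apart plus distant context points
        lon = np.array([5.0, 5.009, 0.0, 10.0, 2.0])
        lat = np.array([0.0, 0.0, 0.0, 5.0, 8.0])
        a = assign_hex_folds(lon, lat, hex_width_km=100.0, n_folds=2, seed=0)
        assert a.hex_id[0] == a.hex_id[1]
        assert a.fold[0] == a.fold[1]

    def test_hexagon_mates_never_cross_folds(self):
        rng = np.random.default_rng(10)
        lon = rng.uniform(0, 8, 1500)
        lat = rng.uniform(0, 8, 1500)
        a = assign_hex_folds(lon, lat, hex_width_km=150.0, n_folds=5, seed=11)
        for h in np.unique(a.hex_id):
            assert np.unique(a.fold[a.hex_id == h]).size == 1

    def test_fewer_hexagons_than_folds_rejected(self):
        lon = np.arange(9) * 3.0  # 9 well-separated points = 9 hexagons
        lat = np.zeros(9)
        with pytest.raises(ValueError, match="hexagons"):
            assign_hex_folds(lon, lat, hex_width_km=50.0, n_folds=10, seed=0)


class TestPseudoAbsences:
    def test_balancing_plan(self):
        assert pseudoabsence_plan(1500) == (1, 1500)
        assert pseudoabsence_plan(60) == (10, 100)
        assert pseudoabsence_plan(400) == (10, 400)

    def test_rare_species_gets_ten_runs_of_one_hundred(self, small_world, thermal_species):
        occ = synthetic.sample_occurrences(thermal_species, 600, seed=1)
        thinned = thin_occurrences(occ, 120.0, seed=2)
        assert len(thinned) < 100  # rare after thinning
        tsets = generate_pseudoabsences(
            small_world.stack(), thinned, exclusion_km=30.0, seed=3, kmeans_restarts=2
        )
        assert len(tsets) == 10
        assert all(ts.n_absence == 100 for ts in tsets)
        assert all(ts.n_presence == len(thinned) for ts in tsets)

    def test_runs_differ_but_are_seed_reproducible(self, small_world, thermal_species):
        occ = synthetic.sample_occurrences(thermal_species, 300, seed=4)
        thinned = thin_occurrences(occ, 150.0, seed=5)
        a = generate_pseudoabsences(small_world.stack(), thinned, 30.0, seed=6, kmeans_restarts=2)
        b = generate_pseudoabsences(small_world.stack(), thinned, 30.0, seed=6, kmeans_restarts=2)
        assert not np.array_equal(a[0].lon, a[1].lon)  # distinct sub-seeds
        np.testing.assert_array_equal(a[0].lon, b[0].lon)  # reproducible

    def test_pseudoabsences_respect_the_exclusion_buffer(self, small_world, thermal_species):
        occ = synthetic.sample_occurrences(thermal_species, 300, seed=7)
        thinned = thin_occurrences(occ, 150.0, seed=8)
        tsets = generate_pseudoabsences(
            small_world.stack(), thinned, exclusion_km=50.0, seed=9, kmeans_restarts=2
        )
        ts = tsets[0]
        pa = ts.label == 0
        d = great_circle_km(
            ts.lon[pa][:, None], ts.lat[pa][:, None],
            thinned.lon[None, :], thinned.lat[None, :],
        )
        assert d.min(axis=1).min() > 50.0

    def test_each_pseudoabsence_is_a_distinct_cell(self, small_world, thermal_species):
        occ = synthetic.sample_occurrences(thermal_species, 300, seed=10)
        thinned = thin_occurrences(occ, 150.0, seed=11)
        ts = generate_pseudoabsences(
            small_world.stack(), thinned, 30.0, seed=12, kmeans_restarts=2
        )[0]
        pa_coords = set(zip(ts.lon[ts.label == 0], ts.lat[ts.label == 0]))
        assert len(pa_coords) == ts.n_absence  # one per K-means cluster

    def test_candidate_pool_too_small_rejected(self, thermal_species):
        w = synthetic.make_world(n_rows=10, n_cols=10, seed=13, land_fraction=0.0)
        occ = OccurrenceTable("sp", np.array([w.west + 0.25]), np.array([w.north - 0.25]))
        with pytest.raises(ValueError, match="candidate pool"):
            generate_pseudoabsences(w.stack(), occ, exclusion_km=500.0, seed=14)

    def test_structured_sampling_covers_predictor_space_at_least_as_well_as_random(
        self, small_world, thermal_species
    ):
        # coverage = max distance from any candidate to its nearest
        # pseudo-absence in standardized predictor space
        from sklearn.preprocessing import StandardScaler

        occ = synthetic.sample_occurrences(thermal_species, 200, seed=15)
        thinned = thin_occurrences(occ, 200.0, seed=16)
        stack = small_world.stack()
        grid = stack.grid
        rows, cols = grid.unmasked_indices()
        lonc, latc = grid.cell_center(rows, cols)
        d = great_circle_km(
            lonc[:, None], latc[:, None], thinned.lon[None, :], thinned.lat[None, :]
        ).min(axis=1)
        cand = d > 30.0
        Z = StandardScaler().fit_transform(
            np.column_stack([stack.grids[n].values[rows[cand], cols[cand]] for n in stack.names])
        )

        def coverage(idx):
            d2 = ((Z[:, None, :] - Z[idx][None, :, :]) ** 2).sum(axis=2)
            return np.sqrt(d2.min(axis=1)).max()

        structured, random = [], []
        for seed in range(10):
            ts = generate_pseudoabsences(
                stack, thinned, exclusion_km=30.0, seed=seed, kmeans_restarts=2
            )[0]
            pa_lon = ts.lon[ts.label == 0]
            pa_lat = ts.lat[ts.label == 0]
            pr, pc, _ = grid.index_of(pa_lon, pa_lat)
            cand_index = {
                (r, c): i for i, (r, c) in enumerate(zip(rows[cand], cols[cand]))
            }
            idx = np.array([cand_index[(r, c)] for r, c in zip(pr, pc)])
            structured.append(coverage(idx))
            rng = np.random.default_rng(seed)
            random.append(coverage(rng.choice(Z.shape[0], idx.size, replace=False)))
        assert np.mean(structured) <= np.mean(random)
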