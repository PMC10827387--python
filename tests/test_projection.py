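"""Ensembles, uncertainty, reclassification, and depth/dispersal clipping."""

from dataclasses import dataclass, field

import numpy as np
import pytest

from marinesdm.geo_io import KM_PER_DEGREE, OccurrenceTable, PredictorStack, RasterGrid, great_circle_km
from marinesdm.projection import (
    RangeMap,
    build_ensemble,
    clip_depth,
    clip_dispersal,
    ensemble_predict,
    reclassify,
)

CELL = 0.05
CELL_KM = CELL * KM_PER_DEGREE


@dataclass
class ConstModel:
    """Stub member predicting a constant suitability."""

    value: float
    feature_names: list = field(default_factory=lambda: ["salinity"])

    def predict(self, X):
        return np.full(len(X), self.value)


def _flat_stack(n=6):
    vals = np.full((n, n), 35.0)
    mask = np.zeros((n, n), bool)
    return PredictorStack(
        "baseline", {"salinity": RasterGrid(vals, mask, 0.0, n * CELL, CELL)}
    )


def _binary_map(vals, north=None):
    vals = np.asarray(vals, float)
    north = north if north is not None else vals.shape[0] * CELL
    grid = RasterGrid(vals, np.zeros_like(vals, bool), 0.0, north, CELL)
    return RangeMap(grid, "baseline", {})


def two_patch_map(gap_km, n_rows=8, patch_cols=6):
    """Two suitable patches at the equator separated by a gap of
    unsuitable cells spanning roughly gap_km."""
    n_gap = round(gap_km / CELL_KM)
    n_cols = 2 * patch_cols + n_gap
    vals = np.zeros((n_rows, n_cols))
    vals[:, :patch_cols] = 1
    vals[:, patch_cols + n_gap:] = 1
    north = n_rows / 2 * CELL  # straddle the equator
    rm = _binary_map(vals, north=north)
    occ = OccurrenceTable("sp", np.array([CELL * 1.5]), np.array([0.0]))
    return rm, occ


class TestBuildEnsemble:
    def test_equal_skill_gives_equal_weights(self):
        models = {a: ConstModel(0.5) for a in ("brt", "adaboost", "xgb")}
        ens = build_ensemble(models, {a: 0.8 for a in models})
        assert ens.weights == pytest.approx({a: 1 / 3 for a in models})

    def test_single_member_gets_weight_one(self):
        ens = build_ensemble({"brt": ConstModel(0.4)}, {"brt": 0.9})
        assert ens.weights == {"brt": 1.0}

    def test_auc_weights_are_skill_above_random(self):
        ens = build_ensemble(
            {a: ConstModel(0.5) for a in ("brt", "adaboost", "xgb")},
            {"brt": 0.9, "adaboost": 0.7, "xgb": 0.5},
        )
        assert ens.weights["brt"] == pytest.approx(2 / 3)
        assert ens.weights["adaboost"] == pytest.approx(1 / 3)
        assert ens.weights["xgb"] == 0.0

    def test_all_members_at_random_skill_fall_back_to_equal(self):
        with pytest.warns(UserWarning, match="equal weights"):
            ens = build_ensemble(
                {"brt": ConstModel(0.5), "xgb": ConstModel(0.5)},
                {"brt": 0.5, "xgb": 0.4},
            )
        assert ens.weights == pytest.approx({"brt": 0.5, "xgb": 0.5})

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            build_ensemble({}, {})


class TestEnsemblePredict:
    def test_identical_members_have_zero_uncertainty(self):
        ens = build_ensemble(
            {"brt": ConstModel(0.7), "xgb": ConstModel(0.7)},
            {"brt": 0.8, "xgb": 0.8},
        )
        suit, unc = ensemble_predict(ens, _flat_stack())
        assert np.allclose(suit.values, 0.7)
        assert np.allclose(unc.values, 0.0)

    def test_disagreeing_members_closed_form_sd(self):
        ens = build_ensemble(
            {"brt": ConstModel(0.0), "xgb": ConstModel(1.0)},
            {"brt": 0.8, "xgb": 0.8},
        )
        suit, unc = ensemble_predict(ens, _flat_stack())
        assert np.allclose(suit.values, 0.5)
        assert np.allclose(unc.values, np.sqrt(0.5))  # sd with n-1 = 0.707

    def test_ensemble_stays_within_member_envelope(self, small_world, training_set, monotone_map):
        from marinesdm.models import fit_model
        from tests.test_models import SMALL_HP

        members = {
            a: fit_model(training_set, a, SMALL_HP[a], monotone_map, seed=1)
            for a in SMALL_HP
        }
        ens = build_ensemble(members, {"brt": 0.9, "adaboost": 0.8, "xgb": 0.7})
        stack = small_world.stack()
        suit, _ = ensemble_predict(ens, stack)
        from marinesdm.models import predict_map

        maps = np.stack([predict_map(m, stack).values for m in members.values()])
        ok = ~stack.mask
        assert (suit.values[ok] >= np.min(maps, axis=0)[ok] - 1e-12).all()
        assert (suit.values[ok] <= np.max(maps, axis=0)[ok] + 1e-12).all()


class TestReclassify:
    def _suit(self):
        vals = np.linspace(0, 1, 16).reshape(4, 4)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        vals = np.where(mask, np.nan, vals)
        return RasterGrid(vals, mask, 0.0, 0.2, CELL)

    def test_zero_threshold_marks_everything_present(self):
        rm = reclassify(self._suit(), 0.0)
        assert rm.presence_mask.sum() == 15

    def test_threshold_above_map_maximum_marks_everything_absent(self):
        rm = reclassify(self._suit(), 1.0)
        assert rm.presence_mask.sum() == 1  # only the exact 1.0 cell
        vals = self._suit()
        vals.values[vals.values == 1.0] = 0.9
        assert reclassify(vals, 1.0).presence_mask.sum() == 0

    def test_nodata_preserved(self):
        rm = reclassify(self._suit(), 0.5)
        assert np.isnan(rm.grid.values[0, 0])


class TestClipDepth:
    def _range_and_bathy(self):
        rm = _binary_map(np.ones((4, 4)))
        depth = np.full((4, 4), 20.0)
        depth[2, 2] = 500.0
        bathy = RasterGrid(depth, np.zeros((4, 4), bool), 0.0, 0.2, CELL)
        return rm, bathy

    def test_cells_deeper_than_the_species_limit_removed(self):
        rm, bathy = self._range_and_bathy()
        out = clip_depth(rm, bathy, 30.0)
        assert out.grid.values[2, 2] == 0.0
        assert out.presence_mask.sum() == 15

    def test_no_change_when_limit_exceeds_deepest_cell(self):
        rm, bathy = self._range_and_bathy()
        out = clip_depth(rm, bathy, 600.0)
        np.testing.assert_array_equal(out.grid.values, rm.grid.values)

    def test_clip_never_adds_presence_and_is_idempotent(self):
        rm, bathy = self._range_and_bathy()
        once = clip_depth(rm, bathy, 30.0)
        twice = clip_depth(once, bathy, 30.0)
        assert (once.presence_mask <= rm.presence_mask).all()
        np.testing.assert_array_equal(once.grid.values, twice.grid.values)

    def test_grid_mismatch_rejected(self):
        rm, _ = self._range_and_bathy()
        bathy = RasterGrid(np.zeros((5, 5)), np.zeros((5, 5), bool), 0.0, 0.25, CELL)
        with pytest.raises(ValueError, match="co-registered"):
            clip_depth(rm, bathy, 30.0)


class TestClipDispersal:
    def test_patch_beyond_250km_gap_removed(self):
        rm, occ = two_patch_map(250.0)
        out = clip_dispersal(rm, occ, 200.0)
        assert out.grid.values[:, -1].sum() == 0  # patch B gone
        assert out.grid.values[:, 0].sum() > 0    # patch A kept

    def test_patch_within_150km_gap_retained(self):
        rm, occ = two_patch_map(150.0)
        out = clip_dispersal(rm, occ, 200.0)
        assert out.grid.values[:, -1].sum() > 0

    def test_occurrence_inside_detached_patch_keeps_it(self):
        rm, occ = two_patch_map(300.0)
        far_lon = (rm.grid.n_cols - 1) * CELL
        occ2 = OccurrenceTable(
            "sp", np.r_[occ.lon, far_lon], np.r_[occ.lat, 0.0]
        )
        out = clip_dispersal(rm, occ2, 200.0)
        assert out.grid.values[:, -1].sum() > 0

    def test_no_occurrences_warns_and_returns_unchanged(self):
        rm, _ = two_patch_map(300.0)
        with pytest.warns(UserWarning, match="no occurrences"):
            out = clip_dispersal(rm, None, 200.0)
        np.testing.assert_array_equal(out.grid.values, rm.grid.values)

    def test_clipping_is_monotone_and_idempotent(self):
        rm, occ = two_patch_map(250.0)
        once = clip_dispersal(rm, occ, 200.0)
        twice = clip_dispersal(once, occ, 200.0)
        assert (once.presence_mask <= rm.presence_mask).all()
        np.testing.assert_array_equal(once.grid.values, twice.grid.values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_reachability_on_random_maps(self, seed):
        # oracle: explicit multi-source BFS over presence cells with
        # haversine edges of at most one dispersal step
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        field = ndimage.gaussian_filter(rng.standard_normal((50, 50)), 3.0)
        vals = (field > np.quantile(field, 0.7)).astype(float)
        rm = _binary_map(vals)
        rows, cols = np.nonzero(vals == 1)
        pick = rng.choice(rows.size, 3, replace=False)
        lon, lat = rm.grid.cell_center(rows[pick], cols[pick])
        occ = OccurrenceTable("sp", lon, lat)
        step = 40.0  # km, small enough to break this 50x50 map apart

        out = clip_dispersal(rm, occ, step)

        p_lon, p_lat = rm.grid.cell_center(rows, cols)
        d = great_circle_km(
            p_lon[:, None], p_lat[:, None], p_lon[None, :], p_lat[None, :]
        )
        reached = np.zeros(rows.size, bool)
        d_occ = great_circle_km(
            p_lon[:, None], p_lat[:, None], lon[None, :], lat[None, :]
        )
        frontier = list(np.nonzero(d_occ.min(axis=1) <= step)[0])
        reached[frontier] = True
        while frontier:
            i = frontier.pop()
            nxt = np.nonzero((d[i] <= step) & ~reached)[0]
            reached[nxt] = True
            frontier.extend(nxt.tolist())
        expected = np.zeros_like(vals)
        expected[rows[reached], cols[reached]] = 1.0
        np.testing.assert_array_equal(out.grid.values, expected)
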