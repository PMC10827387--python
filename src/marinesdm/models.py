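"""Monotone-constrained boosted-tree learners and spatially blocked
grid-search cross-validation.

Three gradient-boosting families are fitted per species: classic boosted
regression trees (BRT), an AdaBoost-style learner tuned by iteration count,
leaf budget and shrinkage, and XGBoost.  Each accepts per-predictor
monotone constraints so ecologically implausible response shapes (e.g.
suitability increasing without bound with maximum temperature) are ruled
out at fit time, which also curbs overfitting.  Hyperparameters are chosen
by exhaustive grid search under hexagonal spatial-block cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_io import PredictorStack, RasterGrid
from .metrics import auc, boyce_index, confusion_metrics, mtp_threshold
from .sampling import TrainingSet

__all__ = [
    "ALGORITHMS",
    "FULL_GRIDS",
    "REDUCED_GRIDS",
    "DEFAULT_MONOTONE",
    "FittedModel",
    "CVReport",
    "enumerate_grid",
    "fit_model",
    "cross_validate",
    "predict_map",
]

ALGORITHMS = ("brt", "adaboost", "xgb")

#: Full hyperparameter lattices searched per algorithm.
FULL_GRIDS: dict[str, dict[str, list]] = {
    "brt": {
        "learning_rate": [0.1, 0.01, 0.001],
        "tree_complexity": [1, 2, 3, 4],
        "n_trees": list(range(50, 1001, 50)),
    },
    "adaboost": {
        "n_iterations": list(range(50, 251, 50)),
        "degrees_of_freedom": list(range(1, 13)),
        "shrinkage": [0.25, 0.5, 0.75, 1.0],
    },
    "xgb": {
        "gamma": [0, 1, 2, 3, 4, 5],
        "interaction_depth": [1, 2, 3, 4],
        "shrinkage": [0.1, 0.2, 0.3, 0.4, 0.5],
        "n_rounds": list(range(10, 101, 10)),
    },
}

#: Desk-scale lattices (8 combinations each) spanning the full grids' axes.
REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "brt": {
        "learning_rate": [0.1, 0.01],
        "tree_complexity": [2, 3],
        "n_trees": [50, 150],
    },
    "adaboost": {
        "n_iterations": [50, 150],
        "degrees_of_freedom": [3, 8],
        "shrinkage": [0.5, 1.0],
    },
    "xgb": {
        "gamma": [0, 1],
        "interaction_depth": [2, 3],
        "shrinkage": [0.1, 0.3],
        "n_rounds": [50],
    },
}

#: Expected direction of each predictor's effect on suitability.  Stressors
#: (maximum temperature, ice cover, wave energy, current speed) act
#: negatively; resources and minimum temperature act positively.
DEFAULT_MONOTONE: dict[str, int] = {
    "ocean_temperature_max": -1,
    "sea_ice_cover": -1,
    "wave_energy": -1,
    "sea_water_speed": -1,
    "ocean_temperature_min": +1,
    "salinity": +1,
    "nitrate": +1,
    "ph": +1,
    "oxygen": +1,
    "phytoplankton": +1,
    "slope": +1,
    "ruggedness": +1,
    "silicate": +1,
}


@dataclass
class FittedModel:
    """A fitted monotone boosted-tree classifier."""

    algorithm: str
    hyperparams: dict
    feature_names: list[str]
    monotone: dict[str, int]
    estimator: object
    seed: int
    n_presence: int
    n_absence: int

    def predict(self, X) -> np.ndarray:
        """Suitability in [0, 1] for a feature matrix (columns in
        ``feature_names`` order; DataFrames are reordered by name)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names]
        else:
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names)
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


@dataclass
class CVReport:
    """Per-fold and mean cross-validation metrics for one algorithm/run."""

    algorithm: str
    run: int
    best_params: dict
    folds: pd.DataFrame  # columns: fold, auc, sensitivity, specificity, tss, boyce
    means: dict[str, float]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def enumerate_grid(algorithm: str, full: bool = True) -> list[dict]:
    """All hyperparameter combinations of the algorithm's lattice, as a
    deterministic Cartesian product."""
    grids = FULL_GRIDS if full else REDUCED_GRIDS
    if algorithm not in grids:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    g = grids[algorithm]
    keys = list(g)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(g[k] for k in keys))]


def _monotone_vector(feature_names: list[str], monotone: dict[str, int]) -> list[int]:
    out = []
    for name in feature_names:
        if name not in monotone:
            raise ValueError(f"no monotone direction declared for predictor {name!r}")
        d = int(monotone[name])
        if d not in (-1, 0, 1):
            raise ValueError(f"monotone direction must be -1, 0 or +1, got {d}")
        out.append(d)
    return out


def _in_lattice(algorithm: str, hyperparams: dict) -> bool:
    grid = FULL_GRIDS[algorithm]
    return all(k in grid and v in grid[k] for k, v in hyperparams.items())


def fit_model(
    train: TrainingSet,
    algorithm: str,
    hyperparams: dict,
    monotone_map: dict[str, int],
    seed: int = 0,
) -> FittedModel:
    """Fit one boosted-tree classifier with monotone constraints.

    Hyperparameter vocabulary: BRT takes ``learning_rate``,
    ``tree_complexity`` (max tree depth) and ``n_trees``; the
    AdaBoost-style learner takes ``n_iterations``, ``degrees_of_freedom``
    (leaf budget: a tree may grow d+1 leaves) and ``shrinkage``; XGBoost
    takes ``gamma``, ``interaction_depth``, ``shrinkage`` and ``n_rounds``.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    y = np.asarray(train.label)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = train.features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("training features must be finite")
    names = list(train.features.columns)
    mono = _monotone_vector(names, monotone_map)
    if not _in_lattice(algorithm, hyperparams):
        warnings.warn(
            f"{algorithm} hyperparameters {hyperparams} outside the standard lattice"
        )
    hp = dict(hyperparams)
    if algorithm == "brt":
        from sklearn.ensemble import HistGradientBoostingClassifier

        est = HistGradientBoostingClassifier(
            max_iter=int(hp["n_trees"]),
            max_depth=int(hp["tree_complexity"]),
            learning_rate=float(hp["learning_rate"]),
            monotonic_cst=mono,
            early_stopping=False,
            random_state=seed,
        )
    elif algorithm == "adaboost":
        import lightgbm

        est = lightgbm.LGBMClassifier(
            n_estimators=int(hp["n_iterations"]),
            num_leaves=int(hp["degrees_of_freedom"]) + 1,
            learning_rate=float(hp["shrinkage"]),
            monotone_constraints=mono,
            min_child_samples=5,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
    else:  # xgb
        import xgboost

        est = xgboost.XGBClassifier(
            n_estimators=int(hp["n_rounds"]),
            max_depth=int(hp["interaction_depth"]),
            learning_rate=float(hp["shrinkage"]),
            gamma=float(hp["gamma"]),
            monotone_constraints=tuple(mono),
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    est.fit(train.features[names], y)
    return FittedModel(
        algorithm=algorithm,
        hyperparams=hp,
        feature_names=names,
        monotone={n: d for n, d in zip(names, mono)},
        estimator=est,
        seed=seed,
        n_presence=train.n_presence,
        n_absence=train.n_absence,
    )


def _fold_training_set(train: TrainingSet, idx: np.ndarray) -> TrainingSet:
    return TrainingSet(
        run=train.run,
        lon=train.lon[idx],
        lat=train.lat[idx],
        label=train.label[idx],
        features=train.features.iloc[idx].reset_index(drop=True),
    )


def _safe_boyce(pres_scores: np.ndarray, back_scores: np.ndarray) -> float:
    """Boyce index, or NaN when a fold is too small for it to be defined."""
    if pres_scores.size < 5 or back_scores.size < 20:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return boyce_index(
            pres_scores, back_scores, min_presences=5, min_background=20
        )


def _parsimony_key(hp: dict) -> int:
    return int(hp.get("n_trees") or hp.get("n_rounds") or hp.get("n_iterations") or 0)


def cross_validate(
    train: TrainingSet,
    algorithm: str,
    grid: list[dict],
    monotone_map: dict[str, int],
    seed: int = 0,
    min_sensitivity: float = 0.95,
) -> tuple[dict, CVReport]:
    """Spatial-block grid search: each grid point is scored by n-fold CV
    over the training set's fold labels; the winner has the highest mean
    test AUC, ties broken by higher mean Boyce then fewer boosting
    iterations.  Returns the winning hyperparameters and their CV report.
    """
    if train.fold is None:
        raise ValueError("training set has no fold assignment")
    fold_labels = np.unique(train.fold)
    if fold_labels.size < 2:
        raise ValueError("need at least 2 folds")
    for f in fold_labels:
        if (train.label[train.fold == f] == 1).sum() < 1:
            raise ValueError(
                f"fold {f} has no presences; re-tessellate or merge folds"
            )
    if not grid:
        raise ValueError("empty hyperparameter grid")

    best = None
    for hp in grid:
        rows = []
        for f in fold_labels:
            test_idx = np.nonzero(train.fold == f)[0]
            fit_idx = np.nonzero(train.fold != f)[0]
            if len(np.unique(train.label[fit_idx])) < 2 or len(np.unique(train.label[test_idx])) < 2:
                continue
            model = fit_model(_fold_training_set(train, fit_idx), algorithm, hp, monotone_map, seed)
            fit_scores = model.predict(train.features.iloc[fit_idx])
            test_scores = model.predict(train.features.iloc[test_idx])
            y_test = train.label[test_idx]
            thr = mtp_threshold(
                fit_scores[train.label[fit_idx] == 1], min_sensitivity=min_sensitivity
            ).threshold
            sens, spec, tss = confusion_metrics(y_test, test_scores, thr)
            rows.append(
                {
                    "fold": int(f),
                    "auc": auc(y_test, test_scores),
                    "sensitivity": sens,
                    "specificity": spec,
                    "tss": tss,
                    "boyce": _safe_boyce(test_scores[y_test == 1], test_scores),
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        mean_auc = float(df["auc"].mean())
        mean_boyce = float(np.nanmean(df["boyce"])) if df["boyce"].notna().any() else 0.0
        key = (mean_auc, mean_boyce, -_parsimony_key(hp))
        if best is None or key > best[0]:
            best = (key, hp, df)
    if best is None:
        raise ValueError("no grid point could be evaluated on any fold")
    _, best_hp, df = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN Boyce column
        means = {
            m: float(np.nanmean(df[m]))
            for m in ("auc", "sensitivity", "specificity", "tss", "boyce")
        }
    report = CVReport(
        algorithm=algorithm, run=train.run, best_params=dict(best_hp), folds=df, means=means
    )
    return dict(best_hp), report


def save_model(model: FittedModel, path) -> None:
    """Persist a fitted model (joblib bundle: metadata + estimator)."""
    import joblib

    joblib.dump(
        {
            "algorithm": model.algorithm,
            "hyperparams": model.hyperparams,
            "feature_names": model.feature_names,
            "monotone": model.monotone,
            "estimator": model.estimator,
            "seed": model.seed,
            "n_presence": model.n_presence,
            "n_absence": model.n_absence,
        },
        path,
    )


def load_model(path) -> FittedModel:
    import joblib

    return FittedModel(**joblib.load(path))


def predict_map(model: FittedModel, stack: PredictorStack) -> RasterGrid:
    """Per-cell suitability predictions over the stack's unmasked cells."""
    missing = [n for n in model.feature_names if n not in stack.grids]
    if missing:
        raise ValueError(f"stack is missing predictor layers: {missing}")
    grid = stack.grid
    out = np.full(grid.shape, np.nan)
    rows, cols = grid.unmasked_indices()
    if rows.size:
        X = np.column_stack([stack.grids[n].values[rows, cols] for n in model.feature_names])
        out[rows, cols] = model.predict(X)
    return RasterGrid(out, grid.mask.copy(), grid.west, grid.north, grid.cell_deg)
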