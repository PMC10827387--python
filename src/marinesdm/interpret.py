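"""Model interpretation: relative predictor contributions, partial
dependence, and tolerance-limit (tipping point) extraction.

Contributions are permutation importances — the drop in training AUC when
one predictor's column is shuffled — so the three algorithms and their
ensemble are scored by one model-agnostic rule.  Partial-dependence curves
average model predictions over the training rows with one predictor swept
across its observed range; the tipping point of a predictor is where its
partial-dependence curve crosses the species' suitability threshold: the
largest tolerated value for predictors acting negatively (side "max"), the
smallest required value for predictors acting positively (side "min").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import auc
from .models import FittedModel
from .projection import EnsembleModel
from .sampling import TrainingSet

__all__ = [
    "PartialDependence",
    "TippingPoint",
    "relative_contribution",
    "partial_dependence",
    "ensemble_partial_dependence",
    "extract_tipping_point",
]


@dataclass
class PartialDependence:
    """Mean predicted suitability along one predictor's value grid."""

    predictor: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must have equal length")
        if not (np.diff(self.grid) > 0).all():
            raise ValueError("partial-dependence grid must be strictly increasing")


@dataclass(frozen=True)
class TippingPoint:
    """A recovered tolerance limit.

    ``status`` is "ok" for a proper crossing, "unbounded_in_range" when the
    curve never drops below the threshold inside the sampled range (the
    limit lies beyond it), or "absent" when the curve never reaches the
    threshold at all (value is None).
    """

    value: float | None
    side: str  # "min" or "max"
    status: str = "ok"


def _subsample_rows(X: pd.DataFrame, max_rows: int = 2000) -> pd.DataFrame:
    if len(X) <= max_rows:
        return X
    idx = np.linspace(0, len(X) - 1, max_rows).astype(int)  # deterministic
    return X.iloc[idx]


def partial_dependence(
    model: FittedModel,
    train_features: pd.DataFrame,
    predictor: str,
    n_grid: int = 100,
) -> PartialDependence:
    """Partial dependence of the model on one predictor over its training
    range (rows subsampled to at most 2000 for speed)."""
    if predictor not in model.feature_names:
        raise ValueError(f"predictor {predictor!r} not in the model's feature set")
    if n_grid < 10:
        raise ValueError("need at least 10 grid points")
    col = train_features[predictor].to_numpy(dtype=float)
    lo, hi = float(col.min()), float(col.max())
    if hi <= lo:
        raise ValueError(f"predictor {predictor!r} has zero variance in training data")
    grid = np.linspace(lo, hi, n_grid)
    X = _subsample_rows(train_features[model.feature_names]).to_numpy(dtype=float)
    j = model.feature_names.index(predictor)
    # evaluate all grid points in one batched prediction
    big = np.vstack([np.column_stack([X[:, :j], np.full(len(X), g), X[:, j + 1:]]) for g in grid])
    preds = model.predict(big).reshape(n_grid, len(X))
    vals = preds.mean(axis=1)
    return PartialDependence(predictor=predictor, grid=grid, values=vals)


def ensemble_partial_dependence(
    ensemble: EnsembleModel,
    train_features: pd.DataFrame,
    predictor: str,
    n_grid: int = 100,
) -> PartialDependence:
    """Weight-averaged partial dependence across ensemble members (runs
    averaged within each algorithm first)."""
    curves = []
    weights = []
    grid = None
    for algo, models in ensemble.members.items():
        per_run = []
        for m in models:
            pd_ = partial_dependence(m, train_features, predictor, n_grid)
            grid = pd_.grid
            per_run.append(pd_.values)
        curves.append(np.mean(per_run, axis=0))
        weights.append(ensemble.weights[algo])
    vals = np.average(np.vstack(curves), axis=0, weights=weights)
    return PartialDependence(predictor=predictor, grid=grid, values=vals)


def extract_tipping_point(
    pd_curve: PartialDependence,
    direction: int,
    suitability_threshold: float,
) -> TippingPoint:
    """Tolerance limit from a partial-dependence curve.

    For ``direction = -1`` (stressor): the largest grid value with
    suitability at or above the threshold (side "max").  For
    ``direction = +1``: the smallest such grid value (side "min").
    """
    if not (0.0 < suitability_threshold < 1.0):
        raise ValueError("suitability threshold must be in (0, 1)")
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    side = "max" if direction == -1 else "min"
    above = pd_curve.values >= suitability_threshold
    if not above.any():
        return TippingPoint(value=None, side=side, status="absent")
    if above.all():
        idx = -1 if direction == -1 else 0
        return TippingPoint(
            value=float(pd_curve.grid[idx]), side=side, status="unbounded_in_range"
        )
    idx = np.nonzero(above)[0]
    g = pd_curve.grid[idx[-1]] if direction == -1 else pd_curve.grid[idx[0]]
    return TippingPoint(value=float(g), side=side, status="ok")


def _model_contribution(
    model: FittedModel,
    features: pd.DataFrame,
    labels: np.ndarray,
    predictors: list[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation importance per predictor, normalized to sum 100."""
    X = features[model.feature_names].to_numpy(dtype=float)
    base = auc(labels, model.predict(X))
    drops = np.zeros(len(predictors))
    for i, name in enumerate(predictors):
        if name not in model.feature_names:
            continue  # exactly zero contribution
        j = model.feature_names.index(name)
        tot = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            tot += base - auc(labels, model.predict(Xp))
        drops[i] = max(tot / n_permutations, 0.0)
    if drops.sum() == 0:
        used = np.array([n in model.feature_names for n in predictors], dtype=float)
        return 100.0 * used / used.sum()
    return 100.0 * drops / drops.sum()


def relative_contribution(
    ensemble: EnsembleModel,
    train: TrainingSet,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative contribution (%) of each predictor, per algorithm and for
    the ensemble.

    Per member model, contribution is the mean drop in training AUC over
    ``n_permutations`` shuffles of the predictor's column, floored at zero
    and normalized to 100%; run models are averaged within an algorithm.
    The ensemble column is the weight-averaged member contribution,
    re-normalized to 100%.  Returns a DataFrame indexed by predictor with
    one column per algorithm plus "ensemble", each summing to 100.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(train.label)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    predictors = list(train.features.columns)
    rng = np.random.default_rng(seed)
    cols = {}
    for algo, models in ensemble.members.items():
        per_run = [
            _model_contribution(m, train.features, labels, predictors, n_permutations, rng)
            for m in models
        ]
        contrib = np.mean(per_run, axis=0)
        cols[algo] = 100.0 * contrib / contrib.sum()
    ens = np.zeros(len(predictors))
    for algo in ensemble.members:
        ens += ensemble.weights[algo] * cols[algo]
    cols["ensemble"] = 100.0 * ens / ens.sum()
    return pd.DataFrame(cols, index=predictors)
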