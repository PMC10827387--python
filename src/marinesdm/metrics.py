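"""Model evaluation metrics for presence/pseudo-absence SDMs.

AUC, threshold-based sensitivity/specificity/TSS, the continuous Boyce
index for presence-only evaluation, the minimum-training-area (MTP)
reclassification threshold, and predictor collinearity diagnostics
(pairwise Pearson r and variance inflation factors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricSet",
    "ThresholdResult",
    "auc",
    "confusion_metrics",
    "boyce_index",
    "mtp_threshold",
    "collinearity",
]


@dataclass(frozen=True)
class MetricSet:
    """One row of an evaluation report."""

    auc: float
    sensitivity: float
    specificity: float
    tss: float
    boyce: float


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of minimum-training-area threshold selection.

    ``threshold`` is the largest suitability cutoff keeping training
    sensitivity at or above the requested bound — the cutoff that minimises
    predicted area subject to that bound.
    """

    threshold: float
    sensitivity: float
    area_fraction: float


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both presence (1) and absence (0) labels are required")
    return pos, neg

def auc(labels, scores) -> float:
    """Rank-based AUC: probability a random presence outscores a random
    absence, ties counting one half (Mann-Whitney U / (n1 * n0))."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores)
    n1, n0 = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_metrics(labels, scores, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) with presence predicted when
    ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    pred = scores >= threshold
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return sens, spec, sens + spec - 1.0


def boyce_index(
    presence_scores,
    background_scores,
    n_windows: int = 101,
    window_fraction: float = 0.1,
    min_presences: int = 20,
    min_background: int = 100,
) -> float:
    """Continuous Boyce index for presence-only evaluation.

    Overlapping windows of width ``window_fraction`` times the background
    score range slide over that range; each window's P/E ratio is the
    presence fraction over the background (expected) fraction, windows with
    zero expected fraction are skipped, and the index is the Spearman rank
    correlation between P/E and window midpoint.  Consecutive duplicate P/E
    values (long runs of empty windows) are collapsed to one before
    correlating, as in the reference continuous-Boyce procedure, so runs of
    tied zeros do not drown the signal.  Ranges over [-1, 1]; returns 0
    (with a warning) when P/E is constant and the correlation is undefined.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size < min_presences:
        raise ValueError(f"need at least {min_presences} presence scores, got {pres.size}")
    if back.size < min_background:
        raise ValueError(f"need at least {min_background} background scores, got {back.size}")
    lo, hi = float(back.min()), float(back.max())
    if hi <= lo:
        warnings.warn("constant background scores: Boyce index undefined, returning 0")
        return 0.0
    width = window_fraction * (hi - lo)
    lows = np.linspace(lo, hi - width, n_windows)
    mids, pe = [], []
    for low in lows:
        high = low + width
        e = np.mean((back >= low) & (back <= high))
        if e == 0:
            continue
        p = np.mean((pres >= low) & (pres <= high))
        mids.append(low + width / 2.0)
        pe.append(p / e)
    pe = np.asarray(pe)
    mids = np.asarray(mids)
    if pe.size:
        keep = np.r_[True, pe[1:] != pe[:-1]]
        pe, mids = pe[keep], mids[keep]
    if len(pe) < 2 or np.allclose(pe, pe[0]):
        warnings.warn("constant P/E ratio: Boyce index undefined, returning 0")
        return 0.0
    rho = stats.spearmanr(pe, mids).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def mtp_threshold(
    presence_scores,
    suitability_map=None,
    min_sensitivity: float = 0.95,
) -> ThresholdResult:
    """Minimum-training-area threshold.

    The largest score ``t`` (among observed presence scores, plus 0) such
    that the fraction of presences with score >= t is at least
    ``min_sensitivity``; maximising ``t`` minimises the predicted area.
    ``suitability_map`` (a RasterGrid), when given, is used to report the
    predicted-presence fraction of its unmasked cells.
    """
    pres = np.asarray(presence_scores, dtype=float)
    if pres.size == 0:
        raise ValueError("presence scores must be non-empty")
    if not (0.0 < min_sensitivity <= 1.0):
        raise ValueError("min_sensitivity must be in (0, 1]")
    candidates = np.unique(pres)
    best_t = 0.0
    best_sens = 1.0
    for t in candidates:  # ascending; keep the largest feasible
        sens = float(np.mean(pres >= t))
        if sens >= min_sensitivity:
            best_t, best_sens = float(t), sens
    area = float("nan")
    if suitability_map is not None:
        vals = suitability_map.values[~suitability_map.mask]
        area = float(np.mean(vals >= best_t)) if vals.size else float("nan")
    return ThresholdResult(threshold=best_t, sensitivity=best_sens, area_fraction=area)


def collinearity(feature_matrix, names: list[str] | None = None):
    """Pairwise Pearson r and variance inflation factors.

    VIF_j = 1 / (1 - R²_j) from an OLS regression (with intercept) of
    predictor j on all others.  Zero-variance predictors get NaN r entries
    and NaN VIF; perfectly collinear predictors get infinite VIF.
    Returns ``(r_matrix, vif)`` as (p, p) and (p,) arrays.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if X.shape[0] < 3:
        raise ValueError("need at least three rows")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix must be finite")
    n, p = X.shape
    sd = X.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    vif = np.full(p, np.nan)
    for j in range(p):
        if sd[j] == 0:
            continue
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(n * sd[j] ** 2)
        r2 = 1.0 - ss_res / ss_tot
        vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return r, vif
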