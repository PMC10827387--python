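"""Spatial structure handling: autocorrelation distance, occurrence
thinning, hexagonal cross-validation blocks, and climatically structured
pseudo-absences.

Presence-only records are spatially biased and autocorrelated.  The
workflow implemented here estimates the distance over which predictor
values at paired sites remain significantly correlated, thins occurrences
to that distance, blocks cross-validation folds into hexagons of the same
width so test folds are spatially independent of training folds, and draws
pseudo-absences one per K-means cluster of predictor space so absences
cover the available environment without redundancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .geo_io import KM_PER_DEGREE, OccurrenceTable, PredictorStack, extract_values, great_circle_km

__all__ = [
    "Correlogram",
    "HexFoldAssignment",
    "TrainingSet",
    "estimate_autocorrelation_distance",
    "thin_occurrences",
    "assign_hex_folds",
    "generate_pseudoabsences",
]

logger = logging.getLogger(__name__)

#: Species with more occurrences than this get a single 1:1-balanced run.
LARGE_SPECIES_CUTOFF = 1000
#: Rare species get this many independent pseudo-absence runs ...
N_RUNS_RARE = 10
#: ... each with at least this many pseudo-absences.
MIN_PSEUDOABSENCES = 100


@dataclass
class Correlogram:
    """Pearson correlation of predictor values between paired sites, by
    great-circle distance class."""

    edges_km: np.ndarray              # class edges, length n_classes + 1
    r: np.ndarray                     # pooled Pearson r per class
    n: np.ndarray                     # points entering each class's r
    significant: np.ndarray           # bool per class
    uncorrelated_distance_km: float   # lower edge of first non-significant class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower_km": self.edges_km[:-1],
                "upper_km": self.edges_km[1:],
                "r": self.r,
                "n": self.n,
                "significant": self.significant,
            }
        )


@dataclass
class HexFoldAssignment:
    """Hexagon id and cross-validation fold (1..n_folds) per record."""

    hex_id: np.ndarray
    fold: np.ndarray
    hex_width_km: float


@dataclass
class TrainingSet:
    """Labelled presences and pseudo-absences with extracted features."""

    run: int
    lon: np.ndarray
    lat: np.ndarray
    label: np.ndarray                   # 1 presence, 0 pseudo-absence
    features: pd.DataFrame              # one column per predictor
    fold: np.ndarray | None = None      # assigned by assign_hex_folds

    def __post_init__(self) -> None:
        n = self.lon.size
        if not (self.lat.size == n == self.label.size == len(self.features)):
            raise ValueError("training set arrays must have equal length")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if not np.isfinite(self.features.to_numpy()).all():
            raise ValueError("features must be finite (no masked-cell values)")

    @property
    def n_presence(self) -> int:
        return int((self.label == 1).sum())

    @property
    def n_absence(self) -> int:
        return int((self.label == 0).sum())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"lon": self.lon, "lat": self.lat, "label": self.label})
        out["fold"] = -1 if self.fold is None else self.fold
        out["run"] = self.run
        return pd.concat([out, self.features.reset_index(drop=True)], axis=1)


def estimate_autocorrelation_distance(
    stack: PredictorStack,
    n_pairs: int = 10_000,
    class_width_km: float = 50.0,
    max_distance_km: float = 1000.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> Correlogram:
    """Estimate the distance beyond which predictor values at paired sites
    are no longer significantly positively correlated.

    Random unmasked cell pairs are binned by great-circle distance; within
    each class, the standardized predictor values of the two sites (pooled
    over predictors) give one Pearson r.  A class counts as correlated when
    r > 0 with a two-sided p-value below ``alpha``.  The uncorrelated
    distance is the lower edge of the first non-correlated class, falling
    back to ``max_distance_km`` when every class is correlated.
    """
    if not stack.grids:
        raise ValueError("empty predictor stack")
    if n_pairs < 1000:
        raise ValueError("need at least 1000 pairs")
    grid = stack.grid
    rows, cols = grid.unmasked_indices()
    n_cells = rows.size
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, n_cells, size=n_pairs)
    ib = rng.integers(0, n_cells, size=n_pairs)
    lon_a, lat_a = grid.cell_center(rows[ia], cols[ia])
    lon_b, lat_b = grid.cell_center(rows[ib], cols[ib])
    d = great_circle_km(lon_a, lat_a, lon_b, lat_b)

    # standardized predictor values at both pair ends; zero-variance
    # predictors carry no correlation signal and are excluded
    za, zb = [], []
    for name in stack.names:
        vals = stack.grids[name].values[rows, cols]
        sd = vals.std()
        if sd == 0:
            continue
        z = (vals - vals.mean()) / sd
        za.append(z[ia])
        zb.append(z[ib])
    edges = np.arange(0.0, max_distance_km + class_width_km, class_width_km)
    n_classes = len(edges) - 1
    r_out = np.full(n_classes, np.nan)
    n_out = np.zeros(n_classes, dtype=int)
    sig = np.zeros(n_classes, dtype=bool)
    cls = np.digitize(d, edges) - 1
    pair_counts = np.bincount(cls[(cls >= 0) & (cls < n_classes)], minlength=n_classes)
    if (pair_counts < 30).all():
        raise ValueError("fewer than 30 pairs in every distance class; increase n_pairs")
    for c in range(n_classes):
        in_class = cls == c
        if not za:
            continue  # all predictors zero-variance: every class non-significant
        xs = np.concatenate([z[in_class] for z in za])
        ys = np.concatenate([z[in_class] for z in zb])
        n_out[c] = xs.size
        if xs.size < 3 or xs.std() == 0 or ys.std() == 0:
            continue
        res = stats.pearsonr(xs, ys)
        r_out[c] = res.statistic
        sig[c] = (res.statistic > 0) and (res.pvalue < alpha)
    non_sig = np.nonzero(~sig)[0]
    dist = float(edges[non_sig[0]]) if non_sig.size else float(max_distance_km)
    return Correlogram(edges, r_out, n_out, sig, dist)


def thin_occurrences(
    occ: OccurrenceTable, min_distance_km: float, seed: int = 0
) -> OccurrenceTable:
    """Greedy spatial thinning: visit records in seeded random order and
    keep one iff no already-kept record lies within ``min_distance_km``."""
    if min_distance_km < 0:
        raise ValueError("min_distance_km must be non-negative")
    if min_distance_km == 0 or len(occ) == 0:
        return OccurrenceTable(occ.species_id, occ.lon.copy(), occ.lat.copy())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(occ))
    kept_lon: list[float] = []
    kept_lat: list[float] = []
    for i in order:
        if kept_lon:
            d = great_circle_km(occ.lon[i], occ.lat[i], np.asarray(kept_lon), np.asarray(kept_lat))
            if np.min(d) < min_distance_km:
                continue
        kept_lon.append(occ.lon[i])
        kept_lat.append(occ.lat[i])
    return OccurrenceTable(occ.species_id, np.asarray(kept_lon), np.asarray(kept_lat))


def _hex_axial(x_km: np.ndarray, y_km: np.ndarray, width_km: float) -> np.ndarray:
    """Axial (q, r) coordinates of flat-topped hexagons with across-flats
    width ``width_km`` containing the given planar points."""
    size = width_km / np.sqrt(3.0)  # circumradius
    qf = (2.0 / 3.0) * x_km / size
    rf = (-1.0 / 3.0) * x_km / size + (np.sqrt(3.0) / 3.0) * y_km / size
    # cube rounding
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return np.column_stack([q, r]).astype(int)


def assign_hex_folds(
    lon: np.ndarray,
    lat: np.ndarray,
    hex_width_km: float,
    n_folds: int = 10,
    seed: int = 0,
) -> HexFoldAssignment:
    """Assign records to cross-validation folds by hexagonal spatial block.

    Points are projected onto a local equirectangular plane centered on
    their median, tessellated into flat-topped hexagons of the given
    across-flats width, and the occupied hexagons are shuffled and dealt
    round-robin to folds — records sharing a hexagon can never cross folds.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if hex_width_km <= 0:
        raise ValueError("hexagon width must be positive")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = np.median(lon), np.median(lat)
    x = (lon - lon0) * KM_PER_DEGREE * np.cos(np.radians(lat0))
    y = (lat - lat0) * KM_PER_DEGREE
    axial = _hex_axial(x, y, hex_width_km)
    hex_keys, hex_id = np.unique(axial, axis=0, return_inverse=True)
    n_hex = hex_keys.shape[0]
    if n_hex < n_folds:
        raise ValueError(
            f"only {n_hex} occupied hexagons for {n_folds} folds; "
            "reduce n_folds or the hexagon width"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_hex)
    hex_fold = np.empty(n_hex, dtype=int)
    hex_fold[order] = np.arange(n_hex) % n_folds + 1
    return HexFoldAssignment(hex_id=hex_id, fold=hex_fold[hex_id], hex_width_km=hex_width_km)


def pseudoabsence_plan(n_occ: int) -> tuple[int, int]:
    """(number of runs, pseudo-absences per run) given an occurrence count:
    one 1:1-balanced run above the large-species cutoff, otherwise 10 runs
    of at least 100 pseudo-absences each."""
    if n_occ > LARGE_SPECIES_CUTOFF:
        return 1, n_occ
    return N_RUNS_RARE, max(MIN_PSEUDOABSENCES, n_occ)


def generate_pseudoabsences(
    stack: PredictorStack,
    occ_thinned: OccurrenceTable,
    exclusion_km: float,
    seed: int = 0,
    predictors: list[str] | None = None,
    kmeans_restarts: int = 10,
) -> list[TrainingSet]:
    """Climatically structured pseudo-absences, one per K-means cluster.

    Candidate cells are unmasked cells farther than ``exclusion_km`` from
    every occurrence.  Per run, K-means with k equal to the desired
    pseudo-absence count partitions the candidates' standardized predictor
    values, and the member nearest each cluster centroid becomes one
    pseudo-absence, guaranteeing environmental coverage without
    redundancy.  Returns one TrainingSet per run combining presences
    (label 1, features at occurrence cells) and pseudo-absences (label 0).
    """
    if len(occ_thinned) == 0:
        raise ValueError("no occurrences to balance against")
    names = predictors or stack.names
    grid = stack.grid

    # presences: keep only records on valid cells
    pres_X, keep = extract_values(stack, occ_thinned.lon, occ_thinned.lat, names)
    if not keep.any():
        raise ValueError("no occurrence falls on an unmasked cell")
    pres_lon, pres_lat = occ_thinned.lon[keep], occ_thinned.lat[keep]
    pres_X = pres_X[keep]
    n_occ = pres_lon.size

    n_runs, n_pa = pseudoabsence_plan(n_occ)

    rows, cols = grid.unmasked_indices()
    c_lon, c_lat = grid.cell_center(rows, cols)
    far = np.ones(c_lon.size, dtype=bool)
    chunk = 2000
    for start in range(0, c_lon.size, chunk):
        sl = slice(start, start + chunk)
        d = great_circle_km(
            c_lon[sl, None], c_lat[sl, None], pres_lon[None, :], pres_lat[None, :]
        )
        far[sl] = d.min(axis=1) > exclusion_km
    cand_rows, cand_cols = rows[far], cols[far]
    cand_lon, cand_lat = c_lon[far], c_lat[far]
    if cand_rows.size < n_pa:
        raise ValueError(
            f"candidate pool ({cand_rows.size} cells) smaller than the "
            f"desired pseudo-absence count ({n_pa})"
        )
    cand_X = np.column_stack([stack.grids[n].values[cand_rows, cand_cols] for n in names])
    scaler = StandardScaler()
    cand_Z = scaler.fit_transform(cand_X)

    sub_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    out = []
    for run in range(n_runs):
        km = KMeans(n_clusters=n_pa, n_init=kmeans_restarts, random_state=int(sub_seeds[run]))
        labels = km.fit_predict(cand_Z)
        reps = np.empty(n_pa, dtype=int)
        for k in range(n_pa):
            members = np.nonzero(labels == k)[0]
            dist2 = ((cand_Z[members] - km.cluster_centers_[k]) ** 2).sum(axis=1)
            reps[k] = members[np.argmin(dist2)]
        pa_X = cand_X[reps]
        ts = TrainingSet(
            run=run,
            lon=np.concatenate([pres_lon, cand_lon[reps]]),
            lat=np.concatenate([pres_lat, cand_lat[reps]]),
            label=np.concatenate([np.ones(n_occ, int), np.zeros(n_pa, int)]),
            features=pd.DataFrame(np.vstack([pres_X, pa_X]), columns=names),
        )
        out.append(ts)
        logger.info(
            "run %d: %d presences, %d climatically structured pseudo-absences",
            run, n_occ, n_pa,
        )
    return out
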