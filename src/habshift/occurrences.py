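"""Occurrence cleaning, pseudo-absence construction, and sample extraction.

Presence-only records are thinned to one per grid cell to damp spatial
autocorrelation, pseudo-absences are drawn by the "disk" strategy (uniform
over domain cells at least a buffer distance from every presence), features
are read off the raster stack at each point, and the labelled table is
split stratified into train/test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import EnvStack, GridSpec, RasterGrid

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class OccurrenceRecord:
    x: float
    y: float
    label: int  # 1 = presence, 0 = (pseudo-)absence
    source: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


class OccurrenceSet:
    """Labelled point records with provenance."""

    def __init__(self, records: Sequence[OccurrenceRecord] = ()) -> None:
        self.records: List[OccurrenceRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def xy(self) -> np.ndarray:
        if not self.records:
            return np.empty((0, 2))
        return np.array([(r.x, r.y) for r in self.records])

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def presences(self) -> "OccurrenceSet":
        return OccurrenceSet([r for r in self.records if r.label == 1])

    def absences(self) -> "OccurrenceSet":
        return OccurrenceSet([r for r in self.records if r.label == 0])

    def combined_with(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(self.records + other.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.x, r.y, r.label, r.source) for r in self.records],
            columns=["x", "y", "label", "source"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        recs = [
            OccurrenceRecord(float(r.x), float(r.y), int(r.label), str(getattr(r, "source", "")))
            for r in df.itertuples(index=False)
        ]
        return cls(recs)


@dataclass(frozen=True)
class PrepConfig:
    """Sample-construction settings.

    thin_cell_size and min_absence_distance are in map units (km on the
    nominal 1-km grid); absence_ratio is pseudo-absences per presence.
    """

    thin_cell_size: float = 1.0
    min_absence_distance: float = 10.0
    absence_ratio: float = 1.0
    train_fraction: float = 0.7
    stratified: bool = True
    metric: str = "euclidean"  # or "haversine" for WGS84 degree inputs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.min_absence_distance <= 0:
            raise ValueError("min_absence_distance must be positive")
        if self.metric not in ("euclidean", "haversine"):
            raise ValueError("metric must be 'euclidean' or 'haversine'")


@dataclass
class SampleMatrix:
    """Per-point feature table + labels + variable registry."""

    features: pd.DataFrame
    labels: np.ndarray
    point_index: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.point_index = np.asarray(self.point_index, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if len(self.features) == 0:
            raise ValueError("empty sample matrix")
        if self.features.isna().any().any():
            raise ValueError("sample matrix contains missing values")

    @property
    def variable_names(self) -> List[str]:
        return list(self.features.columns)

    @property
    def n(self) -> int:
        return len(self.features)

    def subset_variables(self, names: Sequence[str]) -> "SampleMatrix":
        return SampleMatrix(self.features[list(names)].copy(), self.labels.copy(), self.point_index.copy())

    def take(self, idx: np.ndarray) -> "SampleMatrix":
        return SampleMatrix(
            self.features.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            self.point_index[idx],
        )


def thin_occurrences(points: OccurrenceSet, cell_size: float) -> OccurrenceSet:
    """Keep at most one point per thinning-grid cell (first in input order)."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if len(points) == 0:
        raise ValueError("empty occurrence set")
    seen = set()
    kept = []
    for rec in points:
        key = (int(np.floor(rec.x / cell_size)), int(np.floor(rec.y / cell_size)))
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return OccurrenceSet(kept)


def _haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between lon/lat degree arrays."""
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def generate_pseudo_absences(
    presences: OccurrenceSet, domain: RasterGrid, cfg: PrepConfig
) -> OccurrenceSet:
    """Disk pseudo-absence sampling.

    Candidate cells are valid domain cells whose centers lie at least
    ``cfg.min_absence_distance`` from every presence; round(absence_ratio ×
    n_presences) of them are drawn uniformly without replacement (one
    pseudo-absence per cell, mirroring the one-presence-per-cell rule).
    """
    if any(r.label != 1 for r in presences):
        raise ValueError("presences must all be labelled 1")
    n_req = int(round(cfg.absence_ratio * len(presences)))
    if n_req == 0:
        return OccurrenceSet([])
    spec = domain.spec
    cx, cy = spec.cell_centers()
    eligible = domain.valid & (domain.values != 0 if domain.kind == "binary" else True)
    centers = np.column_stack([cx[eligible], cy[eligible]])
    pres_xy = presences.xy
    if len(pres_xy):
        if cfg.metric == "haversine":
            dmin = _haversine_km(centers, pres_xy).min(axis=1)
        else:
            tree = cKDTree(pres_xy)
            dmin, _ = tree.query(centers, k=1)
        keep = dmin >= cfg.min_absence_distance
        centers = centers[keep]
    if len(centers) < n_req:
        raise ValueError(
            f"only {len(centers)} eligible cells outside the "
            f"{cfg.min_absence_distance}-unit buffers; {n_req} requested"
        )
    rng = np.random.default_rng(cfg.seed)
    pick = rng.choice(len(centers), size=n_req, replace=False)
    records = [
        OccurrenceRecord(float(x), float(y), 0, "pseudo-absence")
        for x, y in centers[np.sort(pick)]
    ]
    return OccurrenceSet(records)


def extract_samples(stack: EnvStack, occurrences: OccurrenceSet) -> SampleMatrix:
    """Read one feature row per point from the stack at the containing cell.

    Points falling on nodata (any layer) or off-grid are dropped with a
    logged count; categorical layers pass through as integer codes.
    """
    xy = occurrences.xy
    rows, cols = stack.spec.index_of(xy[:, 0], xy[:, 1])
    on_grid = (rows >= 0) & (cols >= 0)
    names = stack.layer_names
    data = {}
    valid = on_grid.copy()
    for name in names:
        grid = stack[name]
        vals = np.full(len(xy), np.nan)
        vals[on_grid] = grid.values[rows[on_grid], cols[on_grid]]
        nod = np.zeros(len(xy), dtype=bool)
        nod[on_grid] = grid.nodata_mask[rows[on_grid], cols[on_grid]]
        valid &= ~nod
        data[name] = vals
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("extract_samples: dropped %d points (off-grid or nodata)", n_dropped)
    if not valid.any():
        raise ValueError("all points fall off-grid or on nodata cells")
    features = pd.DataFrame(data).loc[valid].reset_index(drop=True)
    labels = occurrences.labels[valid]
    point_index = np.flatnonzero(valid)
    return SampleMatrix(features, labels, point_index)


def split_samples(samples: SampleMatrix, cfg: PrepConfig) -> Tuple[SampleMatrix, SampleMatrix]:
    """Stratified train/test split; floor(train_fraction × n) per stratum
    goes to train, remainder to test. Deterministic under cfg.seed."""
    labels = samples.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both label classes must be present")
    if counts.min() < 2:
        raise ValueError("each label class needs at least 2 members")
    rng = np.random.default_rng(cfg.seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    if cfg.stratified:
        for c in classes:
            idx = np.flatnonzero(labels == c)
            perm = rng.permutation(idx)
            n_train = int(np.floor(cfg.train_fraction * len(idx)))
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
    else:
        perm = rng.permutation(samples.n)
        n_train = int(np.floor(cfg.train_fraction * samples.n))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx_a = np.sort(np.asarray(train_idx, dtype=int))
    test_idx_a = np.sort(np.asarray(test_idx, dtype=int))
    return samples.take(train_idx_a), samples.take(test_idx_a)
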