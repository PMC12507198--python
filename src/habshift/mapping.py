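"""Suitability surfaces, natural-breaks classification, and area tables.

The fitted model is applied cellwise to the predictor stack to produce a
probability surface; Fisher–Jenks natural breaks split the surface into
four ordered habitability classes (low=1, middle=2, habitability=3,
high=4); per-region class areas and shares are tabulated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import RasterGrid, RegionMask, check_regions_disjoint
from .landscape import ScenarioSpec
from .models import FittedModel

CLASS_LABELS = {1: "low", 2: "middle", 3: "habitability", 4: "high"}

#: cap on the number of cell values fed to the exact Jenks DP; larger
#: surfaces are subsampled with a seeded draw before fitting breaks
JENKS_SAMPLE_CAP = 10_000


@dataclass
class SuitabilityMap:
    probability: RasterGrid
    breaks: Sequence[float]
    classes: RasterGrid
    scenario: ScenarioSpec

    def __post_init__(self) -> None:
        b = list(self.breaks)
        if len(b) != 3 or not (b[0] < b[1] < b[2]):
            raise ValueError("need 3 strictly ascending breaks")


def predict_probability_surface(
    model: FittedModel, stack, mask: Optional[RasterGrid] = None
) -> RasterGrid:
    """Apply the model cellwise over the stack.

    Only the model's retained variables are read from the stack; cells
    masked out (or nodata in any used layer) propagate as nodata.
    """
    missing = [v for v in model.variable_names if v not in stack]
    if missing:
        raise KeyError(f"stack is missing retained layers: {missing}")
    spec = stack.spec
    nodata = np.zeros(spec.shape, dtype=bool)
    if mask is not None:
        if mask.spec != spec:
            raise ValueError("mask not aligned with stack")
        nodata |= mask.nodata_mask | (mask.values == 0)
    cols = []
    for name in model.variable_names:
        grid = stack[name]
        nodata |= grid.nodata_mask
        cols.append(grid.values.ravel())
    X = np.column_stack(cols)
    valid = ~nodata.ravel()
    out = np.full(spec.n_cells, np.nan)
    if valid.any():
        out[valid] = model.predict_proba(X[valid])
    return RasterGrid(spec, out.reshape(spec.shape), nodata)


def jenks_breaks(
    values: Sequence[float],
    k: int,
    sample_cap: int = JENKS_SAMPLE_CAP,
    seed: int = 0,
) -> List[float]:
    """Fisher–Jenks optimal 1-D classification into k classes.

    Dynamic programming over the sorted values minimizes the total
    within-class sum of squared deviations from class means; cost ties
    resolve toward the smaller lower class. Returned breaks are the k−1
    midpoints between adjacent class boundary values.

    Inputs longer than ``sample_cap`` are subsampled (seeded) before the
    O(k·n²) DP; pass ``sample_cap=None`` to force the exact solution.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values, got {np.unique(v).size}")
    if sample_cap is not None and v.size > sample_cap:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=sample_cap, replace=False)
        if np.unique(v).size < k:  # pathological sample; fall back to exact
            v = np.asarray(values, dtype=float).ravel()
            v = v[np.isfinite(v)]
    x = np.sort(v)
    n = x.size
    # prefix sums for O(1) within-class SSD of x[i:j] (j exclusive)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd_vec(i: np.ndarray, j: int) -> np.ndarray:
        m = j - i
        s = cs[j] - cs[i]
        return cs2[j] - cs2[i] - s * s / m

    # cost[c][j] = optimal cost of splitting x[:j] into c classes
    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    j_all = np.arange(1, n + 1)
    cost[1][1:] = cs2[1:] - cs[1:] * cs[1:] / j_all
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            # last class = x[i:j]; argmin returns the smallest optimal i,
            # which resolves cost ties toward the smaller lower classes
            i = np.arange(c - 1, j)
            cand = cost[c - 1][i] + ssd_vec(i, j)
            best = int(np.argmin(cand))
            cost[c][j] = cand[best]
            split[c][j] = i[best]
    # recover boundary indices
    bounds = []
    j = n
    for c in range(k, 1, -1):
        j = int(split[c][j])
        bounds.append(j)
    bounds.reverse()
    return [float((x[i - 1] + x[i]) / 2.0) for i in bounds]


def classify_suitability(probability: RasterGrid, breaks: Sequence[float]) -> RasterGrid:
    """Ordered class grid: label = 1 + number of breaks <= cell value.

    Intervals are lower-inclusive (a value equal to a break joins the class
    above it); the top class is closed. Nodata propagates.
    """
    b = np.asarray(breaks, dtype=float)
    if not (np.diff(b) > 0).all():
        raise ValueError("breaks must be strictly ascending")
    v = probability.values
    labels = 1 + (v[..., None] >= b).sum(axis=-1)
    labels = labels.astype(float)
    labels[probability.nodata_mask] = np.nan
    return RasterGrid(probability.spec, labels, probability.nodata_mask.copy(), kind="categorical")


def _round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (numpy/python banker's rounding avoided)."""
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def area_shares(areas: Sequence[float]) -> List[float]:
    """Percent shares of a list of areas, rounded to 2 d.p. half away from zero."""
    total = float(np.sum(areas))
    if total <= 0:
        raise ValueError("total area must be positive")
    return [_round_half_away(100.0 * a / total) for a in areas]


def tabulate_class_areas(
    classes: RasterGrid,
    regions: List[RegionMask],
    cell_area: float = 1.0,
    scenario_id: str = "current",
) -> pd.DataFrame:
    """Per-(region, class) areas and shares.

    area = cell count × cell_area (km²); share = area / region area × 100,
    rounded to 2 decimals half away from zero. Regions must be disjoint.
    """
    check_regions_disjoint(regions)
    rows = []
    valid = classes.valid
    for reg in regions:
        in_reg = (reg.mask.values == 1) & reg.mask.valid & valid
        region_cells = int(in_reg.sum())
        counts = {c: int(((classes.values == c) & in_reg).sum()) for c in CLASS_LABELS}
        region_area = region_cells * cell_area
        for c, label in CLASS_LABELS.items():
            area = counts[c] * cell_area
            share = _round_half_away(100.0 * area / region_area) if region_area > 0 else 0.0
            rows.append(
                {
                    "region_id": reg.region_id,
                    "scenario_id": scenario_id,
                    "class": c,
                    "class_label": label,
                    "area_km2": area,
                    "share_pct": share,
                }
            )
    return pd.DataFrame(rows)
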