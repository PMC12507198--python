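"""Forest-overlap analysis.

The top two habitability classes (3 and 4) merge into the "primary
habitability area"; intersecting it with the (static) forest mask per
region quantifies potential encroachment of suitable-habitat expansion on
forest land, and differencing against the current-climate overlap gives
the change columns.
"""
from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd

from .grids import RasterGrid, RegionMask, check_regions_disjoint
from .mapping import _round_half_away


def primary_mask(classes: RasterGrid) -> RasterGrid:
    """Binary mask of the primary habitability area (classes 3 and 4)."""
    v = classes.values
    valid = classes.valid
    known = np.isin(v[valid], (1, 2, 3, 4))
    if not known.all():
        bad = sorted(set(v[valid][~known].tolist()))
        raise ValueError(f"unknown class labels {bad}")
    mask = np.where(valid, np.isin(v, (3, 4)).astype(float), 0.0)
    return RasterGrid(classes.spec, mask, classes.nodata_mask.copy(), kind="binary")


def overlap_table(
    classes: RasterGrid,
    forest: RasterGrid,
    regions: List[RegionMask],
    cell_area: float = 1.0,
    current: Optional[pd.DataFrame] = None,
    scenario_id: str = "current",
) -> pd.DataFrame:
    """Per-region overlap between habitability classes and forest.

    Columns: overlap of class 4 (high) with forest, class 3 (habitability)
    with forest, their sum (primary), and — when a current-climate table is
    supplied — delta and percent change relative to the current primary
    overlap (2 d.p., half away from zero).
    """
    if forest.spec != classes.spec:
        raise ValueError("forest mask not aligned with class grid")
    check_regions_disjoint(regions)
    primary_mask(classes)  # label validation
    valid = classes.valid & forest.valid
    f = forest.values == 1
    rows = []
    for reg in regions:
        in_reg = (reg.mask.values == 1) & reg.mask.valid & valid
        high = int(((classes.values == 4) & f & in_reg).sum()) * cell_area
        hab = int(((classes.values == 3) & f & in_reg).sum()) * cell_area
        rows.append(
            {
                "region_id": reg.region_id,
                "scenario_id": scenario_id,
                "overlap_high_km2": high,
                "overlap_habitability_km2": hab,
                "overlap_primary_km2": high + hab,
            }
        )
    out = pd.DataFrame(rows)
    if current is not None:
        cur = current.set_index("region_id")["overlap_primary_km2"]
        missing = sorted(set(out["region_id"]) ^ set(cur.index))
        if missing:
            raise KeyError(f"region keys do not match current table: {missing}")
        base = cur.loc[out["region_id"]].to_numpy(dtype=float)
        delta = out["overlap_primary_km2"].to_numpy(dtype=float) - base
        out["delta_vs_current_km2"] = delta
        out["pct_change_vs_current"] = [
            _round_half_away(100.0 * d / b) if b > 0 else np.nan
            for d, b in zip(delta, base)
        ]
    else:
        out["delta_vs_current_km2"] = np.nan
        out["pct_change_vs_current"] = np.nan
    return out
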