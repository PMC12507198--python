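"""Future-scenario projection and change tables.

A scenario shifts climate layers additively (terrain and soil held fixed),
the fitted model is re-applied, and the surface is classified either with
the current-climate breaks (default — changes are then attributable to
climate, not reclassification) or with freshly fitted breaks.
"""
from __future__ import annotations

from typing import List, Optional

import pandas as pd

from .grids import RasterGrid, RegionMask
from .landscape import ScenarioSpec, apply_scenario_deltas
from .mapping import (
    SuitabilityMap,
    classify_suitability,
    jenks_breaks,
    predict_probability_surface,
    _round_half_away,
)
from .models import FittedModel

BREAK_POLICIES = ("fixed_current", "refit")


def build_suitability_map(
    model: FittedModel,
    stack,
    scenario: ScenarioSpec,
    mask: Optional[RasterGrid] = None,
    breaks: Optional[List[float]] = None,
    seed: int = 0,
) -> SuitabilityMap:
    """Predict, (optionally) fit breaks, classify."""
    prob = predict_probability_surface(model, stack, mask)
    if breaks is None:
        breaks = jenks_breaks(prob.valid_values(), 4, seed=seed)
    classes = classify_suitability(prob, breaks)
    return SuitabilityMap(prob, breaks, classes, scenario)


def project_scenario(
    model: FittedModel,
    base_stack,
    scenario: ScenarioSpec,
    break_policy: str = "fixed_current",
    current_map: Optional[SuitabilityMap] = None,
    mask: Optional[RasterGrid] = None,
    seed: int = 0,
) -> SuitabilityMap:
    """Project suitability under a future scenario.

    ``fixed_current`` classifies the projected surface with the
    current-climate breaks (requires ``current_map``); ``refit`` fits new
    breaks on the projected surface.
    """
    if break_policy not in BREAK_POLICIES:
        raise ValueError(f"unknown break policy {break_policy!r}")
    future_stack = apply_scenario_deltas(base_stack, scenario)
    if break_policy == "fixed_current":
        if current_map is None:
            raise ValueError("fixed_current policy requires the current-climate map")
        breaks = list(current_map.breaks)
    else:
        breaks = None
    return build_suitability_map(model, future_stack, scenario, mask, breaks, seed=seed)


def change_table(current: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """Join current and future area tables on (region, class) and difference.

    delta_area = area_future − area_current (km²); delta_share_points =
    share_future − share_current (percentage points, 2 d.p. half away from
    zero). Raises on any key mismatch.
    """
    keys = ["region_id", "class"]
    cur = current.set_index(keys)
    fut = future.set_index(keys)
    missing = sorted(set(cur.index) ^ set(fut.index))
    if missing:
        raise KeyError(f"region/class keys do not match: {missing}")
    fut = fut.loc[cur.index]
    out = pd.DataFrame(
        {
            "scenario_id": fut["scenario_id"].to_numpy(),
            "class_label": cur["class_label"].to_numpy(),
            "area_future_km2": fut["area_km2"].to_numpy(),
            "area_current_km2": cur["area_km2"].to_numpy(),
            "share_future_pct": fut["share_pct"].to_numpy(),
            "share_current_pct": cur["share_pct"].to_numpy(),
        },
        index=cur.index,
    ).reset_index()
    out["delta_area_km2"] = out["area_future_km2"] - out["area_current_km2"]
    out["delta_share_points"] = [
        _round_half_away(f - c)
        for f, c in zip(out["share_future_pct"], out["share_current_pct"])
    ]
    return out
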