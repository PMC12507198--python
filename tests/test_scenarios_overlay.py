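"""Scenario projection, change tables, and forest-overlap analysis."""
import numpy as np
import pandas as pd
import pytest

from habshift import (
    GridSpec,
    ModelSpec,
    RasterGrid,
    RegionMask,
    ScenarioSpec,
    build_suitability_map,
    change_table,
    overlap_table,
    primary_mask,
    project_scenario,
)
from habshift.grids import EnvStack
from habshift.models import fit_model
from habshift.occurrences import SampleMatrix


def _fitted_on_temperature(seed=0, coef_sign=+1):
    """Logistic model whose only driver is a temperature-like layer."""
    rng = np.random.default_rng(seed)
    x = rng.normal(15, 6, size=400)
    logit = coef_sign * 0.8 * (x - 15) / 6 + rng.normal(0, 0.3, 400)
    y = (logit > 0).astype(int)
    sm = SampleMatrix(pd.DataFrame({"BIO1": x}), y, np.arange(400))
    return fit_model(ModelSpec("MAXENT_LOGISTIC", seed=seed), sm)


def _stack_with_bio1(seed=1, n=20):
    spec = GridSpec(n, n)
    stack = EnvStack(spec)
    rng = np.random.default_rng(seed)
    stack.add("BIO1", RasterGrid(spec, rng.normal(15, 6, size=(n, n))), "climate")
    stack.add("DEM", RasterGrid(spec, rng.normal(800, 500, size=(n, n))), "topographic")
    return stack


def test_zero_delta_scenario_reproduces_current_map():
    model = _fitted_on_temperature()
    stack = _stack_with_bio1()
    current = build_suitability_map(model, stack, ScenarioSpec("current"), seed=0)
    projected = project_scenario(
        model, stack, ScenarioSpec("SSP1_2.6", "2050s", {}), "fixed_current", current
    )
    np.testing.assert_array_equal(
        projected.probability.values, current.probability.values
    )
    np.testing.assert_array_equal(projected.classes.values, current.classes.values)
    assert list(projected.breaks) == list(current.breaks)


def test_warming_raises_mean_probability_for_positive_coefficient():
    model = _fitted_on_temperature(coef_sign=+1)
    stack = _stack_with_bio1()
    current = build_suitability_map(model, stack, ScenarioSpec("current"), seed=0)
    warmed = project_scenario(
        model, stack, ScenarioSpec("SSP5_8.5", "2090s", {"BIO1": 3.0}),
        "fixed_current", current,
    )
    assert warmed.probability.values.mean() > current.probability.values.mean()


def test_unknown_break_policy_rejected():
    model = _fitted_on_temperature()
    stack = _stack_with_bio1()
    with pytest.raises(ValueError, match="policy"):
        project_scenario(model, stack, ScenarioSpec("SSP1_2.6", "2050s", {}), "bogus")


def _areas(region, scenario, areas):
    return pd.DataFrame(
        {
            "region_id": region,
            "scenario_id": scenario,
            "class": [1, 2, 3, 4],
            "class_label": ["low", "middle", "habitability", "high"],
            "area_km2": areas,
            "share_pct": [round(100 * a / sum(areas), 2) for a in areas],
        }
    )


def test_change_table_identity_is_zero():
    cur = _areas("R", "current", [10.0, 20.0, 30.0, 40.0])
    fut = cur.copy()
    fut["scenario_id"] = "SSP1_2.6,2050s"
    ct = change_table(cur, fut)
    assert (ct["delta_area_km2"] == 0).all()
    assert (ct["delta_share_points"] == 0).all()


def test_change_table_matches_elementwise_subtraction():
    rng = np.random.default_rng(8)
    a = rng.uniform(10, 50, 4).round(2)
    b = rng.uniform(10, 50, 4).round(2)
    cur, fut = _areas("R", "current", a), _areas("R", "f", b)
    ct = change_table(cur, fut).set_index("class")
    for c in (1, 2, 3, 4):
        assert ct.loc[c, "delta_area_km2"] == pytest.approx(b[c - 1] - a[c - 1])
    # total region area conserved -> class deltas sum to area difference
    assert ct["delta_area_km2"].sum() == pytest.approx(b.sum() - a.sum())


def test_change_table_key_mismatch():
    cur = _areas("R1", "current", [1, 2, 3, 4])
    fut = _areas("R2", "f", [1, 2, 3, 4])
    with pytest.raises(KeyError):
        change_table(cur, fut)


def test_primary_mask_extremes_and_oracle():
    spec = GridSpec(6, 6)
    all_low = RasterGrid(spec, np.ones((6, 6)), kind="categorical")
    assert primary_mask(all_low).values.sum() == 0
    all_high = RasterGrid(spec, np.full((6, 6), 4.0), kind="categorical")
    assert primary_mask(all_high).values.sum() == 36
    rng = np.random.default_rng(0)
    classes = RasterGrid(spec, rng.integers(1, 5, (6, 6)).astype(float), kind="categorical")
    pm = primary_mask(classes)
    for i in range(6):
        for j in range(6):
            assert pm.values[i, j] == (classes.values[i, j] in (3, 4))


def test_primary_mask_rejects_unknown_label():
    spec = GridSpec(2, 2)
    with pytest.raises(ValueError, match="unknown"):
        primary_mask(RasterGrid(spec, np.array([[1.0, 2.0], [7.0, 4.0]]), kind="categorical"))


def _full_region(spec):
    return [RegionMask("all", RasterGrid(spec, np.ones(spec.shape), kind="binary"))]


def test_overlap_zero_for_disjoint_masks():
    spec = GridSpec(4, 4)
    classes = np.ones((4, 4)); classes[0] = 4  # primary only in row 0
    forest = np.zeros((4, 4)); forest[2] = 1   # forest only in row 2
    tab = overlap_table(
        RasterGrid(spec, classes, kind="categorical"),
        RasterGrid(spec, forest, kind="binary"),
        _full_region(spec),
    )
    assert tab["overlap_primary_km2"].iloc[0] == 0


def test_overlap_matches_cellwise_and_oracle():
    rng = np.random.default_rng(3)
    spec = GridSpec(3, 3)
    classes = RasterGrid(spec, rng.integers(1, 5, (3, 3)).astype(float), kind="categorical")
    forest = RasterGrid(spec, rng.integers(0, 2, (3, 3)).astype(float), kind="binary")
    tab = overlap_table(classes, forest, _full_region(spec), cell_area=2.0)
    high = hab = 0
    for i in range(3):
        for j in range(3):
            if forest.values[i, j] == 1:
                high += classes.values[i, j] == 4
                hab += classes.values[i, j] == 3
    row = tab.iloc[0]
    assert row["overlap_high_km2"] == high * 2.0
    assert row["overlap_habitability_km2"] == hab * 2.0
    # additivity: class-3 and class-4 overlaps partition the primary overlap
    assert row["overlap_primary_km2"] == row["overlap_high_km2"] + row["overlap_habitability_km2"]


def test_overlap_monotone_in_forest_mask():
    rng = np.random.default_rng(5)
    spec = GridSpec(10, 10)
    classes = RasterGrid(spec, rng.integers(1, 5, (10, 10)).astype(float), kind="categorical")
    small = rng.integers(0, 2, (10, 10)).astype(float)
    big = np.clip(small + rng.integers(0, 2, (10, 10)), 0, 1).astype(float)
    t_small = overlap_table(classes, RasterGrid(spec, small, kind="binary"), _full_region(spec))
    t_big = overlap_table(classes, RasterGrid(spec, big, kind="binary"), _full_region(spec))
    for col in ("overlap_high_km2", "overlap_habitability_km2", "overlap_primary_km2"):
        assert t_big[col].iloc[0] >= t_small[col].iloc[0]


def test_overlap_change_columns_against_current():
    spec = GridSpec(4, 4)
    cur_classes = np.ones((4, 4)); cur_classes[:2] = 4
    fut_classes = np.ones((4, 4)); fut_classes[:3] = 4
    forest = RasterGrid(spec, np.ones((4, 4)), kind="binary")
    cur = overlap_table(RasterGrid(spec, cur_classes, kind="categorical"), forest, _full_region(spec))
    fut = overlap_table(
        RasterGrid(spec, fut_classes, kind="categorical"), forest, _full_region(spec),
        current=cur, scenario_id="SSP5_8.5,2090s",
    )
    assert fut["delta_vs_current_km2"].iloc[0] == 4.0
    assert fut["pct_change_vs_current"].iloc[0] == 50.0


def test_overlap_misaligned_grids_rejected():
    classes = RasterGrid(GridSpec(3, 3), np.ones((3, 3)), kind="categorical")
    forest = RasterGrid(GridSpec(4, 4), np.ones((4, 4)), kind="binary")
    with pytest.raises(ValueError, match="aligned"):
        overlap_table(classes, forest, _full_region(GridSpec(3, 3)))
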