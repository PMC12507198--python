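"""Probability surfaces, Fisher–Jenks breaks, classification, area tables."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habshift import (
    GridSpec,
    ModelSpec,
    RasterGrid,
    RegionMask,
    area_shares,
    classify_suitability,
    jenks_breaks,
    predict_probability_surface,
    tabulate_class_areas,
)
from habshift.grids import EnvStack
from habshift.models import fit_model

from conftest import make_samples


def brute_force_jenks_ssd(values, k):
    """Minimum total within-class SSD over all contiguous partitions."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        total = sum(ssd(x[bounds[i] : bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best


def classes_ssd(values, breaks):
    x = np.asarray(values, dtype=float)
    labels = 1 + (x[:, None] >= np.asarray(breaks)).sum(axis=1)
    return sum(
        ((x[labels == c] - x[labels == c].mean()) ** 2).sum()
        for c in np.unique(labels)
    )


def test_jenks_two_cluster_example():
    breaks = jenks_breaks([1, 2, 3, 10, 11, 12], 2)
    assert len(breaks) == 1
    assert 3 < breaks[0] < 10


def test_jenks_k_equals_distinct_values():
    values = [1.0, 4.0, 9.0, 16.0]
    breaks = jenks_breaks(values, 4)
    assert classes_ssd(values, breaks) == pytest.approx(0.0)


def test_jenks_rejects_too_few_distinct():
    with pytest.raises(ValueError):
        jenks_breaks([1.0, 1.0, 2.0], 3)
    with pytest.raises(ValueError):
        jenks_breaks([1.0, 2.0, 3.0], 1)


@pytest.mark.parametrize("k", [2, 3, 4])
def test_jenks_matches_exhaustive_enumeration(k):
    rng = np.random.default_rng(100 + k)
    for _ in range(20):
        values = rng.uniform(0, 1, size=rng.integers(k + 1, 13))
        breaks = jenks_breaks(values, k)
        assert classes_ssd(values, breaks) == pytest.approx(
            brute_force_jenks_ssd(values, k), abs=1e-9
        )


def test_jenks_sampled_breaks_agree_on_classification():
    rng = np.random.default_rng(0)
    values = rng.beta(2, 5, size=12_000)
    full = jenks_breaks(values, 4, sample_cap=None)
    sampled = jenks_breaks(values, 4, sample_cap=10_000, seed=1)
    lab_full = 1 + (values[:, None] >= np.asarray(full)).sum(axis=1)
    lab_smp = 1 + (values[:, None] >= np.asarray(sampled)).sum(axis=1)
    assert (lab_full == lab_smp).mean() >= 0.99


def test_classification_boundary_convention():
    spec = GridSpec(1, 3)
    prob = RasterGrid(spec, np.array([[0.75, 0.1, 0.5]]))
    classes = classify_suitability(prob, [0.25, 0.5, 0.75])
    # a value equal to a break joins the class above it
    np.testing.assert_array_equal(classes.values, [[4, 1, 3]])


def test_classification_uniform_low():
    spec = GridSpec(2, 2)
    prob = RasterGrid(spec, np.full((2, 2), 0.01))
    classes = classify_suitability(prob, [0.2, 0.5, 0.8])
    np.testing.assert_array_equal(classes.values, np.ones((2, 2)))


def test_classification_matches_interval_search_oracle():
    rng = np.random.default_rng(2)
    spec = GridSpec(15, 15)
    prob = RasterGrid(spec, rng.uniform(size=(15, 15)))
    breaks = [0.3, 0.6, 0.85]
    classes = classify_suitability(prob, breaks)
    for i in range(15):
        for j in range(15):
            v = prob.values[i, j]
            expected = 1 + sum(v >= b for b in breaks)
            assert classes.values[i, j] == expected


def test_classification_rejects_unsorted_breaks():
    prob = RasterGrid(GridSpec(1, 1), np.array([[0.5]]))
    with pytest.raises(ValueError):
        classify_suitability(prob, [0.5, 0.3, 0.8])


@given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
@settings(max_examples=100, deadline=None)
def test_classification_monotone_in_probability(a, b):
    spec = GridSpec(1, 2)
    prob = RasterGrid(spec, np.array([[a, b]]))
    classes = classify_suitability(prob, [0.25, 0.5, 0.75]).values[0]
    if a <= b:
        assert classes[0] <= classes[1]
    else:
        assert classes[0] >= classes[1]


def _model_and_stack():
    sm = make_samples(n=200, p=3, seed=7, informative=1)
    model = fit_model(ModelSpec("RF", seed=0), sm)
    spec = GridSpec(10, 10)
    stack = EnvStack(spec)
    rng = np.random.default_rng(1)
    for name in sm.variable_names:
        stack.add(name, RasterGrid(spec, rng.normal(size=(10, 10))), "climate")
    return model, stack


def test_surface_constant_stack_constant_output():
    sm = make_samples(n=100, p=2, seed=3, informative=0)
    model = fit_model(ModelSpec("MAXENT_LOGISTIC", seed=0), sm)
    spec = GridSpec(6, 6)
    stack = EnvStack(spec)
    for name in sm.variable_names:
        stack.add(name, RasterGrid(spec, np.full((6, 6), 0.3)), "climate")
    surf = predict_probability_surface(model, stack)
    assert np.ptp(surf.values) == pytest.approx(0.0)


def test_surface_matches_tabular_prediction_oracle():
    model, stack = _model_and_stack()
    surf = predict_probability_surface(model, stack)
    X = np.column_stack([stack[n].values.ravel() for n in model.variable_names])
    expected = model.predict_proba(X).reshape(10, 10)
    np.testing.assert_allclose(surf.values, expected)


def test_surface_propagates_mask():
    model, stack = _model_and_stack()
    mask_vals = np.ones((10, 10))
    mask_vals[0, :] = 0
    mask = RasterGrid(stack.spec, mask_vals, kind="binary")
    surf = predict_probability_surface(model, stack, mask)
    assert np.isnan(surf.values[0]).all()
    assert surf.nodata_mask[0].all()
    assert not surf.nodata_mask[1:].any()


def test_surface_missing_layer_named_in_error():
    model, stack = _model_and_stack()
    partial = EnvStack(stack.spec)
    names = model.variable_names
    partial.add(names[0], stack[names[0]].copy(), "climate")
    with pytest.raises(KeyError, match=names[1]):
        predict_probability_surface(model, partial)


def _region(spec, mask_vals, rid="r1"):
    return RegionMask(rid, RasterGrid(spec, mask_vals.astype(float), kind="binary"))


def test_tabulate_uniform_high_class():
    spec = GridSpec(10, 10)
    classes = RasterGrid(spec, np.full((10, 10), 4.0), kind="categorical")
    table = tabulate_class_areas(classes, [_region(spec, np.ones((10, 10)))], 1.0)
    high = table[table["class"] == 4].iloc[0]
    assert high["area_km2"] == 100.0
    assert high["share_pct"] == 100.0


def test_tabulate_matches_counting_oracle_and_conserves_area():
    rng = np.random.default_rng(4)
    spec = GridSpec(12, 12)
    classes = RasterGrid(
        spec, rng.integers(1, 5, size=(12, 12)).astype(float), kind="categorical"
    )
    left = np.zeros((12, 12)); left[:, :6] = 1
    right = np.zeros((12, 12)); right[:, 6:] = 1
    regions = [_region(spec, left, "L"), _region(spec, right, "R")]
    table = tabulate_class_areas(classes, regions, 2.5)
    for _, row in table.iterrows():
        reg = left if row["region_id"] == "L" else right
        count = int(((classes.values == row["class"]) & (reg == 1)).sum())
        assert row["area_km2"] == count * 2.5
    for rid in ("L", "R"):
        sub = table[table["region_id"] == rid]
        assert sub["area_km2"].sum() == 72 * 2.5
        assert abs(sub["share_pct"].sum() - 100.0) <= 0.02


def test_tabulate_rejects_overlapping_regions():
    spec = GridSpec(4, 4)
    classes = RasterGrid(spec, np.ones((4, 4)), kind="categorical")
    ones = np.ones((4, 4))
    with pytest.raises(ValueError, match="overlap"):
        tabulate_class_areas(classes, [_region(spec, ones, "a"), _region(spec, ones, "b")], 1.0)


def test_area_shares_rounding():
    assert area_shares([1, 1, 1]) == [33.33, 33.33, 33.33]
    assert area_shares([43.67, 34.52, 8.12, 5.47])[0] == 47.58
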