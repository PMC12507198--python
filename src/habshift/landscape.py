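"""Synthetic study-system generator.

Produces everything a habitat-suitability analysis consumes — a stack of
spatially autocorrelated predictor layers with engineered collinearity, a
known logistic "true" suitability surface, presence points drawn from it, a
forest mask correlated with suitability, additive per-scenario climate
shifts, and a contiguous region partition — so the full pipeline can be
exercised and validated without any external download.

Every generator is a pure function of its configuration and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import EnvStack, GridSpec, LayerClass, RasterGrid, RegionMask
from .occurrences import OccurrenceSet, OccurrenceRecord

# Canonical 47-layer predictor registry: 19 bioclimatic layers, 4 terrain
# layers (elevation, aspect, slope, landform class), and layered soil
# properties (thickness, N/pH/P/K/organic-carbon at 4 depths, texture class
# at 3 depths).
_BIOCLIM = [f"BIO{i}" for i in range(1, 20)]
_TERRAIN = ["DEM", "ASP", "SLO", "DMTZ"]
_DEPTHS4 = ["0-5", "5-15", "15-30", "30-60"]
_SOIL = (
    ["ST"]
    + [f"TN{d}" for d in _DEPTHS4]
    + [f"PH{d}" for d in _DEPTHS4]
    + [f"TP{d}" for d in _DEPTHS4]
    + [f"TK{d}" for d in _DEPTHS4]
    + [f"SOC{d}" for d in _DEPTHS4]
    + [f"USDA{d}" for d in _DEPTHS4[:3]]
)
DEFAULT_LAYER_NAMES: List[str] = _BIOCLIM + _TERRAIN + _SOIL

CATEGORICAL_LAYERS = {"DMTZ", "USDA0-5", "USDA5-15", "USDA15-30"}

SCENARIO_IDS = ("current", "SSP1_2.6", "SSP3_7.0", "SSP5_8.5")
PERIODS = ("2050s", "2090s", "none")


def layer_class_of(name: str) -> LayerClass:
    if name in _BIOCLIM:
        return "climate"
    if name in _TERRAIN:
        return "topographic"
    return "soil"


@dataclass(frozen=True)
class ScenarioSpec:
    """One climate scenario: an identifier plus additive layer shifts.

    Deltas are additive shifts, in layer units, applied to climate-class
    layers only; terrain and soil are held fixed across scenarios.
    """

    scenario_id: str
    period: str = "none"
    deltas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario id {self.scenario_id!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")

    @property
    def label(self) -> str:
        if self.scenario_id == "current" or self.period == "none":
            return self.scenario_id
        return f"{self.scenario_id},{self.period}"


@dataclass
class SyntheticTruth:
    """Ground-truth configuration of the synthetic study system.

    Attributes
    ----------
    driver_names
        Layers that causally drive suitability.
    coefficients
        One logistic coefficient per driver (on the standardized layer).
    intercept
        Logistic intercept; controls baseline prevalence.
    autocorr_length
        Gaussian smoothing length (cells) of every continuous field.
    collinear_pairs
        (source, derived, target |r|) triples; the derived layer is rebuilt
        from the source so their sample Pearson correlation hits the target.
    scenario_deltas
        scenario label -> {climate layer -> additive shift}.
    forest_cover_target
        Fraction of the domain covered by forest, in (0, 1).
    layer_names
        Full predictor registry (defaults to the 47-layer set).
    """

    driver_names: Sequence[str] = ("BIO1", "BIO12", "BIO4", "DEM", "ST")
    coefficients: Sequence[float] = (1.0, 1.2, -0.8, -0.7, 0.6)
    intercept: float = -0.5
    autocorr_length: float = 5.0
    collinear_pairs: Sequence[Tuple[str, str, float]] = (
        ("BIO1", "BIO11", 0.92),
        ("BIO12", "BIO16", 0.90),
        ("BIO4", "BIO7", 0.85),
    )
    scenario_deltas: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "SSP1_2.6,2050s": {"BIO1": 0.8, "BIO12": 0.2},
            "SSP1_2.6,2090s": {"BIO1": 1.2, "BIO12": 0.3},
            "SSP3_7.0,2050s": {"BIO1": 1.4, "BIO12": 0.3},
            "SSP3_7.0,2090s": {"BIO1": 2.8, "BIO12": 0.5},
            "SSP5_8.5,2050s": {"BIO1": 1.8, "BIO12": 0.4},
            "SSP5_8.5,2090s": {"BIO1": 4.0, "BIO12": 0.7},
        }
    )
    forest_cover_target: float = 0.55
    seed: int = 0
    layer_names: Sequence[str] = tuple(DEFAULT_LAYER_NAMES)
    n_categories: int = 6

    def __post_init__(self) -> None:
        names = set(self.layer_names)
        missing = [d for d in self.driver_names if d not in names]
        if missing:
            raise ValueError(f"driver layers not in registry: {missing}")
        if len(self.driver_names) != len(self.coefficients):
            raise ValueError("one coefficient per driver required")
        if not 0.0 < self.forest_cover_target < 1.0:
            raise ValueError("forest_cover_target must be in (0, 1)")
        for s, d, r in self.collinear_pairs:
            if s not in names or d not in names:
                raise ValueError(f"collinear pair ({s}, {d}) references unknown layer")
            if not 0.8 <= abs(r) < 1.0:
                raise ValueError(f"collinear pair target |r|={r} must be in [0.8, 1)")

    def scenarios(self) -> List[ScenarioSpec]:
        """All configured future scenarios as ScenarioSpec objects."""
        out = []
        for label, deltas in self.scenario_deltas.items():
            sid, _, period = label.partition(",")
            out.append(ScenarioSpec(sid, period or "none", dict(deltas)))
        return out


def _smooth_field(rng: np.random.Generator, spec: GridSpec, length: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise with the given correlation length."""
    z = rng.standard_normal(spec.shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="reflect")
    z -= z.mean()
    sd = z.std()
    if sd > 0:
        z /= sd
    return z


def _exact_correlate(source: np.ndarray, noise: np.ndarray, r: float) -> np.ndarray:
    """Field whose *sample* Pearson correlation with ``source`` is exactly r.

    The noise field is residualized against the source and both parts are
    standardized before mixing, so the sample correlation is r by
    construction, not merely in expectation.
    """
    s = (source - source.mean()) / source.std()
    e = noise - noise.mean()
    e = e - (e.ravel() @ s.ravel()) / (s.ravel() @ s.ravel()) * s
    sd = e.std()
    if sd == 0:
        raise ValueError("degenerate noise field for collinear layer")
    e /= sd
    return r * s + np.sqrt(1.0 - r * r) * e


# Per-family (mean, sd) used to place synthetic layers on plausible scales.
_FAMILY_SCALE = {
    "BIO_T": (15.0, 6.0),     # temperature-like, °C
    "BIO_P": (1100.0, 400.0), # precipitation-like, mm
    "TERRAIN": (800.0, 500.0),
    "SOIL": (1.0, 0.4),
}


def _layer_scale(name: str) -> Tuple[float, float]:
    if name.startswith("BIO"):
        idx = int(name[3:])
        return _FAMILY_SCALE["BIO_T"] if idx <= 11 else _FAMILY_SCALE["BIO_P"]
    if name in _TERRAIN:
        return _FAMILY_SCALE["TERRAIN"]
    return _FAMILY_SCALE["SOIL"]


def generate_env_stack(truth: SyntheticTruth, spec: GridSpec) -> EnvStack:
    """Generate the full predictor stack.

    Continuous layers are Gaussian-smoothed white noise (correlation length
    ``truth.autocorr_length`` cells) rescaled to a per-family plausible
    mean/sd. Each configured collinear pair rebuilds the derived layer from
    the source so their sample |r| equals the target exactly. Categorical
    layers (landform, soil texture) are quantile bins of a smoothed field.
    """
    rng = np.random.default_rng(truth.seed)
    derived_of = {d: (s, r) for s, d, r in truth.collinear_pairs}
    stack = EnvStack(spec)
    raw: Dict[str, np.ndarray] = {}
    # First pass: independent standardized fields for every layer.
    for name in truth.layer_names:
        raw[name] = _smooth_field(rng, spec, truth.autocorr_length)
    # Second pass: overwrite derived members of collinear pairs.
    for name in truth.layer_names:
        if name in derived_of:
            source, r = derived_of[name]
            raw[name] = _exact_correlate(raw[source], raw[name], r)
    for name in truth.layer_names:
        z = raw[name]
        if name in CATEGORICAL_LAYERS:
            # quantile-bin into a small label set
            edges = np.quantile(z, np.linspace(0, 1, truth.n_categories + 1)[1:-1])
            values = np.digitize(z, edges).astype(float)
            stack.add(name, RasterGrid(spec, values, kind="categorical"), layer_class_of(name))
        else:
            mean, sd = _layer_scale(name)
            stack.add(name, RasterGrid(spec, mean + sd * z), layer_class_of(name))
    return stack


def compute_true_suitability(stack: EnvStack, truth: SyntheticTruth) -> RasterGrid:
    """Cellwise logistic suitability from the configured drivers.

    eta = intercept + sum_j coef_j * standardized(driver_j); p = 1/(1+e^-eta).
    """
    eta = np.full(stack.spec.shape, float(truth.intercept))
    for name, coef in zip(truth.driver_names, truth.coefficients):
        if name not in stack:
            raise KeyError(f"driver layer {name!r} missing from stack")
        v = stack[name].values
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta = eta + coef * z
    p = 1.0 / (1.0 + np.exp(-eta))
    return RasterGrid(stack.spec, p)


def sample_presences(suitability: RasterGrid, n: int, seed: int) -> OccurrenceSet:
    """Draw n presence points at cell centers, P(cell) ∝ suitability."""
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.where(suitability.valid, suitability.values, 0.0).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability surface has no support (all zero)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, replace=True, p=w / total)
    rows, cols = np.unravel_index(idx, suitability.spec.shape)
    spec = suitability.spec
    xs = spec.origin_x + (cols + 0.5) * spec.cell_size
    ys = spec.origin_y + (rows + 0.5) * spec.cell_size
    records = [
        OccurrenceRecord(float(x), float(y), 1, "synthetic") for x, y in zip(xs, ys)
    ]
    return OccurrenceSet(records)


def generate_forest_mask(
    suitability: RasterGrid, truth: SyntheticTruth, seed: int
) -> RasterGrid:
    """Binary forest mask with cover ~= forest_cover_target, biased toward
    high-suitability cells so overlay analyses have signal."""
    rng = np.random.default_rng(seed)
    noise = _smooth_field(rng, suitability.spec, truth.autocorr_length)
    s = suitability.values
    sd = s.std()
    s_std = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    score = s_std + 0.6 * noise
    # threshold at the (1 - target) quantile -> cover fraction exact up to ties
    thr = np.quantile(score, 1.0 - truth.forest_cover_target)
    mask = (score >= thr).astype(float)
    return RasterGrid(suitability.spec, mask, suitability.nodata_mask.copy(), kind="binary")


def apply_scenario_deltas(stack: EnvStack, scenario: ScenarioSpec) -> EnvStack:
    """Additively shift the listed climate layers; all others bit-identical."""
    for name in scenario.deltas:
        if name not in stack:
            raise KeyError(f"delta references unknown layer {name!r}")
        if stack.layer_class(name) != "climate":
            raise ValueError(f"delta on non-climate layer {name!r}")
    out = EnvStack(stack.spec)
    for name in stack:
        grid = stack[name]
        if name in scenario.deltas:
            shifted = RasterGrid(
                grid.spec,
                grid.values + scenario.deltas[name],
                grid.nodata_mask.copy(),
                grid.kind,
            )
            out.add(name, shifted, stack.layer_class(name))
        else:
            out.add(name, grid.copy(), stack.layer_class(name))
    return out


def partition_regions(spec: GridSpec, k: int, seed: int) -> List[RegionMask]:
    """Partition the domain into k disjoint contiguous regions.

    k = 4 uses a quadrant split with seeded jitter of the two split lines
    (mirroring a four-region study layout); other k use jittered vertical
    strips. Masks are pairwise disjoint and cover the domain.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > spec.n_cells:
        raise ValueError(f"cannot partition {spec.n_cells} cells into {k} regions")
    rng = np.random.default_rng(seed)
    labels = np.zeros(spec.shape, dtype=int)
    if k == 4 and spec.n_rows >= 2 and spec.n_cols >= 2:
        jit = lambda n: int(np.clip(round(n / 2 + rng.normal(0, n / 10)), 1, n - 1))
        r_split, c_split = jit(spec.n_rows), jit(spec.n_cols)
        labels[r_split:, :c_split] = 1
        labels[:r_split, c_split:] = 2
        labels[r_split:, c_split:] = 3
    else:
        base = np.linspace(0, spec.n_cols, k + 1)
        cuts = [0]
        for b in base[1:-1]:
            lo, hi = cuts[-1] + 1, spec.n_cols - (k - len(cuts))
            cuts.append(int(np.clip(round(b + rng.normal(0, spec.n_cols / (6 * k))), lo, hi)))
        cuts.append(spec.n_cols)
        for i in range(k):
            labels[:, cuts[i] : cuts[i + 1]] = i
    regions = []
    for i in range(k):
        mask = (labels == i).astype(float)
        regions.append(RegionMask(f"region_{i + 1}", RasterGrid(spec, mask, kind="binary")))
    return regions
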