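"""Lattice containers shared by every pipeline stage.

All rasters in a run live on a single :class:`GridSpec` — a regular,
axis-aligned lattice in planar map units with the origin at the lower-left
corner (row 0 is the southernmost row). Geometry is deliberately minimal:
co-registration is an input contract, not something this package performs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Literal, Mapping, Tuple

import numpy as np

LayerKind = Literal["continuous", "categorical", "binary"]
LayerClass = Literal["climate", "topographic", "soil"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster lattice.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; must be >= 1.
    origin_x, origin_y
        Map coordinates of the lower-left corner of the lower-left cell.
    cell_size
        Cell edge length in map units (nominally 1 km).
    crs_tag
        Free-text tag describing the coordinate frame. ``"planar"`` (the
        default) means Euclidean map units; a tag containing ``"wgs84"``
        signals geographic degrees to distance-aware consumers.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_tag: str = "planar"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays of grid shape."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y).

        Points outside the lattice get index -1 in the offending axis.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.origin_y) / self.cell_size).astype(int)
        col = np.where((col >= 0) & (col < self.n_cols), col, -1)
        row = np.where((row >= 0) & (row < self.n_rows), row, -1)
        return row, col


@dataclass
class RasterGrid:
    """One raster layer: values + nodata mask on a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    kind: LayerKind = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value lattice shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.spec.shape:
                raise ValueError("nodata mask shape mismatch")
        if self.kind == "binary":
            valid = self.values[~self.nodata_mask]
            if valid.size and not np.isin(valid, (0, 1)).all():
                raise ValueError("binary grid contains values outside {0, 1}")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.spec, self.values.copy(), self.nodata_mask.copy(), self.kind)


class EnvStack:
    """Ordered, named collection of co-registered raster layers.

    Each layer carries a class tag (climate / topographic / soil) mirroring
    the three habitat-factor families commonly used in suitability modelling.
    """

    def __init__(self, spec: GridSpec) -> None:
        self.spec = spec
        self._layers: Dict[str, RasterGrid] = {}
        self._classes: Dict[str, LayerClass] = {}

    def add(self, name: str, grid: RasterGrid, layer_class: LayerClass) -> None:
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if grid.spec != self.spec:
            raise ValueError(f"layer {name!r} not on the stack's grid")
        self._layers[name] = grid
        self._classes[name] = layer_class

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    def layer_class(self, name: str) -> LayerClass:
        return self._classes[name]

    @property
    def classes(self) -> Mapping[str, LayerClass]:
        return dict(self._classes)

    def copy(self) -> "EnvStack":
        out = EnvStack(self.spec)
        for name, grid in self._layers.items():
            out.add(name, grid.copy(), self._classes[name])
        return out


@dataclass
class RegionMask:
    """Binary membership mask for one analysis region."""

    region_id: str
    mask: RasterGrid

    def __post_init__(self) -> None:
        if self.mask.kind != "binary":
            raise ValueError("region mask must be a binary grid")

    @property
    def n_cells(self) -> int:
        return int(self.mask.values[self.mask.valid].sum())


def check_regions_disjoint(regions: list[RegionMask]) -> None:
    """Raise if any two region masks overlap."""
    total = None
    for reg in regions:
        m = reg.mask.values.astype(int)
        total = m if total is None else total + m
    if total is not None and (total > 1).any():
        raise ValueError("region masks overlap")
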