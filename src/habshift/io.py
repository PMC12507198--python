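"""Plain-text I/O: ESRI ASCII grids, occurrence CSV, JSON sidecars, YAML config.

Rasters are stored as single-band ESRI ASCII grids (.asc) — a widely
readable GIS text format — one file per layer, with a JSON registry
carrying layer order, class tags, kinds, and the grid geometry. Row 0 of
the in-memory lattice is the southernmost row; .asc files store rows
north-to-south, so arrays are flipped on write/read.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .grids import EnvStack, GridSpec, RasterGrid
from .occurrences import OccurrenceSet

NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path: Path | str) -> None:
    path = Path(path)
    spec = grid.spec
    values = np.where(grid.nodata_mask, NODATA, grid.values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt="%.10g")


def read_ascii_grid(
    path: Path | str, kind: str = "continuous", crs_tag: str = "planar"
) -> RasterGrid:
    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1].copy()
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        crs_tag=crs_tag,
    )
    nodata = values == header.get("nodata_value", NODATA)
    values = np.where(nodata, np.nan if kind == "continuous" else 0.0, values)
    return RasterGrid(spec, values, nodata, kind)  # type: ignore[arg-type]


def write_stack(stack: EnvStack, out_dir: Path | str, extra: Optional[dict] = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = {
        "spec": {
            "n_rows": stack.spec.n_rows,
            "n_cols": stack.spec.n_cols,
            "origin_x": stack.spec.origin_x,
            "origin_y": stack.spec.origin_y,
            "cell_size": stack.spec.cell_size,
            "crs_tag": stack.spec.crs_tag,
        },
        "layers": [
            {"name": n, "class": stack.layer_class(n), "kind": stack[n].kind}
            for n in stack
        ],
    }
    if extra:
        registry.update(extra)
    for name in stack:
        write_ascii_grid(stack[name], out_dir / f"{_safe(name)}.asc")
    with open(out_dir / "registry.json", "w") as fh:
        json.dump(registry, fh, indent=2, sort_keys=True)


def read_stack(in_dir: Path | str) -> EnvStack:
    in_dir = Path(in_dir)
    with open(in_dir / "registry.json") as fh:
        registry = json.load(fh)
    s = registry["spec"]
    spec = GridSpec(
        s["n_rows"], s["n_cols"], s["origin_x"], s["origin_y"], s["cell_size"], s["crs_tag"]
    )
    stack = EnvStack(spec)
    for entry in registry["layers"]:
        grid = read_ascii_grid(
            in_dir / f"{_safe(entry['name'])}.asc", entry["kind"], s["crs_tag"]
        )
        stack.add(entry["name"], grid, entry["class"])
    return stack


def _safe(name: str) -> str:
    return name.replace("/", "_")


def write_occurrences(occ: OccurrenceSet, path: Path | str) -> None:
    occ.to_frame().to_csv(path, index=False)


def read_occurrences(path: Path | str) -> OccurrenceSet:
    return OccurrenceSet.from_frame(pd.read_csv(path, keep_default_na=False))


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
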