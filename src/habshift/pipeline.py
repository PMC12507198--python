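"""End-to-end orchestration: simulate → prep → select → fit → map →
project → overlay → report, with a reproducibility manifest.

A single global seed drives every stage through stable per-stage derived
sub-seeds (CRC32 of the stage name mixed with the seed), so re-running the
same config and seed reproduces every artifact bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grids import GridSpec, RasterGrid, RegionMask
from .landscape import (
    ScenarioSpec,
    SyntheticTruth,
    compute_true_suitability,
    generate_env_stack,
    generate_forest_mask,
    partition_regions,
    sample_presences,
)
from .mapping import SuitabilityMap, tabulate_class_areas
from .models import (
    ALGORITHMS,
    FittedModel,
    MetricsReport,
    ModelSpec,
    compute_metrics,
    select_best_model,
    tune_and_fit,
)
from .occurrences import PrepConfig, extract_samples, generate_pseudo_absences, split_samples, thin_occurrences
from .overlay import overlap_table
from .scenarios import build_suitability_map, change_table, project_scenario
from .selection import SelectionConfig, correlation_matrix, rank_importance, resolve_collinearity
from .io import write_ascii_grid, write_occurrences, write_stack


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Full-run configuration; defaults mirror the published study settings
    at a desk-scale synthetic domain."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1.0  # km
    n_presences: int = 400
    n_regions: int = 4
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)
    prep: PrepConfig = field(default_factory=PrepConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    algorithms: Sequence[str] = ALGORITHMS
    model_grids: Mapping[str, Mapping[str, Sequence[object]]] = field(default_factory=dict)
    k_folds: int = 5
    break_policy: str = "fixed_current"
    scenarios: Optional[Sequence[str]] = None  # None -> all configured in truth
    cell_area: float = 1.0  # km² per cell
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown algorithm ids: {unknown}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "truth" in d:
            t = dict(d["truth"])
            if "collinear_pairs" in t:
                t["collinear_pairs"] = [tuple(p) for p in t["collinear_pairs"]]
            d["truth"] = SyntheticTruth(**t)
        if "prep" in d:
            d["prep"] = PrepConfig(**d["prep"])
        if "selection" in d:
            d["selection"] = SelectionConfig(**d["selection"])
        return cls(**d)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["truth"]["driver_names"] = list(out["truth"]["driver_names"])
        out["truth"]["coefficients"] = list(out["truth"]["coefficients"])
        out["truth"]["collinear_pairs"] = [list(p) for p in out["truth"]["collinear_pairs"]]
        out["truth"]["layer_names"] = list(out["truth"]["layer_names"])
        out["truth"]["scenario_deltas"] = {
            k: dict(v) for k, v in out["truth"]["scenario_deltas"].items()
        }
        out["algorithms"] = list(out["algorithms"])
        out["model_grids"] = {k: {p: list(v) for p, v in g.items()} for k, g in out["model_grids"].items()}
        out["scenarios"] = list(out["scenarios"]) if out["scenarios"] is not None else None
        return out


@dataclass
class RunResult:
    """In-memory results of one pipeline run (the manifest references the
    on-disk artifacts)."""

    config: RunConfig
    retained_variables: List[str]
    reports: List[MetricsReport]
    best_model_id: str
    best_model: FittedModel
    current_map: SuitabilityMap
    current_areas: pd.DataFrame
    scenario_maps: Dict[str, SuitabilityMap]
    scenario_areas: Dict[str, pd.DataFrame]
    change_tables: Dict[str, pd.DataFrame]
    overlap_tables: pd.DataFrame
    importance: pd.DataFrame
    regions: List[RegionMask]
    forest: RasterGrid
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: Path | str) -> RunResult:
    """Execute the full pipeline, persisting every intermediate under
    ``out_dir`` and writing ``manifest.json`` last (atomically)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}
    paths: Dict[str, str] = {}
    t0 = time.time()

    def tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0 - sum(timings.values()), 3)

    # --- simulate -----------------------------------------------------
    spec = GridSpec(config.n_rows, config.n_cols, cell_size=config.cell_size)
    truth = config.truth
    stack = generate_env_stack(truth, spec)
    true_suit = compute_true_suitability(stack, truth)
    presences_raw = sample_presences(
        true_suit, config.n_presences, stage_seed(config.seed, "presences")
    )
    forest = generate_forest_mask(true_suit, truth, stage_seed(config.seed, "forest"))
    regions = partition_regions(spec, config.n_regions, stage_seed(config.seed, "regions"))
    write_stack(stack, out / "stack", extra={"seed": config.seed})
    write_ascii_grid(true_suit, out / "true_suitability.asc")
    write_ascii_grid(forest, out / "forest.asc")
    for reg in regions:
        write_ascii_grid(reg.mask, out / f"region_{reg.region_id}.asc")
    paths["stack"] = str(out / "stack")
    tick("simulate")

    # --- prep ---------------------------------------------------------
    prep = PrepConfig(
        **{**_shallow(config.prep), "seed": stage_seed(config.seed, "prep")}
    )
    presences = thin_occurrences(presences_raw, prep.thin_cell_size)
    domain = RasterGrid(spec, np.ones(spec.shape), kind="binary")
    absences = generate_pseudo_absences(presences, domain, prep)
    occurrences = presences.combined_with(absences)
    write_occurrences(occurrences, out / "occurrences.csv")
    paths["occurrences"] = str(out / "occurrences.csv")
    samples = extract_samples(stack, occurrences)
    train, test = split_samples(samples, prep)
    tick("prep")

    # --- select -------------------------------------------------------
    sel = SelectionConfig(
        r_threshold=config.selection.r_threshold,
        seed=stage_seed(config.seed, "select"),
        n_estimators=config.selection.n_estimators,
    )
    corr = correlation_matrix(train)
    imp = rank_importance(train, sel)
    retained = resolve_collinearity(corr, imp, sel)
    corr.to_frame().to_csv(out / "correlation.csv")
    imp.to_frame().to_csv(out / "importance.csv", index=False)
    with open(out / "retained_variables.json", "w") as fh:
        json.dump(retained, fh, indent=2)
    paths["retained_variables"] = str(out / "retained_variables.json")
    train_r = train.subset_variables(retained)
    test_r = test.subset_variables(retained)
    tick("select")

    # --- train / evaluate ---------------------------------------------
    reports: List[MetricsReport] = []
    fitted: Dict[str, FittedModel] = {}
    for algo in config.algorithms:
        mspec = ModelSpec(algo, seed=stage_seed(config.seed, f"fit:{algo}"))
        model = tune_and_fit(mspec, train_r, config.model_grids.get(algo), config.k_folds)
        scores = model.score_samples(test_r)
        reports.append(compute_metrics(scores, test_r.labels, model_id=algo))
        fitted[algo] = model
    best_id = select_best_model(reports)
    metrics_df = pd.DataFrame(
        [
            {
                "model": r.model_id,
                "auc": r.auc,
                "f1": r.f1,
                "accuracy": r.accuracy,
                "precision": r.precision,
                "recall": r.recall,
            }
            for r in reports
        ]
    )
    metrics_df.to_csv(out / "metrics.csv", index=False)
    paths["metrics"] = str(out / "metrics.csv")
    best = fitted[best_id]
    tick("fit")

    # --- map (current climate) ----------------------------------------
    jenks_seed = stage_seed(config.seed, "jenks")
    current_scn = ScenarioSpec("current")
    current_map = build_suitability_map(best, stack, current_scn, seed=jenks_seed)
    current_areas = tabulate_class_areas(
        current_map.classes, regions, config.cell_area, "current"
    )
    write_ascii_grid(current_map.probability, out / "probability_current.asc")
    write_ascii_grid(current_map.classes, out / "classes_current.asc")
    tick("map")

    # --- project scenarios --------------------------------------------
    scenario_specs = truth.scenarios()
    if config.scenarios is not None:
        wanted = set(config.scenarios)
        scenario_specs = [s for s in scenario_specs if s.label in wanted]
        missing = wanted - {s.label for s in scenario_specs}
        if missing:
            raise ValueError(f"unknown scenario labels: {sorted(missing)}")
    scenario_maps: Dict[str, SuitabilityMap] = {}
    scenario_areas: Dict[str, pd.DataFrame] = {}
    changes: Dict[str, pd.DataFrame] = {}
    for scn in scenario_specs:
        smap = project_scenario(
            best, stack, scn, config.break_policy, current_map, seed=jenks_seed
        )
        scenario_maps[scn.label] = smap
        areas = tabulate_class_areas(smap.classes, regions, config.cell_area, scn.label)
        scenario_areas[scn.label] = areas
        changes[scn.label] = change_table(current_areas, areas)
        write_ascii_grid(smap.classes, out / f"classes_{_safe(scn.label)}.asc")
    all_areas = pd.concat(
        [current_areas] + list(scenario_areas.values()), ignore_index=True
    )
    all_areas.to_csv(out / "areas.csv", index=False)
    paths["areas"] = str(out / "areas.csv")
    if changes:
        pd.concat(changes.values(), ignore_index=True).to_csv(out / "changes.csv", index=False)
        paths["changes"] = str(out / "changes.csv")
    tick("project")

    # --- overlay -------------------------------------------------------
    cur_overlap = overlap_table(
        current_map.classes, forest, regions, config.cell_area, None, "current"
    )
    overlaps = [cur_overlap]
    for label, smap in scenario_maps.items():
        overlaps.append(
            overlap_table(smap.classes, forest, regions, config.cell_area, cur_overlap, label)
        )
    overlap_df = pd.concat(overlaps, ignore_index=True)
    overlap_df.to_csv(out / "overlap.csv", index=False)
    paths["overlap"] = str(out / "overlap.csv")
    tick("overlay")

    # --- report + manifest ---------------------------------------------
    _write_summary(out / "summary.txt", metrics_df, best_id, retained, all_areas, overlap_df)
    paths["summary"] = str(out / "summary.txt")
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"habshift": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stage_timings_s": timings,
        "outputs": paths,
        "checksums": checksums,
        "best_model": best_id,
        "retained_variables": retained,
        "n_presences": len(presences),
        "n_absences": len(absences),
        "n_samples": samples.n,
    }
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tmp.replace(out / "manifest.json")
    tick("report")

    return RunResult(
        config=config,
        retained_variables=retained,
        reports=reports,
        best_model_id=best_id,
        best_model=best,
        current_map=current_map,
        current_areas=current_areas,
        scenario_maps=scenario_maps,
        scenario_areas=scenario_areas,
        change_tables=changes,
        overlap_tables=overlap_df,
        importance=imp.to_frame(),
        regions=regions,
        forest=forest,
        manifest=manifest,
    )


def _shallow(cfg: PrepConfig) -> dict:
    return {
        "thin_cell_size": cfg.thin_cell_size,
        "min_absence_distance": cfg.min_absence_distance,
        "absence_ratio": cfg.absence_ratio,
        "train_fraction": cfg.train_fraction,
        "stratified": cfg.stratified,
        "metric": cfg.metric,
    }


def _safe(label: str) -> str:
    return label.replace(",", "_").replace(".", "-")


def _write_summary(
    path: Path,
    metrics: pd.DataFrame,
    best_id: str,
    retained: List[str],
    areas: pd.DataFrame,
    overlaps: pd.DataFrame,
) -> None:
    lines = []
    lines.append("habitat-suitability pipeline summary")
    lines.append("")
    lines.append(f"retained variables ({len(retained)}): {', '.join(retained)}")
    lines.append("")
    lines.append("model metrics (held-out test set):")
    lines.append(metrics.round(4).to_string(index=False))
    lines.append("")
    lines.append(f"best model: {best_id}")
    lines.append("")
    lines.append("class areas by region and scenario:")
    lines.append(areas.to_string(index=False))
    lines.append("")
    lines.append("forest overlap by region and scenario:")
    lines.append(overlaps.to_string(index=False))
    path.write_text("\n".join(lines) + "\n")
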