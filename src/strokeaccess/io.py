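"""Delimited-text readers/writers, run configuration and pipeline orchestration.

All entity tables travel as plain CSV with fixed headers (see the schema
constants in :mod:`strokeaccess.instance`); travel times are long-form triplets
with only in-catchment pairs required.  ``run_pipeline`` chains the full
analysis — generate or read an instance, compute the accessibility and
crowdedness surfaces, solve the reallocation QP, re-evaluate both surfaces
under the optimized staffing, summarize, aggregate by region, optionally sweep
the decay coefficient — and writes every output table plus a machine-readable
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .access import (
    DEFAULT_SCALE,
    DecayConfig,
    accessibility_surface,
    conservation_residuals,
    crowdedness_surface,
)
from .allocate import DEFAULT_RIDGE, DEFAULT_UPPER_BOUND, build_problem, solve_allocation
from .instance import (
    Instance,
    SchemaError,
    TravelTimeMatrix,
    validate_facilities,
    validate_meshes,
    validate_regions,
)
from .report import (
    DEFAULT_BETAS,
    DEFAULT_STAFFED_THRESHOLD,
    aggregate_by_region,
    beta_sweep,
    classify_urbanicity,
    summarize_access,
    summarize_crowdedness,
)
from .synthetic import GeneratorParams, generate_instance

logger = logging.getLogger(__name__)

MESHES_FILE = "meshes.csv"
FACILITIES_FILE = "facilities.csv"
TRAVEL_FILE = "travel_times.csv"
REGIONS_FILE = "regions.csv"


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    Defaults are the study settings: decay coefficient 0.07/min, catchment
    120 min, per-facility cap 5, staffed threshold 0.01, sweep over beta
    0.07..0.02.
    """

    beta: float = 0.07
    threshold_minutes: float = 120.0
    scale: float = DEFAULT_SCALE
    upper_bound: float = DEFAULT_UPPER_BOUND
    staffed_threshold: float = DEFAULT_STAFFED_THRESHOLD
    betas_for_sweep: tuple = DEFAULT_BETAS
    ridge: float = DEFAULT_RIDGE
    seed: int = 0
    generator: dict | None = None
    input_dir: str | None = None
    output_dir: str = "results"
    run_sweep: bool = False
    write_geojson: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML (or JSON) mapping; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "betas_for_sweep" in data:
            data["betas_for_sweep"] = tuple(data["betas_for_sweep"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas_for_sweep"] = list(self.betas_for_sweep)
        return d

    def decay(self, beta: float | None = None) -> DecayConfig:
        return DecayConfig(
            beta=self.beta if beta is None else beta,
            threshold_minutes=self.threshold_minutes,
        )


def read_instance(
    input_dir: str | Path, threshold_minutes: float = 120.0
) -> tuple[Instance, int]:
    """Read the four entity tables; returns (instance, dropped travel rows).

    Travel-time rows at or beyond the catchment threshold are dropped with a
    logged count — the kernel is structurally zero there.
    """
    input_dir = Path(input_dir)
    meshes = validate_meshes(pd.read_csv(input_dir / MESHES_FILE))
    facilities = validate_facilities(pd.read_csv(input_dir / FACILITIES_FILE))
    travel = pd.read_csv(input_dir / TRAVEL_FILE)
    for col in ("mesh_id", "facility_id", "minutes"):
        if col not in travel.columns:
            raise SchemaError(f"travel_times table is missing column {col!r}")
    bad = np.flatnonzero(travel["minutes"].to_numpy(dtype=float) < 0)
    if bad.size:
        raise SchemaError(f"travel time is negative at row {bad[0]}")
    in_range = travel["minutes"].to_numpy(dtype=float) < threshold_minutes
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info(
            "dropped %d travel-time rows at >= %g minutes", n_dropped, threshold_minutes
        )
    ttm = TravelTimeMatrix.from_frame(travel[in_range], threshold_minutes)
    regions_path = input_dir / REGIONS_FILE
    if regions_path.exists():
        regions = validate_regions(pd.read_csv(regions_path))
    else:
        regions = pd.DataFrame({"region_id": [], "urban_proportion": []})
    return Instance(meshes, facilities, ttm, regions), n_dropped


def write_instance(instance: Instance, output_dir: str | Path) -> None:
    """Write the four entity tables as CSV."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    instance.meshes.to_csv(output_dir / MESHES_FILE, index=False)
    instance.facilities.to_csv(output_dir / FACILITIES_FILE, index=False)
    instance.travel_times.to_frame().to_csv(output_dir / TRAVEL_FILE, index=False)
    instance.regions.to_csv(output_dir / REGIONS_FILE, index=False)


def write_points_geojson(
    df: pd.DataFrame, id_column: str, path: str | Path, crs_note: str = "planar-km"
) -> None:
    """Write a point layer as GeoJSON; coordinates are taken from x/y columns."""
    features = []
    prop_cols = [c for c in df.columns if c not in ("x", "y")]
    for _, row in df.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": {c: _jsonable(row[c]) for c in prop_cols},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"coordinate_system": crs_note, "id_column": id_column},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


@dataclass
class PipelineResult:
    """Everything one run produced, plus the manifest written to disk."""

    instance: Instance
    optimized: Instance
    access_current: object
    access_optimized: object
    crowd_current: object
    crowd_optimized: object
    solution: object
    summary_access: pd.DataFrame
    summary_crowdedness: pd.DataFrame
    region_summary: pd.DataFrame
    manifest: dict
    sweep: object = None


def _obtain_instance(config: RunConfig) -> tuple[Instance, int]:
    if config.input_dir is not None:
        return read_instance(config.input_dir, config.threshold_minutes)
    gen = dict(config.generator or {})
    gen.setdefault("seed", config.seed)
    gen.setdefault("threshold_minutes", config.threshold_minutes)
    return generate_instance(GeneratorParams(**gen)), 0


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config`` and write all tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    instance, n_dropped = _obtain_instance(config)
    write_instance(instance, out)

    decay = config.decay()
    acc_cur = accessibility_surface(
        instance.meshes, instance.facilities, instance.travel_times, decay, config.scale
    )
    crw_cur = crowdedness_surface(
        instance.meshes, instance.facilities, instance.travel_times, decay
    )

    problem = build_problem(
        instance.meshes,
        instance.facilities,
        instance.travel_times,
        decay,
        upper_bound=config.upper_bound,
        ridge=config.ridge,
    )
    solution = solve_allocation(problem)
    optimized = instance.with_staff(solution.staff)

    acc_opt = accessibility_surface(
        optimized.meshes, optimized.facilities, optimized.travel_times, decay, config.scale
    )
    crw_opt = crowdedness_surface(
        optimized.meshes, optimized.facilities, optimized.travel_times, decay
    )

    summary_access = pd.DataFrame(
        [
            summarize_access(acc_cur, instance.meshes, "current").as_dict(),
            summarize_access(acc_opt, optimized.meshes, "optimized").as_dict(),
        ]
    )
    summary_crowd = pd.DataFrame(
        [
            summarize_crowdedness(
                crw_cur, instance.facilities, config.staffed_threshold, "current"
            ).as_dict(),
            summarize_crowdedness(
                crw_opt, optimized.facilities, config.staffed_threshold, "optimized"
            ).as_dict(),
        ]
    )

    regions = classify_urbanicity(instance.regions) if len(instance.regions) else instance.regions
    if len(regions):
        region_summary = aggregate_by_region(
            instance.facilities,
            crw_cur.crowdedness,
            crw_opt.crowdedness,
            instance.facilities["staff"].to_numpy(dtype=float),
            solution.staff,
            regions,
        )
    else:
        region_summary = pd.DataFrame()

    sweep = None
    if config.run_sweep:
        sweep = beta_sweep(
            instance,
            betas=config.betas_for_sweep,
            threshold_minutes=config.threshold_minutes,
            scale=config.scale,
            upper_bound=config.upper_bound,
            staffed_threshold=config.staffed_threshold,
            ridge=config.ridge,
        )

    res_cur = conservation_residuals(instance.meshes, instance.facilities, acc_cur, crw_cur)
    res_opt = conservation_residuals(optimized.meshes, optimized.facilities, acc_opt, crw_opt)
    manifest = {
        "config": config.to_dict(),
        "n_meshes": int(len(instance.meshes)),
        "n_facilities": int(len(instance.facilities)),
        "n_travel_pairs": int(len(instance.travel_times)),
        "n_dropped_travel_rows": n_dropped,
        "total_demand": instance.total_demand,
        "total_staff_current": instance.total_staff,
        "total_staff_optimized": float(solution.staff.sum()),
        "uncovered_meshes": int(len(acc_cur.uncovered_mesh_ids)),
        "unserved_meshes": int(len(crw_cur.unserved_mesh_ids)),
        "unserved_population": crw_cur.unserved_population,
        "empty_catchment_facilities": int(problem.empty_catchment.sum()),
        "conservation_current": res_cur,
        "conservation_optimized": res_opt,
        "objective_current": solution.objective_current,
        "objective_optimized": solution.objective_optimized,
        "kkt": dataclasses.asdict(solution.kkt),
        "solver_status": solution.solver_status,
        "rank_deficient": solution.rank_deficient,
    }

    # output tables
    access_table = pd.DataFrame(
        {
            "mesh_id": acc_cur.mesh_ids,
            "access_current": acc_cur.access,
            "access_optimized": acc_opt.access,
        }
    )
    access_table.to_csv(out / "access_meshes.csv", index=False)
    facility_table = pd.DataFrame(
        {
            "facility_id": instance.facilities["facility_id"],
            "region_id": instance.facilities["region_id"],
            "current_staff": instance.facilities["staff"].to_numpy(dtype=float),
            "optimized_staff": solution.staff,
            "delta": solution.staff - instance.facilities["staff"].to_numpy(dtype=float),
            "pci_current": crw_cur.crowdedness,
            "pci_optimized": crw_opt.crowdedness,
        }
    )
    facility_table.to_csv(out / "facility_results.csv", index=False)
    summary_access.to_csv(out / "summary_access.csv", index=False)
    summary_crowd.to_csv(out / "summary_crowdedness.csv", index=False)
    if len(region_summary):
        region_summary.to_csv(out / "region_summary.csv", index=False)
    if sweep is not None:
        sweep.access.to_csv(out / "sweep_access.csv", index=False)
        sweep.crowdedness.to_csv(out / "sweep_crowdedness.csv", index=False)
    if config.write_geojson:
        write_points_geojson(instance.meshes, "mesh_id", out / "meshes.geojson")
        write_points_geojson(instance.facilities, "facility_id", out / "facilities.geojson")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        instance=instance,
        optimized=optimized,
        access_current=acc_cur,
        access_optimized=acc_opt,
        crowd_current=crw_cur,
        crowd_optimized=crw_opt,
        solution=solution,
        summary_access=summary_access,
        summary_crowdedness=summary_crowd,
        region_summary=region_summary,
        manifest=manifest,
        sweep=sweep,
    )
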