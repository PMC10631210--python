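"""Disparity summaries, the decay-coefficient sensitivity sweep, and regional
aggregation with urbanicity classes.

Accessibility is summarized demand-weighted (each mesh counts in proportion to
its population aged >= 65), matching the weighting of the reallocation
objective; crowdedness is summarized unweighted over staffed facilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .access import (
    DEFAULT_SCALE,
    AccessSurface,
    CrowdednessSurface,
    DecayConfig,
    accessibility_surface,
    crowdedness_surface,
)
from .allocate import DEFAULT_RIDGE, DEFAULT_UPPER_BOUND, AllocationSolution, build_problem, solve_allocation
from .instance import Instance

logger = logging.getLogger(__name__)

DEFAULT_BETAS = (0.07, 0.06, 0.05, 0.04, 0.03, 0.02)
DEFAULT_STAFFED_THRESHOLD = 0.01


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest v with cumulative weight(<= v) >= W/2."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, 0.5 * total, side="left"))
    return float(v[order][idx])


def weighted_sd(values, weights) -> float:
    """Weighted population standard deviation sqrt(sum w (v - vbar)^2 / sum w)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_sd of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    mean = float(w @ v) / total
    return float(np.sqrt(w @ (v - mean) ** 2 / total))


@dataclass
class AccessSummary:
    """Demand-weighted location/dispersion of the accessibility index."""

    weighted_median: float
    weighted_sd: float
    min: float
    max: float
    beta: float
    scenario: str

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "scenario": self.scenario,
            "weighted_median": self.weighted_median,
            "weighted_sd": self.weighted_sd,
            "min": self.min,
            "max": self.max,
        }


@dataclass
class CrowdednessSummary:
    """Unweighted crowdedness statistics over staffed facilities."""

    mean: float
    sd: float
    min: float
    max: float
    staffed_count: int
    beta: float
    scenario: str

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "scenario": self.scenario,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "staffed_count": self.staffed_count,
        }


def summarize_access(
    surface: AccessSurface,
    meshes: pd.DataFrame,
    scenario: str = "current",
) -> AccessSummary:
    """Demand-weighted median and SD of A_i plus the unweighted range.

    The range spans all meshes including uncovered ones, so a zero minimum
    signals meshes beyond every catchment.
    """
    weights = meshes["population"].to_numpy(dtype=float)
    return AccessSummary(
        weighted_median=weighted_median(surface.access, weights),
        weighted_sd=weighted_sd(surface.access, weights),
        min=float(surface.access.min()),
        max=float(surface.access.max()),
        beta=surface.beta,
        scenario=scenario,
    )


def summarize_crowdedness(
    surface: CrowdednessSurface,
    facilities: pd.DataFrame,
    staffed_threshold: float = DEFAULT_STAFFED_THRESHOLD,
    scenario: str = "current",
) -> CrowdednessSummary:
    """Mean/SD/range of C_j over facilities with staff >= threshold.

    Fractional optimized allocations make a hard "has staff" notion ambiguous;
    the threshold (default 0.01 physicians) draws that line.
    """
    staff = facilities["staff"].to_numpy(dtype=float)
    staffed = staff >= staffed_threshold
    c = surface.crowdedness[staffed]
    if c.size == 0:
        logger.warning("no facility meets the staffed threshold %g", staffed_threshold)
        return CrowdednessSummary(np.nan, np.nan, np.nan, np.nan, 0, surface.beta, scenario)
    return CrowdednessSummary(
        mean=float(c.mean()),
        sd=float(c.std()),
        min=float(c.min()),
        max=float(c.max()),
        staffed_count=int(staffed.sum()),
        beta=surface.beta,
        scenario=scenario,
    )


@dataclass
class SweepResult:
    """Per-beta, per-scenario summary tables from the sensitivity sweep."""

    access: pd.DataFrame
    crowdedness: pd.DataFrame
    solutions: dict = field(default_factory=dict)


def beta_sweep(
    instance: Instance,
    betas=DEFAULT_BETAS,
    threshold_minutes: float = 120.0,
    scale: float = DEFAULT_SCALE,
    upper_bound: float = DEFAULT_UPPER_BOUND,
    staffed_threshold: float = DEFAULT_STAFFED_THRESHOLD,
    ridge: float = DEFAULT_RIDGE,
) -> SweepResult:
    """Recompute surfaces and re-solve the reallocation QP for each beta.

    Lowering beta flattens the decay kernel, widening the effective catchments;
    the sweep shows how much of the disparity reduction survives that change.
    """
    if any(b <= 0 for b in betas):
        raise ValueError("betas must be positive")
    access_rows, crowd_rows, solutions = [], [], {}
    for beta in betas:
        config = DecayConfig(beta=beta, threshold_minutes=threshold_minutes)
        problem = build_problem(
            instance.meshes, instance.facilities, instance.travel_times, config,
            upper_bound=upper_bound, ridge=ridge,
        )
        solution = solve_allocation(problem)
        solutions[beta] = solution
        optimized = instance.with_staff(solution.staff)
        for scenario, inst in (("current", instance), ("optimized", optimized)):
            surf_a = accessibility_surface(
                inst.meshes, inst.facilities, inst.travel_times, config, scale
            )
            surf_c = crowdedness_surface(
                inst.meshes, inst.facilities, inst.travel_times, config
            )
            access_rows.append(summarize_access(surf_a, inst.meshes, scenario).as_dict())
            crowd_rows.append(
                summarize_crowdedness(
                    surf_c, inst.facilities, staffed_threshold, scenario
                ).as_dict()
            )
    return SweepResult(
        access=pd.DataFrame(access_rows),
        crowdedness=pd.DataFrame(crowd_rows),
        solutions=solutions,
    )


def classify_urbanicity(regions: pd.DataFrame) -> pd.DataFrame:
    """Assign high/medium/low urbanicity by urban-population proportion.

    The top quarter of regions (floor(n/4)) is classed high, the bottom quarter
    low, the rest medium.  Ties are broken by region_id order so the split is
    deterministic.  With fewer than four regions the split is degenerate and
    every region is classed medium (with a warning).
    """
    out = regions.copy()
    n = len(out)
    if n < 4:
        logger.warning("fewer than 4 regions; urbanicity split is degenerate, all medium")
        out["urbanicity_class"] = "medium"
        return out
    k = n // 4
    order = out.sort_values(
        ["urban_proportion", "region_id"], ascending=[False, True], kind="stable"
    ).index
    classes = pd.Series("medium", index=out.index)
    classes.loc[order[:k]] = "high"
    rest = [i for i in order[k:]]
    low_order = (
        out.loc[rest]
        .sort_values(["urban_proportion", "region_id"], ascending=[True, True], kind="stable")
        .index
    )
    classes.loc[low_order[:k]] = "low"
    out["urbanicity_class"] = classes
    return out


def aggregate_by_region(
    facilities: pd.DataFrame,
    pci_current: np.ndarray,
    pci_optimized: np.ndarray,
    staff_current: np.ndarray,
    staff_optimized: np.ndarray,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region mean crowdedness and staffing totals, current vs optimized.

    Regional mean crowdedness is unweighted over the region's facilities.
    Regions without facilities keep NaN crowdedness and zero staff.
    """
    known = set(regions["region_id"])
    unknown = set(facilities["region_id"]) - known
    if unknown:
        raise ValueError(f"facilities reference unknown region_id(s): {sorted(unknown)[:5]}")
    df = pd.DataFrame(
        {
            "region_id": facilities["region_id"].to_numpy(),
            "pci_current": np.asarray(pci_current, dtype=float),
            "pci_optimized": np.asarray(pci_optimized, dtype=float),
            "staff_current": np.asarray(staff_current, dtype=float),
            "staff_optimized": np.asarray(staff_optimized, dtype=float),
        }
    )
    grouped = df.groupby("region_id")
    agg = pd.DataFrame(
        {
            "mean_pci_current": grouped["pci_current"].mean(),
            "mean_pci_optimized": grouped["pci_optimized"].mean(),
            "staff_current": grouped["staff_current"].sum(),
            "staff_optimized": grouped["staff_optimized"].sum(),
        }
    )
    out = regions.set_index("region_id").join(agg, how="left")
    out["staff_current"] = out["staff_current"].fillna(0.0)
    out["staff_optimized"] = out["staff_optimized"].fillna(0.0)
    out["delta_pci"] = out["mean_pci_optimized"] - out["mean_pci_current"]
    out["delta_staff"] = out["staff_optimized"] - out["staff_current"]
    return out.reset_index()
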