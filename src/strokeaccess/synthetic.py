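"""Synthetic study-region generator.

The real analysis runs on proprietary inputs: a national census mesh of the
population aged >= 65, certified stroke-center addresses, and a commercial road
network.  This module generates instances with the same statistical structure —
spatially clustered heavy-tailed demand, facilities placed preferentially where
demand is, travel times thresholded at the catchment bound, and a fixed
national staffing total — so every downstream stage is testable end to end.

Travel times are planar Euclidean distances divided by a fixed speed
(default 0.75 km/min, about 45 km/h of effective door-to-door car travel);
road topology is deliberately out of scope, since the catchment computations
only consume a minutes matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .instance import Instance, TravelTimeMatrix

#: National counts: facilities and specialists at the September 2021 census of
#: certified stroke centers.
JAPAN_N_FACILITIES = 662
JAPAN_TOTAL_STAFF = 1605
JAPAN_N_REGIONS = 47


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one synthetic study region.

    The defaults describe a country-scale instance at reduced mesh resolution:
    each synthetic mesh stands for a coarser demand cell than a 500 m census
    mesh, so per-mesh populations are drawn with a higher log-mean than a raw
    census cell would have.
    """

    n_meshes: int = 5000
    n_facilities: int = JAPAN_N_FACILITIES
    n_regions: int = JAPAN_N_REGIONS
    n_urban_centers: int = 40
    total_staff: int = JAPAN_TOTAL_STAFF
    staff_cap: int = 5
    mean_log_population: float = 5.0
    sd_log_population: float = 1.2
    cluster_sd_km: float = 15.0
    facility_demand_affinity: float = 1.0
    travel_speed_km_per_min: float = 0.75
    seed: int = 0
    domain_km: float = 600.0
    threshold_minutes: float = 120.0
    facility_jitter_km: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_meshes", "n_facilities", "n_regions", "n_urban_centers",
                     "total_staff", "staff_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("travel_speed_km_per_min", "cluster_sd_km", "domain_km",
                     "threshold_minutes", "sd_log_population"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.total_staff > self.n_facilities * self.staff_cap:
            raise ValueError(
                f"infeasible staff distribution: total_staff={self.total_staff} exceeds "
                f"n_facilities*staff_cap={self.n_facilities * self.staff_cap}"
            )
        if self.seed is None:
            raise ValueError("seed is required")


def _distribute_staff(rng: np.random.Generator, n_facilities: int, total: int, cap: int) -> np.ndarray:
    """Integer staffing by repeated unit increments under the per-facility cap."""
    staff = np.zeros(n_facilities, dtype=int)
    for _ in range(total):
        open_slots = np.flatnonzero(staff < cap)
        staff[open_slots[rng.integers(len(open_slots))]] += 1
    return staff


def generate_instance(params: GeneratorParams) -> Instance:
    """Generate one synthetic instance; identical params + seed give identical output.

    Mesh locations cluster normally around urban centers of heavy-tailed size;
    mesh populations are log-normal; facilities are placed at mesh locations
    sampled with probability proportional to demand raised to the affinity
    exponent; regions are the Voronoi cells of random seed points; and each
    region's urban-population proportion is the share of its population lying
    within one cluster radius of an urban center.
    """
    rng = np.random.default_rng(params.seed)
    L = params.domain_km

    region_seeds = rng.uniform(0.0, L, size=(params.n_regions, 2))
    centers = rng.uniform(0.0, L, size=(params.n_urban_centers, 2))
    center_weight = rng.lognormal(0.0, 1.0, size=params.n_urban_centers)
    center_weight /= center_weight.sum()

    assignment = rng.choice(params.n_urban_centers, size=params.n_meshes, p=center_weight)
    mesh_xy = centers[assignment] + rng.normal(0.0, params.cluster_sd_km, size=(params.n_meshes, 2))
    population = np.maximum(
        1,
        np.rint(
            rng.lognormal(params.mean_log_population, params.sd_log_population, params.n_meshes)
        ).astype(int),
    )

    pick_p = population.astype(float) ** params.facility_demand_affinity
    pick_p /= pick_p.sum()
    replace_pick = params.n_facilities > params.n_meshes
    host = rng.choice(params.n_meshes, size=params.n_facilities, p=pick_p, replace=replace_pick)
    fac_xy = mesh_xy[host] + rng.normal(0.0, params.facility_jitter_km, size=(params.n_facilities, 2))

    staff = _distribute_staff(rng, params.n_facilities, params.total_staff, params.staff_cap)

    def nearest_region(xy: np.ndarray) -> np.ndarray:
        d2 = ((xy[:, None, :] - region_seeds[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    mesh_region = nearest_region(mesh_xy)
    fac_region = nearest_region(fac_xy)

    region_ids = np.array([f"r{i:02d}" for i in range(params.n_regions)])
    mesh_ids = np.array([f"m{i:06d}" for i in range(params.n_meshes)])
    fac_ids = np.array([f"f{i:04d}" for i in range(params.n_facilities)])

    meshes = pd.DataFrame(
        {
            "mesh_id": mesh_ids,
            "x": mesh_xy[:, 0],
            "y": mesh_xy[:, 1],
            "population": population,
            "region_id": region_ids[mesh_region],
        }
    )
    facilities = pd.DataFrame(
        {
            "facility_id": fac_ids,
            "x": fac_xy[:, 0],
            "y": fac_xy[:, 1],
            "staff": staff,
            "region_id": region_ids[fac_region],
        }
    )

    # travel times: Euclidean km / speed, stored only inside the catchment
    diff_x = mesh_xy[:, 0][:, None] - fac_xy[:, 0][None, :]
    diff_y = mesh_xy[:, 1][:, None] - fac_xy[:, 1][None, :]
    minutes = np.hypot(diff_x, diff_y) / params.travel_speed_km_per_min
    rows, cols = np.nonzero(minutes < params.threshold_minutes)
    ttm = TravelTimeMatrix(
        mesh_ids=mesh_ids[rows],
        facility_ids=fac_ids[cols],
        minutes=minutes[rows, cols],
        threshold_minutes=params.threshold_minutes,
    )

    # urban proportion: population share within one cluster radius of a center
    d2_center = ((mesh_xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    urban_mesh = d2_center.min(axis=1) <= params.cluster_sd_km**2
    pop_total = np.bincount(mesh_region, weights=population, minlength=params.n_regions)
    pop_urban = np.bincount(
        mesh_region, weights=population * urban_mesh, minlength=params.n_regions
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        urban_proportion = np.where(pop_total > 0, pop_urban / np.maximum(pop_total, 1), 0.0)
    regions = pd.DataFrame({"region_id": region_ids, "urban_proportion": urban_proportion})

    return Instance(meshes=meshes, facilities=facilities, travel_times=ttm, regions=regions)


def japan_scale_fixture(seed: int, n_meshes: int = 5000, **overrides) -> Instance:
    """Synthetic instance at the national scale of the study system.

    662 facilities share 1,605 specialists (at most 5 each) across 47 regions;
    the mesh count is reduced relative to the census grid, with per-mesh
    populations scaled up accordingly.
    """
    params = GeneratorParams(
        n_meshes=n_meshes,
        n_facilities=JAPAN_N_FACILITIES,
        n_regions=JAPAN_N_REGIONS,
        total_staff=JAPAN_TOTAL_STAFF,
        staff_cap=5,
        seed=seed,
    )
    if overrides:
        params = replace(params, **overrides)
    return generate_instance(params)
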