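"""Core data containers: entity tables and the sparse travel-time matrix.

Meshes, facilities and regions are plain :class:`pandas.DataFrame` objects with
fixed schemas (see :data:`MESH_COLUMNS` etc.); the travel-time matrix is kept in
long/triplet form because only pairs inside the catchment threshold are ever
stored — the zero branch of the truncated decay kernel is structural, not
numerical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

MESH_COLUMNS = ("mesh_id", "x", "y", "population", "region_id")
FACILITY_COLUMNS = ("facility_id", "x", "y", "staff", "region_id")
TRAVEL_COLUMNS = ("mesh_id", "facility_id", "minutes")
REGION_COLUMNS = ("region_id", "urban_proportion")


class SchemaError(ValueError):
    """Raised when an entity table violates its schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def _require_unique(df: pd.DataFrame, col: str, name: str) -> None:
    dup = df[col][df[col].duplicated()]
    if len(dup):
        raise SchemaError(f"{name} table has duplicate {col}: {sorted(set(dup))[:5]}")


def _require_nonnegative(df: pd.DataFrame, col: str, name: str) -> None:
    bad = np.flatnonzero(np.asarray(df[col], dtype=float) < 0)
    if bad.size:
        raise SchemaError(f"{name} table has negative {col} at row {bad[0]}")


def validate_meshes(meshes: pd.DataFrame) -> pd.DataFrame:
    _require_columns(meshes, MESH_COLUMNS, "meshes")
    _require_unique(meshes, "mesh_id", "meshes")
    _require_nonnegative(meshes, "population", "meshes")
    return meshes


def validate_facilities(facilities: pd.DataFrame) -> pd.DataFrame:
    _require_columns(facilities, FACILITY_COLUMNS, "facilities")
    _require_unique(facilities, "facility_id", "facilities")
    _require_nonnegative(facilities, "staff", "facilities")
    return facilities


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    _require_columns(regions, REGION_COLUMNS, "regions")
    _require_unique(regions, "region_id", "regions")
    p = np.asarray(regions["urban_proportion"], dtype=float)
    bad = np.flatnonzero((p < 0) | (p > 1))
    if bad.size:
        raise SchemaError(f"regions table has urban_proportion outside [0,1] at row {bad[0]}")
    return regions


@dataclass
class TravelTimeMatrix:
    """Sparse mesh-to-facility travel times in minutes, thresholded at ``d0``.

    Only pairs with ``minutes < threshold_minutes`` are stored; any pair absent
    from the triplets is treated as unreachable (decay weight zero).
    """

    mesh_ids: np.ndarray
    facility_ids: np.ndarray
    minutes: np.ndarray
    threshold_minutes: float = 120.0

    def __post_init__(self) -> None:
        self.mesh_ids = np.asarray(self.mesh_ids)
        self.facility_ids = np.asarray(self.facility_ids)
        self.minutes = np.asarray(self.minutes, dtype=float)
        if not (len(self.mesh_ids) == len(self.facility_ids) == len(self.minutes)):
            raise SchemaError("travel-time triplet arrays have unequal lengths")
        if self.threshold_minutes <= 0:
            raise SchemaError("threshold_minutes must be positive")
        bad = np.flatnonzero(self.minutes < 0)
        if bad.size:
            raise SchemaError(f"travel time is negative at row {bad[0]}")
        bad = np.flatnonzero(self.minutes >= self.threshold_minutes)
        if bad.size:
            raise SchemaError(
                f"travel time at row {bad[0]} is >= threshold "
                f"({self.minutes[bad[0]]:g} >= {self.threshold_minutes:g}); "
                "drop out-of-catchment rows before constructing the matrix"
            )
        pairs = pd.MultiIndex.from_arrays([self.mesh_ids, self.facility_ids])
        if pairs.has_duplicates:
            raise SchemaError("duplicate (mesh_id, facility_id) pair in travel times")

    def __len__(self) -> int:
        return len(self.minutes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold_minutes: float = 120.0) -> "TravelTimeMatrix":
        _require_columns(df, TRAVEL_COLUMNS, "travel_times")
        return cls(
            mesh_ids=df["mesh_id"].to_numpy(),
            facility_ids=df["facility_id"].to_numpy(),
            minutes=df["minutes"].to_numpy(dtype=float),
            threshold_minutes=threshold_minutes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mesh_id": self.mesh_ids, "facility_id": self.facility_ids, "minutes": self.minutes}
        )

    def positions(self, meshes: pd.DataFrame, facilities: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Row/column positions of each triplet in the given entity tables."""
        mesh_pos = pd.Index(meshes["mesh_id"]).get_indexer(self.mesh_ids)
        fac_pos = pd.Index(facilities["facility_id"]).get_indexer(self.facility_ids)
        if (mesh_pos < 0).any():
            missing = self.mesh_ids[mesh_pos < 0][0]
            raise SchemaError(f"travel times reference unknown mesh_id {missing!r}")
        if (fac_pos < 0).any():
            missing = self.facility_ids[fac_pos < 0][0]
            raise SchemaError(f"travel times reference unknown facility_id {missing!r}")
        return mesh_pos, fac_pos

    def kernel_matrix(
        self,
        meshes: pd.DataFrame,
        facilities: pd.DataFrame,
        weights: np.ndarray,
    ) -> sp.csr_matrix:
        """Assemble a CSR matrix (meshes x facilities) from per-triplet weights."""
        rows, cols = self.positions(meshes, facilities)
        keep = weights > 0
        return sp.csr_matrix(
            (weights[keep], (rows[keep], cols[keep])),
            shape=(len(meshes), len(facilities)),
        )


@dataclass
class Instance:
    """One complete study instance: demand, supply, travel times and regions."""

    meshes: pd.DataFrame
    facilities: pd.DataFrame
    travel_times: TravelTimeMatrix
    regions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(REGION_COLUMNS)))

    def __post_init__(self) -> None:
        validate_meshes(self.meshes)
        validate_facilities(self.facilities)
        if len(self.regions):
            validate_regions(self.regions)

    @property
    def total_demand(self) -> float:
        return float(self.meshes["population"].sum())

    @property
    def total_staff(self) -> float:
        return float(self.facilities["staff"].sum())

    def with_staff(self, staff: Iterable[float]) -> "Instance":
        """Copy of the instance with a replacement staffing vector."""
        staff = np.asarray(list(staff), dtype=float)
        if staff.shape != (len(self.facilities),):
            raise ValueError("staff vector length does not match facilities")
        facilities = self.facilities.copy()
        facilities["staff"] = staff
        return Instance(self.meshes, facilities, self.travel_times, self.regions)
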