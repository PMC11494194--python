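"""Seascape container and validated input loading.

A Seascape bundles the site table (id, reef, geomorphic zone, sector
label, planar and 3D substrate areas, depth, habitat limit K, centroid),
the cluster connectivity matrix, and optional site DHW scalers. Loaders
are schema-checked: every invariant is asserted at load time and a single
validation error lists all failures with row/column context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, mean_connectivity
from .disturbance import DisturbanceSchedule, SiteDHWScaler

__all__ = [
    "Seascape",
    "ValidationError",
    "validate_site_table",
    "load_site_table",
    "load_connectivity",
    "load_schedule",
    "load_colony_records",
]

SITE_COLUMNS = {
    "site_id": str,
    "reef": str,
    "zone": str,
    "planar_area_m2": float,
    "substrate_area_m2": float,
    "depth_m": float,
    "K_pct": float,
}

COLONY_COLUMNS = ["colony_id", "coral_type", "year", "area_t_cm2", "area_t1_cm2", "survived"]


class ValidationError(ValueError):
    """Raised with the full list of schema/invariant failures."""

    def __init__(self, failures: list[str]):
        self.failures = failures
        super().__init__("input validation failed:\n  - " + "\n  - ".join(failures))


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    failures: list[str] = []
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            failures.append(f"site table missing column {col!r}")
    if failures:
        raise ValidationError(failures)
    dup = sites["site_id"][sites["site_id"].duplicated()]
    if len(dup):
        failures.append(f"duplicated site ids: {sorted(set(dup))}")
    for col in ("planar_area_m2", "substrate_area_m2"):
        bad = sites.loc[sites[col] <= 0, "site_id"]
        if len(bad):
            failures.append(f"{col} must be > 0 (sites {list(bad)})")
    bad = sites.loc[(sites["K_pct"] < 0) | (sites["K_pct"] > 100), "site_id"]
    if len(bad):
        failures.append(f"K_pct must be in [0, 100] (sites {list(bad)})")
    bad = sites.loc[sites["depth_m"] < 0, "site_id"]
    if len(bad):
        failures.append(f"depth_m must be >= 0 (sites {list(bad)})")
    if failures:
        raise ValidationError(failures)
    out = sites.copy()
    out["site_id"] = out["site_id"].astype(str)
    out["reef"] = out["reef"].astype(str)
    if "modelled" not in out.columns:
        out["modelled"] = True
    if "sector" not in out.columns:
        out["sector"] = pd.NA
    return out.reset_index(drop=True)


@dataclass
class Seascape:
    """Validated site mosaic plus cluster connectivity and DHW scalers."""

    sites: pd.DataFrame
    connectivity: ConnectivityMatrix
    scalers: SiteDHWScaler | None = None

    def __post_init__(self) -> None:
        self.sites = validate_site_table(self.sites)
        ids = tuple(self.sites["site_id"])
        if self.connectivity.site_ids != ids:
            raise ValidationError(
                ["connectivity site ids do not match (or are not ordered as) the site table"]
            )
        if self.scalers is not None:
            missing = set(ids) - set(self.scalers.table["site"])
            if missing:
                raise ValidationError([f"sites without DHW scalers: {sorted(missing)}"])

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    def reef_of(self) -> pd.Series:
        return self.sites.set_index("site_id")["reef"]

    def with_uniform_K(self, K: float) -> "Seascape":
        sites = self.sites.copy()
        sites["K_pct"] = float(K)
        return Seascape(sites=sites, connectivity=self.connectivity, scalers=self.scalers)

    def total_planar_area_ha(self) -> float:
        return float(self.sites["planar_area_m2"].sum()) / 1e4

    def potential_coral_area_ha(self) -> float:
        """Total possible live coral area (ha): sum of site area x K."""
        return float(
            (self.sites["planar_area_m2"] * self.sites["K_pct"] / 100.0).sum()
        ) / 1e4


def load_site_table(path) -> pd.DataFrame:
    return validate_site_table(pd.read_csv(path))


def load_connectivity(paths) -> ConnectivityMatrix:
    """Load one or more dense CSV matrices (site-id header row and index
    column) and reduce them to their mean."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    mats = [ConnectivityMatrix.from_frame(pd.read_csv(p, index_col=0)) for p in paths]
    return mean_connectivity(mats)


def load_schedule(path) -> DisturbanceSchedule:
    return DisturbanceSchedule(table=pd.read_csv(path))


def load_colony_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    failures = [f"colony records missing column {c!r}" for c in COLONY_COLUMNS if c not in df.columns]
    if failures:
        raise ValidationError(failures)
    if (df["area_t_cm2"] <= 0).any():
        raise ValidationError(["area_t_cm2 must be positive"])
    alive = df["area_t1_cm2"].notna()
    if (df.loc[alive, "area_t1_cm2"] <= 0).any():
        raise ValidationError(["area_t1_cm2 must be positive when present"])
    if not df["survived"].isin([0, 1]).all():
        raise ValidationError(["survived must be 0/1"])
    return df
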