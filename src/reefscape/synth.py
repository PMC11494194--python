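"""Synthetic seascape, colony, connectivity and disturbance generators.

Every input stream of the simulator can be emulated with known ground
truth: a reef-cluster site table with log-normal site areas in the ~1-25
ha range, an exponential-distance-decay connectivity matrix with a fixed
loss fraction, tagged-colony demographic records simulated from the exact
statistical families the fitting module assumes (log-normal growth,
logistic survival, Poisson fecundity), and a disturbance schedule with
pulse heatwave/cyclone/COTS years plus fine-scale heatwave DHW fields for
scaler fitting. Defaults are sized to a five-reef case-study cluster;
everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .disturbance import DisturbanceSchedule, N_COTS_AGE_CLASSES

__all__ = [
    "SyntheticSpec",
    "TrueVitalParams",
    "gen_seascape",
    "gen_connectivity",
    "gen_colony_data",
    "gen_disturbance_schedule",
    "write_bundle",
]

_ZONES = ("Slope", "ShelteredSlope", "Crest", "OuterFlat")
_SECTORS = ("back", "flank1", "flank2", "front")


@dataclass(frozen=True)
class TrueVitalParams:
    """Ground-truth vital-rate parameters used to simulate colony data."""

    growth_intercept: float = 0.3
    growth_slope: float = 0.9
    growth_sd: float = 0.25
    survival_intercept: float = 0.0
    survival_slope: float = 1.2
    epp_intercept: float = 1.0  # log eggs-per-polyp at 1 cm^2
    epp_slope: float = 0.3
    ppc_intercept: float = 2.5  # log polyps-per-cm^2 at 1 cm^2
    ppc_slope: float = -0.2
    max_area_cm2: float = 2000.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Scenario description for a full synthetic fixture bundle."""

    n_reefs: int = 5
    sites_per_reef: int = 10
    site_area_ha: tuple[float, float] = (1.0, 25.0)  # range of site planar areas
    depth_m: tuple[float, float] = (2.0, 18.0)
    K_pct: tuple[float, float] = (30.0, 90.0)  # site-specific habitat range
    decay_length_m: float = 2000.0
    loss_fraction: float = 0.3
    start_year: int = 2008
    end_year: int = 2022
    heatwave_years: tuple[int, ...] = (2017,)
    heatwave_dhw: float = 8.0
    cyclone_years: tuple[int, ...] = (2011,)
    cyclone_category: int = 2
    cots_years: tuple[int, ...] = ()
    cots_adult_density: float = 0.02  # individuals m^-2 in outbreak years
    dhw_site_cv: float = 0.2  # within-reef spatial spread of heat stress
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reefs < 1 or self.sites_per_reef < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.loss_fraction <= 1.0:
            raise ValueError("loss_fraction must be in [0, 1]")


def gen_seascape(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a site table for a cluster of reefs.

    Site areas are log-normal, truncated into the configured hectare
    range; depths uniform; zones and manta-tow sectors cycled; site
    centroids scattered around reef centres laid out ~5 km apart.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.site_area_ha
    mu, sigma = np.log(np.sqrt(lo * hi)), 0.6
    rows = []
    for r in range(spec.n_reefs):
        reef = f"reef{r + 1:02d}"
        cx, cy = 5000.0 * r, 2500.0 * (r % 2)
        for s in range(spec.sites_per_reef):
            area_ha = float(np.clip(rng.lognormal(mu, sigma), lo, hi))
            rows.append(
                dict(
                    site_id=f"{reef}-s{s + 1:03d}",
                    reef=reef,
                    zone=_ZONES[s % len(_ZONES)],
                    sector=_SECTORS[s % len(_SECTORS)],
                    planar_area_m2=area_ha * 1e4,
                    depth_m=float(rng.uniform(*spec.depth_m)),
                    K_pct=float(rng.uniform(*spec.K_pct)),
                    x_m=cx + float(rng.normal(0, 800)),
                    y_m=cy + float(rng.normal(0, 800)),
                    modelled=True,
                )
            )
    df = pd.DataFrame(rows)
    slope = rng.uniform(0, 35, size=len(df))
    df["substrate_area_m2"] = df["planar_area_m2"] / np.cos(np.deg2rad(slope))
    return df


def gen_connectivity(
    centroids: pd.DataFrame,
    decay_length_m: float = 2000.0,
    loss_fraction: float = 0.3,
    seed: int | None = None,
) -> ConnectivityMatrix:
    """Exponential-distance-decay larval transfer matrix.

    Entries decay as exp(-d/decay_length); each column is rescaled to sum
    to (1 - loss_fraction), the within-cluster retention. ``centroids``
    needs columns (site_id, x_m, y_m).
    """
    ids = tuple(str(s) for s in centroids["site_id"])
    xy = centroids[["x_m", "y_m"]].to_numpy(dtype=float)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    M = np.exp(-d / decay_length_m)
    if seed is not None:
        rng = np.random.default_rng(seed)
        M *= rng.uniform(0.5, 1.5, size=M.shape)  # hydrodynamic asymmetry
    colsum = M.sum(axis=0)
    M = M * (1.0 - loss_fraction) / colsum[None, :]
    return ConnectivityMatrix(site_ids=ids, matrix=M)


def gen_colony_data(
    true_params: TrueVitalParams,
    n_colonies: int = 500,
    n_years: int = 2,
    seed: int | np.random.Generator | None = None,
    coral_type: str = "corymbose_acropora",
) -> pd.DataFrame:
    """Simulate tagged-colony monitoring records from known parameters.

    Each colony-year yields a record with area at t, survival drawn from
    the logistic model on log10 area, area at t+1 from the log-normal
    growth model (blank if dead), and egg/polyp counts from the Poisson
    fecundity models. Ground truth is in ``true_params`` for recovery
    tests.
    """
    if n_colonies < 10:
        raise ValueError("need at least 10 colonies")
    p = true_params
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    log_max = np.log10(p.max_area_cm2)
    for c in range(n_colonies):
        la = rng.uniform(0.0, log_max)  # log10 area at first tagging
        for y in range(n_years):
            area_t = 10.0**la
            eta = p.survival_intercept + p.survival_slope * la
            surv = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            la1 = p.growth_intercept + p.growth_slope * la + rng.normal(0, p.growth_sd)
            area_t1 = 10.0**la1 if surv else np.nan
            epp = rng.poisson(np.exp(p.epp_intercept + p.epp_slope * la))
            ppc = rng.poisson(np.exp(p.ppc_intercept + p.ppc_slope * la))
            rows.append(
                dict(
                    colony_id=f"c{c:05d}",
                    coral_type=coral_type,
                    year=2000 + y,
                    area_t_cm2=area_t,
                    area_t1_cm2=area_t1,
                    survived=surv,
                    eggs_per_polyp=epp,
                    polyps_per_cm2=ppc,
                )
            )
            if not surv:
                break
            la = la1
    return pd.DataFrame(rows)


def gen_disturbance_schedule(
    spec: SyntheticSpec, sites: pd.DataFrame | None = None
) -> tuple[DisturbanceSchedule, pd.DataFrame]:
    """Build the reef-level schedule and fine-scale heatwave DHW fields.

    The schedule covers every (year, reef) with zero forcing except the
    configured heatwave / cyclone / COTS pulse years. The second return
    value holds site-level DHW for the heatwave years (log-normal spread
    around the reef mean with coefficient of variation ``dhw_site_cv``),
    the input for fitting site DHW scalers; its reef means match the
    schedule exactly by construction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    reefs = [f"reef{r + 1:02d}" for r in range(spec.n_reefs)]
    rows = []
    for year in range(spec.start_year, spec.end_year + 1):
        for reef in reefs:
            row = dict(
                year=year,
                reef=reef,
                dhw_max=spec.heatwave_dhw if year in spec.heatwave_years else 0.0,
                cyclone_category=spec.cyclone_category if year in spec.cyclone_years else 0,
            )
            adult = spec.cots_adult_density if year in spec.cots_years else 0.0
            for a in range(N_COTS_AGE_CLASSES):
                row[f"cots_age{a + 1}"] = adult if a >= 3 else 0.0
            rows.append(row)
    schedule = DisturbanceSchedule(table=pd.DataFrame(rows))

    fields = []
    if sites is not None and spec.heatwave_years:
        sigma = np.sqrt(np.log(1 + spec.dhw_site_cv**2))
        for year in spec.heatwave_years:
            for reef, sub in sites.groupby("reef"):
                raw = rng.lognormal(-(sigma**2) / 2, sigma, size=len(sub))
                raw *= spec.heatwave_dhw / raw.mean()  # reef mean exact
                for sid, dhw in zip(sub["site_id"], raw):
                    fields.append(dict(year=year, site=sid, dhw=float(dhw)))
    return schedule, pd.DataFrame(fields, columns=["year", "site", "dhw"])


def write_bundle(spec: SyntheticSpec, out_dir, n_colonies: int = 500) -> dict[str, Path]:
    """Write a complete fixture bundle (CSV files) ready for a run.

    Produces the site table, connectivity matrix, disturbance schedule,
    fine-scale DHW fields, colony records for both coral types, and the
    ground-truth parameter record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites = gen_seascape(spec)
    conn = gen_connectivity(
        sites, spec.decay_length_m, spec.loss_fraction, seed=spec.seed + 2
    )
    schedule, dhw_fields = gen_disturbance_schedule(spec, sites)
    rng = np.random.default_rng(spec.seed + 3)
    acro = TrueVitalParams()
    # slower growth, flatter/higher survival for the sub-massive type
    subm = TrueVitalParams(
        growth_intercept=0.15,
        growth_slope=0.93,
        growth_sd=0.2,
        survival_intercept=1.0,
        survival_slope=1.0,
        max_area_cm2=1200.0,
    )
    colonies = pd.concat(
        [
            gen_colony_data(acro, n_colonies, seed=rng, coral_type="corymbose_acropora"),
            gen_colony_data(subm, n_colonies, seed=rng, coral_type="small_submassive"),
        ],
        ignore_index=True,
    )
    paths = {
        "sites": out / "sites.csv",
        "connectivity": out / "connectivity.csv",
        "schedule": out / "schedule.csv",
        "dhw_fields": out / "dhw_fields.csv",
        "colonies": out / "colonies.csv",
        "truth": out / "true_params.csv",
    }
    sites.to_csv(paths["sites"], index=False)
    conn.to_frame().to_csv(paths["connectivity"])
    schedule.table.to_csv(paths["schedule"], index=False)
    dhw_fields.to_csv(paths["dhw_fields"], index=False)
    colonies.to_csv(paths["colonies"], index=False)
    truth = pd.DataFrame(
        [dict(coral_type="corymbose_acropora", **acro.__dict__),
         dict(coral_type="small_submassive", **subm.__dict__)]
    )
    truth.to_csv(paths["truth"], index=False)
    return paths
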