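"""Annual simulation loop over the seascape.

Each replicate draws one projection kernel per coral type from the
bootstrap kernel sets (capturing demographic uncertainty), then iterates
years. Within a year, in order: (1) the density-dependent demographic
update at every site, (2) fertilisation of the year's egg output,
(3) dispersal across the connectivity matrix plus external larval supply,
(4) settlement into the settler pools, (5) acute disturbance mortality,
(6) recording. Egg and larva pools are within-year transients and are
cleared once routed, so reproduction is never double counted between the
kernel's discrete chain and the dispersal stage.

All randomness flows from one root seed through per-replicate child
streams, so any replicate's trajectory is independent of how many other
replicates run alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import SiteState, coral_cover, step_community
from .connectivity import distribute_external, disperse, fertilise, settle
from .disturbance import DisturbanceSchedule, apply_disturbances, downscale_dhw
from .kernel import EGG, LARVA, SETTLER, CoralTypeSpec, IPMKernel, intrinsic_growth
from .metrics import initialise_from_cover
from .seascape import Seascape

__all__ = ["SimulationConfig", "run_simulation"]


@dataclass
class SimulationConfig:
    """Run settings for the annual metacommunity loop.

    ``initial_cover_pct`` seeds every modelled site at that total cover
    (split between types per ``type_split``) using each kernel's stable
    size distribution — mirroring initialisation from observed cover.
    """

    start_year: int
    end_year: int
    n_replicates: int = 1
    seed: int = 0
    initial_cover_pct: float = 10.0
    type_split: dict[str, float] | None = None
    clamp_density: bool = False
    settlers_exposed: bool = False
    record_per_type: bool = True

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @staticmethod
    def from_yaml(path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return SimulationConfig(**raw)


def _site_dhw_lookup(
    seascape: Seascape, schedule: DisturbanceSchedule | None
) -> dict[tuple[int, str], float]:
    """Per-(year, site) DHW after downscaling; empty if no scalers/schedule."""
    if schedule is None or seascape.scalers is None:
        return {}
    reef_dhw = schedule.table[["year", "reef", "dhw_max"]]
    site_dhw = downscale_dhw(reef_dhw, seascape.scalers)
    return {
        (int(r.year), str(r.site)): float(r.dhw)
        for r in site_dhw.itertuples(index=False)
    }


def run_simulation(
    seascape: Seascape,
    kernel_sets: dict[str, list[IPMKernel]],
    specs: dict[str, CoralTypeSpec],
    config: SimulationConfig,
    schedule: DisturbanceSchedule | None = None,
    external_supply: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the metacommunity and return tidy cover trajectories.

    Returns a frame with columns (replicate, year, site_id, reef,
    coral_type, cover_pct) where ``coral_type`` includes each type and
    ``"total"``. Sites flagged not modelled carry zero cover in all years.
    ``external_supply`` columns: year, reef, coral_type, larvae.
    """
    type_names = list(kernel_sets)
    for t in type_names:
        if not kernel_sets[t]:
            raise ValueError(f"no kernels supplied for type {t}")
    sites = seascape.sites
    modelled = sites["modelled"].astype(bool).to_numpy()
    site_ids = seascape.site_ids
    dhw_lookup = _site_dhw_lookup(seascape, schedule)

    root = np.random.SeedSequence(config.seed)
    records: list[dict] = []

    def record(rep: int, year: int, states: dict[str, SiteState], grids) -> None:
        for sid in site_ids:
            st = states.get(sid)
            if st is None:
                per = {t: 0.0 for t in type_names}
            else:
                per = coral_cover(st, grids, per_type=True)
            reef = sites.loc[sites["site_id"] == sid, "reef"].iloc[0]
            if config.record_per_type:
                for t in type_names:
                    records.append(
                        dict(replicate=rep, year=year, site_id=sid, reef=reef,
                             coral_type=t, cover_pct=per[t])
                    )
            records.append(
                dict(replicate=rep, year=year, site_id=sid, reef=reef,
                     coral_type="total", cover_pct=float(sum(per.values())))
            )

    for rep, child in enumerate(root.spawn(config.n_replicates)):
        rng = np.random.default_rng(child)
        kernels = {t: kernel_sets[t][rng.integers(len(kernel_sets[t]))] for t in type_names}
        grids = {t: kernels[t].grid for t in type_names}
        ops = {t: intrinsic_growth(kernels[t]) for t in type_names}

        states: dict[str, SiteState] = {}
        for row in sites.itertuples(index=False):
            if not row.modelled:
                continue
            states[row.site_id] = initialise_from_cover(
                min(config.initial_cover_pct, row.K_pct),
                kernels,
                site_id=row.site_id,
                reference_area_m2=row.substrate_area_m2,
                K=row.K_pct,
                type_split=config.type_split,
            )
        record(rep, config.start_year, states, grids)

        for year in range(config.start_year, config.end_year):
            # (1) demography under shared density dependence
            for sid in states:
                states[sid] = step_community(
                    states[sid], ops, grids, clamp_density=config.clamp_density
                )
            # (2)-(4) reproduction, dispersal, settlement per type
            for t in type_names:
                eggs = np.array(
                    [states[sid].abundance[t][EGG] if sid in states else 0.0
                     for sid in site_ids]
                )
                released = fertilise(eggs, specs[t].fertilisation_prob)
                arriving, _lost = disperse(released, seascape.connectivity)
                if external_supply is not None:
                    ext = external_supply[
                        (external_supply["year"] == year)
                        & (external_supply["coral_type"] == t)
                    ]
                    for r in ext.itertuples(index=False):
                        reef_sites = sites[
                            (sites["reef"] == r.reef) & sites["modelled"]
                        ]
                        if reef_sites.empty:
                            continue
                        shares = distribute_external(
                            float(r.larvae),
                            reef_sites.set_index("site_id")["planar_area_m2"],
                        )
                        for sid, extra in shares.items():
                            arriving[site_ids.index(sid)] += extra
                settlers = settle(arriving, specs[t].settlement_prob)
                for i, sid in enumerate(site_ids):
                    if sid in states:
                        vec = states[sid].abundance[t]
                        vec[SETTLER] += settlers[i]
                        vec[EGG] = 0.0
                        vec[LARVA] = 0.0
            # (5) acute disturbances of this year
            if schedule is not None:
                for row in sites.itertuples(index=False):
                    if row.site_id not in states:
                        continue
                    states[row.site_id] = apply_disturbances(
                        states[row.site_id],
                        year,
                        schedule,
                        reef=row.reef,
                        depth_m=row.depth_m,
                        grid=grids,
                        specs=specs,
                        site_dhw=dhw_lookup.get((year, row.site_id)),
                        settlers_exposed=config.settlers_exposed,
                    )
            # (6) record post-step cover under the following year's label
            record(rep, year + 1, states, grids)

    return pd.DataFrame.from_records(records)
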