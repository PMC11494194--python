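# reefscape

Size-structured coral metacommunity simulation across the mosaic of sites
that make up a reef cluster.

Coral cover on a reef varies as much *within* the reef — between slopes,
crests and flats a few hundred metres apart — as it does between reefs.
`reefscape` is a simulator for that within-reef scale: each site hosts a
simple two-type coral community (a fast, fragile corymbose *Acropora* and
a slow, robust small sub-massive coral), sites are linked by larval
connectivity, each site has a map-derived ceiling on how much coral it can
hold, and marine heatwaves, cyclones and crown-of-thorns starfish (COTS)
outbreaks remove coral in specific years. It is aimed at reef ecologists
and modellers who want to ask where within a reef cover will recover, how
fast, and how sensitive those answers are to assuming the habitat ceiling
is uniform.

## The model

Each coral type *ft* at site *i* is a vector **N** over three discrete
stages (eggs, larvae, settlers) and 100 size classes of colony planar
area. A discretised integral projection model (IPM) kernel

    k(y, x) = s(x) g(x, y) + f(x, y)

is built from regressions of survival *s*, growth *g* and fecundity *f*
on log₁₀ colony area, fitted to tagged-colony records by maximum
likelihood with a nonparametric bootstrap for uncertainty. The intrinsic
growth operator is `r = K_ipm − I`, and the annual community update is a
discrete logistic equation with a single shared crowding term:

    C_i,t  = Σ_ft Σ_n N_ft,i,n,t · a_ft,n        (total cover)
    D_i,t  = (K_i − C_i,t) / K_i                 (remaining habitat)
    N_t+1  = N_t + D_i,t · r · N_t

where `K_i` is the site's maximum coral habitat (%), estimated from
classified benthic rasters by Monte-Carlo sampling of within-pixel
composition (dominant class 26–100%, others 0–25%), or set uniform.

Each year: demographic update → egg fertilisation → larval dispersal over
a site×site connectivity matrix (column sums ≤ 1; the deficit is larvae
lost from the cluster) plus external larval supply shared by site area →
settlement → disturbance mortality. The three hazards combine
multiplicatively; bleaching mortality is a logistic function of
depth-attenuated degree heating weeks (DHW), cyclone mortality a logistic
function of wind speed by morphology, and COTS consumption is allocated
between the types with a 14 : 4.3 preference for *Acropora*.

## Worked example

Two reefs of five sites each, a cyclone in 2011 and a heatwave in 2017,
vital rates fitted to 500 synthetic tagged colonies, ten replicates:

```python
import numpy as np
import reefscape as rs

spec = rs.SyntheticSpec(n_reefs=2, sites_per_reef=5, seed=42,
                        cyclone_years=(2011,), heatwave_years=(2017,))
sites = rs.gen_seascape(spec)
conn = rs.gen_connectivity(sites, spec.decay_length_m, spec.loss_fraction, seed=43)
schedule, dhw_fields = rs.gen_disturbance_schedule(spec, sites)
scalers = rs.fit_dhw_scalers(dhw_fields, sites.set_index("site_id")["reef"])
sea = rs.Seascape(sites=sites, connectivity=conn, scalers=scalers)

records = rs.gen_colony_data(rs.TrueVitalParams(), n_colonies=500, n_years=1, seed=44)
specs = rs.default_type_specs()
kernels = {t: rs.replicate_kernels(records, specs[t], 10, seed=45 + i, n_classes=50)
           for i, t in enumerate(specs)}

cfg = rs.SimulationConfig(start_year=2008, end_year=2022, n_replicates=10,
                          seed=1, initial_cover_pct=10.0)
traj = rs.run_simulation(sea, kernels, specs, cfg, schedule=schedule)
total = traj[traj["coral_type"] == "total"]

by_year = total.groupby("year")["cover_pct"].mean()
windows = rs.recovery_windows(schedule, min_span=2)
rates = [rs.annual_change(sub, w)
         for (_, _), sub in total.groupby(["replicate", "site_id"]) for w in windows]
print(f"annual change: {np.mean(rates):.2f} +/- {np.std(rates):.2f} % cover/yr")
```

This prints mean covers of 10.0% (2008), 11.2% (2011) dropping to 10.5%
after the cyclone, 24.9% (2017) with the heatwave knocking the *Acropora*
component from 11.1% to 10.5% while the robust type keeps growing, and
44.2% by 2022. The recovery windows are 2008–2010, 2012–2016 and
2018–2022 (the event years are excluded and windows must span at least
two years), and the time-averaged annual change inside them is

    annual change: 2.39 +/- 2.14 % cover/yr

i.e. cover grows a little over two percentage points per year when no
acute disturbance interrupts it, with large spread between sites.

The same workflow is available from the shell: `reefscape synth`,
`reefscape habitat`, `reefscape fit`, `reefscape run`, `reefscape
metrics` (see `reefscape --help`).

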