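# Methods

## Model structure

The simulator couples three layers.

**Demography.** Each coral type is described by an integral projection
model over colony planar area (cm²), discretised to 100 size classes plus
three discrete stages (eggs, larvae, settlers). The class edges are
log-spaced from the area of a 1 cm diameter colony (π·0.25 ≈ 0.785 cm²)
to 90% of the largest observed colony, and the representative area of a
class is the geometric midpoint of its edges — coral sizes span more than
three orders of magnitude, so a linear grid would waste almost all of its
resolution on the largest colonies. Vital-rate regressions all use
log₁₀(area) as the predictor: growth is a linear model of log-area at
t+1 with constant log-scale spread (log-normal error family), survival a
logistic regression on the binary outcome, and fecundity the product of
two Poisson regressions (eggs per polyp × polyps per cm² × colony area;
the product form is the default, a direct colony-level egg regression can
be substituted). Fits are maximum likelihood (statsmodels OLS / Logit /
Poisson GLM) with a nonparametric whole-record bootstrap (default 100
resamples) supplying parameter uncertainty and replicate kernels; a
posterior-sampling fit could be slotted in at the same interface.

The survival–growth block is assembled by the midpoint rule: column *x*
carries s(aₓ) times the normal growth density integrated over each
class, with mass falling outside the grid accumulated into the boundary
classes ("eviction") so every column sums exactly to s(aₓ) — no
individuals are silently lost or created. Shrinkage is permitted: the
growth distribution has mass below the current size and no separate
shrinkage model is fitted. Degenerate survival data (all alive or all
dead) fall back to a constant probability clamped to [0.001, 0.999] to
avoid an unbounded logit. The discrete chain routes eggs to larvae with
the fertilisation probability and settlers into the smallest size class
with the first-year post-settlement survival; larvae leave the
within-site kernel because their transport is handled by the
connectivity layer.

**Community dynamics.** The intrinsic growth operator r = K_ipm − I is
plugged into a discrete logistic update N ← N + D·r·N with
D = (K − C)/K computed once per year from *total* community cover before
either type is updated: both types draw on the same limiting resource
(space), and computing D first makes the update order-independent
between types. Cover counts only the continuous size classes —
eggs, larvae and settlers occupy no benthic space — and is normalised by
the site's 3D substrate area (planar / cos(slope)) so that C and K are
commensurable percentages. D is allowed to go negative when cover
overshoots K (the overshoot then decays); a clamp-at-zero switch exists
in the config. Negative abundances that a strongly negative D could
produce are floored at zero and the clipped mass is logged on the state.

**Seascape and annual loop.** Sites are the spatial unit (sub-kilometre,
single geomorphic zone); reefs group sites; the cluster is the closed
dispersal domain plus an external larval supply. The within-year order
is demography → fertilisation → dispersal (+ external supply distributed
to a reef's sites proportionally to site area) → settlement →
disturbance mortality → recording; spawning precedes the summer
heat-stress season in the region this emulates, which fixes disturbance
after reproduction. Egg and larva pools are within-year transients and
are cleared once routed, so the kernel's egg→larva entry and the
dispersal stage never double-count. All randomness (kernel draws per
replicate) descends from one root seed through per-replicate
`SeedSequence` children, so a replicate's trajectory is independent of
how many replicates run.

## Habitat limits from maps

Classified benthic rasters (pixels labelled Sand, Rubble, Rock or
Coral/Algae; Rock and Coral/Algae count as suitable coral habitat) are
handled as plain CSV grids of pixel rows — the modelled quantities need
only class labels and centroid geometry, so no geospatial raster stack
is required. A dominant label only bounds within-pixel composition, so K
is estimated by replicate sampling: dominant fraction ~ U(0.26, 1.00),
each non-dominant fraction ~ U(0, 0.25), per pixel per replicate. The
draws are renormalised to sum to one before the suitable share is
extracted, because pixel composition is compositional (independent
uniforms need not sum to 100%); a no-renormalise mode that simply caps at
1 is provided for sensitivity checks. The default is 100 replicates; the
mean and standard error over replicates are reported with the seed.
Zones that are not predominantly hard substrate (lagoon, inner flats)
are excluded from partitioning and simulation and carry K = 0.

Site partitioning clusters pixel centroids within each hard-substrate
zone by complete-linkage agglomeration cut at a maximum diameter
(default 1 km). Complete linkage guarantees the cut bounds every site's
largest pairwise pixel distance; sites may be discontiguous but never
mix zones.

## Disturbances

Reef-level annual maximum DHW series are downscaled to sites with
multiplicative scalers fitted as proportional residuals (site DHW /
reef-mean DHW) over fine-scale heatwave-year fields, renormalised so the
site mean within each reef is exactly 1 — downscaling therefore
preserves the reef series exactly. Bleaching mortality is
logit⁻¹(b₀ + b₁·E) rescaled by its E = 0 baseline so zero heat stress
gives exactly zero mortality, with E = DHW·exp(−λ·max(0, depth − 2 m)).
The depth attenuation λ = 0.05 m⁻¹ yields, for a DHW-8 event, roughly
44% / 20% / 10% *Acropora* mortality at 3 / 10 / 16 m — a depth-refuge
gradient of realistic magnitude. Cyclone categories map to wind speed
through a Bureau-of-Meteorology style band-midpoint table (overridable)
and mortality is logistic in wind per morphology, with branching corals
more fragile than small sub-massive ones at every wind speed; mortality
is uniform across size classes (size-dependent dislodgement is a known
omission, see Limitations). COTS consumption sums density × site area ×
per-starfish rate over eight age classes (the two youngest are
non-feeding) and is allocated between types proportionally to preference
weight × standing cover area with weights 14 (*Acropora*) and 4.3
(sub-massive), capped at the standing cover. The three hazards combine
multiplicatively within a year, which makes their order immaterial.

The bleaching and cyclone coefficients and the COTS consumption rates
ship as documented calibration placeholders: the functional forms and
their qualitative ordering are fixed and tested, but the numeric values
should be re-estimated against regional mortality data before any
management use.

## Synthetic data and what passing tests show

The generator emulates every input stream with known ground truth: site
tables with log-normal areas in the ~1–25 ha range across five reefs
(the scale of the case-study cluster the defaults mirror),
exponential-distance-decay connectivity with columns summing to
1 − loss, colony records drawn from exactly the statistical families the
fitting module assumes, and pulse disturbance schedules with fine-scale
heatwave fields whose reef means match the reef series by construction.
Default coral traits (fertilisation 0.75, settlement 0.10, first-year
survival 0.05–0.06) were chosen so that a closed *Acropora* site
recovers at ~3–5% cover yr⁻¹ toward its ceiling, the recovery regime
observed on mid-shelf reefs; they were fixed from that single
closed-site probe and not revisited.

Because the colony generator uses the fitted models' own error families,
parameter-recovery tests demonstrate correctness of the estimation
machinery, not robustness to real-world misspecification (measurement
error in photographed areas, overdispersed fecundity, temporal vital-rate
variation). Similarly the synthetic seascape has no real bathymetry or
hydrodynamics, so passing scenario tests show the model's internal logic
(habitat ceilings bind, disturbance signatures propagate, site variance
grows with heterogeneous K), not predictive skill on any actual reef.

## Numerical choices and problem sizes

- Kernel discretisation: 100 classes for production use; tests and the
  acceptance script use 20–60 classes and 5–10 bootstrap kernels per
  type, which keeps the full suite within a few minutes while exercising
  identical code paths.
- Parameter-recovery harness: 5,000 colonies per trial, bootstrap
  B = 100; the test runs 100 trials, the acceptance script 30.
- Eviction check tolerance 1e-10; logistic-reduction and
  operator-equivalence checks at 1e-12.
- Deterministic growth (spread → 0) places all mass in the class
  containing the predicted mean rather than evaluating a degenerate
  density.
- The reference-cluster contrast uses 5 reefs × 10 sites, 2008–2022,
  one category-2 cyclone in 2015, 5 replicates, site-specific K drawn
  from U(30, 90)% against the uniform-80% alternative.

## Limitations

- No colony–colony interaction or within-site spatial structure; the
  shared crowding term is the only competition.
- Cyclone exposure does not vary within a reef and mortality is
  size-independent.
- COTS densities are exogenous inputs; starfish population dynamics are
  not modelled.
- Environmental covariates do not enter the vital-rate regressions; the
  habitat ceiling K is a proxy for all of them.
- Connectivity matrices are inputs; the package averages and validates
  them but does not simulate larval transport.
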