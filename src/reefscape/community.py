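"""Density-dependent annual community dynamics at a single site.

Two coral-type populations share one site and one limiting resource:
benthic space. Total cover C (%) is computed from the size structure, the
remaining habitat fraction D = (K - C) / K modulates the intrinsic growth
operator of both types simultaneously, and each type's state vector is
advanced with the discrete logistic update

    N_{t+1} = N_t + D_t * r * N_t

where ``r`` is the kernel minus the identity. When cover overshoots the
habitat limit K, D is negative and the overshoot decays (optionally D can
be clamped at zero via ``clamp_density``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import SizeGrid
from .kernel import EGG, LARVA, N_DISCRETE, SETTLER

__all__ = ["SiteState", "coral_cover", "density_dependence", "step_community"]

CM2_PER_M2 = 1e4

GridLike = "SizeGrid | dict[str, SizeGrid]"


def _grid_for(grid, name: str) -> SizeGrid:
    """Resolve a per-type grid: a dict keyed by coral type or one shared grid."""
    return grid[name] if isinstance(grid, dict) else grid


@dataclass
class SiteState:
    """Per-site abundances for each coral type plus habitat attributes.

    ``abundance[type_name]`` is a vector over (egg, larva, settler, size
    classes); eggs/larvae/settlers occupy no benthic space and contribute
    nothing to cover.
    """

    site_id: str
    abundance: dict[str, np.ndarray]
    reference_area_m2: float
    K: float  # maximum coral habitat, % of reference area
    clipped_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.reference_area_m2 <= 0:
            raise ValueError(f"site {self.site_id}: reference area must be positive")
        if not 0.0 <= self.K <= 100.0:
            raise ValueError(f"site {self.site_id}: K must be in [0, 100]")
        self.abundance = {k: np.asarray(v, dtype=float).copy() for k, v in self.abundance.items()}
        for name, v in self.abundance.items():
            if np.any(~np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"site {self.site_id}, type {name}: abundances must be finite and >= 0")

    def copy(self) -> "SiteState":
        return SiteState(
            site_id=self.site_id,
            abundance={k: v.copy() for k, v in self.abundance.items()},
            reference_area_m2=self.reference_area_m2,
            K=self.K,
            clipped_mass=self.clipped_mass,
        )

    @staticmethod
    def empty(site_id: str, type_names: list[str], grid,
              reference_area_m2: float, K: float) -> "SiteState":
        return SiteState(
            site_id=site_id,
            abundance={
                t: np.zeros(N_DISCRETE + _grid_for(grid, t).n_classes) for t in type_names
            },
            reference_area_m2=reference_area_m2,
            K=K,
        )


def coral_cover(state: SiteState, grid, per_type: bool = False):
    """Total (or per-type) live coral cover as % of the site reference area.

    C = 100 * sum_ft sum_n N_{ft,n} * a_{ft,n} / reference_area; ``grid``
    may be one shared SizeGrid or a dict of per-type grids.
    """
    if state.reference_area_m2 <= 0:
        raise ValueError("reference area must be positive")
    ref_cm2 = state.reference_area_m2 * CM2_PER_M2
    covers: dict[str, float] = {}
    for name, vec in state.abundance.items():
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite abundance for type {name}")
        areas = _grid_for(grid, name).areas
        if vec.size - N_DISCRETE != areas.size:
            raise ValueError("state vector does not match grid")
        covers[name] = 100.0 * float(vec[N_DISCRETE:] @ areas) / ref_cm2
    if per_type:
        return covers
    return float(sum(covers.values()))


def density_dependence(K: float, C: float, clamp: bool = False) -> float:
    """Remaining-habitat fraction D = (K - C) / K.

    D = 1 with no coral, 0 at the habitat limit, and negative when cover
    overshoots K (overshoot then decays). Sites with K <= 0 support no
    growth (D = 0).
    """
    if K <= 0:
        return 0.0
    D = (K - C) / K
    if clamp:
        D = max(D, 0.0)
    return float(D)


def step_community(
    state: SiteState,
    growth_ops: dict[str, np.ndarray],
    grid,
    clamp_density: bool = False,
) -> SiteState:
    """Advance one site one year under shared density dependence.

    A single D is computed from *total* community cover before either type
    is updated (both types draw on the same space), then each type's vector
    is advanced by ``N + D * r @ N``. Egg production (the egg row of ``r``)
    accrues to the egg pool; settlers feed the smallest size class through
    the kernel's discrete chain. Negative abundances produced by a negative
    D are floored at zero and the clipped mass is accumulated on the state.
    """
    C = coral_cover(state, grid)
    D = density_dependence(state.K, C, clamp=clamp_density)
    new = state.copy()
    clipped = 0.0
    for name, vec in state.abundance.items():
        r = growth_ops[name]
        if r.shape[0] != vec.size:
            raise ValueError(f"growth operator for {name} does not match state dimension")
        nxt = vec + D * (r @ vec)
        neg = nxt < 0
        if np.any(neg):
            clipped += float(-nxt[neg].sum())
            nxt[neg] = 0.0
        new.abundance[name] = nxt
    new.clipped_mass = state.clipped_mass + clipped
    return new
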