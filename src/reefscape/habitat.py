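"""Map-derived coral habitat limits and site partitioning.

Benthic habitat maps classify each 10 m pixel by its dominant benthic
category — Sand, Rubble, Rock or Coral/Algae — with Rock and Coral/Algae
counted as suitable coral habitat. Because a dominant label only bounds
the within-pixel composition (the dominant category covers 26-100% of the
pixel, each other category at most 25%), the habitat limit K of a site is
estimated by replicate Monte-Carlo sampling of within-pixel fractions.

Rasters are handled as plain tabular grids (one row per pixel: row, col,
benthic class, optional geomorphic zone), so no geospatial stack is
required; pixel centroids in metres follow from the pixel edge length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "BENTHIC_CLASSES",
    "SUITABLE_CLASSES",
    "HARD_SUBSTRATE_ZONES",
    "SiteHabitat",
    "compute_coral_habitat",
    "partition_sites",
    "substrate_area_3d",
]

BENTHIC_CLASSES = ("Sand", "Rubble", "Rock", "CoralAlgae")
SUITABLE_CLASSES = ("Rock", "CoralAlgae")

#: geomorphic zones assumed to be predominantly hard substrate; only these
#: are partitioned into sites and simulated, all others carry K = 0.
HARD_SUBSTRATE_ZONES = ("Slope", "ShelteredSlope", "Crest", "OuterFlat")

DOMINANT_RANGE = (0.26, 1.00)
NON_DOMINANT_RANGE = (0.0, 0.25)


@dataclass(frozen=True)
class SiteHabitat:
    """Monte-Carlo habitat summary for one site."""

    site_id: str
    K_mean: float  # %
    K_se: float  # %
    planar_area_m2: float
    substrate_area_3d_m2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.K_mean <= 100.0:
            raise ValueError("K_mean must be in [0, 100]")
        if self.K_se < 0:
            raise ValueError("K_se must be >= 0")


def _replicate_suitable_fraction(
    dominant: np.ndarray,
    rng: np.random.Generator,
    n_reps: int,
    renormalise: bool,
    dominant_range: tuple[float, float],
    non_dominant_range: tuple[float, float],
) -> np.ndarray:
    """Per-replicate, per-pixel suitable (Rock + Coral/Algae) fraction.

    ``dominant`` holds each pixel's dominant-class index into
    BENTHIC_CLASSES. Returns an (n_reps, n_pixels) array.
    """
    n_pix = dominant.size
    # fractions[rep, pixel, class]
    lo, hi = non_dominant_range
    fr = rng.uniform(lo, hi, size=(n_reps, n_pix, 4))
    dlo, dhi = dominant_range
    dom_draw = rng.uniform(dlo, dhi, size=(n_reps, n_pix))
    idx = np.arange(n_pix)
    fr[:, idx, dominant] = dom_draw
    if renormalise:
        fr = fr / fr.sum(axis=2, keepdims=True)
    else:
        fr = np.minimum(fr, 1.0)
    suit = np.zeros((n_reps, n_pix))
    for cls in SUITABLE_CLASSES:
        suit += fr[:, :, BENTHIC_CLASSES.index(cls)]
    return np.minimum(suit, 1.0)


def compute_coral_habitat(
    pixels: pd.DataFrame,
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
    site_id: str = "site",
    pixel_edge_m: float = 10.0,
    mean_slope_deg: float = 0.0,
    renormalise: bool = True,
    dominant_range: tuple[float, float] = DOMINANT_RANGE,
    non_dominant_range: tuple[float, float] = NON_DOMINANT_RANGE,
) -> SiteHabitat:
    """Estimate the maximum coral habitat K (%) of one site's pixels.

    Each replicate draws, for every pixel, a within-pixel fraction for the
    dominant category from U(0.26, 1.00) and for each non-dominant category
    from U(0, 0.25); the fractions are renormalised to sum to one (pixel
    composition is compositional) and the Rock + Coral/Algae share is the
    pixel's suitable fraction. The replicate's K is the area-weighted mean
    suitable fraction x 100; K_mean and K_se summarise the replicates.
    """
    if len(pixels) == 0:
        raise ValueError("compute_coral_habitat needs at least one pixel")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    classes = pixels["benthic_class"].astype(str)
    unknown = set(classes) - set(BENTHIC_CLASSES)
    if unknown:
        raise ValueError(f"unknown benthic classes: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dominant = np.array([BENTHIC_CLASSES.index(c) for c in classes])
    suit = _replicate_suitable_fraction(
        dominant, rng, n_reps, renormalise, dominant_range, non_dominant_range
    )
    if "pixel_area_m2" in pixels.columns:
        w = pixels["pixel_area_m2"].to_numpy(dtype=float)
    else:
        w = np.full(len(pixels), pixel_edge_m**2)
    K_reps = 100.0 * (suit @ w) / w.sum()
    K_mean = float(np.mean(K_reps))
    K_se = float(np.std(K_reps, ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    planar = float(w.sum())
    return SiteHabitat(
        site_id=site_id,
        K_mean=min(K_mean, 100.0),
        K_se=K_se,
        planar_area_m2=planar,
        substrate_area_3d_m2=substrate_area_3d(planar, mean_slope_deg),
    )


def partition_sites(
    pixels: pd.DataFrame,
    max_diameter_m: float = 1000.0,
    pixel_edge_m: float = 10.0,
) -> pd.Series:
    """Partition hard-substrate pixels into sites of bounded diameter.

    Within each hard-substrate geomorphic zone, pixel centroids are
    agglomerated by complete linkage on Euclidean distance and the tree is
    cut at ``max_diameter_m``, which guarantees every site's largest
    pairwise pixel distance stays within the cut. Sites never mix zones and
    may be spatially discontiguous. Returns a site-id Series aligned to
    ``pixels`` (NaN for pixels in non-modelled zones).
    """
    if "zone" not in pixels.columns:
        raise ValueError("partition_sites needs a 'zone' column")
    out = pd.Series(pd.NA, index=pixels.index, dtype="object")
    any_hard = False
    for zone, sub in pixels.groupby("zone"):
        if zone not in HARD_SUBSTRATE_ZONES:
            continue
        any_hard = True
        xy = sub[["col", "row"]].to_numpy(dtype=float) * pixel_edge_m
        if len(sub) == 1:
            labels = np.array([1])
        else:
            Z = linkage(pdist(xy), method="complete")
            labels = fcluster(Z, t=max_diameter_m, criterion="distance")
        out.loc[sub.index] = [f"{zone}-{int(l):03d}" for l in labels]
    if not any_hard:
        import warnings

        warnings.warn("no hard-substrate pixels; empty partition", stacklevel=2)
    return out


def substrate_area_3d(planar_area_m2: float, mean_slope_deg: float) -> float:
    """Three-dimensional substrate area on a sloping seabed.

    area_3d = planar_area / cos(slope); a 60 degree slope doubles the
    substrate available to corals relative to the planar footprint.
    """
    if planar_area_m2 < 0:
        raise ValueError("planar area must be >= 0")
    if not 0.0 <= mean_slope_deg < 90.0:
        raise ValueError("mean slope must be in [0, 90) degrees")
    return float(planar_area_m2 / np.cos(np.deg2rad(mean_slope_deg)))
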