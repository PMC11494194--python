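"""Trajectory summaries: recovery windows, time-averaged annual change in
cover, grouped aggregation, and state initialisation from observed cover.

Trajectories are tidy frames with columns (replicate, site_id, reef, year,
cover_pct) plus optional grouping labels (sector). The time-averaged
annual change in cover over a disturbance-free window is the endpoint
difference divided by the window span, in percentage points of cover per
year (a regression-slope mode is available for noisy series).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .community import SiteState, coral_cover
from .demography import SizeGrid
from .disturbance import DisturbanceSchedule
from .kernel import N_DISCRETE, IPMKernel

__all__ = [
    "recovery_windows",
    "annual_change",
    "aggregate",
    "initialise_from_cover",
]


def recovery_windows(
    schedule: DisturbanceSchedule,
    min_span: int = 2,
    dhw_threshold: float = 4.0,
    cots_threshold: float = 0.01,
    reef: str | None = None,
) -> list[tuple[int, int]]:
    """Maximal disturbance-free year intervals spanning at least ``min_span`` years.

    A year is disturbed if any (or the chosen) reef records a cyclone of
    category >= 1, a DHW maximum above ``dhw_threshold`` degC-weeks, or a
    total COTS density above ``cots_threshold`` starfish m^-2. Windows are
    runs of consecutive clean years [start, end] with end - start >= min_span.
    """
    t = schedule.table
    if reef is not None:
        t = t[t["reef"] == reef]
    cots_cols = schedule.cots_columns()
    cots_total = t[cots_cols].sum(axis=1) if cots_cols else pd.Series(0.0, index=t.index)
    disturbed_rows = (
        (t["cyclone_category"] >= 1)
        | (t["dhw_max"] > dhw_threshold)
        | (cots_total > cots_threshold)
    )
    disturbed_years = set(t.loc[disturbed_rows, "year"].astype(int))
    years = sorted(t["year"].astype(int).unique())
    windows: list[tuple[int, int]] = []
    start: int | None = None
    prev: int | None = None
    for y in years:
        clean = y not in disturbed_years
        contiguous = prev is not None and y == prev + 1
        if clean and (start is None or not contiguous):
            start = y
        elif not clean:
            if start is not None and prev is not None and prev - start >= min_span:
                windows.append((start, prev))
            start = None
        prev = y
    if start is not None and prev is not None and prev - start >= min_span:
        windows.append((start, prev))
    return windows


def annual_change(
    trajectory: pd.DataFrame,
    window: tuple[int, int],
    mode: str = "endpoint",
) -> float:
    """Time-averaged annual change in cover over a window, % cover yr^-1.

    ``trajectory`` needs columns (year, cover_pct) for one series. The
    default endpoint mode is (C_end - C_start) / (end - start); ``mode=
    'slope'`` fits a least-squares line through all years in the window.
    """
    start, end = window
    if end <= start:
        raise ValueError("window must span at least one year")
    t = trajectory.set_index("year")["cover_pct"]
    if start not in t.index or end not in t.index:
        raise ValueError(f"window {window} not covered by trajectory years")
    if mode == "endpoint":
        return float((t.loc[end] - t.loc[start]) / (end - start))
    if mode == "slope":
        sub = t.loc[start:end]
        slope = np.polyfit(sub.index.to_numpy(dtype=float), sub.to_numpy(dtype=float), 1)[0]
        return float(slope)
    raise ValueError(f"unknown mode {mode!r}")


def aggregate(
    trajectories: pd.DataFrame,
    grouping: str = "reef",
    weights: str = "equal",
    area_col: str = "area_m2",
) -> pd.DataFrame:
    """Summarise site trajectories by group and year.

    Site covers are first averaged (optionally area-weighted) within each
    group per replicate; the replicate-level group means are then
    summarised across replicates (mean, sd, n). Columns in: (replicate,
    year, cover_pct, <grouping>[, area_m2]). Empty groups are dropped with
    a warning.
    """
    if grouping not in trajectories.columns:
        raise ValueError(f"no grouping column {grouping!r}")
    df = trajectories.dropna(subset=[grouping])
    dropped = set(trajectories[grouping].dropna().unique()) ^ set(df[grouping].unique())
    if len(df) < len(trajectories):
        warnings.warn("rows without group labels omitted from aggregation", stacklevel=2)
    if weights == "equal":
        rep = df.groupby([grouping, "replicate", "year"])["cover_pct"].mean()
    elif weights == "area":
        if area_col not in df.columns:
            raise ValueError(f"area weighting needs column {area_col!r}")

        def _wmean(g: pd.DataFrame) -> float:
            w = g[area_col].to_numpy(dtype=float)
            return float(np.average(g["cover_pct"], weights=w))

        rep = df.groupby([grouping, "replicate", "year"]).apply(_wmean, include_groups=False)
        rep.name = "cover_pct"
    else:
        raise ValueError(f"unknown weights {weights!r}")
    out = rep.groupby([grouping, "year"]).agg(["mean", "std", "count"]).reset_index()
    out = out.rename(columns={"mean": "cover_mean", "std": "cover_sd", "count": "n_replicates"})
    out["cover_sd"] = out["cover_sd"].fillna(0.0)
    _ = dropped
    return out


def initialise_from_cover(
    target_cover_pct: float,
    kernels: dict[str, IPMKernel],
    site_id: str,
    reference_area_m2: float,
    K: float,
    type_split: dict[str, float] | None = None,
) -> SiteState:
    """Build a site state at a prescribed total cover.

    Each type's size structure is the stable size distribution of its
    survival-growth kernel (dominant right eigenvector), scaled so the
    summed community cover equals ``target_cover_pct``; the target is
    split between types per ``type_split`` (default equal shares).
    Egg/larva/settler pools start empty.
    """
    if not 0.0 <= target_cover_pct <= 100.0:
        raise ValueError("target cover must be in [0, 100]")
    names = list(kernels)
    if type_split is None:
        type_split = {t: 1.0 / len(names) for t in names}
    if abs(sum(type_split.values()) - 1.0) > 1e-9:
        raise ValueError("type split fractions must sum to 1")
    grids = {t: kernels[t].grid for t in names}
    state = SiteState.empty(site_id, names, grids, reference_area_m2, K)
    ref_cm2 = reference_area_m2 * 1e4
    for t in names:
        share = target_cover_pct * type_split[t]
        if share == 0:
            continue
        w = kernels[t].stable_size_distribution()
        area_per_unit = float(w @ grids[t].areas)  # cm^2 of cover per unit abundance
        scale = share / 100.0 * ref_cm2 / area_per_unit
        state.abundance[t][N_DISCRETE:] = scale * w
    return state
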