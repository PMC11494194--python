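"""Vital-rate regressions and size discretisation for coral colonies.

Colony planar area (cm^2) is the continuous state of the population model.
All regressions are carried out on ``log10(area)``: growth is a linear model
of log-area at ``t+1`` on log-area at ``t`` with constant log-scale spread
(log-normal error), survival is a logistic regression of the binary outcome
on log-area, and fecundity is the product of two Poisson regressions
(eggs per polyp, polyps per cm^2) times colony area.

The fitting engine is maximum likelihood (statsmodels) with a nonparametric
bootstrap for uncertainty; ``bootstrap_vital_rates`` draws whole-record
resamples so that replicate projection kernels can be assembled from
resampled fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SizeGrid",
    "GrowthModel",
    "SurvivalModel",
    "FecundityModel",
    "VitalRates",
    "build_size_grid",
    "fit_growth",
    "fit_survival",
    "fit_fecundity",
    "fit_vital_rates",
    "bootstrap_vital_rates",
]

#: planar area (cm^2) of a circular colony 1 cm in diameter — the smallest
#: colony tracked by the size grid.
MIN_COLONY_AREA_CM2 = float(np.pi * 0.5**2)

#: fraction of the largest observed colony taken as the upper grid bound.
UPPER_BOUND_FRACTION = 0.9

# survival probability clamp for degenerate (all-alive / all-dead) data
_SURVIVAL_CLAMP = (0.001, 0.999)


@dataclass(frozen=True)
class SizeGrid:
    """Discretisation of colony planar area into size classes.

    Class edges are log-spaced between the area of a 1 cm diameter colony
    and ``UPPER_BOUND_FRACTION`` of the largest observed colony; the
    representative area of each class is the geometric midpoint of its edges.
    """

    bounds: np.ndarray  # (n_classes + 1,) class edges, cm^2
    areas: np.ndarray  # (n_classes,) representative areas, cm^2

    def __post_init__(self) -> None:
        bounds = np.asarray(self.bounds, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "bounds", bounds)
        object.__setattr__(self, "areas", areas)
        if bounds.ndim != 1 or areas.ndim != 1 or bounds.size != areas.size + 1:
            raise ValueError("bounds must have one more entry than areas")
        if not np.all(np.diff(bounds) > 0):
            raise ValueError("class bounds must be strictly increasing")
        if not np.all(np.diff(areas) > 0):
            raise ValueError("representative areas must be strictly increasing")
        if not (np.all(areas > bounds[:-1]) and np.all(areas < bounds[1:])):
            raise ValueError("each representative area must lie inside its class")

    @property
    def n_classes(self) -> int:
        return self.areas.size

    @property
    def log_bounds(self) -> np.ndarray:
        return np.log10(self.bounds)


def build_size_grid(max_observed_area: float, n_classes: int = 100) -> SizeGrid:
    """Build a log-spaced size grid from 1 cm diameter up to 90% of the
    largest observed colony area.

    Parameters
    ----------
    max_observed_area : float
        Largest colony planar area in the demographic dataset, cm^2.
    n_classes : int
        Number of size classes (default 100).
    """
    if not np.isfinite(max_observed_area) or max_observed_area <= 0:
        raise ValueError("max_observed_area must be a positive, finite area")
    upper = UPPER_BOUND_FRACTION * float(max_observed_area)
    if upper <= MIN_COLONY_AREA_CM2:
        raise ValueError(
            "max_observed_area too small: 90% of it must exceed the area of "
            f"a 1 cm diameter colony ({MIN_COLONY_AREA_CM2:.4f} cm^2)"
        )
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    bounds = np.logspace(np.log10(MIN_COLONY_AREA_CM2), np.log10(upper), n_classes + 1)
    areas = np.sqrt(bounds[:-1] * bounds[1:])  # geometric midpoints
    return SizeGrid(bounds=bounds, areas=areas)


@dataclass(frozen=True)
class GrowthModel:
    """Log-normal growth: log10(area_{t+1}) ~ Normal(intercept + slope*log10(area_t), sd)."""

    intercept: float
    slope: float
    sd: float

    def mean_log10(self, area: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(area, dtype=float))

    def predict_mean_area(self, area: np.ndarray) -> np.ndarray:
        """Median of the predicted area distribution (cm^2)."""
        return 10.0 ** self.mean_log10(area)


@dataclass(frozen=True)
class SurvivalModel:
    """Logistic survival: logit P(survive) = intercept + slope*log10(area)."""

    intercept: float
    slope: float
    constant: float | None = None  # set for degenerate all-alive/all-dead fits

    def prob(self, area: np.ndarray) -> np.ndarray:
        area = np.asarray(area, dtype=float)
        if self.constant is not None:
            return np.full(area.shape, self.constant)
        eta = self.intercept + self.slope * np.log10(area)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class FecundityModel:
    """Egg output as eggs-per-polyp x polyps-per-cm^2 x colony area.

    Both factors are log-link Poisson regressions on log10(area).
    """

    epp_intercept: float
    epp_slope: float
    ppc_intercept: float
    ppc_slope: float

    def eggs_per_polyp(self, area: np.ndarray) -> np.ndarray:
        la = np.log10(np.asarray(area, dtype=float))
        return np.exp(self.epp_intercept + self.epp_slope * la)

    def polyps_per_cm2(self, area: np.ndarray) -> np.ndarray:
        la = np.log10(np.asarray(area, dtype=float))
        return np.exp(self.ppc_intercept + self.ppc_slope * la)

    def eggs(self, area: np.ndarray) -> np.ndarray:
        area = np.asarray(area, dtype=float)
        return self.eggs_per_polyp(area) * self.polyps_per_cm2(area) * area


@dataclass(frozen=True)
class VitalRates:
    growth: GrowthModel
    survival: SurvivalModel
    fecundity: FecundityModel
    max_observed_area: float = field(default=np.nan)


def _paired_growth_records(records: pd.DataFrame) -> pd.DataFrame:
    sub = records.dropna(subset=["area_t_cm2", "area_t1_cm2"])
    sub = sub[(sub["area_t_cm2"] > 0) & (sub["area_t1_cm2"] > 0)]
    return sub


def fit_growth(records: pd.DataFrame) -> GrowthModel:
    """OLS of log10(area_{t+1}) on log10(area_t); residual sd is the spread."""
    sub = _paired_growth_records(records)
    x = np.log10(sub["area_t_cm2"].to_numpy(dtype=float))
    y = np.log10(sub["area_t1_cm2"].to_numpy(dtype=float))
    if np.unique(x).size < 2:
        raise ValueError("growth fit needs at least 2 distinct colony sizes")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.scale))
    if not np.isfinite(resid_sd):
        resid_sd = 0.0
    return GrowthModel(intercept=float(res.params[0]), slope=float(res.params[1]), sd=resid_sd)


def fit_survival(records: pd.DataFrame) -> SurvivalModel:
    """Logistic regression of survival (0/1) on log10(area_t).

    If every record has the same outcome the logit is unbounded; the model
    falls back to a constant probability clamped to [0.001, 0.999].
    """
    sub = records.dropna(subset=["area_t_cm2", "survived"])
    sub = sub[sub["area_t_cm2"] > 0]
    y = sub["survived"].to_numpy(dtype=float)
    x = np.log10(sub["area_t_cm2"].to_numpy(dtype=float))
    if y.size == 0:
        raise ValueError("no survival records")
    lo, hi = _SURVIVAL_CLAMP
    if np.all(y == y[0]):
        p = float(np.clip(y[0], lo, hi))
        return SurvivalModel(intercept=0.0, slope=0.0, constant=p)
    X = sm.add_constant(x)
    res = sm.Logit(y, X).fit(disp=0)
    return SurvivalModel(intercept=float(res.params[0]), slope=float(res.params[1]))


def fit_fecundity(records: pd.DataFrame) -> FecundityModel:
    """Poisson regressions for eggs-per-polyp and polyps-per-cm^2 on log10(area)."""

    def _poisson(sub: pd.DataFrame, col: str) -> tuple[float, float]:
        counts = sub[col].to_numpy(dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"negative counts in {col}")
        x = np.log10(sub["area_t_cm2"].to_numpy(dtype=float))
        X = sm.add_constant(x)
        if np.all(counts == 0):
            return -np.inf, 0.0  # exp(-inf) = 0 everywhere
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        return float(res.params[0]), float(res.params[1])

    epp = records.dropna(subset=["area_t_cm2", "eggs_per_polyp"])
    epp = epp[epp["area_t_cm2"] > 0]
    ppc = records.dropna(subset=["area_t_cm2", "polyps_per_cm2"])
    ppc = ppc[ppc["area_t_cm2"] > 0]
    if epp.empty or ppc.empty:
        raise ValueError("fecundity fit needs eggs_per_polyp and polyps_per_cm2 records")
    e0, e1 = _poisson(epp, "eggs_per_polyp")
    p0, p1 = _poisson(ppc, "polyps_per_cm2")
    return FecundityModel(epp_intercept=e0, epp_slope=e1, ppc_intercept=p0, ppc_slope=p1)


def fit_vital_rates(records: pd.DataFrame) -> VitalRates:
    """Fit growth, survival and fecundity models to one coral type's records."""
    growth = fit_growth(records)
    survival = fit_survival(records)
    fecundity = fit_fecundity(records)
    areas = pd.concat([records["area_t_cm2"], records.get("area_t1_cm2")]).dropna()
    max_area = float(areas.max()) if len(areas) else np.nan
    return VitalRates(growth=growth, survival=survival, fecundity=fecundity,
                      max_observed_area=max_area)


def bootstrap_vital_rates(
    records: pd.DataFrame,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> list[VitalRates]:
    """Nonparametric bootstrap of the vital-rate fits.

    Resamples whole records with replacement ``n_boot`` times and refits all
    three models each time. Deterministic given ``rng``.
    """
    if len(records) < 30:
        raise ValueError("bootstrap needs at least 30 colony records")
    rng = np.random.default_rng() if rng is None else rng
    out: list[VitalRates] = []
    n = len(records)
    attempts = 0
    while len(out) < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise RuntimeError("bootstrap failed to produce enough valid refits")
        idx = rng.integers(0, n, size=n)
        sample = records.iloc[idx].reset_index(drop=True)
        try:
            out.append(fit_vital_rates(sample))
        except (ValueError, np.linalg.LinAlgError):
            continue  # degenerate resample (e.g. one distinct size): redraw
    return out


def bootstrap_se(fits: list[VitalRates]) -> dict[str, float]:
    """Bootstrap standard errors of the main vital-rate parameters."""
    arr = {
        "growth_intercept": [f.growth.intercept for f in fits],
        "growth_slope": [f.growth.slope for f in fits],
        "growth_sd": [f.growth.sd for f in fits],
        "survival_intercept": [f.survival.intercept for f in fits],
        "survival_slope": [f.survival.slope for f in fits],
        "epp_intercept": [f.fecundity.epp_intercept for f in fits],
        "epp_slope": [f.fecundity.epp_slope for f in fits],
        "ppc_intercept": [f.fecundity.ppc_intercept for f in fits],
        "ppc_slope": [f.fecundity.ppc_slope for f in fits],
    }
    return {k: float(np.std(v, ddof=1)) for k, v in arr.items()}
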