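"""Derived map products: prevalence surfaces, correlation surfaces, age profiles.

A fitted model is turned into pixel-level summaries: for each grid pixel the
14 predictors are evaluated at the pixel covariates (at a fixed reference year
and age), the implied (mu, Sigma, rho) reconstructed, and the five indicator
prevalences plus the six pairwise correlations summarised over posterior
draws (mean and equal-tailed 95% interval).

Pixels classed as Barren or Permanent Snow and Ice, and pixels above 3000 m,
are flagged as not included and carry no derived values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distribution import RESPONSES, CholeskyFactors, mvn_params, threshold_probability
from .fitting import FitResult
from .simulate import ANEMIA_CUTOFF, Z_CUT, CovariateFields

EARTH_RADIUS_KM = 6371.0
#: Grid step in decimal degrees approximating 20 km pixels at the equator.
DEFAULT_PIXEL_DEG = 0.18

CORR_PAIRS = [
    (i, j) for i in range(len(RESPONSES)) for j in range(i + 1, len(RESPONSES))
]
CORR_NAMES = [f"rho_{RESPONSES[i]}_{RESPONSES[j]}" for i, j in CORR_PAIRS]


@dataclass(frozen=True)
class IndicatorDefinition:
    """A clinical threshold on one Gaussian margin."""

    name: str
    response: str
    cut: float
    tail: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.tail not in ("below", "above"):
            raise ValueError("tail must be 'below' or 'above'")


def default_indicators(overweight_on: str = "waz") -> list[IndicatorDefinition]:
    """Anemia, stunting, underweight, wasting and overweight definitions.

    Overweight defaults to P(WAZ > 2); the weight-for-height convention is
    available via ``overweight_on='whz'``.
    """
    if overweight_on not in ("waz", "whz"):
        raise ValueError("overweight_on must be 'waz' or 'whz'")
    return [
        IndicatorDefinition("anemia", "hb", ANEMIA_CUTOFF, "below"),
        IndicatorDefinition("stunting", "haz", -Z_CUT, "below"),
        IndicatorDefinition("underweight", "waz", -Z_CUT, "below"),
        IndicatorDefinition("wasting", "whz", -Z_CUT, "below"),
        IndicatorDefinition("overweight", overweight_on, Z_CUT, "above"),
    ]


def make_prediction_grid(
    bbox: tuple[float, float, float, float],
    fields: CovariateFields,
    step: float = DEFAULT_PIXEL_DEG,
) -> pd.DataFrame:
    """Regular pixel-centre grid over the bbox with covariates from ``fields``."""
    lon0, lon1, lat0, lat1 = bbox
    lons = np.arange(lon0 + step / 2, lon1, step)
    lats = np.arange(lat0 + step / 2, lat1, step)
    gx, gy = np.meshgrid(lons, lats)
    grid = fields.evaluate(gx.ravel(), gy.ravel())
    grid.insert(0, "pixel_id", np.arange(len(grid)))
    grid["pixel_size_km"] = step * 111.2
    return grid


def mask_pixels(grid: pd.DataFrame) -> pd.DataFrame:
    """Assign exclusion flags: barren, snow_ice, elevation above 3000 m.

    Pixels with missing elevation get a distinct ``missing_elevation`` reason;
    all remaining pixels are ``ok``.
    """
    grid = grid.copy()
    reasons = np.full(len(grid), "ok", dtype=object)
    land = grid.get("land_cover", pd.Series(["" for _ in range(len(grid))])).astype(str)
    elev = pd.to_numeric(grid.get("elevation", np.nan), errors="coerce")
    reasons[(elev > 3000.0).to_numpy()] = "elevation_gt_3000"
    # land-cover reasons take precedence when a pixel matches several rules
    reasons[land.to_numpy() == "Barren"] = "barren"
    reasons[land.to_numpy() == "Permanent Snow and Ice"] = "snow_ice"
    reasons[elev.isna().to_numpy()] = "missing_elevation"
    grid["mask"] = reasons
    return grid


def _summaries_over_draws(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        return mean, mean, mean
    lo, hi = np.quantile(stack, [0.025, 0.975], axis=0)
    return mean, lo, hi


def predict_grid(
    fit: FitResult,
    grid: pd.DataFrame,
    year: int,
    age_months: float,
    indicators: list[IndicatorDefinition] | None = None,
    max_draws: int = 100,
    extra_covariates: dict | None = None,
) -> pd.DataFrame:
    """Per-pixel prevalence and pairwise-correlation summaries.

    Unmasked pixels are evaluated at their covariates with ``age`` and
    ``year`` fixed; covariates the model needs but the grid lacks (e.g. a
    reference sex or wealth level) are supplied via ``extra_covariates``.
    Returns a long-format table: one row per (pixel, quantity) with posterior
    mean and equal-tailed 95% interval.  Masked pixels appear with their mask
    reason and no values.
    """
    indicators = indicators if indicators is not None else default_indicators()
    if "mask" not in grid.columns:
        grid = mask_pixels(grid)
    ok = grid[grid["mask"] == "ok"].copy()
    ok["age"] = float(age_months)
    ok["year"] = float(year)
    for key, val in (extra_covariates or {}).items():
        ok[key] = val

    ridx = {r: m for m, r in enumerate(RESPONSES)}
    rows: list[dict] = []
    if len(ok):
        prev_stack: list[np.ndarray] = []
        corr_stack: list[np.ndarray] = []
        for mu, lam, phi in fit.param_draws(ok, max_draws=max_draws):
            params = mvn_params(mu, CholeskyFactors(phi=phi, lam=lam))
            prev = np.column_stack(
                [
                    threshold_probability(
                        params.mu[:, ridx[ind.response]],
                        params.sd[:, ridx[ind.response]],
                        ind.cut,
                        ind.tail,
                    )
                    for ind in indicators
                ]
            )
            corr = np.column_stack([params.rho[:, i, j] for i, j in CORR_PAIRS])
            prev_stack.append(prev)
            corr_stack.append(corr)
        names = [ind.name for ind in indicators] + CORR_NAMES
        values = np.concatenate([np.asarray(prev_stack), np.asarray(corr_stack)], axis=2)
        mean, lo, hi = _summaries_over_draws(values)
        for q, name in enumerate(names):
            for p in range(len(ok)):
                rows.append(
                    {
                        "pixel_id": ok["pixel_id"].iloc[p] if "pixel_id" in ok else p,
                        "lon": ok["lon"].iloc[p],
                        "lat": ok["lat"].iloc[p],
                        "year": year,
                        "age": age_months,
                        "quantity": name,
                        "mean": mean[p, q],
                        "lower95": lo[p, q],
                        "upper95": hi[p, q],
                        "mask": "ok",
                    }
                )
    for _, px in grid[grid["mask"] != "ok"].iterrows():
        rows.append(
            {
                "pixel_id": px.get("pixel_id", np.nan),
                "lon": px["lon"],
                "lat": px["lat"],
                "year": year,
                "age": age_months,
                "quantity": "not_included",
                "mean": np.nan,
                "lower95": np.nan,
                "upper95": np.nan,
                "mask": px["mask"],
            }
        )
    return pd.DataFrame(rows)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in kilometres."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, float)) for v in (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def buffer_reference_row(
    survey: pd.DataFrame, lon: float, lat: float, buffer_km: float = 20.0
) -> pd.DataFrame:
    """Reference covariates near a location: within-buffer median / mode.

    Numeric covariates are fixed at the median observed within the buffer,
    categorical covariates at the mode (ties broken by the first sorted
    level).  Raises if no observation falls inside the buffer.
    """
    d = haversine_km(survey["lon"], survey["lat"], lon, lat)
    sub = survey[d <= buffer_km]
    if sub.empty:
        raise ValueError(
            f"no observations within {buffer_km} km of ({lon}, {lat}); "
            "increase the buffer radius"
        )
    ref: dict = {"lon": lon, "lat": lat}
    skip = set(RESPONSES) | {"lon", "lat", "child_id", "cluster_id"}
    for col in sub.columns:
        if col in skip:
            continue
        if pd.api.types.is_numeric_dtype(sub[col]):
            ref[col] = float(sub[col].median())
        else:
            counts = sub[col].astype(str).value_counts()
            top = counts[counts == counts.max()].index
            ref[col] = sorted(top)[0]
    return pd.DataFrame([ref])


def age_profile(
    fit: FitResult,
    location: tuple[float, float],
    survey: pd.DataFrame,
    buffer_km: float = 20.0,
    age_grid: np.ndarray | None = None,
    indicators: list[IndicatorDefinition] | None = None,
    max_draws: int = 100,
) -> pd.DataFrame:
    """Prevalence and correlation curves over age at one location.

    All covariates other than age are fixed at the within-buffer median (mode
    for categoricals) around ``location``; age runs over ``age_grid``
    (default 6..59 months).
    """
    indicators = indicators if indicators is not None else default_indicators()
    ages = np.arange(6, 60, dtype=float) if age_grid is None else np.asarray(age_grid, float)
    lon, lat = location
    ref = buffer_reference_row(survey, lon, lat, buffer_km)
    frame = ref.loc[ref.index.repeat(len(ages))].reset_index(drop=True)
    frame["age"] = ages
    ridx = {r: m for m, r in enumerate(RESPONSES)}
    prev_stack, corr_stack = [], []
    for mu, lam, phi in fit.param_draws(frame, max_draws=max_draws):
        params = mvn_params(mu, CholeskyFactors(phi=phi, lam=lam))
        prev_stack.append(
            np.column_stack(
                [
                    threshold_probability(
                        params.mu[:, ridx[ind.response]],
                        params.sd[:, ridx[ind.response]],
                        ind.cut,
                        ind.tail,
                    )
                    for ind in indicators
                ]
            )
        )
        corr_stack.append(np.column_stack([params.rho[:, i, j] for i, j in CORR_PAIRS]))
    names = [ind.name for ind in indicators] + CORR_NAMES
    values = np.concatenate([np.asarray(prev_stack), np.asarray(corr_stack)], axis=2)
    mean, lo, hi = _summaries_over_draws(values)
    rows = []
    for q, name in enumerate(names):
        for a, age in enumerate(ages):
            rows.append(
                {
                    "lon": lon,
                    "lat": lat,
                    "age": age,
                    "quantity": name,
                    "mean": mean[a, q],
                    "lower95": lo[a, q],
                    "upper95": hi[a, q],
                }
            )
    return pd.DataFrame(rows)
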