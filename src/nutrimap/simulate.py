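"""Synthetic DHS-like survey generator.

Emulates the statistical structure of a multi-country household survey of
children aged 6-59 months: clustered spatial sampling (primary sampling
units), smooth environmental covariate fields sampled at cluster sites, a
spatially graded wealth index, and a four-dimensional Gaussian response
(Hb, HAZ, WAZ, WHZ) whose 14 distributional parameters depend on configured
covariate effects.  Ground-truth parameter tables are returned alongside the
survey so every downstream estimator can be scored against the generative
model.

Environmental fields use a fixed low-rank random-cosine expansion (a random
Fourier feature approximation to a Gaussian process) so that evaluation at any
coordinate is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import (
    PARAM_LABELS,
    RESPONSES,
    CholeskyFactors,
    mvn_params,
    pack_params,
    sample as sample_mvn,
    sigma_to_factors,
    threshold_probability,
    unpack_params,
)

#: WHO anemia cutoff for children 6-59 months (g/L) and z-score cutoffs.
ANEMIA_CUTOFF = 110.0
Z_CUT = 2.0
AGE_RANGE = (6, 59)

SCHEMA = [
    "child_id",
    "cluster_id",
    "lon",
    "lat",
    "age",
    "sex",
    "wealth_code",
    "year",
    "temperature",
    "malaria_incidence",
    "elevation",
    "land_cover",
    "hb",
    "haz",
    "waz",
    "whz",
]


class RandomCosineField:
    """Smooth stationary random field f(s) = amp * sqrt(2/K) sum_k cos(w_k.s + b_k).

    Frequencies are Gaussian with scale 1/lengthscale, giving an approximate
    squared-exponential covariance with unit marginal variance times amp**2.
    """

    def __init__(self, amplitude: float, lengthscale: float, seed, n_features: int = 64):
        rng = np.random.default_rng(seed)
        self.amplitude = float(amplitude)
        self.omega = rng.normal(scale=1.0 / max(lengthscale, 1e-12), size=(n_features, 2))
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
        self.scale = np.sqrt(2.0 / n_features)

    def __call__(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        pts = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
        return self.amplitude * self.scale * np.cos(pts @ self.omega.T + self.phase).sum(axis=1)


@dataclass(frozen=True)
class Effect:
    """One configured covariate effect on a distributional parameter.

    ``form`` is one of:

    - ``linear``: amplitude * (x - center) / scale
    - ``saturating``: amplitude * saturating ramp of age (rapid early change)
    - ``rise_plateau``: amplitude * smoothstep of age reaching a plateau at
      ``plateau`` months (used for the stunting age profile)
    - ``spatial``: a seeded random-cosine field over (lon, lat), SD ~= amplitude
    - ``binary``: amplitude * (covariate == level, centred at 1/2)

    Age forms are centred over the uniform 6-59 month reference distribution,
    so amplitudes shift shape, not the marginal level.
    """

    parameter: str
    covariate: str
    form: str
    amplitude: float
    center: float = 0.0
    scale: float = 1.0
    plateau: float = 36.0
    level: str = "female"

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_LABELS:
            raise ValueError(f"unknown distributional parameter {self.parameter!r}")
        if self.form not in ("linear", "saturating", "rise_plateau", "spatial", "binary"):
            raise ValueError(f"unknown effect form {self.form!r}")


def _saturating(age: np.ndarray) -> np.ndarray:
    s = (np.asarray(age, float) - AGE_RANGE[0]) / (AGE_RANGE[1] - AGE_RANGE[0])
    return (1.0 - np.exp(-3.0 * s)) / (1.0 - np.exp(-3.0))


def _smoothstep(age: np.ndarray, plateau: float) -> np.ndarray:
    s = np.clip((np.asarray(age, float) - AGE_RANGE[0]) / (plateau - AGE_RANGE[0]), 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``base_mu``/``base_sigma`` set the marginal response distribution at
    covariate-effect zero; effects perturb individual distributional
    parameters around those intercepts.
    """

    n_clusters: int = 400
    children_per_cluster: tuple[int, int] = (15, 30)
    bbox: tuple[float, float, float, float] = (-10.0, 10.0, -10.0, 10.0)  # lon0, lon1, lat0, lat1
    years: tuple[int, int] = (2010, 2020)
    base_mu: np.ndarray = field(default_factory=lambda: np.zeros(len(RESPONSES)))
    base_sigma: np.ndarray = field(default_factory=lambda: np.eye(len(RESPONSES)))
    effects: list[Effect] = field(default_factory=list)
    anemia_cutoff: float = ANEMIA_CUTOFF
    z_cut: float = Z_CUT
    overweight_on: str = "waz"
    field_lengthscale: float = 4.0
    field_amplitude_scale: float = 1.0
    effect_lengthscale: float = 4.0
    barren_prop: float = 0.05
    snow_prop: float = 0.01
    elevation_exceed_3000: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        self.base_mu = np.asarray(self.base_mu, dtype=float)
        self.base_sigma = np.asarray(self.base_sigma, dtype=float)
        if self.bbox[1] <= self.bbox[0] or self.bbox[3] <= self.bbox[2]:
            raise ValueError("empty bounding box")
        if self.overweight_on not in ("waz", "whz"):
            raise ValueError("overweight_on must be 'waz' or 'whz'")
        np.linalg.cholesky(self.base_sigma)  # raises if not SPD


def default_survey_config(seed: int | None = None) -> SyntheticConfig:
    """Default DHS-like generator conditions.

    Base means are back-solved under Gaussian margins from prevalence levels
    representative of recent sub-Saharan surveys (anemia 69.6%, stunting
    32.9%, underweight 14.8%, wasting 5.2%, overweight 2.5%); mu_WAZ and
    sigma_WAZ are solved jointly from the underweight/overweight pair.  The correlation structure encodes
    rho(WAZ,WHZ)=0.70, rho(HAZ,WAZ)=0.68, a weakly negative rho(HAZ,WHZ)
    (-0.02, near the positive-definiteness boundary implied by the two strong
    correlations) and small Hb-anthropometry correlations.  Age effects make
    anemia and wasting decline with age while stunting rises to a plateau
    around month 36.
    """
    sd = np.array([15.0, 1.1, 1.331, 1.1])
    corr = np.array(
        [
            [1.00, 0.10, 0.12, 0.08],
            [0.10, 1.00, 0.68, -0.02],
            [0.12, 0.68, 1.00, 0.70],
            [0.08, -0.02, 0.70, 1.00],
        ]
    )
    base_sigma = corr * np.outer(sd, sd)
    base_mu = np.array([102.3, -1.51, -0.609, -0.211])
    effects = [
        Effect("mu_hb", "age", "saturating", 8.0),
        Effect("mu_hb", "lonlat", "spatial", 4.0),
        Effect("mu_hb", "malaria_incidence", "linear", -4.0, center=0.25, scale=0.15),
        Effect("mu_hb", "wealth_code", "linear", 3.0, center=3.0, scale=2.0),
        Effect("mu_hb", "year", "linear", 1.5, center=2015.0, scale=5.0),
        Effect("mu_haz", "age", "rise_plateau", -0.7),
        Effect("mu_haz", "lonlat", "spatial", 0.25),
        Effect("mu_haz", "sex", "binary", 0.08),
        Effect("mu_haz", "wealth_code", "linear", 0.12, center=3.0, scale=2.0),
        Effect("mu_haz", "year", "linear", 0.08, center=2015.0, scale=5.0),
        Effect("mu_waz", "age", "linear", -0.25, center=32.5, scale=26.5),
        Effect("mu_waz", "lonlat", "spatial", 0.15),
        Effect("mu_whz", "age", "saturating", 0.45),
        Effect("phi_43", "age", "linear", 0.08, center=32.5, scale=26.5),
    ]
    return SyntheticConfig(base_mu=base_mu, base_sigma=base_sigma, effects=effects, seed=seed)


class CovariateFields:
    """Deterministic environmental covariate surfaces over the bbox.

    Continuous fields are random-cosine expansions; land cover is a spatially
    correlated categorical field obtained by thresholding a latent smooth
    field at quantiles matching the configured class proportions, and
    elevation is shifted so a configured fraction of the region exceeds
    3000 m.
    """

    LAND_CLASSES = ("Permanent Snow and Ice", "Barren", "Grassland", "Cropland", "Forest")

    def __init__(self, config: SyntheticConfig, seed):
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        kids = ss.spawn(5)
        ls = config.field_lengthscale
        amp = config.field_amplitude_scale
        self.config = config
        self.temperature = RandomCosineField(3.0 * amp, ls, kids[0])
        self.malaria = RandomCosineField(0.15 * amp, ls, kids[1])
        self.elevation_raw = RandomCosineField(700.0 * amp, ls, kids[2])
        self.land_latent = RandomCosineField(1.0 * amp, ls, kids[3])
        self.wealth_gradient = RandomCosineField(1.0 * amp, 2.0 * ls, kids[4])

        lon0, lon1, lat0, lat1 = config.bbox
        gx, gy = np.meshgrid(np.linspace(lon0, lon1, 41), np.linspace(lat0, lat1, 41))
        grid_elev = self.elevation_raw(gx.ravel(), gy.ravel())
        p = config.elevation_exceed_3000
        self._elev_shift = 600.0 if p <= 0 else float(
            3000.0 - np.quantile(grid_elev, 1.0 - p)
        )
        grid_land = self.land_latent(gx.ravel(), gy.ravel())
        cum = np.cumsum([config.snow_prop, config.barren_prop])
        if np.ptp(grid_land) == 0:
            self._land_cuts = np.array([-np.inf, -np.inf, 0.0])
        else:
            rest = (1.0 - cum[-1]) / 3.0
            qs = np.concatenate([cum, cum[-1] + np.array([rest, 2 * rest])])
            self._land_cuts = np.quantile(grid_land, qs[:4])

    def evaluate(self, lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        elev = np.clip(self.elevation_raw(lon, lat) + self._elev_shift, 0.0, None)
        land_idx = np.searchsorted(self._land_cuts, self.land_latent(lon, lat))
        return pd.DataFrame(
            {
                "lon": lon,
                "lat": lat,
                "temperature": 25.0 + self.temperature(lon, lat),
                "malaria_incidence": np.clip(0.25 + self.malaria(lon, lat), 0.0, 1.0),
                "elevation": elev,
                "land_cover": np.asarray(self.LAND_CLASSES)[land_idx],
            }
        )


@dataclass
class SimulatedSurvey:
    """A generated survey with its ground-truth parameter table."""

    observations: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig
    generator: "SurveyGenerator"


class SurveyGenerator:
    """Draws surveys and exposes the true parameter surfaces for scoring."""

    def __init__(self, config: SyntheticConfig, seed: int | None = None):
        if seed is None:
            seed = config.seed if config.seed is not None else 0
        self.config = config
        ss = np.random.SeedSequence(seed)
        k_fields, k_effects, k_survey = ss.spawn(3)
        self.fields = CovariateFields(config, k_fields)
        self._survey_seed = k_survey
        self.effect_fields: dict[int, RandomCosineField] = {}
        eff_kids = k_effects.spawn(max(len(config.effects), 1))
        lon0, lon1, lat0, lat1 = config.bbox
        gx, gy = np.meshgrid(np.linspace(lon0, lon1, 41), np.linspace(lat0, lat1, 41))
        self._spatial_means: dict[int, float] = {}
        for i, eff in enumerate(config.effects):
            if eff.form == "spatial":
                f = RandomCosineField(eff.amplitude, config.effect_lengthscale, eff_kids[i])
                self.effect_fields[i] = f
                self._spatial_means[i] = float(f(gx.ravel(), gy.ravel()).mean())
        ages = np.arange(AGE_RANGE[0], AGE_RANGE[1] + 1, dtype=float)
        self._sat_mean = float(_saturating(ages).mean())
        self._step_means = {}

    def _effect_values(self, i: int, eff: Effect, table: pd.DataFrame) -> np.ndarray:
        if eff.form == "linear":
            x = np.asarray(table[eff.covariate], float)
            return eff.amplitude * (x - eff.center) / eff.scale
        if eff.form == "saturating":
            return eff.amplitude * (_saturating(table["age"]) - self._sat_mean)
        if eff.form == "rise_plateau":
            if eff.plateau not in self._step_means:
                ages = np.arange(AGE_RANGE[0], AGE_RANGE[1] + 1, dtype=float)
                self._step_means[eff.plateau] = float(_smoothstep(ages, eff.plateau).mean())
            return eff.amplitude * (
                _smoothstep(table["age"], eff.plateau) - self._step_means[eff.plateau]
            )
        if eff.form == "spatial":
            f = self.effect_fields[i]
            return f(table["lon"], table["lat"]) - self._spatial_means[i]
        # binary
        ind = (table[eff.covariate].astype(str) == eff.level).to_numpy(dtype=float)
        return eff.amplitude * (ind - 0.5)

    def true_eta(self, table: pd.DataFrame) -> np.ndarray:
        """The 14 true predictors (flat ordering) per row of ``table``."""
        base_factors = sigma_to_factors(self.config.base_sigma)
        theta0 = pack_params(
            self.config.base_mu, base_factors.lam, base_factors.phi
        )
        eta = np.tile(theta0, (len(table), 1))
        col = {label: k for k, label in enumerate(PARAM_LABELS)}
        for i, eff in enumerate(self.config.effects):
            eta[:, col[eff.parameter]] += self._effect_values(i, eff, table)
        return eta

    def true_params(self, table: pd.DataFrame):
        """(mu, lam, phi) true per-row distributional parameters."""
        return unpack_params(self.true_eta(table))

    def truth_table(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-row true moments and indicator prevalences."""
        mu, lam, phi = self.true_params(table)
        params = mvn_params(mu, CholeskyFactors(phi=phi, lam=lam))
        out = {}
        for m, r in enumerate(RESPONSES):
            out[f"mu_{r}"] = params.mu[:, m]
            out[f"sd_{r}"] = params.sd[:, m]
        for i in range(len(RESPONSES)):
            for j in range(i + 1, len(RESPONSES)):
                out[f"rho_{RESPONSES[i]}_{RESPONSES[j]}"] = params.rho[:, i, j]
        cfg = self.config
        out["prev_anemia"] = threshold_probability(
            params.mu[:, 0], params.sd[:, 0], cfg.anemia_cutoff, "below"
        )
        for name, ridx in (("stunting", 1), ("underweight", 2), ("wasting", 3)):
            out[f"prev_{name}"] = threshold_probability(
                params.mu[:, ridx], params.sd[:, ridx], -cfg.z_cut, "below"
            )
        ov = 2 if cfg.overweight_on == "waz" else 3
        out["prev_overweight"] = threshold_probability(
            params.mu[:, ov], params.sd[:, ov], cfg.z_cut, "above"
        )
        return pd.DataFrame(out, index=table.index)

    def simulate(self, seed: int | None = None) -> SimulatedSurvey:
        cfg = self.config
        rng = np.random.default_rng(self._survey_seed if seed is None else seed)
        if cfg.n_clusters == 0:
            empty = pd.DataFrame({c: pd.Series(dtype=float) for c in SCHEMA})
            return SimulatedSurvey(empty, pd.DataFrame(), cfg, self)
        lon0, lon1, lat0, lat1 = cfg.bbox
        c_lon = rng.uniform(lon0, lon1, cfg.n_clusters)
        c_lat = rng.uniform(lat0, lat1, cfg.n_clusters)
        c_year = rng.integers(cfg.years[0], cfg.years[1] + 1, cfg.n_clusters)
        lo, hi = cfg.children_per_cluster
        sizes = rng.integers(lo, hi + 1, cfg.n_clusters)
        cl = np.repeat(np.arange(cfg.n_clusters), sizes)
        n = len(cl)
        table = self.fields.evaluate(c_lon[cl], c_lat[cl])
        table.insert(0, "cluster_id", cl)
        table.insert(0, "child_id", np.arange(n))
        table["age"] = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, n)
        table["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
        wealth_score = self.fields.wealth_gradient(table["lon"], table["lat"]) + rng.normal(
            0.0, 0.5, n
        )
        cuts = np.sqrt(1.25) * np.array([-0.8416, -0.2533, 0.2533, 0.8416])
        table["wealth_code"] = 1 + np.searchsorted(cuts, wealth_score)
        table["year"] = c_year[cl]
        mu, lam, phi = self.true_params(table)
        y = sample_mvn(mu, CholeskyFactors(phi=phi, lam=lam), seed=rng)
        for m, r in enumerate(RESPONSES):
            table[r] = y[:, m]
        table = table[SCHEMA]
        return SimulatedSurvey(table, self.truth_table(table), cfg, self)


def simulate_covariate_fields(config: SyntheticConfig, seed: int = 0) -> pd.DataFrame:
    """Cluster-level environmental covariates at seeded uniform cluster sites."""
    gen = SurveyGenerator(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    lon0, lon1, lat0, lat1 = config.bbox
    lon = rng.uniform(lon0, lon1, config.n_clusters)
    lat = rng.uniform(lat0, lat1, config.n_clusters)
    out = gen.fields.evaluate(lon, lat)
    out.insert(0, "cluster_id", np.arange(config.n_clusters))
    return out


def simulate_survey(config: SyntheticConfig, seed: int = 0) -> SimulatedSurvey:
    """Generate a child-level survey plus its ground-truth parameter table."""
    return SurveyGenerator(config, seed).simulate()


def plausibility_check(table: pd.DataFrame, z_bound: float = 6.0) -> dict:
    """WHO-plausibility screening: positive Hb and |z-score| exceedance rates.

    Under the default Gaussian scales the expected |z| > 6 exceedance is of
    order 1e-4, so the fractions reported here should be tiny but need not be
    exactly zero.
    """
    if len(table) == 0:
        return {"hb_nonpositive": 0.0, "z_exceed": 0.0}
    z = table[["haz", "waz", "whz"]].to_numpy(dtype=float)
    return {
        "hb_nonpositive": float((table["hb"].to_numpy() <= 0).mean()),
        "z_exceed": float((np.abs(z) > z_bound).any(axis=1).mean()),
    }
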