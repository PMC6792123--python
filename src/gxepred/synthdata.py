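"""Synthetic breeding populations, climates, soils and G x E yields.

The generator emulates the structure of a northern-European barley
breeding programme at desk scale: a parent generation genotyped at
biallelic SNPs, progeny produced by random bi-parental crosses, a handful
of trial locations with location-specific climate distributions (each
location has its own temperature level and wetness), per-field soil
profiles fixed across years, and yield observations composed of a
polygenic genetic main effect, an environment effect, a soil x rain
driven genotype-by-environment interaction and heteroscedastic noise:

    y_ij = g_i + e_j + gamma_i * s_j + eps_ij

with ``s_j`` the standardized product of the field's clay share and the
season rainfall total (an environmental stress score) and ``gamma_i`` a
polygenic susceptibility. The environment effect is partly driven by the
same stress (waterlogging depresses mean yield for every genotype) and
partly i.i.d. site-year noise, so per-environment mean yields carry real
information about the growing conditions. Every component's realized
variance is scaled to its configured share, and the ground truth is
retained so that model recovery can be tested exactly.

Default variance shares follow the calibration conventions for z-scaled
yields: environment-effect variance 0.25, residual noise around 0.1, and
a genetic main-effect share of 0.4 (middle of the calibration grid) with
an equally strong interaction share (0.4) reflecting a regime where
G x E matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, SoilProfile, TrialTable, WeatherSeries

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticDataset",
           "simulate_population", "simulate_climate", "simulate_yields", "simulate"]


@dataclass
class SimConfig:
    """All knobs of the synthetic breeding experiment."""

    n_parents: int = 40
    n_progeny: int = 160
    n_markers: int = 400
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_locations: int = 6
    years: tuple[int, ...] = (2010, 2011, 2012, 2013, 2014)
    fields_per_location: int = 1
    var_genetic: float = 0.4
    var_env: float = 0.25
    var_gxe: float = 0.4
    var_noise: float = 0.1
    #: share of the environment main effect driven by the environmental
    #: covariates (waterlogging stress lowers every genotype's yield, so
    #: mean yields are informative about the environment — the premise of
    #: the mean-yield kernel-weight regression); the rest is i.i.d. noise
    env_covariate_share: float = 0.5
    gxe_mechanism: str = "soil_rain"  # or "none"
    obs_density: float = 0.4
    # climate knobs
    temp_base_range: tuple[float, float] = (12.0, 16.0)
    temp_amplitude: float = 5.0
    temp_ar: float = 0.6
    temp_noise_sd: float = 2.5
    wet_prob_range: tuple[float, float] = (0.25, 0.55)
    rain_lognorm_mu: float = 1.2
    rain_lognorm_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 2:
            raise ValueError("need at least 2 parents")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("var_genetic", "var_env", "var_gxe", "var_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth components retained by the simulator."""

    g: np.ndarray            # genetic main effects per line
    e: np.ndarray            # environment effects per env
    xi: np.ndarray           # interaction matrix (lines x envs)
    marker_effects: np.ndarray
    stress: np.ndarray       # s_j per env
    susceptibility: np.ndarray  # gamma_i per line
    line_ids: np.ndarray
    env_ids: np.ndarray


@dataclass
class SyntheticDataset:
    """Everything one in silico experiment needs."""

    config: SimConfig
    genotypes: GenotypeMatrix
    weather: dict[tuple[str, int], WeatherSeries]
    soils: dict[str, SoilProfile]
    zones: dict[str, str]
    sowing: dict[str, str]       # env -> ISO sowing date
    trials: TrialTable
    truth: SyntheticTruth


# ---------------------------------------------------------------------------

def simulate_population(cfg: SimConfig, rng: np.random.Generator | None = None
                        ) -> GenotypeMatrix:
    """Parents drawn from marker MAFs; progeny from random bi-parental crosses.

    Parent dosages are Binomial(2, maf_m) per marker; each progeny samples
    two distinct parents and receives one allele per parent with
    probability dosage/2 (random-union-of-gametes approximation).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    parents = rng.binomial(2, maf, size=(cfg.n_parents, cfg.n_markers)).astype(float)
    progeny = np.empty((cfg.n_progeny, cfg.n_markers))
    for k in range(cfg.n_progeny):
        p1, p2 = rng.choice(cfg.n_parents, size=2, replace=False)
        progeny[k] = (
            rng.binomial(1, parents[p1] / 2.0) + rng.binomial(1, parents[p2] / 2.0)
        )
    ids = np.array(
        [f"P{i:04d}" for i in range(cfg.n_parents)]
        + [f"C{i:04d}" for i in range(cfg.n_progeny)], dtype=object)
    generation = np.array(
        ["parent"] * cfg.n_parents + ["progeny"] * cfg.n_progeny, dtype=object)
    markers = np.array([f"snp{m:05d}" for m in range(cfg.n_markers)], dtype=object)
    return GenotypeMatrix(ids, markers, np.vstack([parents, progeny]), generation)


def simulate_climate(cfg: SimConfig, rng: np.random.Generator | None = None
                     ) -> tuple[dict, dict, dict, dict]:
    """Location-specific daily weather, per-field soils, zones and sowing dates.

    Daily mean temperature is a location base level plus a seasonal
    sinusoid peaking in mid-July plus AR(1) noise; rainfall is a wet-day
    Bernoulli times a log-normal amount with a location-specific wet-day
    probability. Series span April 1 - September 30. Soil composition is
    Dirichlet over (sand, silt, clay) with a Beta organic share, fixed per
    field across years.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    weather: dict[tuple[str, int], WeatherSeries] = {}
    soils: dict[str, SoilProfile] = {}
    zones: dict[str, str] = {}
    sowing: dict[str, str] = {}
    n_zones = min(4, cfg.n_locations)
    for li in range(cfg.n_locations):
        loc = f"L{li:02d}"
        zones[loc] = f"zone{li % n_zones}"
        base = rng.uniform(*cfg.temp_base_range)
        wet_p = rng.uniform(*cfg.wet_prob_range)
        for year in cfg.years:
            dates = pd.date_range(f"{year}-04-01", f"{year}-09-30", freq="D")
            doy = dates.dayofyear.to_numpy()
            seasonal = base + cfg.temp_amplitude * np.sin(
                np.pi * (doy - 91) / 183.0)  # peaks around day 182 (early July)
            noise = np.zeros(len(doy))
            eps = rng.normal(0.0, cfg.temp_noise_sd, len(doy))
            for d in range(1, len(doy)):
                noise[d] = cfg.temp_ar * noise[d - 1] + eps[d]
            tmean = seasonal + noise
            wet = rng.random(len(doy)) < wet_p
            amounts = rng.lognormal(cfg.rain_lognorm_mu, cfg.rain_lognorm_sd, len(doy))
            rain = np.where(wet, amounts, 0.0)
            weather[(loc, year)] = WeatherSeries(
                loc, year, pd.DataFrame({"date": dates, "tmean": tmean, "rain": rain}))
        for fi in range(cfg.fields_per_location):
            fb = f"{loc}-F{fi}"
            sand, silt, clay = rng.dirichlet((2.0, 2.0, 2.0))
            soils[fb] = SoilProfile(fb, sand, silt, clay, float(rng.beta(2.0, 8.0)))
    return weather, soils, zones, sowing


def _scale_to_variance(x: np.ndarray, target: float) -> np.ndarray:
    sd = x.std()
    if sd == 0 or target == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target) / sd


def simulate_yields(genotypes: GenotypeMatrix, weather, soils, zones, cfg: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[TrialTable, SyntheticTruth, dict]:
    """Compose yields from the generative decomposition with known truth."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    X = genotypes.dosages
    Xc = X - X.mean(axis=0)
    n_lines = genotypes.n_lines

    w_g = rng.normal(0.0, 1.0, cfg.n_markers)
    g = _scale_to_variance(Xc @ w_g, cfg.var_genetic)

    env_rows = []
    for (loc, year) in sorted(weather.keys()):
        for fi in range(cfg.fields_per_location):
            fb = f"{loc}-F{fi}"
            env_rows.append((loc, year, fb))
    env_ids = np.array([f"{l}:{y}:{f}" for l, y, f in env_rows], dtype=object)
    n_env = len(env_rows)

    sowing = {}
    for (loc, year, fb), env in zip(env_rows, env_ids):
        day = int(rng.integers(1, 21))
        sowing[env] = f"{year}-05-{day:02d}"

    if cfg.gxe_mechanism == "soil_rain" and cfg.var_gxe > 0:
        season_rain = np.array([
            weather[(loc, yr)].days.loc[
                lambda d: d["date"].dt.month.isin([5, 6, 7, 8]), "rain"].sum()
            for loc, yr, _ in env_rows
        ])
        clay = np.array([soils[fb].clay for _, _, fb in env_rows])
        s = clay * season_rain
        s = (s - s.mean()) / max(s.std(), 1e-12)
        w_gamma = rng.normal(0.0, 1.0, cfg.n_markers)
        gamma = Xc @ w_gamma
        gamma = (gamma - gamma.mean()) / max(gamma.std(), 1e-12)
        xi = np.outer(gamma, s)
        xi = _scale_to_variance(xi, cfg.var_gxe)
        gamma = xi[:, np.argmax(np.abs(s))] / s[np.argmax(np.abs(s))]
    elif cfg.gxe_mechanism == "none" or cfg.var_gxe == 0:
        s = np.zeros(n_env)
        gamma = np.zeros(n_lines)
        xi = np.zeros((n_lines, n_env))
    else:
        raise ValueError(f"unknown gxe_mechanism {cfg.gxe_mechanism!r}")

    # environment main effect: a covariate-driven quality component (high
    # waterlogging stress depresses mean yield across all genotypes) plus
    # i.i.d. year-site noise; exact-variance scaling keeps the realized
    # decomposition on target even at modest environment counts
    share = cfg.env_covariate_share if s.std() > 0 else 0.0
    e_raw = (-np.sqrt(share) * s
             + np.sqrt(1.0 - share) * rng.normal(0.0, 1.0, n_env))
    e = _scale_to_variance(e_raw, cfg.var_env)

    obs = rng.random((n_lines, n_env)) < cfg.obs_density
    # every line observed somewhere, every env has some lines
    for i in np.where(~obs.any(axis=1))[0]:
        obs[i, rng.integers(n_env)] = True
    for j in np.where(~obs.any(axis=0))[0]:
        obs[rng.integers(n_lines), j] = True

    ii, jj = np.where(obs)
    eps = rng.normal(0.0, np.sqrt(cfg.var_noise), len(ii))
    y = g[ii] + e[jj] + xi[ii, jj] + eps
    records = pd.DataFrame({
        "line_id": genotypes.line_ids[ii],
        "location": [env_rows[j][0] for j in jj],
        "year": [env_rows[j][1] for j in jj],
        "field_block": [env_rows[j][2] for j in jj],
        "yield": y,
    })
    truth = SyntheticTruth(
        g=g, e=e, xi=xi, marker_effects=w_g, stress=s, susceptibility=gamma,
        line_ids=genotypes.line_ids, env_ids=env_ids,
    )
    return TrialTable(records), truth, sowing


def simulate(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Run the full generator: population, climate and yields."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genotypes = simulate_population(cfg, np.random.default_rng(cfg.seed))
    weather, soils, zones, _ = simulate_climate(cfg, np.random.default_rng(cfg.seed + 1))
    trials, truth, sowing = simulate_yields(
        genotypes, weather, soils, zones, cfg, np.random.default_rng(cfg.seed + 2))
    return SyntheticDataset(cfg, genotypes, weather, soils, zones, sowing, trials, truth)
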