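"""BLUP baselines and the temperature-sum crop-stage machinery.

Two mixed-model comparison methods are provided:

* **GBLUP** — yields regressed on fixed field-block effects plus a random
  genetic effect with the genomic kernel as covariance;
* **GE-BLUP** — a random effect over genotype x environment cells whose
  covariance is the Kronecker product ``Sigma_G (x) Sigma_E`` of a genomic
  and an environmental kinship, evaluated only on the observed/predicted
  cells (the Kronecker structure makes each needed entry a product of two
  kernel entries, so the full dense product is never formed).

The environmental kinship summarizes weather per crop developmental stage
(vegetative, heading, grain filling); stage timing is estimated from
growing-degree accumulation: heading at 440.2 degree-days and ripening at
905.9 degree-days of cumulative daily mean temperature above the base.

Variance components are estimated by REML using the spectral
reparameterization of the single-random-effect model (eigendecomposition
of the kernel projected off the fixed effects, then a one-dimensional
search over the variance ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .datamodel import SoilProfile, WeatherSeries
from .kernels import Kernel, linear_kernel, normalize_unit_diagonal

__all__ = [
    "CropStageConfig",
    "CropStages",
    "estimate_crop_stages",
    "GEBlupCovariateBuilder",
    "GBLUP",
    "GEBLUP",
    "MixedModelResults",
]


# ---------------------------------------------------------------------------
# Crop stages
# ---------------------------------------------------------------------------

@dataclass
class CropStageConfig:
    """Temperature-sum thresholds and window rules for barley development.

    ``heading_sum`` / ``ripening_sum`` are cumulative degree-day thresholds
    (deg C x day above ``base_temperature``); the vegetative stage spans the
    first 3 weeks from sowing, the heading window runs from 2 weeks before
    to 1 week after the estimated heading day, and grain filling starts the
    day after the heading window and ends 1 week after estimated ripening.
    """

    heading_sum: float = 440.2
    ripening_sum: float = 905.9
    vegetative_weeks: int = 3
    heading_window: tuple[int, int] = (-2, 1)  # weeks around heading
    grainfill_extra_weeks: int = 1
    base_temperature: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.heading_sum < self.ripening_sum:
            raise ValueError("need 0 < heading_sum < ripening_sum")


@dataclass
class CropStages:
    """Stage windows as inclusive 1-based day intervals from sowing."""

    heading_day: int
    ripening_day: int
    vegetative: tuple[int, int]
    heading: tuple[int, int]
    grain_filling: tuple[int, int]


def estimate_crop_stages(daily_tmean: np.ndarray, cfg: CropStageConfig | None = None
                         ) -> CropStages:
    """Estimate stage windows from daily mean temperatures starting at sowing.

    ``daily_tmean[0]`` is the sowing day (day 1). The heading day is the
    first day whose cumulative sum of ``max(tmean - base, 0)`` reaches the
    heading threshold; ripening likewise.
    """
    cfg = cfg or CropStageConfig()
    t = np.asarray(daily_tmean, dtype=float)
    gdd = np.cumsum(np.maximum(t - cfg.base_temperature, 0.0))
    head = np.searchsorted(gdd, cfg.heading_sum)
    if head >= len(gdd):
        raise ValueError(
            f"temperature sum never reaches heading threshold {cfg.heading_sum}"
        )
    ripe = np.searchsorted(gdd, cfg.ripening_sum)
    if ripe >= len(gdd):
        raise ValueError(
            f"temperature sum never reaches ripening threshold {cfg.ripening_sum}"
        )
    heading_day = int(head) + 1  # 1-based
    ripening_day = int(ripe) + 1
    veg = (1, cfg.vegetative_weeks * 7)
    head_win = (
        max(1, heading_day + cfg.heading_window[0] * 7),
        heading_day + cfg.heading_window[1] * 7,
    )
    grain = (head_win[1] + 1, ripening_day + cfg.grainfill_extra_weeks * 7)
    return CropStages(heading_day, ripening_day, veg, head_win, grain)


class GEBlupCovariateBuilder:
    """Stage-summarized environmental covariates and kinship for GE-BLUP.

    Per environment: mean and standard deviation of daily temperature and
    rainfall within each of the three stage windows (12 covariates), the
    four soil proportions, and one-hot growth-zone indicators. Covariates
    are z-normalized across the training environments; the kinship is the
    unit-diagonal-normalized linear kernel.
    """

    def __init__(self, cfg: CropStageConfig | None = None):
        self.cfg = cfg or CropStageConfig()
        self._fitted = False

    @staticmethod
    def _stage_stats(weather: np.ndarray, stages: CropStages) -> np.ndarray:
        out = []
        n_days = weather.shape[0]
        for lo, hi in (stages.vegetative, stages.heading, stages.grain_filling):
            if hi > n_days:
                raise ValueError(
                    f"stage window (days {lo}-{hi}) outside weather coverage ({n_days} days)"
                )
            block = weather[lo - 1:hi]
            for col in range(2):  # tmean, rain
                out.extend([block[:, col].mean(), block[:, col].std()])
        return np.asarray(out)

    def environment_vector(self, weather_from_sowing: np.ndarray, soil: SoilProfile,
                           zone_onehot: np.ndarray) -> np.ndarray:
        """Raw (un-normalized) covariate vector for one environment.

        ``weather_from_sowing`` is an (n_days, 2) array of (tmean, rain)
        starting at the sowing day.
        """
        stages = estimate_crop_stages(weather_from_sowing[:, 0], self.cfg)
        return np.concatenate([
            self._stage_stats(weather_from_sowing, stages),
            soil.vector(),
            np.asarray(zone_onehot, dtype=float),
        ])

    def fit(self, vectors: np.ndarray, ids) -> "GEBlupCovariateBuilder":
        X = np.asarray(vectors, dtype=float)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._X = (X - self._mu) / self._sd
        self.ids = np.asarray(ids, dtype=object)
        self.kernel = normalize_unit_diagonal(
            linear_kernel(self._X, ids=self.ids, provenance="geblup_env"))
        self._fitted = True
        return self


# ---------------------------------------------------------------------------
# Single-random-effect REML machinery
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResults:
    """REML variance components, fixed effects and BLUPs."""

    sigma2_u: float
    sigma2_e: float
    beta: np.ndarray
    blup: np.ndarray          # random effects of the training units
    reml_loglik: float
    _Vinv_resid: np.ndarray = field(repr=False, default=None)
    _unit_ids: np.ndarray = field(repr=False, default=None)
    _K_train: np.ndarray = field(repr=False, default=None)
    _Z: np.ndarray = field(repr=False, default=None)

    @property
    def heritability(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    def predict_units(self, k_rows: np.ndarray) -> np.ndarray:
        """BLUP for new units from kernel rows against training units."""
        k_rows = np.atleast_2d(np.asarray(k_rows, dtype=float))
        return k_rows @ (self._Z.T @ self._Vinv_resid)

    def summary(self) -> str:
        return (
            "mixed-model REML fit\n"
            f"  sigma2_u = {self.sigma2_u:.5f}\n"
            f"  sigma2_e = {self.sigma2_e:.5f}\n"
            f"  h2(kernel) = {self.heritability:.4f}\n"
            f"  restricted log-likelihood = {self.reml_loglik:.4f}"
        )


def _reml_single_kernel(y: np.ndarray, X: np.ndarray, ZKZ: np.ndarray
                        ) -> tuple[float, float, float]:
    """REML for ``y = X b + u + e`` with ``Cov(u) = s2u * ZKZ``.

    Returns ``(sigma2_u, sigma2_e, reml_loglik)`` via the eigen
    decomposition of ``S ZKZ S`` with ``S`` the fixed-effect projection.
    """
    n, p = X.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        raise ValueError("fixed-effect design is not identifiable (rank deficient)")
    S = np.eye(n) - X @ np.linalg.solve(XtX, X.T)
    # eigendecompose S(ZKZ'+I)S: the p projection zeros separate cleanly
    # from genuine zero kernel eigenvalues (which map to 1)
    w, U = np.linalg.eigh(S @ (ZKZ + np.eye(n)) @ S)
    order = np.argsort(w)[::-1]
    w, U = w[order][: n - p], U[:, order][:, : n - p]
    w = np.maximum(w - 1.0, 0.0)
    eta = U.T @ y
    nf = n - p

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = w + d
        ss = float(np.sum(eta**2 / denom))
        ll = -0.5 * (nf * np.log(2 * np.pi * ss / nf) + nf + np.sum(np.log(denom)))
        return -ll

    res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    ss = float(np.sum(eta**2 / (w + delta)))
    sigma2_u = ss / nf
    sigma2_e = delta * sigma2_u
    return sigma2_u, sigma2_e, -res.fun


def _fit_mixed(y: np.ndarray, X: np.ndarray, K: np.ndarray, Z: np.ndarray
               ) -> MixedModelResults:
    ZKZ = Z @ K @ Z.T
    s2u, s2e, ll = _reml_single_kernel(y, X, ZKZ)
    n = len(y)
    V = s2u * ZKZ + s2e * np.eye(n)
    Vinv_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vinv_X, Vinv_X.T @ y)
    resid = y - X @ beta
    Vinv_r = np.linalg.solve(V, resid)
    blup = s2u * (K @ (Z.T @ Vinv_r))
    return MixedModelResults(
        sigma2_u=s2u, sigma2_e=s2e, beta=beta, blup=blup, reml_loglik=ll,
        _Vinv_resid=s2u * Vinv_r, _K_train=K, _Z=Z,
    )


# ---------------------------------------------------------------------------
# GBLUP / GE-BLUP model classes
# ---------------------------------------------------------------------------

class GBLUP:
    """Genomic BLUP: fixed field-block effects + random genetic effect.

    Parameters
    ----------
    trials : TrialTable
        Observations (z scale).
    Kg : Kernel
        Genomic kernel; must cover every line in ``trials``.
    fixed : {"env", "intercept"}
        Fixed-effect design: per-environment (field-block) indicators or
        intercept only.
    """

    def __init__(self, trials, Kg: Kernel, fixed: str = "env"):
        lines = list(Kg.ids)
        lmap = {l: i for i, l in enumerate(lines)}
        d = trials.data
        unknown = set(d["line_id"]) - set(lines)
        if unknown:
            raise ValueError(f"genomic kernel does not cover lines {sorted(unknown)[:3]}...")
        self.trials = trials
        self.Kg = Kg
        self.y = d["yield"].to_numpy(dtype=float)
        n = len(self.y)
        rows = np.arange(n)
        self.Z = np.zeros((n, len(lines)))
        self.Z[rows, [lmap[l] for l in d["line_id"]]] = 1.0
        if fixed == "env":
            envs = sorted(d["env"].unique())
            emap = {e: j for j, e in enumerate(envs)}
            self.X = np.zeros((n, len(envs)))
            self.X[rows, [emap[e] for e in d["env"]]] = 1.0
        elif fixed == "intercept":
            self.X = np.ones((n, 1))
        else:
            raise ValueError(f"unknown fixed design {fixed!r}")

    def fit(self) -> MixedModelResults:
        res = _fit_mixed(self.y, self.X, self.Kg.matrix, self.Z)
        res._unit_ids = self.Kg.ids
        return res


class GEBLUP:
    """BLUP over genotype x environment cells with Kronecker covariance.

    ``Cov(u_cells) = sigma2_u * (Sigma_G (x) Sigma_E)`` restricted to the
    observed cells: entry for cells (i,j),(i',j') is
    ``Kg[i,i'] * Ke[j,j']``. Prediction for unseen cells uses the
    cross-covariance rows in the same product form; the dense Kronecker
    matrix is never formed.
    """

    #: refuse problems whose observed-cell covariance would be larger than this
    MAX_CELLS = 6000

    def __init__(self, trials, Kg: Kernel, Ke_env: Kernel, fixed: str = "env"):
        d = trials.data
        if len(d) > self.MAX_CELLS:
            raise MemoryError(
                f"{len(d)} observed cells exceeds the dense cell-covariance guard "
                f"({self.MAX_CELLS}); subsample or restrict the training set"
            )
        lmap = {l: i for i, l in enumerate(Kg.ids)}
        emap = {e: j for j, e in enumerate(Ke_env.ids)}
        try:
            self.cell_g = np.array([lmap[l] for l in d["line_id"]])
            self.cell_e = np.array([emap[e] for e in d["env"]])
        except KeyError as exc:
            raise ValueError(f"kernel does not cover {exc.args[0]!r}") from exc
        self.Kg, self.Ke = Kg, Ke_env
        self.y = d["yield"].to_numpy(dtype=float)
        n = len(self.y)
        rows = np.arange(n)
        if fixed == "env":
            envs = sorted(d["env"].unique())
            em = {e: j for j, e in enumerate(envs)}
            self.X = np.zeros((n, len(envs)))
            self.X[rows, [em[e] for e in d["env"]]] = 1.0
        elif fixed == "intercept":
            self.X = np.ones((n, 1))
        else:
            raise ValueError(f"unknown fixed design {fixed!r}")

    def _cell_cov(self, gi, ei, gj, ej) -> np.ndarray:
        return self.Kg.matrix[np.ix_(gi, gj)] * self.Ke.matrix[np.ix_(ei, ej)]

    def fit(self) -> "GEBlupResults":
        K_oo = self._cell_cov(self.cell_g, self.cell_e, self.cell_g, self.cell_e)
        res = _fit_mixed(self.y, self.X, K_oo, np.eye(len(self.y)))
        return GEBlupResults(res, self)


@dataclass
class GEBlupResults:
    """GE-BLUP fit; prediction via Kronecker cross-covariance rows."""

    mixed: MixedModelResults
    model: GEBLUP

    @property
    def sigma2_u(self) -> float:
        return self.mixed.sigma2_u

    @property
    def sigma2_e(self) -> float:
        return self.mixed.sigma2_e

    def predict_cells(self, geno_rows: np.ndarray, env_rows: np.ndarray) -> np.ndarray:
        """Predict cells given genomic and environmental kernel rows.

        ``geno_rows``: (n_cells, n_train_lines) rows of the genomic kernel;
        ``env_rows``: (n_cells, n_train_envs) rows of the environmental
        kinship — one row pair per predicted cell.
        """
        geno_rows = np.atleast_2d(geno_rows)
        env_rows = np.atleast_2d(env_rows)
        C_no = (geno_rows[:, self.model.cell_g] * env_rows[:, self.model.cell_e])
        return C_no @ (self.mixed._Vinv_resid)

    def summary(self) -> str:
        return self.mixed.summary().replace("mixed-model", "GE-BLUP (Kronecker)")
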