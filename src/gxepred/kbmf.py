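"""Kernelized Bayesian matrix factorization of yield with G x E terms.

The yield of genotype ``i`` in environment ``j`` is decomposed as

    y_ij = g_i + e_j + xi_ij + eps_ij,      eps_ij ~ N(0, sigma_j^2),

where the genetic main effect is a genomic-kernel regression
``g = Kg a_g0 + noise``, the environment main effect ``e_j`` is a random
effect, and the interaction matrix is low-rank, ``Xi = Hg He^T``, with the
latent sides themselves kernel regressions on the genomic and
environmental kernels (``Hg = Kg Ag + noise``, ``He = Ke Ae + noise``).
All parameters carry conjugate Gaussian/Gamma priors and the posterior is
approximated by a fully factorized variational distribution optimized by
coordinate ascent; the evidence lower bound (ELBO) is computed after every
sweep and must be non-decreasing.

Because environments are represented purely through their covariates (the
location and year never enter the regression directly), a future season at
a known location can be predicted by building composite kernel rows from
each historical year's weather and taking the per-genotype median of the
per-year predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma, gammaln

from . import calibration as _cal
from .datamodel import SoilProfile, WeatherSeries, extract_season
from .kernels import EnvironmentKernelBuilder, Kernel

__all__ = ["Hyperparameters", "ObservationMask", "GxEFactorModel", "GxEFactorResults"]

_ELBO_SLACK = 1e-6


@dataclass
class Hyperparameters:
    """All prior parameters of the yield factorization model.

    Defaults follow the calibration conventions for z-scaled yields:
    residual precisions ``sigma_j^-2 ~ Gamma(10, 1)`` (shape-rate; prior
    mean precision 10, i.e. noise variance around 0.1), environment-effect
    variance 0.25, and the remaining values produced by the variance
    calibration for a chosen ``(Var_genetic, Phi, R)`` grid point.
    """

    lambda_g0: float
    sigma2_g0: float
    R: int = 0
    lambda_g: float | None = None
    sigma2_g: float | None = None
    lambda_e: float | None = None
    sigma2_e: float | None = None
    alpha_j: float = 10.0
    beta_j: float = 1.0
    sigma2_e0: float = 0.25
    var_genetic: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.R < 0 or int(self.R) != self.R:
            raise ValueError("interaction rank R must be a non-negative integer")
        self.R = int(self.R)
        pos = {"lambda_g0": self.lambda_g0, "sigma2_g0": self.sigma2_g0,
               "alpha_j": self.alpha_j, "beta_j": self.beta_j,
               "sigma2_e0": self.sigma2_e0}
        if self.R > 0:
            pos.update({"lambda_g": self.lambda_g, "sigma2_g": self.sigma2_g,
                        "lambda_e": self.lambda_e, "sigma2_e": self.sigma2_e})
        for name, v in pos.items():
            if v is None or v <= 0:
                raise ValueError(f"hyperparameter {name} must be positive, got {v}")

    @classmethod
    def calibrated(cls, Kg, Ke=None, R: int = 0, var_genetic: float = 0.4,
                   phi: float = 1.0, targets: _cal.CalibrationTargets | None = None,
                   **overrides) -> "Hyperparameters":
        """Build a hyperparameter set from interpretable variance targets."""
        lambda_g0, sigma2_g0 = _cal.calibrate_main_effect(Kg, var_genetic, targets)
        kw = dict(lambda_g0=lambda_g0, sigma2_g0=sigma2_g0, R=R,
                  var_genetic=var_genetic, phi=phi)
        if R > 0:
            if Ke is None:
                raise ValueError("environmental kernel required when R > 0")
            lg, sg, le, se = _cal.calibrate_interactions(Kg, Ke, R, phi, var_genetic, targets)
            kw.update(lambda_g=lg, sigma2_g=sg, lambda_e=le, sigma2_e=se)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ObservationMask:
    """Observed cells of the genotype x environment yield matrix.

    Replicated observations of the same cell are averaged, with the
    replicate count kept as a precision weight (the mean of ``m``
    replicates has noise variance ``sigma_j^2 / m``).
    """

    geno_idx: np.ndarray
    env_idx: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    n_genotypes: int
    n_environments: int

    def __post_init__(self) -> None:
        self.geno_idx = np.asarray(self.geno_idx, dtype=int)
        self.env_idx = np.asarray(self.env_idx, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.values)
        if not (len(self.geno_idx) == len(self.env_idx) == len(self.weights) == n):
            raise ValueError("observation arrays must have equal length")
        if n == 0:
            raise ValueError("empty observation mask")
        if self.geno_idx.min() < 0 or self.geno_idx.max() >= self.n_genotypes:
            raise ValueError("genotype index out of range")
        if self.env_idx.min() < 0 or self.env_idx.max() >= self.n_environments:
            raise ValueError("environment index out of range")
        key = self.geno_idx * self.n_environments + self.env_idx
        if len(np.unique(key)) != n:
            raise ValueError("duplicate (genotype, environment) cells; aggregate first")

    @classmethod
    def from_trials(cls, trials, line_ids: Sequence, env_ids: Sequence) -> "ObservationMask":
        lmap = {l: i for i, l in enumerate(line_ids)}
        emap = {e: j for j, e in enumerate(env_ids)}
        agg = trials.aggregated()
        known = agg["line_id"].isin(lmap) & agg["env"].isin(emap)
        agg = agg[known]
        if agg.empty:
            raise ValueError("no trial records match the kernel ids")
        return cls(
            geno_idx=np.array([lmap[l] for l in agg["line_id"]]),
            env_idx=np.array([emap[e] for e in agg["env"]]),
            values=agg["yield"].to_numpy(dtype=float),
            weights=agg["n_rep"].to_numpy(dtype=float),
            n_genotypes=len(lmap),
            n_environments=len(emap),
        )


def compute_elbo(h: Hyperparameters, Kg: np.ndarray, Ke: np.ndarray,
                 obs: ObservationMask, st: dict) -> float:
    """Evidence lower bound of a factorized posterior state.

    ``st`` holds the posterior moments (``mu_a0, S_a0, mu_g, v_g, mu_e,
    v_e, tau_shape, tau_rate`` and, for R > 0, the interaction blocks).
    The value computed here from a finished fit equals the tail of its
    ELBO trace.
    """
    R = h.R
    Ng, Ne = Kg.shape[0], Ke.shape[0]
    oi, oj, y, w = obs.geno_idx, obs.env_idx, obs.values, obs.weights
    mu_a0, S_a0 = st["mu_a0"], st["S_a0"]
    mu_g, v_g, mu_e, v_e = st["mu_g"], st["v_g"], st["mu_e"], st["v_e"]
    a_t, b_t = st["tau_shape"], st["tau_rate"]
    Etau = a_t / b_t
    Eltau = digamma(a_t) - np.log(b_t)

    if R > 0:
        mu_Hg, S_Hg, mu_He, S_He = st["mu_Hg"], st["S_Hg"], st["mu_He"], st["S_He"]
        mu_Ag, S_Ag, mu_Ae, S_Ae = st["mu_Ag"], st["S_Ag"], st["mu_Ae"], st["S_Ae"]
        m_xi = np.einsum("cr,cr->c", mu_Hg[oi], mu_He[oj])
        Smg = S_Hg + np.einsum("ir,is->irs", mu_Hg, mu_Hg)
        Sme = S_He + np.einsum("jr,js->jrs", mu_He, mu_He)
        quad = np.einsum("crs,csr->c", Smg[oi], Sme[oj])
    else:
        m_xi = np.zeros(len(y))
        quad = np.zeros(len(y))
    mean_resid = y - mu_g[oi] - mu_e[oj] - m_xi
    Er2 = mean_resid**2 + v_g[oi] + v_e[oj] + (quad - m_xi**2)

    ll = float(0.5 * np.sum(np.log(w) + Eltau[oj] - np.log(2 * np.pi))
               - 0.5 * np.sum(w * Etau[oj] * Er2))
    kl_tau = float(
        np.sum(h.alpha_j * np.log(h.beta_j) - gammaln(h.alpha_j)
               + (h.alpha_j - 1) * Eltau - h.beta_j * Etau)
        + np.sum(a_t - np.log(b_t) + gammaln(a_t) + (1 - a_t) * digamma(a_t)))
    _, logdet_Sa0 = np.linalg.slogdet(S_a0)
    diag_KSK_a0 = np.einsum("ij,jk,ki->i", Kg, S_a0, Kg)
    t_a0 = float(
        0.5 * Ng * np.log(h.lambda_g0) - 0.5 * Ng * np.log(2 * np.pi)
        - 0.5 * h.lambda_g0 * (mu_a0 @ mu_a0 + np.trace(S_a0))
        + 0.5 * (logdet_Sa0 + Ng * (1 + np.log(2 * np.pi))))
    dev_g = mu_g - Kg @ mu_a0
    t_g = float(
        -0.5 * Ng * np.log(2 * np.pi * h.sigma2_g0)
        - (dev_g @ dev_g + v_g.sum() + diag_KSK_a0.sum()) / (2 * h.sigma2_g0)
        + 0.5 * np.sum(np.log(2 * np.pi * np.e * v_g)))
    t_e = float(
        -0.5 * Ne * np.log(2 * np.pi * h.sigma2_e0)
        - (mu_e @ mu_e + v_e.sum()) / (2 * h.sigma2_e0)
        + 0.5 * np.sum(np.log(2 * np.pi * np.e * v_e)))
    elbo = ll + kl_tau + t_a0 + t_g + t_e
    if R > 0:
        _, logdet_SAg = np.linalg.slogdet(S_Ag)
        diag_KSK_Ag = np.einsum("ij,jk,ki->i", Kg, S_Ag, Kg)
        t_Ag = float(
            0.5 * Ng * R * np.log(h.lambda_g) - 0.5 * Ng * R * np.log(2 * np.pi)
            - 0.5 * h.lambda_g * (np.sum(mu_Ag**2) + R * np.trace(S_Ag))
            + 0.5 * R * (logdet_SAg + Ng * (1 + np.log(2 * np.pi))))
        dev_Hg = mu_Hg - Kg @ mu_Ag
        _, ld_SHg = np.linalg.slogdet(S_Hg)
        t_Hg = float(
            -0.5 * Ng * R * np.log(2 * np.pi * h.sigma2_g)
            - (np.sum(dev_Hg**2) + np.trace(S_Hg, axis1=1, axis2=2).sum()
               + R * diag_KSK_Ag.sum()) / (2 * h.sigma2_g)
            + 0.5 * (ld_SHg.sum() + Ng * R * (1 + np.log(2 * np.pi))))
        _, logdet_SAe = np.linalg.slogdet(S_Ae)
        diag_KSK_Ae = np.einsum("ij,jk,ki->i", Ke, S_Ae, Ke)
        t_Ae = float(
            0.5 * Ne * R * np.log(h.lambda_e) - 0.5 * Ne * R * np.log(2 * np.pi)
            - 0.5 * h.lambda_e * (np.sum(mu_Ae**2) + R * np.trace(S_Ae))
            + 0.5 * R * (logdet_SAe + Ne * (1 + np.log(2 * np.pi))))
        dev_He = mu_He - Ke @ mu_Ae
        _, ld_SHe = np.linalg.slogdet(S_He)
        t_He = float(
            -0.5 * Ne * R * np.log(2 * np.pi * h.sigma2_e)
            - (np.sum(dev_He**2) + np.trace(S_He, axis1=1, axis2=2).sum()
               + R * diag_KSK_Ae.sum()) / (2 * h.sigma2_e)
            + 0.5 * (ld_SHe.sum() + Ne * R * (1 + np.log(2 * np.pi))))
        elbo += t_Ag + t_Hg + t_Ae + t_He
    return elbo


class GxEFactorModel:
    """Variational Bayesian G x E yield factorization model.

    Parameters
    ----------
    Kg, Ke : Kernel or ndarray
        Genomic kernel over the training genotypes and composite
        environmental kernel over the training environments. ``Ke`` may be
        omitted for the main-effects-only model (R = 0).
    obs : ObservationMask
        Observed (genotype, environment) yield cells on the z scale.
    hyp : Hyperparameters
    """

    def __init__(self, Kg, Ke, obs: ObservationMask, hyp: Hyperparameters):
        self.Kg = Kg.matrix if isinstance(Kg, Kernel) else np.asarray(Kg, float)
        if Ke is None:
            if hyp.R > 0:
                raise ValueError("environmental kernel required when R > 0")
            self.Ke = np.zeros((obs.n_environments, obs.n_environments))
        else:
            self.Ke = Ke.matrix if isinstance(Ke, Kernel) else np.asarray(Ke, float)
        if self.Kg.shape[0] != obs.n_genotypes:
            raise ValueError("genomic kernel does not cover all genotypes in obs")
        if self.Ke.shape[0] != obs.n_environments:
            raise ValueError("environmental kernel does not cover all environments in obs")
        for name, M in (("Kg", self.Kg), ("Ke", self.Ke)):
            w = np.linalg.eigvalsh(M)
            if w.min() < -1e-6 * max(w.max(), 1e-12):
                raise ValueError(f"{name} is not PSD after clipping (min eig {w.min():.2e})")
        self.obs = obs
        self.hyp = hyp

    @classmethod
    def from_trials(cls, trials, Kg: Kernel, Ke: Kernel | None, hyp: Hyperparameters
                    ) -> "GxEFactorModel":
        env_ids = Ke.ids if Ke is not None else trials.environments["env"].to_numpy()
        obs = ObservationMask.from_trials(trials, Kg.ids, env_ids)
        return cls(Kg, Ke, obs, hyp)

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 200, tol: float = 1e-6, seed: int = 0) -> "GxEFactorResults":
        h = self.hyp
        R = h.R
        Kg, Ke = self.Kg, self.Ke
        Ng, Ne = Kg.shape[0], Ke.shape[0]
        oi, oj = self.obs.geno_idx, self.obs.env_idx
        y, w = self.obs.values, self.obs.weights
        rng = np.random.default_rng(seed)

        # --- constant posterior covariances of the kernel-weight blocks ---
        Kg2 = Kg @ Kg
        S_a0 = np.linalg.inv(h.lambda_g0 * np.eye(Ng) + Kg2 / h.sigma2_g0)
        if R > 0:
            S_Ag = np.linalg.inv(h.lambda_g * np.eye(Ng) + Kg2 / h.sigma2_g)
            S_Ae = np.linalg.inv(h.lambda_e * np.eye(Ne) + Ke @ Ke / h.sigma2_e)

        # --- initialization ------------------------------------------------
        n_cells_j = np.bincount(oj, minlength=Ne).astype(float)
        ybar_g = np.bincount(oi, weights=y * w, minlength=Ng)
        cnt_g = np.bincount(oi, weights=w, minlength=Ng)
        ybar_g = np.where(cnt_g > 0, ybar_g / np.maximum(cnt_g, 1.0), 0.0)
        mu_a0 = S_a0 @ (Kg @ ybar_g) / h.sigma2_g0  # ridge-style warm start
        mu_g = Kg @ mu_a0
        v_g = np.full(Ng, h.sigma2_g0)
        mu_e = np.zeros(Ne)
        v_e = np.full(Ne, h.sigma2_e0)
        a_t = np.full(Ne, h.alpha_j)
        b_t = np.full(Ne, h.beta_j)
        if R > 0:
            mu_Ag = np.zeros((Ng, R))
            mu_Hg = 0.01 * rng.standard_normal((Ng, R))
            S_Hg = np.broadcast_to(h.sigma2_g * np.eye(R), (Ng, R, R)).copy()
            mu_Ae = np.zeros((Ne, R))
            mu_He = 0.01 * rng.standard_normal((Ne, R))
            S_He = np.broadcast_to(h.sigma2_e * np.eye(R), (Ne, R, R)).copy()

        def cell_interaction():
            if R == 0:
                return np.zeros(len(y)), np.zeros(len(y))
            m_xi = np.einsum("cr,cr->c", mu_Hg[oi], mu_He[oj])
            Smg = S_Hg + np.einsum("ir,is->irs", mu_Hg, mu_Hg)
            Sme = S_He + np.einsum("jr,js->jrs", mu_He, mu_He)
            quad = np.einsum("crs,csr->c", Smg[oi], Sme[oj])
            return m_xi, quad

        def expected_sq_residual():
            m_xi, quad = cell_interaction()
            mean_resid = y - mu_g[oi] - mu_e[oj] - m_xi
            return mean_resid**2 + v_g[oi] + v_e[oj] + (quad - m_xi**2), m_xi

        elbo_trace: list[float] = []
        converged = False
        for it in range(max_iter):
            # 1) residual precisions
            Er2, _ = expected_sq_residual()
            a_t = h.alpha_j + 0.5 * n_cells_j
            b_t = h.beta_j + 0.5 * np.bincount(oj, weights=w * Er2, minlength=Ne)
            Etau = a_t / b_t
            wt = w * Etau[oj]

            # 2) genetic main effect: kernel weights then g
            mu_a0 = S_a0 @ (Kg @ mu_g) / h.sigma2_g0
            m_xi, _ = cell_interaction()
            prec_g = 1.0 / h.sigma2_g0 + np.bincount(oi, weights=wt, minlength=Ng)
            num_g = (Kg @ mu_a0) / h.sigma2_g0 + np.bincount(
                oi, weights=wt * (y - mu_e[oj] - m_xi), minlength=Ng)
            mu_g, v_g = num_g / prec_g, 1.0 / prec_g

            # 3) environment main effects
            prec_e = 1.0 / h.sigma2_e0 + np.bincount(oj, weights=wt, minlength=Ne)
            num_e = np.bincount(oj, weights=wt * (y - mu_g[oi] - m_xi), minlength=Ne)
            mu_e, v_e = num_e / prec_e, 1.0 / prec_e

            if R > 0:
                # 4) genotype-side interaction block
                mu_Ag = S_Ag @ (Kg @ mu_Hg) / h.sigma2_g
                Sme = S_He + np.einsum("jr,js->jrs", mu_He, mu_He)
                Lam = np.broadcast_to(np.eye(R) / h.sigma2_g, (Ng, R, R)).copy()
                np.add.at(Lam, oi, wt[:, None, None] * Sme[oj])
                rhs = (Kg @ mu_Ag) / h.sigma2_g
                contrib = (wt * (y - mu_g[oi] - mu_e[oj]))[:, None] * mu_He[oj]
                rhs_full = rhs.copy()
                np.add.at(rhs_full, oi, contrib)
                S_Hg = np.linalg.inv(Lam)
                mu_Hg = np.einsum("irs,is->ir", S_Hg, rhs_full)

                # 5) environment-side interaction block
                mu_Ae = S_Ae @ (Ke @ mu_He) / h.sigma2_e
                Smg = S_Hg + np.einsum("ir,is->irs", mu_Hg, mu_Hg)
                Lam_e = np.broadcast_to(np.eye(R) / h.sigma2_e, (Ne, R, R)).copy()
                np.add.at(Lam_e, oj, wt[:, None, None] * Smg[oi])
                rhs_e = (Ke @ mu_Ae) / h.sigma2_e
                contrib_e = (wt * (y - mu_g[oi] - mu_e[oj]))[:, None] * mu_Hg[oi]
                rhs_e_full = rhs_e.copy()
                np.add.at(rhs_e_full, oj, contrib_e)
                S_He = np.linalg.inv(Lam_e)
                mu_He = np.einsum("jrs,js->jr", S_He, rhs_e_full)

            # --- ELBO ------------------------------------------------------
            state = dict(mu_a0=mu_a0, S_a0=S_a0, mu_g=mu_g, v_g=v_g,
                         mu_e=mu_e, v_e=v_e, tau_shape=a_t, tau_rate=b_t)
            if R > 0:
                state.update(mu_Ag=mu_Ag, S_Ag=S_Ag, mu_Hg=mu_Hg, S_Hg=S_Hg,
                             mu_Ae=mu_Ae, S_Ae=S_Ae, mu_He=mu_He, S_He=S_He)
            elbo = compute_elbo(h, Kg, Ke, self.obs, state)

            if elbo_trace:
                prev = elbo_trace[-1]
                if elbo < prev - _ELBO_SLACK * max(1.0, abs(prev)):
                    raise RuntimeError(
                        f"ELBO decreased at iteration {it} ({prev:.6f} -> {elbo:.6f}); "
                        "variational update order is inconsistent"
                    )
                if abs(elbo - prev) < tol * max(1.0, abs(prev)):
                    elbo_trace.append(elbo)
                    converged = True
                    break
            elbo_trace.append(elbo)

        params = dict(
            mu_a0=mu_a0, S_a0=S_a0, mu_g=mu_g, v_g=v_g, mu_e=mu_e, v_e=v_e,
            tau_shape=a_t, tau_rate=b_t,
        )
        if R > 0:
            params.update(mu_Ag=mu_Ag, S_Ag=S_Ag, mu_Hg=mu_Hg, S_Hg=S_Hg,
                          mu_Ae=mu_Ae, S_Ae=S_Ae, mu_He=mu_He, S_He=S_He)
            # identifiability-respecting prediction parameters: the latent
            # environment factors can absorb a genotype main-effect component
            # (their column means are not pinned to zero by the likelihood).
            # Fold that mean into the genetic kernel regression and predict
            # with centred environment factors, so that a new environment
            # far from the training support reverts to the full additive
            # prediction instead of silently dropping the absorbed part:
            #   g'_new = kg_rows (a0 + Ag m),  he'_new = ke_rows (Ae - d m^T)
            # with m the mean training environment factor and d the ridge
            # representation of the constant vector (exact reparameterization
            # of the fitted surface).
            m_He = mu_He.mean(axis=0)
            d_const = S_Ae @ (Ke @ np.ones(Ne)) / h.sigma2_e
            params["mu_a0_pred"] = mu_a0 + mu_Ag @ m_He
            params["mu_Ae_pred"] = mu_Ae - np.outer(d_const, m_He)
        return GxEFactorResults(
            model=self, params=params, elbo_trace=np.asarray(elbo_trace),
            converged=converged,
        )


@dataclass
class GxEFactorResults:
    """Posterior moments, ELBO trace and prediction interface of a fit."""

    model: GxEFactorModel
    params: dict
    elbo_trace: np.ndarray
    converged: bool

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])

    def compute_elbo(self) -> float:
        """Recompute the ELBO from the stored posterior moments.

        Equals the last entry of :attr:`elbo_trace` up to floating error.
        """
        return compute_elbo(self.model.hyp, self.model.Kg, self.model.Ke,
                            self.model.obs, self.params)

    @property
    def genetic_effects(self) -> np.ndarray:
        """Posterior mean genetic main effects of the training genotypes."""
        return self.params["mu_g"]

    @property
    def environment_effects(self) -> np.ndarray:
        return self.params["mu_e"]

    @property
    def residual_variances(self) -> np.ndarray:
        """Posterior mean residual variance per environment (inverse-Gamma mean)."""
        a, b = self.params["tau_shape"], self.params["tau_rate"]
        return b / np.maximum(a - 1.0, 1e-12)

    def interaction_matrix(self) -> np.ndarray:
        """Posterior mean of the G x E interaction matrix Xi = Hg He^T."""
        if self.model.hyp.R == 0:
            return np.zeros((self.model.obs.n_genotypes, self.model.obs.n_environments))
        return self.params["mu_Hg"] @ self.params["mu_He"].T

    # ------------------------------------------------------------------
    def predict(self, kg_rows: np.ndarray, ke_rows: np.ndarray | None = None,
                env_index: np.ndarray | None = None) -> np.ndarray:
        """Predicted yields for new genotypes x new environments.

        ``kg_rows``: (n_new_geno, Ng) genomic kernel rows against training
        genotypes. ``ke_rows``: (n_new_env, Ne) composite environmental
        kernel rows against training environments (ignored when R = 0, in
        which case pass the number of environments implicitly via
        ``env_index`` or get a single additive column). ``env_index`` maps
        each prediction environment to a training-environment index (whose
        posterior-mean main effect is then used) or -1 for a genuinely new
        environment (prior mean 0).
        """
        kg_rows = np.atleast_2d(np.asarray(kg_rows, dtype=float))
        if kg_rows.shape[1] != self.model.Kg.shape[0]:
            raise ValueError("kg_rows width does not match the training genotype count")
        h = self.model.hyp
        if ke_rows is None:
            ke_rows = np.zeros((1, self.model.Ke.shape[0]))
        ke_rows = np.atleast_2d(np.asarray(ke_rows, dtype=float))
        if ke_rows.shape[1] != self.model.Ke.shape[0]:
            raise ValueError("ke_rows width does not match the training environment count")
        a0 = self.params.get("mu_a0_pred", self.params["mu_a0"])
        g_new = kg_rows @ a0
        if env_index is None:
            e_new = np.zeros(ke_rows.shape[0])
        else:
            env_index = np.asarray(env_index, dtype=int)
            e_new = np.where(env_index >= 0, self.params["mu_e"][env_index], 0.0)
        pred = g_new[:, None] + e_new[None, :]
        if h.R > 0:
            hg = kg_rows @ self.params["mu_Ag"]
            he = ke_rows @ self.params.get("mu_Ae_pred", self.params["mu_Ae"])
            pred = pred + hg @ he.T
        return pred

    @property
    def fittedvalues(self) -> np.ndarray:
        """Model-mean yield surface over the training genotypes x environments."""
        return self.predict(self.model.Kg, self.model.Ke,
                            env_index=np.arange(self.model.Ke.shape[0]))

    def predict_historical(self, kg_rows: np.ndarray,
                           weather_history: Mapping[int, WeatherSeries] | Sequence,
                           soil: SoilProfile, builder: EnvironmentKernelBuilder,
                           zone: str | None = None) -> np.ndarray:
        """Predict a future season from historical weather at a location.

        For each historical year the season block (May 1 - Aug 31) is
        extracted, composite environmental kernel rows are built with the
        frozen training normalizations and kernel weights, and a prediction
        is made; the per-genotype median across years is returned.
        """
        seasons = []
        if isinstance(weather_history, Mapping):
            series = list(weather_history.values())
        else:
            series = list(weather_history)
        if not series:
            raise ValueError("predict_historical requires at least one historical year")
        for ws in series:
            seasons.append(ws if isinstance(ws, np.ndarray) else extract_season(ws))
        preds = []
        for season in seasons:
            blocks = builder_blocks_single(builder, season, soil, zone)
            rows = builder.composite_rows(blocks)
            preds.append(self.predict(kg_rows, rows)[:, 0])
        return np.median(np.stack(preds, axis=1), axis=1)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        h = self.model.hyp
        lines = [
            "G x E kernel factorization fit",
            "=" * 46,
            f"genotypes: {self.model.obs.n_genotypes}   environments: "
            f"{self.model.obs.n_environments}   observed cells: {len(self.model.obs.values)}",
            f"interaction rank R: {h.R}",
            f"ELBO: {self.elbo:.4f} after {len(self.elbo_trace)} sweeps "
            f"(converged: {self.converged})",
            "-" * 46,
            f"{'component':<28}{'value':>12}",
            f"{'Var(genetic main), prior':<28}{(h.var_genetic if h.var_genetic else float('nan')):>12.4f}",
            f"{'sd(g) posterior':<28}{np.std(self.genetic_effects):>12.4f}",
            f"{'sd(e) posterior':<28}{np.std(self.environment_effects):>12.4f}",
            f"{'mean residual variance':<28}{np.mean(self.residual_variances):>12.4f}",
        ]
        if h.R > 0:
            lines.append(f"{'sd(interaction) posterior':<28}{np.std(self.interaction_matrix()):>12.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize posterior moments + hyperparameters to a .npz archive."""
        arrays = {k: np.asarray(v) for k, v in self.params.items()}
        arrays["elbo_trace"] = self.elbo_trace
        arrays["converged"] = np.array(self.converged)
        hyp = self.model.hyp
        arrays["hyp"] = np.array([hyp.lambda_g0, hyp.sigma2_g0, hyp.R,
                                  hyp.lambda_g or 0, hyp.sigma2_g or 0,
                                  hyp.lambda_e or 0, hyp.sigma2_e or 0,
                                  hyp.alpha_j, hyp.beta_j, hyp.sigma2_e0])
        np.savez(path, **arrays)


def builder_blocks_single(builder: EnvironmentKernelBuilder, season: np.ndarray,
                          soil: SoilProfile, zone: str | None) -> dict[str, np.ndarray]:
    """Covariate blocks for a single hypothetical environment."""
    season = np.asarray(season, dtype=float)
    levels = getattr(builder, "_zone_levels", None) or ["z0"]
    z = np.zeros((1, len(levels)))
    label = zone if zone is not None else levels[0]
    if label in levels:
        z[0, levels.index(label)] = 1.0
    return {
        "soil": soil.vector()[None, :],
        "temperature": season[None, :, 0],
        "rain": season[None, :, 1],
        "zone": z,
    }
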