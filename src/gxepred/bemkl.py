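"""Bayesian multiple-kernel regression for environmental kernel weights.

The relative importance of the environmental data sources (soil, rain,
temperature, their interactions, growth zone) is learned by variational
Bayesian multiple-kernel regression: each kernel produces an intermediate
kernel-regression output, and the response (per-environment mean yield) is
a weighted sum of those intermediates. The posterior-mean kernel weights
are then rescaled to unit sum of squares, with an overall sign flip so the
largest-magnitude weight is positive, and frozen before being used to
combine the kernels — weights are learned on training environments only so
that no information leaks from validation or test environments.

Priors: all Gamma precision priors have shape and scale 1, except the
per-sample weight precision whose scale is 10 (stronger shrinkage of the
kernel-regression weights); the regression bias is fixed to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSet

__all__ = [
    "MklConfig",
    "KernelWeightModel",
    "KernelWeightResults",
    "environment_mean_targets",
    "normalize_weights",
]


@dataclass
class MklConfig:
    """Prior and convergence settings for the multiple-kernel regression.

    ``gamma_shape``/``gamma_scale`` parameterize every Gamma precision
    prior (shape-scale convention); ``lambda_scale`` overrides the scale of
    the sample-weight precision prior; ``bias`` is the fixed regression
    intercept.
    """

    gamma_shape: float = 1.0
    gamma_scale: float = 1.0
    lambda_scale: float = 10.0
    bias: float = 0.0
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.gamma_shape, self.gamma_scale, self.lambda_scale) <= 0:
            raise ValueError("Gamma shapes and scales must be positive")


def environment_mean_targets(trials) -> "tuple[np.ndarray, np.ndarray]":
    """Per-environment mean (z-scale) yield, the MKL regression target.

    Returns ``(env_ids, targets)`` sorted by environment id.
    """
    g = trials.data.groupby("env")["yield"]
    means = g.mean()
    if means.isna().any():  # pragma: no cover - grouping never yields empty
        raise ValueError("environment with no yield records")
    return means.index.to_numpy(dtype=object), means.to_numpy(dtype=float)


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Scale to unit sum of squares; flip sign so the largest |weight| > 0."""
    w = np.asarray(raw, dtype=float)
    nrm = float(np.linalg.norm(w))
    if nrm == 0.0:
        raise ValueError("cannot normalize an all-zero weight vector")
    w = w / nrm
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


@dataclass
class KernelWeightResults:
    """Posterior-mean kernel weights and fit diagnostics."""

    names: list[str]
    raw: np.ndarray
    weights: np.ndarray  # normalized
    converged: bool
    n_iter: int
    noise_precision: float

    def summary(self) -> str:
        lines = ["kernel weight summary", "-" * 42]
        lines.append(f"{'kernel':<24}{'raw':>9}{'norm':>9}")
        for n, r, w in zip(self.names, self.raw, self.weights):
            lines.append(f"{n:<24}{r:>9.4f}{w:>9.4f}")
        lines.append("-" * 42)
        lines.append(f"converged: {self.converged} after {self.n_iter} iterations")
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kernel\traw\tnormalized\n")
            for n, r, w in zip(self.names, self.raw, self.weights):
                fh.write(f"{n}\t{r:.10g}\t{w:.10g}\n")


class KernelWeightModel:
    """Variational multiple-kernel regression on environment mean yields.

    Model (per environment ``i`` with response ``y_i``):

    * sample weights ``a ~ N(0, diag(lambda)^-1)`` with Gamma priors on the
      per-sample precisions ``lambda_i``;
    * intermediate outputs ``g_{m,i} ~ N(k_{m,i}^T a, upsilon^-1)`` for
      each kernel ``m``, with a Gamma prior on the shared intermediate
      precision ``upsilon``;
    * kernel weights ``e_m ~ N(0, omega_m^-1)`` with Gamma priors on
      ``omega_m``;
    * response ``y_i ~ N(e^T g_i + b, eps^-1)`` with a Gamma prior on the
      noise precision ``eps``.

    Coordinate-ascent updates of the factorized posterior are iterated
    until the posterior-mean weight vector stabilizes.
    """

    def __init__(self, kernel_set: KernelSet, targets: np.ndarray,
                 config: MklConfig | None = None):
        if len(kernel_set) < 1:
            raise ValueError("need at least one kernel")
        y = np.asarray(targets, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite regression targets")
        if y.shape != (kernel_set.kernels[0].n,):
            raise ValueError("target length does not match kernel size")
        self.kernel_set = kernel_set
        self.y = y
        self.config = config or MklConfig()

    def fit(self, seed: int = 0) -> KernelWeightResults:
        cfg = self.config
        K = self.kernel_set.stacked()  # (P, N, N)
        P, N, _ = K.shape
        y = self.y - cfg.bias
        rng = np.random.default_rng(seed)

        # posterior initialization (means; small symmetric-breaking noise)
        mu_a = np.zeros(N)
        S_a = np.eye(N)
        mu_G = K @ mu_a + 0.01 * rng.standard_normal((P, N))
        S_G = np.eye(P)  # shared across samples
        mu_e = np.full(P, 1.0 / np.sqrt(P))
        S_e = np.eye(P)
        Elam = np.full(N, cfg.gamma_shape * cfg.lambda_scale)
        Eom = np.full(P, cfg.gamma_shape * cfg.gamma_scale)
        Eeps = cfg.gamma_shape * cfg.gamma_scale
        Eups = cfg.gamma_shape * cfg.gamma_scale

        KK = np.einsum("pij,pkj->ik", K, K)  # sum_m K_m K_m^T
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            w_prev = mu_e.copy()

            # q(lambda): per-sample precisions of a
            a2 = mu_a**2 + np.diag(S_a)
            Elam = (cfg.gamma_shape + 0.5) / (1.0 / cfg.lambda_scale + 0.5 * a2)

            # q(a)
            prec_a = np.diag(Elam) + Eups * KK
            S_a = np.linalg.inv(prec_a)
            mu_a = Eups * (S_a @ np.einsum("pij,pj->i", K, mu_G))

            # q(G): shared P x P covariance, per-sample means
            Eee = S_e + np.outer(mu_e, mu_e)
            S_G = np.linalg.inv(Eups * np.eye(P) + Eeps * Eee)
            prior_mean = np.einsum("pij,j->pi", K, mu_a)  # K_m a
            mu_G = S_G @ (Eups * prior_mean + Eeps * np.outer(mu_e, y))

            # q(upsilon): shared intermediate-output precision
            quad_a = np.einsum("pij,jk,pik->", K, S_a, K)  # sum tr(k S_a k')
            dev = mu_G - prior_mean
            g2 = float(np.sum(dev**2) + N * np.trace(S_G) + quad_a)
            Eups = (cfg.gamma_shape + 0.5 * N * P) / (
                1.0 / cfg.gamma_scale + 0.5 * g2)

            # q(omega)
            e2 = mu_e**2 + np.diag(S_e)
            Eom = (cfg.gamma_shape + 0.5) / (1.0 / cfg.gamma_scale + 0.5 * e2)

            # q(e)
            EGG = N * S_G + mu_G @ mu_G.T
            S_e = np.linalg.inv(np.diag(Eom) + Eeps * EGG)
            mu_e = S_e @ (Eeps * mu_G @ y)

            # q(eps)
            resid = float(y @ y - 2.0 * y @ (mu_G.T @ mu_e) + np.sum(Eee * EGG))
            Eeps = (cfg.gamma_shape + 0.5 * N) / (1.0 / cfg.gamma_scale + 0.5 * resid)

            # scale-free criterion: the direction of the weight vector is
            # what downstream kernel combination consumes
            if np.linalg.norm(mu_e) > 0 and np.linalg.norm(w_prev) > 0:
                delta = np.max(np.abs(normalize_weights(mu_e) - normalize_weights(w_prev)))
                if delta < cfg.tol:
                    converged = True
                    break

        if not converged:
            import warnings

            warnings.warn(
                f"kernel-weight learner did not converge in {cfg.max_iter} "
                "iterations; returning best iterate",
                RuntimeWarning,
            )
        return KernelWeightResults(
            names=self.kernel_set.names,
            raw=mu_e.copy(),
            weights=normalize_weights(mu_e),
            converged=converged,
            n_iter=it,
            noise_precision=float(Eeps),
        )
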