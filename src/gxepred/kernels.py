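"""Kernel construction, normalization and combination.

All covariate data enter the models as similarity (kernel) matrices. Two
normalizations are used throughout:

* unit-diagonal: ``K'_ij = K_ij / sqrt(K_ii K_jj)``, so every item has
  self-similarity 1;
* total-variance: ``K'' = c K'`` with ``c = [sum_i Var(k'_i)]^{-1/2}``,
  where ``Var`` is the population (1/N) variance of column ``i``. After
  this scaling, the summed column variances equal 1, so when several
  kernels are added each explains a priori the same amount of variance.

The environmental kernel is a weighted sum over a registry of data-source
and transformation specific kernels (soil, 123-day rain and temperature
season vectors, each linear and Gaussian, the soil x rain Hadamard
interaction, and a growth-zone indicator kernel); the weights come from
Bayesian multiple-kernel learning (:mod:`gxepred.bemkl`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Kernel",
    "KernelSet",
    "linear_kernel",
    "gaussian_kernel",
    "normalize_unit_diagonal",
    "normalize_total_variance",
    "hadamard_interaction",
    "combine_kernels",
    "clip_negative_eigenvalues",
    "DEFAULT_REGISTRY",
    "EnvironmentKernelBuilder",
    "GenomicKernelBuilder",
    "save_kernel",
    "load_kernel",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class Kernel:
    """A square PSD similarity matrix with provenance and normalization flags."""

    matrix: np.ndarray
    ids: np.ndarray
    provenance: str = ""
    unit_diagonal: bool = False
    total_variance: bool = False

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel matrix must be square")
        asym = np.abs(K - K.T).max() if K.size else 0.0
        if asym > 1e-8:
            raise ValueError(f"kernel {self.provenance!r} not symmetric (max dev {asym:.2e})")
        self.matrix = 0.5 * (K + K.T)
        self.ids = np.asarray(self.ids, dtype=object)
        if len(self.ids) != K.shape[0]:
            raise ValueError("kernel ids do not match matrix size")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def check_psd(self, tol: float = _PSD_TOL) -> None:
        w = np.linalg.eigvalsh(self.matrix)
        scale = max(w.max(), 1e-12)
        if w.min() < -tol * scale:
            raise ValueError(
                f"kernel {self.provenance!r} not PSD (min eig {w.min():.3e})"
            )


@dataclass
class KernelSet:
    """An ordered collection of kernels over the same ids."""

    kernels: list[Kernel]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("empty kernel set")
        ref = self.kernels[0].ids
        for k in self.kernels[1:]:
            if len(k.ids) != len(ref) or (k.ids != ref).any():
                raise ValueError("kernels in a set must share identical id ordering")

    def __len__(self) -> int:
        return len(self.kernels)

    def __iter__(self):
        return iter(self.kernels)

    @property
    def ids(self) -> np.ndarray:
        return self.kernels[0].ids

    @property
    def names(self) -> list[str]:
        return [k.provenance for k in self.kernels]

    def stacked(self) -> np.ndarray:
        """(P, N, N) array of member matrices."""
        return np.stack([k.matrix for k in self.kernels])


# ---------------------------------------------------------------------------
# Constructors and normalizations
# ---------------------------------------------------------------------------

def linear_kernel(X: np.ndarray, ids=None, provenance: str = "linear") -> Kernel:
    """Standard linear kernel ``K = X X^T``."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("linear_kernel: covariates contain missing values")
    if X.ndim == 1:
        X = X[None, :]
    ids = np.arange(X.shape[0]) if ids is None else ids
    return Kernel(X @ X.T, ids, provenance)


def gaussian_kernel(
    X: np.ndarray, bandwidth: float | None = None, ids=None, provenance: str = "gaussian"
) -> Kernel:
    """Gaussian kernel ``K_ij = exp(-||x_i - x_j||^2 / (2 h))``.

    The bandwidth ``h`` defaults to the number of covariate columns, the
    package-wide default for all Gaussian kernels.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if np.isnan(X).any():
        raise ValueError("gaussian_kernel: covariates contain missing values")
    h = float(X.shape[1]) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    K = np.exp(-d2 / (2.0 * h))
    np.fill_diagonal(K, 1.0)
    ids = np.arange(X.shape[0]) if ids is None else ids
    return Kernel(K, ids, provenance, unit_diagonal=True)


def normalize_unit_diagonal(k: Kernel) -> Kernel:
    """Rescale to unit diagonal: ``K_ij / sqrt(K_ii K_jj)``."""
    d = np.diag(k.matrix).copy()
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValueError(
            f"kernel {k.provenance!r}: non-positive diagonal at index {bad[0]}"
        )
    s = 1.0 / np.sqrt(d)
    K = k.matrix * np.outer(s, s)
    np.fill_diagonal(K, 1.0)
    return replace(k, matrix=K, unit_diagonal=True)


def _sum_column_variances(K: np.ndarray) -> float:
    # population variance per column, summed
    return float(np.sum(K.var(axis=0)))


def normalize_total_variance(k: Kernel) -> Kernel:
    """Scale so the summed population column variances equal 1."""
    v = _sum_column_variances(k.matrix)
    if v <= 0:
        raise ValueError(f"kernel {k.provenance!r}: all columns constant, cannot normalize")
    c = 1.0 / np.sqrt(v)
    return replace(k, matrix=c * k.matrix, total_variance=True, unit_diagonal=False)


def hadamard_interaction(k1: Kernel, k2: Kernel, provenance: str | None = None) -> Kernel:
    """Elementwise (Schur) product of two unit-diagonal kernels.

    The Schur product theorem guarantees the result stays PSD; unit
    diagonals are preserved, so the product is again a valid normalized
    kernel representing the interaction of the two data sources.
    """
    if not (k1.unit_diagonal and k2.unit_diagonal):
        raise ValueError("hadamard_interaction requires unit-diagonal inputs")
    if len(k1.ids) != len(k2.ids) or (k1.ids != k2.ids).any():
        raise ValueError("hadamard_interaction: kernel id mismatch")
    name = provenance or f"{k1.provenance}x{k2.provenance}"
    return Kernel(k1.matrix * k2.matrix, k1.ids, name, unit_diagonal=True)


def clip_negative_eigenvalues(K: np.ndarray, tol: float = _PSD_TOL) -> np.ndarray:
    """Project onto the PSD cone by zeroing negative eigenvalues."""
    w, V = np.linalg.eigh(K)
    if w.min() >= 0:
        return K
    w = np.clip(w, 0.0, None)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)


def combine_kernels(ks: KernelSet, weights: Sequence[float], final_normalize: bool = True) -> Kernel:
    """Weighted sum of normalized kernels, then total-variance normalized.

    Every member must carry the total-variance flag (i.e. have been through
    the full normalization pipeline). Because learned weights may be
    negative, the sum is projected back onto the PSD cone before use.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(ks),):
        raise ValueError(f"expected {len(ks)} weights, got {w.shape}")
    if not np.isfinite(w).all():
        raise ValueError("non-finite kernel weights")
    for k in ks:
        if not k.total_variance:
            raise ValueError(f"kernel {k.provenance!r} is not total-variance normalized")
    K = np.einsum("p,pij->ij", w, ks.stacked())
    K = clip_negative_eigenvalues(0.5 * (K + K.T))
    out = Kernel(K, ks.ids, "composite")
    if final_normalize:
        out = normalize_total_variance(out)
    return out


# ---------------------------------------------------------------------------
# Environment kernel registry
# ---------------------------------------------------------------------------

#: Default registry: (name, source block, transform). ``soil`` is the
#: 4-vector (sand, silt, clay, organic); ``rain``/``temperature`` are the
#: 123-day season vectors; ``zone`` is a one-hot growth-zone indicator.
#: ``("soil_x_rain", ..., "hadamard")`` multiplies the soil and rain
#: Gaussian kernels elementwise.
DEFAULT_REGISTRY: list[tuple[str, str, str]] = [
    ("soil_gaussian", "soil", "gaussian"),
    ("soil_linear", "soil", "linear"),
    ("rain_gaussian", "rain", "gaussian"),
    ("rain_linear", "rain", "linear"),
    ("temperature_gaussian", "temperature", "gaussian"),
    ("temperature_linear", "temperature", "linear"),
    ("soil_x_rain", "soil_gaussian*rain_gaussian", "hadamard"),
    ("zone_linear", "zone", "linear"),
]


class EnvironmentKernelBuilder:
    """Build the environmental kernel set from covariate blocks.

    The builder is fitted on the *training* environments: it standardizes
    each covariate column (except indicator blocks), computes each registry
    kernel, normalizes it (unit diagonal then total variance) and remembers
    every constant needed to later evaluate consistent cross-kernel rows
    for new environments (e.g. future seasons reconstructed from historical
    weather).

    Parameters
    ----------
    registry : list of (name, source, transform)
        Kernel registry; defaults to :data:`DEFAULT_REGISTRY`.
    """

    def __init__(self, registry: list[tuple[str, str, str]] | None = None):
        self.registry = list(registry) if registry is not None else list(DEFAULT_REGISTRY)
        self._fitted = False

    # -- covariate assembly -------------------------------------------------

    @staticmethod
    def covariate_blocks(env_table: pd.DataFrame, seasons: dict, soils: dict,
                         zones: dict | None = None) -> dict[str, np.ndarray]:
        """Assemble raw covariate blocks for the environments in ``env_table``.

        ``seasons`` maps (location, year) to a (123, 2) season matrix;
        ``soils`` maps field_block to :class:`~gxepred.datamodel.SoilProfile`;
        ``zones`` optionally maps location to a growth-zone label.
        """
        soil_rows, rain_rows, temp_rows, zone_labels = [], [], [], []
        for r in env_table.itertuples():
            key = (r.location, int(r.year))
            if key not in seasons:
                raise KeyError(f"no season weather for environment {r.env} ({key})")
            if r.field_block not in soils:
                raise KeyError(f"no soil profile for environment {r.env} ({r.field_block})")
            season = np.asarray(seasons[key], dtype=float)
            soil_rows.append(soils[r.field_block].vector())
            temp_rows.append(season[:, 0])
            rain_rows.append(season[:, 1])
            zone_labels.append(zones.get(r.location, "z0") if zones else "z0")
        levels = sorted(set(zone_labels))
        zone = np.zeros((len(zone_labels), len(levels)))
        for i, z in enumerate(zone_labels):
            zone[i, levels.index(z)] = 1.0
        return {
            "soil": np.asarray(soil_rows),
            "rain": np.asarray(rain_rows),
            "temperature": np.asarray(temp_rows),
            "zone": zone,
            "_zone_levels": levels,
            "_zone_labels": zone_labels,
        }

    # -- fitting ------------------------------------------------------------

    def fit(self, blocks: dict[str, np.ndarray], ids: Sequence) -> "EnvironmentKernelBuilder":
        """Standardize blocks, build and normalize every registry kernel."""
        self.ids = np.asarray(ids, dtype=object)
        self._zone_levels = blocks.get("_zone_levels")
        self._scalers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._X: dict[str, np.ndarray] = {}
        for name, X in blocks.items():
            if name.startswith("_"):
                continue
            X = np.asarray(X, dtype=float)
            if name == "zone":  # indicators used as-is
                self._scalers[name] = (np.zeros(X.shape[1]), np.ones(X.shape[1]))
                self._X[name] = X
                continue
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            self._scalers[name] = (mu, sd)
            self._X[name] = (X - mu) / sd

        self._base: dict[str, Kernel] = {}   # unit-diagonal stage (for hadamard + rows)
        self._scale: dict[str, float] = {}   # total-variance constants c_p
        kernels: list[Kernel] = []
        for name, source, transform in self.registry:
            k_unit = self._unit_kernel(name, source, transform)
            v = _sum_column_variances(k_unit.matrix)
            if v <= 0:
                raise ValueError(f"kernel {name!r} has zero total variance on training data")
            c = 1.0 / np.sqrt(v)
            self._base[name] = k_unit
            self._scale[name] = c
            kernels.append(
                Kernel(c * k_unit.matrix, self.ids, name, total_variance=True)
            )
        self.kernel_set = KernelSet(kernels)
        self._fitted = True
        return self

    def _unit_kernel(self, name: str, source: str, transform: str) -> Kernel:
        if transform == "hadamard":
            a, b = source.split("*")
            return hadamard_interaction(self._base[a], self._base[b], provenance=name)
        if source not in self._X:
            raise KeyError(f"missing covariate block {source!r} for kernel {name!r}")
        X = self._X[source]
        if transform == "gaussian":
            return replace(gaussian_kernel(X, ids=self.ids), provenance=name)
        if transform == "linear":
            return normalize_unit_diagonal(linear_kernel(X, ids=self.ids, provenance=name))
        raise ValueError(f"unknown transform {transform!r}")

    # -- composition --------------------------------------------------------

    def composite(self, weights: Sequence[float]) -> Kernel:
        """Weighted composite environmental kernel over training environments."""
        self._require_fitted()
        k = combine_kernels(self.kernel_set, weights)
        # remember the final scaling and the PSD projection so cross rows
        # stay consistent with the (possibly eigenvalue-clipped) training
        # kernel: learned weights may be negative, and new-environment rows
        # must live in the same retained eigenspace
        raw = np.einsum("p,pij->ij", np.asarray(weights, float), self.kernel_set.stacked())
        raw = 0.5 * (raw + raw.T)
        w_eig, V = np.linalg.eigh(raw)
        keep = w_eig > 0
        self._psd_projector = (V * keep.astype(float)) @ V.T if not keep.all() else None
        clipped = (V * np.clip(w_eig, 0.0, None)) @ V.T
        self._final_c = 1.0 / np.sqrt(_sum_column_variances(clipped))
        self._weights = np.asarray(weights, dtype=float)
        return replace(k, provenance="environment_composite")

    def composite_rows(self, blocks: dict[str, np.ndarray], weights: Sequence[float] | None = None
                       ) -> np.ndarray:
        """Composite kernel rows (new envs x training envs) with frozen scaling.

        ``blocks`` holds raw covariate blocks for the new environments in
        the same layout as :meth:`covariate_blocks`. Standardization, per-
        kernel normalization constants and the final composite scaling are
        all the ones fixed at fit time, so predictions for new environments
        use exactly the geometry the model was trained in.
        """
        self._require_fitted()
        if weights is None:
            weights = self._weights
        w = np.asarray(weights, dtype=float)
        blocks = dict(blocks)
        if "_zone_labels" in blocks and self._zone_levels:
            # re-encode zone indicators against the training levels; labels
            # unseen in training get an all-zero row
            Z = np.zeros((len(blocks["_zone_labels"]), len(self._zone_levels)))
            for i, z in enumerate(blocks["_zone_labels"]):
                if z in self._zone_levels:
                    Z[i, self._zone_levels.index(z)] = 1.0
            blocks["zone"] = Z
        newX: dict[str, np.ndarray] = {}
        for name, (mu, sd) in self._scalers.items():
            if name not in blocks:
                raise KeyError(f"missing covariate block {name!r} for new environments")
            X = np.asarray(blocks[name], dtype=float)
            newX[name] = X if name == "zone" else (X - mu) / sd

        unit_rows: dict[str, np.ndarray] = {}
        rows_sum = None
        for wp, (name, source, transform) in zip(w, self.registry):
            if transform == "hadamard":
                a, b = source.split("*")
                rows = unit_rows[a] * unit_rows[b]
            else:
                Xn, Xt = newX[source], self._X[source]
                if transform == "gaussian":
                    h = float(Xt.shape[1])
                    d2 = (
                        np.sum(Xn**2, axis=1)[:, None]
                        + np.sum(Xt**2, axis=1)[None, :]
                        - 2.0 * Xn @ Xt.T
                    )
                    rows = np.exp(-np.maximum(d2, 0.0) / (2.0 * h))
                else:
                    raw = Xn @ Xt.T
                    # rows identical to the training mean (zero norm) get zero
                    # similarity rather than a division error
                    dn = np.sum(Xn**2, axis=1)
                    dt = np.sum(Xt**2, axis=1)
                    s_n = np.where(dn > 0, 1.0 / np.sqrt(np.where(dn > 0, dn, 1.0)), 0.0)
                    s_t = np.where(dt > 0, 1.0 / np.sqrt(np.where(dt > 0, dt, 1.0)), 0.0)
                    rows = raw * np.outer(s_n, s_t)
            unit_rows[name] = rows
            contrib = wp * self._scale[name] * rows
            rows_sum = contrib if rows_sum is None else rows_sum + contrib
        if getattr(self, "_psd_projector", None) is not None:
            rows_sum = rows_sum @ self._psd_projector
        return self._final_c * rows_sum

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("EnvironmentKernelBuilder is not fitted")


class GenomicKernelBuilder:
    """Linear genomic kernel on centred dosages, fully normalized.

    Fitted on the training lines; provides consistent cross-kernel rows for
    new (e.g. progeny) lines through the stored column means and
    normalization constants.
    """

    def __init__(self, center: bool = True):
        self.center = center
        self._fitted = False

    def fit(self, dosages: np.ndarray, ids: Sequence) -> "GenomicKernelBuilder":
        X = np.asarray(dosages, dtype=float)
        if np.isnan(X).any():
            raise ValueError("genomic kernel requires imputed (complete) dosages")
        self.ids = np.asarray(ids, dtype=object)
        self._mu = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        Xc = X - self._mu
        raw = Xc @ Xc.T
        d = np.diag(raw).copy()
        if (d <= 0).any():
            # a line identical to the mean genotype: give it unit self-similarity
            d = np.where(d > 0, d, 1.0)
        self._train_diag = d
        s = 1.0 / np.sqrt(d)
        K1 = raw * np.outer(s, s)
        self._c = 1.0 / np.sqrt(_sum_column_variances(K1))
        self._Xc = Xc
        self.kernel = Kernel(self._c * K1, self.ids, "genomic_linear", total_variance=True)
        self._fitted = True
        return self

    def rows(self, dosages: np.ndarray) -> np.ndarray:
        """Normalized kernel rows (new lines x training lines)."""
        if not self._fitted:
            raise RuntimeError("GenomicKernelBuilder is not fitted")
        Xn = np.asarray(dosages, dtype=float) - self._mu
        raw = Xn @ self._Xc.T
        dn = np.sum(Xn**2, axis=1)
        dn = np.where(dn > 0, dn, 1.0)
        return self._c * raw * np.outer(1.0 / np.sqrt(dn), 1.0 / np.sqrt(self._train_diag))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_kernel(k: Kernel, path) -> None:
    """Write a kernel as a delimited matrix with an id header row/column."""
    pd.DataFrame(k.matrix, index=k.ids, columns=k.ids).to_csv(path, sep="\t")


def load_kernel(path, provenance: str = "precomputed") -> Kernel:
    """Read a square delimited kernel matrix with matching id header."""
    df = pd.read_csv(path, sep=_detect_sep_path(path), index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("kernel file row and column ids do not match")
    return Kernel(df.to_numpy(dtype=float), df.index.to_numpy(dtype=object), provenance)


def _detect_sep_path(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","
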