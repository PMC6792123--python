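"""Typed containers and readers for genotype, trial, weather and soil data.

The package works with four kinds of raw input, all plain delimited text:

* a genotype matrix of biallelic SNP dosages (lines x markers, codes 0/1/2,
  missing allowed), optionally derived from a VCF;
* a trial table of yield observations indexed by line, location, year and
  field block;
* daily weather series (mean temperature in deg C, rainfall in mm) per
  location;
* soil texture/organic-content profiles per field block.

Quality control of the genotypes follows the usual genomic-selection
conventions: markers with low minor-allele frequency or too much
missingness are removed first, then lines with too much missingness, and
the small residual fraction of missing dosages is mean-imputed per marker.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "WeatherSeries",
    "SoilProfile",
    "TrialTable",
    "QCError",
    "load_genotypes",
    "genotype_qc",
    "load_vcf_genotypes",
    "load_weather",
    "load_soil",
    "load_trials",
    "ztransform_yields",
    "extract_season",
    "SEASON_START",
    "SEASON_END",
    "SEASON_DAYS",
]

#: Growing-season window used for the weather representation: May 1 to
#: Aug 31 (123 days under the non-leap convention; Feb 29 never intersects
#: the window so leap years need no special case).
SEASON_START = (5, 1)
SEASON_END = (8, 31)
SEASON_DAYS = 123


class QCError(ValueError):
    """Raised when quality control or a data precondition fails."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """SNP dosage matrix with per-line generation labels.

    Parameters
    ----------
    line_ids : array of str
        Unique line identifiers (rows).
    markers : array of str
        Marker identifiers (columns).
    dosages : ndarray, shape (n_lines, n_markers)
        Allele dosages in {0, 1, 2}; ``nan`` marks missing calls.
    generation : array of str
        Per-line label, ``"parent"`` or ``"progeny"``.
    qc_report : dict
        Counts of markers/lines dropped by each filter (filled by QC).
    """

    line_ids: np.ndarray
    markers: np.ndarray
    dosages: np.ndarray
    generation: np.ndarray
    qc_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.generation = np.asarray(self.generation, dtype=object)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise QCError("duplicated line_ids in genotype matrix")
        if self.dosages.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError("dosage matrix shape does not match identifiers")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(self, line_mask=None, marker_mask=None) -> "GenotypeMatrix":
        lm = np.ones(self.n_lines, bool) if line_mask is None else line_mask
        mm = np.ones(self.n_markers, bool) if marker_mask is None else marker_mask
        return GenotypeMatrix(
            self.line_ids[lm],
            self.markers[mm],
            self.dosages[np.ix_(lm, mm)],
            self.generation[lm],
            dict(self.qc_report),
        )

    def loc(self, line_ids: Sequence[str]) -> np.ndarray:
        """Dosage rows for the given line ids, in the given order."""
        index = {l: i for i, l in enumerate(self.line_ids)}
        try:
            rows = [index[l] for l in line_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown line id {exc.args[0]!r}") from exc
        return self.dosages[rows]


def genotype_qc(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.05,
    impute: bool = True,
) -> GenotypeMatrix:
    """Apply marker- then line-level QC filters and mean-impute the rest.

    Markers with minor allele frequency < ``maf_min`` or a missing fraction
    > ``max_missing`` are dropped first; then lines with a missing fraction
    > ``max_missing`` over the retained markers are dropped; finally, any
    residual missing dosages are imputed with the per-marker mean.
    """
    missing = np.isnan(gm.dosages)
    marker_missing = missing.mean(axis=0)
    maf = gm.maf()
    maf_fail = ~(maf >= maf_min)  # nan maf (all-missing marker) fails too
    miss_fail = marker_missing > max_missing
    marker_keep = ~(maf_fail | miss_fail)
    if not marker_keep.any():
        raise QCError(
            "no markers left after QC "
            f"(MAF<{maf_min}: {int(maf_fail.sum())}, "
            f"missing>{max_missing}: {int(miss_fail.sum())})"
        )
    out = gm.subset(marker_mask=marker_keep)

    line_missing = np.isnan(out.dosages).mean(axis=1)
    line_keep = line_missing <= max_missing
    if not line_keep.any():
        raise QCError(f"no lines left after QC (line missingness>{max_missing})")
    out = out.subset(line_mask=line_keep)

    if impute and np.isnan(out.dosages).any():
        col_mean = np.nanmean(out.dosages, axis=0)
        idx = np.where(np.isnan(out.dosages))
        out.dosages[idx] = col_mean[idx[1]]

    out.qc_report = {
        "markers_dropped_maf": int(maf_fail.sum()),
        "markers_dropped_missing": int((miss_fail & ~maf_fail).sum()),
        "lines_dropped_missing": int((~line_keep).sum()),
        "n_markers": out.n_markers,
        "n_lines": out.n_lines,
    }
    return out


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def load_genotypes(
    path,
    maf_min: float = 0.05,
    max_missing: float = 0.05,
    generation_col: str = "generation",
) -> GenotypeMatrix:
    """Read a delimited dosage table (rows=lines, cols=markers) and run QC.

    The first column holds line ids; an optional ``generation`` column holds
    parent/progeny labels (defaults to ``"parent"`` when absent). Cell codes
    are 0/1/2 with empty or ``NA`` for missing.
    """
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str)
    if generation_col in df.columns:
        generation = df.pop(generation_col).to_numpy(dtype=object)
    else:
        generation = np.full(len(df), "parent", dtype=object)
    dosages = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = dosages[~np.isnan(dosages)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise QCError("genotype codes must be 0, 1, 2 or missing")
    gm = GenotypeMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        dosages,
        generation,
    )
    return genotype_qc(gm, maf_min=maf_min, max_missing=max_missing)


def load_vcf_genotypes(path, maf_min: float = 0.05, max_missing: float = 0.05) -> GenotypeMatrix:
    """Read an (uncompressed) VCF, converting GT fields to dosage, then QC."""
    ids: list[str] = []
    rows: list[list[float]] = []
    markers: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = parts[9:]
                continue
            markers.append(parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}")
            row = []
            for sample in parts[9:]:
                gt = sample.split(":")[0].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) > 0 for a in alleles)))
            rows.append(row)
    dosages = np.asarray(rows, dtype=float).T  # samples x markers
    gm = GenotypeMatrix(
        np.asarray(ids, dtype=object),
        np.asarray(markers, dtype=object),
        dosages,
        np.full(len(ids), "parent", dtype=object),
    )
    return genotype_qc(gm, maf_min=maf_min, max_missing=max_missing)


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

@dataclass
class WeatherSeries:
    """Daily weather at one location for one year.

    ``days`` is a DataFrame with columns ``date`` (datetime), ``tmean``
    (deg C) and ``rain`` (mm), strictly increasing in date.
    """

    location: str
    year: int
    days: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.days.reset_index(drop=True).copy()
        d["date"] = pd.to_datetime(d["date"])
        if not d["date"].is_monotonic_increasing or d["date"].duplicated().any():
            raise ValueError(
                f"weather dates for {self.location}/{self.year} must be strictly increasing"
            )
        self.days = d


def load_weather(path) -> dict[tuple[str, int], WeatherSeries]:
    """Read long-format weather CSV (location, date, tmean, rain).

    Returns a mapping from ``(location, year)`` to :class:`WeatherSeries`.
    """
    df = pd.read_csv(path, sep=_detect_sep(path))
    df["date"] = pd.to_datetime(df["date"])
    out: dict[tuple[str, int], WeatherSeries] = {}
    for (loc, yr), sub in df.groupby([df["location"], df["date"].dt.year]):
        out[(str(loc), int(yr))] = WeatherSeries(
            str(loc), int(yr), sub[["date", "tmean", "rain"]].sort_values("date")
        )
    return out


def extract_season(ws: WeatherSeries, max_gap: int = 5) -> np.ndarray:
    """Extract the fixed May 1 - Aug 31 growing-season block.

    Returns a ``(123, 2)`` array of daily ``(tmean, rain)``. The window is
    used regardless of sowing date, so that the same representation can be
    built from historical years where the sowing date is unknown. Small
    gaps (at most ``max_gap`` days per variable, generous relative to the
    2-3 missing days seen in practice) are filled by linear interpolation
    for temperature and by zero for rainfall.
    """
    start = pd.Timestamp(ws.year, *SEASON_START)
    end = pd.Timestamp(ws.year, *SEASON_END)
    d = ws.days
    if d["date"].iloc[0] > start or d["date"].iloc[-1] < end:
        raise ValueError(
            f"weather for {ws.location}/{ws.year} does not cover "
            f"{start.date()}..{end.date()}"
        )
    grid = pd.date_range(start, end, freq="D")
    assert len(grid) == SEASON_DAYS
    season = d.set_index("date").reindex(grid)
    for col, n_missing in (("tmean", season["tmean"].isna().sum()),
                           ("rain", season["rain"].isna().sum())):
        if n_missing > max_gap:
            raise ValueError(
                f"{n_missing} missing {col} days in season window for "
                f"{ws.location}/{ws.year} (max {max_gap})"
            )
    season["tmean"] = season["tmean"].interpolate(limit_direction="both")
    season["rain"] = season["rain"].fillna(0.0)
    return season[["tmean", "rain"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Soil
# ---------------------------------------------------------------------------

@dataclass
class SoilProfile:
    """Soil texture (sand/silt/clay fractions) and organic content of a field."""

    field_block: str
    sand: float
    silt: float
    clay: float
    organic: float

    def __post_init__(self) -> None:
        for name in ("sand", "silt", "clay", "organic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"soil proportion {name}={v} outside [0, 1]")
        if abs(self.sand + self.silt + self.clay - 1.0) > 1e-6:
            raise ValueError("sand+silt+clay must sum to 1")

    def vector(self) -> np.ndarray:
        return np.array([self.sand, self.silt, self.clay, self.organic])


def load_soil(path) -> dict[str, SoilProfile]:
    df = pd.read_csv(path, sep=_detect_sep(path))
    return {
        str(r.field_block): SoilProfile(
            str(r.field_block), float(r.sand), float(r.silt), float(r.clay), float(r.organic)
        )
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def _env_id(location, year, field_block) -> str:
    return f"{location}:{year}:{field_block}"


@dataclass
class TrialTable:
    """Yield observations indexed by line and environment.

    An environment is one ``(location, year, field_block)`` combination;
    trials within one location-year can span several fields with different
    soils, each counting as its own environment. ``data`` has columns
    ``line_id, location, year, field_block, yield`` plus a derived ``env``
    column. ``z_params`` holds the (mean, sd) of the z-transform when one
    has been applied, enabling back-transformation to kg/ha.
    """

    data: pd.DataFrame
    z_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        d = self.data.reset_index(drop=True).copy()
        required = {"line_id", "location", "year", "field_block", "yield"}
        missing = required - set(d.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        if not np.isfinite(d["yield"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite yields in trial table")
        d["year"] = d["year"].astype(int)
        d["env"] = [
            _env_id(l, y, f)
            for l, y, f in zip(d["location"], d["year"], d["field_block"])
        ]
        self.data = d

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def lines(self) -> np.ndarray:
        return np.asarray(sorted(self.data["line_id"].unique()), dtype=object)

    @property
    def environments(self) -> pd.DataFrame:
        """One row per environment with its location/year/field_block."""
        env = (
            self.data[["env", "location", "year", "field_block"]]
            .drop_duplicates("env")
            .sort_values("env")
            .reset_index(drop=True)
        )
        return env

    def yields(self) -> np.ndarray:
        return self.data["yield"].to_numpy(dtype=float)

    def aggregated(self) -> pd.DataFrame:
        """Mean yield per (line, env) cell with replicate counts."""
        g = (
            self.data.groupby(["line_id", "env"], sort=True)["yield"]
            .agg(["mean", "count"])
            .reset_index()
        )
        return g.rename(columns={"mean": "yield", "count": "n_rep"})

    def subset(self, mask) -> "TrialTable":
        return TrialTable(self.data[np.asarray(mask)], self.z_params)


def load_trials(path) -> TrialTable:
    return TrialTable(pd.read_csv(path, sep=_detect_sep(path)))


def ztransform_yields(trials: TrialTable, scope: str = "global") -> TrialTable:
    """Z-transform yields to zero mean and unit variance.

    ``scope="global"`` standardizes over all records (the default; the
    per-environment yield level is then absorbed by the model's environment
    effect). ``scope="per_env"`` centres and scales within each environment
    instead. Population (1/N) variance is used throughout the package.
    """
    if trials.n_obs < 2:
        raise ValueError("need at least 2 records to z-transform")
    d = trials.data.copy()
    y = d["yield"].to_numpy(dtype=float)
    if scope == "global":
        mu, sd = float(y.mean()), float(y.std())
        if sd == 0.0:
            raise ValueError("zero yield variance; cannot z-transform")
        d["yield"] = (y - mu) / sd
        return TrialTable(d, z_params=(mu, sd))
    if scope == "per_env":
        def _z(s):
            sd = s.std(ddof=0)
            if sd == 0.0:
                raise ValueError(f"zero yield variance in environment")
            return (s - s.mean()) / sd
        d["yield"] = d.groupby("env")["yield"].transform(_z)
        return TrialTable(d, z_params=None)
    raise ValueError(f"unknown scope {scope!r}")


def inverse_ztransform(trials: TrialTable, values: np.ndarray) -> np.ndarray:
    """Map z-scale predictions back to kg/ha using stored transform params."""
    if trials.z_params is None:
        raise ValueError("trial table carries no z-transform parameters")
    mu, sd = trials.z_params
    return np.asarray(values, dtype=float) * sd + mu
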