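"""Cold-start cross-validation folds, scoring and sensitivity analysis.

Six prediction setups of increasing difficulty are supported, defined by
what the training set may share with the test set:

=====  ==================  ====================  =========================
setup  test genotypes      test environments     environmental covariates
=====  ==================  ====================  =========================
1      tested              tested                in-season
2      new (progeny)       tested                in-season (CV1)
3      tested              new location-year     in-season (CV2)
4      new (progeny)       new location-year     in-season
5      tested elsewhere    new location + year   historical weather only
6      new (progeny)       new location + year   historical weather only
=====  ==================  ====================  =========================

Setup 6 is the strict cold-start regime: test locations do not appear
among training locations, test years do not appear among training years,
and test genotypes are progeny absent from training. Prediction accuracy
is the Pearson correlation between predicted and observed yields per test
fold; fold correlations are averaged on the Fisher z scale and
back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import GBLUP, GEBLUP, CropStageConfig, GEBlupCovariateBuilder
from .bemkl import KernelWeightModel, MklConfig, environment_mean_targets
from .datamodel import TrialTable, extract_season, ztransform_yields
from .kbmf import GxEFactorModel, Hyperparameters
from .kernels import EnvironmentKernelBuilder, GenomicKernelBuilder

__all__ = [
    "FoldSpec",
    "FoldLimits",
    "ScoreReport",
    "make_folds",
    "fisher_average",
    "select_hyperparameters",
    "sensitivity_analysis",
    "variance_explained_gain",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldLimits:
    max_folds: int = 10
    max_validation_splits: int = 10
    test_fraction: float = 0.2  # used by the random-cell setup (1)


@dataclass
class FoldSpec:
    """One train/test split honouring the setup's constraints."""

    setup: int
    test_locations: tuple
    test_years: tuple
    test_lines: tuple
    train_index: np.ndarray  # positional indices into trials.data
    test_index: np.ndarray
    validation_splits: list = field(default_factory=list)

    def check(self, trials: TrialTable, genotypes=None) -> None:
        """Assert the constraint set of this fold's setup holds."""
        d = trials.data
        tr, te = d.iloc[self.train_index], d.iloc[self.test_index]
        if self.setup in (3, 4, 5, 6):
            shared_env = set(zip(tr["location"], tr["year"])) & set(
                zip(te["location"], te["year"]))
            if shared_env:
                raise AssertionError(f"test location-years in training: {shared_env}")
        if self.setup in (5, 6):
            if set(tr["location"]) & set(te["location"]):
                raise AssertionError("test locations appear among training locations")
            if set(tr["year"]) & set(te["year"]):
                raise AssertionError("test years appear among training years")
        if self.setup in (2, 4, 6):
            if set(tr["line_id"]) & set(te["line_id"]):
                raise AssertionError("test genotypes appear in training")
            if genotypes is not None and self.setup == 6:
                gen = dict(zip(genotypes.line_ids, genotypes.generation))
                bad = {l for l in te["line_id"] if gen.get(l) != "progeny"}
                if bad:
                    raise AssertionError(f"setup-6 test genotypes not progeny: {bad}")


def _env_candidates(d: pd.DataFrame) -> list[tuple]:
    return sorted(set(zip(d["location"], d["year"])))


def make_folds(trials: TrialTable, genotypes, setup: int,
               limits: FoldLimits | None = None, seed: int = 0) -> list[FoldSpec]:
    """Construct deterministic train/test folds for the given setup."""
    limits = limits or FoldLimits()
    if setup not in range(1, 7):
        raise ValueError(f"setup must be 1..6, got {setup}")
    d = trials.data.sort_values(["env", "line_id"], kind="stable").reset_index()
    rng = np.random.default_rng(seed)
    gen = dict(zip(genotypes.line_ids, genotypes.generation))

    folds: list[FoldSpec] = []
    if setup in (3, 4, 5, 6):
        cands = _env_candidates(d)
        if len({l for l, _ in cands}) < 2 or len({y for _, y in cands}) < 2:
            raise ValueError(
                f"setup {setup} needs at least 2 locations and 2 years in the data")
        order = rng.permutation(len(cands))
        for ci in order:
            loc, yr = cands[ci]
            te_mask = (d["location"] == loc) & (d["year"] == yr)
            if setup in (5, 6):
                tr_mask = (d["location"] != loc) & (d["year"] != yr)
            else:
                tr_mask = ~((d["location"] == loc) & (d["year"] == yr))
            if setup in (4, 6):
                te_mask &= d["line_id"].map(lambda l: gen.get(l) == "progeny")
                test_lines = set(d.loc[te_mask, "line_id"])
                tr_mask &= ~d["line_id"].isin(test_lines)
            else:
                train_lines = set(d.loc[tr_mask, "line_id"])
                te_mask &= d["line_id"].isin(train_lines)
            if te_mask.sum() < 3 or tr_mask.sum() < 10:
                continue
            fold = FoldSpec(
                setup=setup,
                test_locations=(loc,),
                test_years=(yr,),
                test_lines=tuple(sorted(set(d.loc[te_mask, "line_id"]))),
                train_index=d.index[tr_mask].to_numpy(),
                test_index=d.index[te_mask].to_numpy(),
            )
            folds.append(fold)
            if len(folds) >= limits.max_folds:
                break
    elif setup == 2:
        progeny = sorted(l for l in set(d["line_id"]) if gen.get(l) == "progeny")
        if not progeny:
            raise ValueError("setup 2 needs progeny genotypes in the trials")
        progeny = list(rng.permutation(progeny))
        n_folds = min(limits.max_folds, max(2, len(progeny) // 20))
        groups = np.array_split(np.asarray(progeny, dtype=object), n_folds)
        for grp in groups:
            te_mask = d["line_id"].isin(set(grp))
            tr_mask = ~te_mask
            te_envs = set(d.loc[te_mask, "env"])
            tr_envs = set(d.loc[tr_mask, "env"])
            te_mask &= d["env"].isin(tr_envs)  # test envs must be tested
            if te_mask.sum() < 3:
                continue
            te = d[te_mask]
            folds.append(FoldSpec(
                setup=2,
                test_locations=tuple(sorted(set(te["location"]))),
                test_years=tuple(sorted(set(te["year"]))),
                test_lines=tuple(sorted(set(te["line_id"]))),
                train_index=d.index[tr_mask].to_numpy(),
                test_index=d.index[te_mask].to_numpy(),
            ))
    else:  # setup 1: random cells with both margins tested
        n = len(d)
        n_test = max(3, int(round(limits.test_fraction * n)))
        for _ in range(limits.max_folds):
            te_idx = rng.choice(n, size=n_test, replace=False)
            te_mask = np.zeros(n, bool)
            te_mask[te_idx] = True
            tr = d[~te_mask]
            keep = d["line_id"].isin(set(tr["line_id"])) & d["env"].isin(set(tr["env"]))
            te_mask &= keep.to_numpy()
            te = d[te_mask]
            folds.append(FoldSpec(
                setup=1,
                test_locations=tuple(sorted(set(te["location"]))),
                test_years=tuple(sorted(set(te["year"]))),
                test_lines=tuple(sorted(set(te["line_id"]))),
                train_index=d.index[~te_mask].to_numpy(),
                test_index=d.index[te_mask].to_numpy(),
            ))
    if not folds:
        raise ValueError(f"no feasible folds for setup {setup} under the given limits")

    # validation splits: same constraint pattern inside each training set
    for fold in folds:
        if setup in (3, 4, 5, 6) and limits.max_validation_splits > 0:
            sub = TrialTable(d.iloc[fold.train_index].drop(columns=["index", "env"]))
            try:
                inner = make_folds(
                    sub, genotypes, setup,
                    FoldLimits(limits.max_validation_splits, 0), seed=seed + 1)
            except ValueError:
                inner = []
            fold.validation_splits = [
                (fold.train_index[f.train_index], fold.train_index[f.test_index])
                for f in inner
            ]
    # map positional indices back to the original record order
    back = d["index"].to_numpy()
    for fold in folds:
        fold.train_index = np.sort(back[fold.train_index])
        fold.test_index = np.sort(back[fold.test_index])
        fold.validation_splits = [
            (np.sort(back[a]), np.sort(back[b])) for a, b in fold.validation_splits
        ]
    return folds


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def fisher_average(correlations) -> float:
    """tanh(mean(atanh(r))): average correlations on the Fisher z scale."""
    r = np.asarray(correlations, dtype=float)
    if r.size == 0:
        raise ValueError("no correlations to average")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| = 1 has infinite Fisher z; cannot average")
    return float(np.tanh(np.mean(np.arctanh(r))))


def variance_explained_gain(r_new: float, r_baseline: float) -> float:
    """Percent increase in explained variance (r^2) of one method over another."""
    if r_baseline == 0:
        raise ValueError("baseline correlation is zero; gain undefined")
    return 100.0 * (r_new**2 / r_baseline**2 - 1.0)


def select_hyperparameters(validation_scores: pd.DataFrame) -> dict:
    """Pick the grid point with the best Fisher-averaged validation score.

    ``validation_scores`` needs columns ``R``, ``var_genetic``, ``phi`` and
    ``score`` (one row per grid point and validation split). Ties break
    toward the simpler model: smaller R, then smaller var_genetic, then
    smaller phi.
    """
    df = validation_scores.dropna(subset=["score"])
    if df.empty:
        raise ValueError("no valid validation scores")
    agg = (
        df.groupby(["R", "var_genetic", "phi"])["score"]
        .apply(lambda s: fisher_average(np.clip(s, -0.999999, 0.999999)))
        .reset_index()
    )
    agg = agg.sort_values(["score", "R", "var_genetic", "phi"],
                          ascending=[False, True, True, True], kind="stable")
    best = agg.iloc[0]
    return {"R": int(best["R"]), "var_genetic": float(best["var_genetic"]),
            "phi": float(best["phi"]), "score": float(best["score"])}


@dataclass
class ScoreReport:
    """Per-fold correlations and their Fisher-z aggregate."""

    setup: int
    model: str
    fold_scores: pd.DataFrame  # columns: fold, location, year, n_cells, score

    @property
    def aggregate(self) -> float:
        r = np.clip(self.fold_scores["score"].dropna().to_numpy(), -0.999999, 0.999999)
        return fisher_average(r)

    def summary(self) -> str:
        lines = [f"setup {self.setup}  model {self.model}",
                 self.fold_scores.to_string(index=False),
                 f"Fisher-z aggregate correlation: {self.aggregate:.4f}"]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.fold_scores.to_csv(path, sep="\t", index=False)


def sensitivity_analysis(model_scores: pd.DataFrame, baseline_scores: pd.DataFrame,
                         interval: float = 0.90, min_perturbations: int = 3
                         ) -> pd.DataFrame:
    """Distribution of (model - baseline) score differences per rank R.

    ``model_scores``: columns ``R``, ``perturbation``, ``score``;
    ``baseline_scores``: columns ``perturbation``, ``score``. Returns per-R
    median and the central ``interval`` quantiles of the differences plus a
    harmed/neutral/helped call (interval excluding 0 on the negative /
    positive side).
    """
    base = baseline_scores.set_index("perturbation")["score"]
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    rows = []
    for R, sub in model_scores.groupby("R"):
        diff = sub.set_index("perturbation")["score"] - base
        diff = diff.dropna().to_numpy()
        wide_flag = len(diff) < min_perturbations
        if wide_flag:
            warnings.warn(
                f"only {len(diff)} perturbations for R={R}; interval is unreliable",
                RuntimeWarning)
        lo, med, hi = np.quantile(diff, [lo_q, 0.5, hi_q]) if len(diff) else (np.nan,) * 3
        call = "neutral"
        if lo > 0:
            call = "helped"
        elif hi < 0:
            call = "harmed"
        rows.append({"R": int(R), "median": med, "lo": lo, "hi": hi,
                     "call": call, "n": len(diff), "wide_interval": wide_flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end experiment driver (synthetic datasets)
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def run_experiment(dataset, setup: int, model: str = "gxehist", R: int = 2,
                   var_genetic: float = 0.4, phi: float = 1.0,
                   limits: FoldLimits | None = None, seed: int = 0,
                   max_iter: int = 60, registry=None,
                   grid: list[tuple[int, float, float]] | None = None) -> ScoreReport:
    """Score one model under one setup on a synthetic dataset.

    ``model`` is one of ``gxehist`` (kernel factorization predicting new
    seasons from historical weather), ``gxe`` (same model with in-season
    weather), ``main`` (additive model, R forced to 0), ``gblup`` or
    ``geblup``.

    When ``grid`` is given (a list of ``(R, var_genetic, phi)`` points)
    and the folds carry validation splits, each test fold first scores
    every grid point on its validation splits under the same setup
    constraints, selects the best point by Fisher-averaged validation
    correlation (ties toward the simpler model), then refits on the full
    training set with the selected point — the nested protocol. Otherwise
    hyperparameters are fixed at the given ``(R, var_genetic, phi)``.
    """
    limits = limits or FoldLimits(max_folds=5, max_validation_splits=0)
    if model == "main":
        R = 0
    folds = make_folds(dataset.trials, dataset.genotypes, setup, limits, seed)
    rows = []
    for fi, fold in enumerate(folds):
        sel = {"R": R, "var_genetic": var_genetic, "phi": phi}
        if grid and fold.validation_splits and model not in ("gblup", "geblup"):
            val_rows = []
            for gR, gvg, gphi in grid:
                for si, (tr_idx, va_idx) in enumerate(fold.validation_splits):
                    vfold = FoldSpec(setup=fold.setup, test_locations=(),
                                     test_years=(), test_lines=(),
                                     train_index=tr_idx, test_index=va_idx)
                    s, _ = _score_fold(dataset, vfold, model, gR, gvg, gphi,
                                       seed + fi, max_iter, registry)
                    val_rows.append({"R": gR, "var_genetic": gvg, "phi": gphi,
                                     "score": s})
            try:
                sel = select_hyperparameters(pd.DataFrame(val_rows))
            except ValueError:
                pass  # no valid validation scores: keep the defaults
        score, n_cells = _score_fold(dataset, fold, model, sel["R"],
                                     sel["var_genetic"], sel["phi"],
                                     seed + fi, max_iter, registry)
        rows.append({"fold": fi, "location": ",".join(map(str, fold.test_locations)),
                     "year": ",".join(map(str, fold.test_years)),
                     "n_cells": n_cells, "score": score, "R": sel["R"],
                     "var_genetic": sel["var_genetic"], "phi": sel["phi"]})
    report = ScoreReport(setup=setup, model=model, fold_scores=pd.DataFrame(rows))
    return report


def _score_fold(dataset, fold: FoldSpec, model: str, R: int, var_genetic: float,
                phi: float, seed: int, max_iter: int, registry) -> tuple[float, int]:
    d = dataset.trials.data
    train = TrialTable(d.iloc[fold.train_index].drop(columns=["env"]))
    test = d.iloc[fold.test_index]
    train_z = ztransform_yields(train)

    train_lines = sorted(set(train_z.data["line_id"]))
    gkb = GenomicKernelBuilder().fit(dataset.genotypes.loc(train_lines), train_lines)
    test_lines = sorted(set(test["line_id"]))
    kg_rows_all = gkb.rows(dataset.genotypes.loc(test_lines))
    line_pos = {l: i for i, l in enumerate(test_lines)}

    if model == "gblup":
        res = GBLUP(train_z, gkb.kernel, fixed="env").fit()
        pred_per_line = res.predict_units(kg_rows_all)
        preds = np.array([pred_per_line[line_pos[l]] for l in test["line_id"]])
        score = _pearson(preds, test["yield"].to_numpy(dtype=float))
        return score, len(test)

    env_table = train_z.environments
    seasons = {k: extract_season(ws) for k, ws in dataset.weather.items()}

    if model == "geblup":
        return _score_geblup(dataset, fold, train_z, test, gkb, kg_rows_all,
                             line_pos, seasons)

    builder = EnvironmentKernelBuilder(registry)
    blocks = builder.covariate_blocks(env_table, seasons, dataset.soils, dataset.zones)
    builder.fit(blocks, env_table["env"].to_numpy(dtype=object))
    env_ids_sorted, targets = environment_mean_targets(train_z)
    # environment_mean_targets sorts by env id; align with builder order
    tmap = dict(zip(env_ids_sorted, targets))
    y_env = np.array([tmap[e] for e in builder.ids])
    weights = KernelWeightModel(builder.kernel_set, y_env).fit(seed=seed).weights
    Ke = builder.composite(weights)

    hyp = Hyperparameters.calibrated(gkb.kernel, Ke, R=R, var_genetic=var_genetic,
                                     phi=phi)
    fit = GxEFactorModel.from_trials(train_z, gkb.kernel, Ke, hyp).fit(
        max_iter=max_iter, tol=1e-5, seed=seed)

    test_envs = test[["env", "location", "year", "field_block"]].drop_duplicates("env")
    env_pos = {e: j for j, e in enumerate(test_envs["env"])}
    if model in ("gxe", "main"):
        te_blocks = builder.covariate_blocks(test_envs, seasons, dataset.soils,
                                             dataset.zones)
        ke_rows = builder.composite_rows(te_blocks)
        # environments already present in training keep their posterior effect
        train_env_pos = {e: j for j, e in enumerate(builder.ids)}
        env_index = np.array([train_env_pos.get(e, -1) for e in test_envs["env"]])
        pred_matrix = fit.predict(kg_rows_all, ke_rows, env_index=env_index)
    elif model == "gxehist":
        cols = []
        for r in test_envs.itertuples():
            hist = [dataset.weather[(r.location, y)]
                    for (loc, y) in dataset.weather if loc == r.location and y != r.year]
            if not hist:
                raise ValueError(f"no historical weather for location {r.location}")
            cols.append(fit.predict_historical(
                kg_rows_all, hist, dataset.soils[r.field_block], builder,
                zone=dataset.zones.get(r.location)))
        pred_matrix = np.stack(cols, axis=1)
    else:
        raise ValueError(f"unknown model {model!r}")

    preds = np.array([
        pred_matrix[line_pos[l], env_pos[e]] for l, e in zip(test["line_id"], test["env"])
    ])
    return _pearson(preds, test["yield"].to_numpy(dtype=float)), len(test)


def _score_geblup(dataset, fold, train_z, test, gkb, kg_rows_all, line_pos, seasons):
    cfg = CropStageConfig()
    cb = GEBlupCovariateBuilder(cfg)

    def env_vec(env_row) -> np.ndarray:
        loc, yr, fb = env_row.location, int(env_row.year), env_row.field_block
        sow = pd.Timestamp(dataset.sowing[env_row.env])
        days = dataset.weather[(loc, yr)].days
        w = days[days["date"] >= sow][["tmean", "rain"]].to_numpy(dtype=float)
        levels = sorted(set(dataset.zones.values()))
        z = np.zeros(len(levels))
        z[levels.index(dataset.zones[loc])] = 1.0
        return cb.environment_vector(w, dataset.soils[fb], z)

    env_table = train_z.environments
    vectors = np.stack([env_vec(r) for r in env_table.itertuples()])
    cb.fit(vectors, env_table["env"].to_numpy(dtype=object))

    m = GEBLUP(train_z, gkb.kernel, cb.kernel, fixed="env")
    res = m.fit()

    test_envs = test[["env", "location", "year", "field_block"]].drop_duplicates("env")
    Xn = np.stack([env_vec(r) for r in test_envs.itertuples()])
    Xn = (Xn - cb._mu) / cb._sd
    raw = Xn @ cb._X.T
    dn = np.sum(Xn**2, axis=1)
    dt = np.sum(cb._X**2, axis=1)
    env_rows_all = raw * np.outer(
        np.where(dn > 0, 1 / np.sqrt(np.where(dn > 0, dn, 1)), 0),
        np.where(dt > 0, 1 / np.sqrt(np.where(dt > 0, dt, 1)), 0))
    env_pos = {e: j for j, e in enumerate(test_envs["env"])}

    gi = np.array([line_pos[l] for l in test["line_id"]])
    ei = np.array([env_pos[e] for e in test["env"]])
    preds = res.predict_cells(kg_rows_all[gi], env_rows_all[ei])
    return _pearson(preds, test["yield"].to_numpy(dtype=float)), len(test)
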