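"""Random-forest modelling of Psi_tlp against bioclimatic predictors.

Fits one forest per species group per climate model on centred/scaled
predictors. Performance is estimated with *nested spatial
cross-validation*: folds are spatially disjoint clusters of grid cells
(coordinate k-means), the outer loop scores generalisation, the inner
loop tunes hyperparameters by random search, so no held-out cell ever
influences the model that is scored on it. Variable importance is the
mean increase in RMSE after permuting a predictor; marginal effects are
partial-dependence curves with a +/-2 SE band across cells.

Default budgets (500 trees, 5x25 outer resampling, 50 inner evaluations,
500 permutations) match common practice for this model class; they can
be scaled down for small synthetic fixtures where the extra replicates
only add runtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ModelConfig",
    "ModelFit",
    "CVResult",
    "spatial_partitions",
    "nested_spatial_cv",
    "tune_final_model",
    "permutation_importance",
    "partial_dependence",
    "save_fit",
    "load_fit",
]

FIT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Forest and resampling parametrisation.

    mtry is the number of predictors considered per split,
    sample_fraction the bootstrap fraction per tree, min_node_size the
    minimal leaf size. Tuning ranges bracket the initial parametrisation.
    """

    ntree: int = 500
    mtry: int = 1
    sample_fraction: float = 0.6
    min_node_size: int = 1
    mtry_range: tuple[int, int] = (1, 6)
    sample_fraction_range: tuple[float, float] = (0.2, 0.9)
    min_node_size_range: tuple[int, int] = (1, 10)
    outer_folds: int = 5
    outer_reps: int = 25
    inner_folds: int = 5
    inner_evals: int = 50
    n_perm: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.inner_evals < 1:
            raise ValueError("inner_evals must be >= 1")


@dataclass
class ModelFit:
    """A tuned forest plus the standardisation learned from training data.

    Standardisation parameters are learned once from the historical
    training predictors and re-applied unchanged to any future table, so
    projections never leak future climate statistics into the scaling.
    """

    forest: RandomForestRegressor
    feature_names: list[str]
    means: pd.Series
    sds: pd.Series
    params: dict
    group: str | None = None
    climate_model: str | None = None
    cv: "CVResult | None" = None
    tuning_trials: pd.DataFrame | None = None
    fold_labels: np.ndarray | None = None
    format_version: int = FIT_FORMAT_VERSION

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"missing predictor columns: {sorted(missing)}")
        Z = (X[self.feature_names] - self.means) / self.sds
        return Z.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(self.transform(X))


@dataclass
class CVResult:
    folds: pd.DataFrame  # repetition, fold, n_test, rmse, r2, tuned params
    mean_rmse: float
    mean_r2: float


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant predictor stays constant
    return mu, sd


def spatial_partitions(centroids: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Spatially disjoint folds: k-means on cell coordinates.

    Clustering coordinates maximises the spatial separation between
    training and validation cells relative to random partitioning.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = centroids.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells n={n}")
    if k == n:
        return np.arange(n)
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(centroids)
    # k-means can only leave a cluster empty with duplicated points; fix
    # by seeding each empty cluster with one cell from the largest one.
    for empty in set(range(k)) - set(labels):
        biggest = np.bincount(labels, minlength=k).argmax()
        labels[np.where(labels == biggest)[0][0]] = empty
    return labels


def _make_forest(params: dict, ntree: int, seed: int, n_features: int,
                 n_samples: int) -> RandomForestRegressor:
    frac = params["sample_fraction"]
    # integer bootstrap size: same semantics, avoids tiny-fraction warnings
    n_boot = None if frac >= 1.0 else max(2, round(frac * n_samples))
    return RandomForestRegressor(
        n_estimators=ntree,
        max_features=min(int(params["mtry"]), n_features),
        min_samples_leaf=int(params["min_node_size"]),
        bootstrap=True,
        max_samples=n_boot,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")  # degenerate constant target
    return 1.0 - float(np.sum((y - np.asarray(yhat)) ** 2)) / ss_tot


def _candidates(config: ModelConfig, rng: np.random.Generator) -> list[dict]:
    lo_m, hi_m = config.mtry_range
    lo_s, hi_s = config.sample_fraction_range
    lo_n, hi_n = config.min_node_size_range
    return [
        {
            "mtry": int(rng.integers(lo_m, hi_m + 1)),
            "sample_fraction": float(rng.uniform(lo_s, hi_s)),
            "min_node_size": int(rng.integers(lo_n, hi_n + 1)),
        }
        for _ in range(config.inner_evals)
    ]


def _cv_rmse(X: np.ndarray, y: np.ndarray, labels: np.ndarray,
             params: dict, config: ModelConfig, seed: int) -> float:
    errs, weights = [], []
    for fold in np.unique(labels):
        te = labels == fold
        tr = ~te
        if tr.sum() < 2:
            continue
        mu, sd = _standardize_fit(X[tr])
        forest = _make_forest(params, config.ntree, seed + int(fold),
                              X.shape[1], int(tr.sum()))
        forest.fit((X[tr] - mu) / sd, y[tr])
        errs.append(_rmse(y[te], forest.predict((X[te] - mu) / sd)))
        weights.append(te.sum())
    return float(np.average(errs, weights=weights))


def _tune(X: np.ndarray, y: np.ndarray, centroids: np.ndarray,
          config: ModelConfig, seed: int,
          trials: list | None = None) -> dict:
    """Random-search over the tuning ranges; objective = spatial-CV RMSE,
    ties broken by smaller mtry. Each trial is appended to ``trials``
    when a log list is supplied."""
    rng = np.random.default_rng(seed)
    k = min(config.inner_folds, len(y))
    labels = spatial_partitions(centroids, k, seed)
    best, best_score = None, np.inf
    for params in _candidates(config, rng):
        score = _cv_rmse(X, y, labels, params, config, seed)
        if trials is not None:
            trials.append({**params, "cv_rmse": score})
        if score < best_score - 1e-12 or (
            abs(score - best_score) <= 1e-12
            and best is not None
            and params["mtry"] < best["mtry"]
        ):
            best, best_score = params, score
    return best


def nested_spatial_cv(
    X: pd.DataFrame, y, centroids: np.ndarray, config: ModelConfig
) -> CVResult:
    """Outer loop scores generalisation; inner loop tunes per partition.

    Each outer repetition re-seeds the k-means partitioning. Inner tuning
    sees only the outer-training cells, so outer-fold scores never use
    rows involved in the tuning of the model they evaluate.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise ValueError("X and y must not contain missing values")
    if len(yv) != len(centroids):
        raise ValueError("rows of X/y must align with centroids")

    rows = []
    for rep in range(config.outer_reps):
        rep_seed = config.seed * 100003 + rep
        labels = spatial_partitions(centroids, config.outer_folds, rep_seed)
        for fold in np.unique(labels):
            te = labels == fold
            tr = ~te
            if tr.sum() < 2:
                raise ValueError(
                    f"outer repetition {rep}: fold {fold} leaves <2 training cells"
                )
            best = _tune(Xv[tr], yv[tr], centroids[tr], config,
                         rep_seed * 31 + int(fold))
            mu, sd = _standardize_fit(Xv[tr])
            forest = _make_forest(best, config.ntree, rep_seed + int(fold),
                                  Xv.shape[1], int(tr.sum()))
            forest.fit((Xv[tr] - mu) / sd, yv[tr])
            yhat = forest.predict((Xv[te] - mu) / sd)
            rows.append(
                {
                    "repetition": rep,
                    "fold": int(fold),
                    "n_test": int(te.sum()),
                    "rmse": _rmse(yv[te], yhat),
                    "r2": _r2(yv[te], yhat),
                    **{f"tuned_{k}": v for k, v in best.items()},
                }
            )
    folds = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan r2
        mean_r2 = float(np.nanmean(folds["r2"]))
    return CVResult(
        folds=folds,
        mean_rmse=float(folds["rmse"].mean()),
        mean_r2=mean_r2,
    )


def tune_final_model(
    X: pd.DataFrame,
    y,
    centroids: np.ndarray,
    config: ModelConfig,
    group: str | None = None,
    climate_model: str | None = None,
    cv: CVResult | None = None,
) -> ModelFit:
    """Production model: spatial-CV random search on the full data, then
    refit on all rows. Nested CV (if supplied) is attached for reporting
    honesty; it does not influence the final hyperparameters."""
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise ValueError("X and y must not contain missing values")
    cent = np.asarray(centroids, dtype=float)
    trials: list = []
    tune_seed = config.seed * 7919 + 1
    best = _tune(Xv, yv, cent, config, tune_seed, trials)
    labels = spatial_partitions(
        cent, min(config.inner_folds, len(yv)), tune_seed
    )
    mu, sd = _standardize_fit(Xv)
    forest = _make_forest(best, config.ntree, config.seed, Xv.shape[1],
                          len(yv))
    forest.fit((Xv - mu) / sd, yv)
    names = list(X.columns)
    return ModelFit(
        forest=forest,
        feature_names=names,
        means=pd.Series(mu, index=names),
        sds=pd.Series(sd, index=names),
        params=best,
        group=group,
        climate_model=climate_model,
        cv=cv,
        tuning_trials=pd.DataFrame(trials),
        fold_labels=labels,
    )


def permutation_importance(
    fit: ModelFit, X: pd.DataFrame, y, n_perm: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Mean change in RMSE after permuting each predictor, over n_perm draws.

    Positive values mean the model relies on the predictor (permutation
    destroys information and RMSE rises). A predictor that is constant in
    X yields exactly zero (permutation is a no-op).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Z = fit.transform(X)
    yv = np.asarray(y, dtype=float)
    base = _rmse(yv, fit.forest.predict(Z))
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(fit.feature_names):
        deltas = np.empty(n_perm)
        col = Z[:, j]
        if np.all(col == col[0]):
            deltas[:] = 0.0  # constant column: any permutation is identity
        else:
            for p in range(n_perm):
                Zp = Z.copy()
                Zp[:, j] = rng.permutation(col)
                deltas[p] = _rmse(yv, fit.forest.predict(Zp)) - base
        rows.append(
            {
                "predictor": name,
                "delta_rmse_mean": float(deltas.mean()),
                "delta_rmse_sd": float(deltas.std(ddof=1)) if n_perm > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "delta_rmse_mean", ascending=False, ignore_index=True
    )


def partial_dependence(
    fit: ModelFit,
    X: pd.DataFrame,
    predictor: str,
    grid: np.ndarray | None = None,
    n_points: int = 20,
) -> pd.DataFrame:
    """Marginal effect curve: mean prediction with the predictor forced to
    each grid value, with a +/-2 SE band across cells."""
    if predictor not in fit.feature_names:
        raise ValueError(f"unknown predictor {predictor!r}")
    if grid is None:
        lo, hi = X[predictor].min(), X[predictor].max()
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must not be empty")
    Z = fit.transform(X)
    j = fit.feature_names.index(predictor)
    mu_j, sd_j = fit.means[predictor], fit.sds[predictor]
    rows = []
    for v in grid:
        Zp = Z.copy()
        Zp[:, j] = (v - mu_j) / sd_j
        preds = fit.forest.predict(Zp)
        se = float(preds.std(ddof=1) / np.sqrt(len(preds))) if len(preds) > 1 else 0.0
        rows.append(
            {
                "value": float(v),
                "pd_mean_mpa": float(preds.mean()),
                "pd_lo_mpa": float(preds.mean() - 2 * se),
                "pd_hi_mpa": float(preds.mean() + 2 * se),
            }
        )
    return pd.DataFrame(rows)


def save_fit(fit: ModelFit, path) -> None:
    joblib.dump({"format_version": FIT_FORMAT_VERSION, "fit": fit}, path)


def load_fit(path) -> ModelFit:
    payload = joblib.load(path)
    if payload.get("format_version") != FIT_FORMAT_VERSION:
        raise ValueError(
            f"unsupported fit format {payload.get('format_version')!r}"
        )
    return payload["fit"]
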