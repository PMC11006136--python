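"""Random-forest Sr isoscape: fitting, cross-validation, prediction and a
quantile-regression-forest uncertainty surface.

The spatial regression predicts bioavailable 87Sr/86Sr from a stack of
co-registered environmental predictor rasters; longitude/latitude are
deliberately NOT predictors.  Uncertainty is estimated in quantile-
regression-forest style: the empirical distribution of training responses in
the terminal nodes that a prediction point falls into, pooled over trees with
Meinshausen weights, gives per-cell quantiles; half the (q84 - q16) spread is
a ~68% (1-sigma-like) error map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .raster import RasterGrid

__all__ = [
    "IsoscapeModel",
    "CVReport",
    "extract_at_points",
    "select_predictors",
    "fit_isoscape",
    "cross_validate",
    "predict_surface",
    "uncertainty_surface",
    "site_variability_diagnostics",
    "load_oxygen_isoscape",
]


@dataclass
class IsoscapeModel:
    """A fitted random-forest isoscape."""

    predictor_names: list[str]
    forest: RandomForestRegressor
    training_n: int
    seed: int
    y_train: np.ndarray
    X_train: np.ndarray
    cv_rmse: float | None = None
    cv_r2: float | None = None
    oob_r2: float | None = None

    def metadata(self) -> dict:
        return {
            "predictors": self.predictor_names,
            "n_trees": self.forest.n_estimators,
            "training_n": self.training_n,
            "seed": self.seed,
            "cv_rmse": self.cv_rmse,
            "cv_r2": self.cv_r2,
            "oob_r2": self.oob_r2,
        }

    def save(self, path) -> None:
        """Serialize the model (joblib binary) with a JSON metadata sidecar."""
        import joblib

        joblib.dump(self, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata(), fh, indent=1)

    @staticmethod
    def load(path) -> "IsoscapeModel":
        import joblib

        return joblib.load(path)


@dataclass
class CVReport:
    """k-fold cross-validation summary.

    ``fold_assignments`` maps each training sample to its fold;
    ``predictions`` are out-of-fold.  Pooled RMSE/R2 are computed over all
    out-of-fold residuals (R2 = 1 - SS_res/SS_tot).
    """

    k: int
    fold_assignments: np.ndarray
    predictions: np.ndarray
    per_fold_rmse: list[float]
    rmse: float
    r2: float
    seed: int = 0


def _stack_matrix(stack: dict[str, RasterGrid], predictors: list[str]):
    """Design matrix over cells valid in every predictor; returns (X, mask)."""
    missing = [p for p in predictors if p not in stack]
    if missing:
        raise ValueError(f"predictor(s) missing from stack: {missing}")
    ref = stack[predictors[0]]
    for name in predictors[1:]:
        if not stack[name].same_grid(ref):
            raise ValueError(f"predictor {name!r} is not co-registered with {predictors[0]!r}")
    layers = [stack[name].values for name in predictors]
    mask = np.all([np.isfinite(v) for v in layers], axis=0)
    X = np.column_stack([v[mask] for v in layers])
    return X, mask


def extract_at_points(stack: dict[str, RasterGrid], lons, lats, predictors=None):
    """Predictor values at the containing cell of each point.

    Rejects points off-grid or on nodata cells, naming the offending rows.
    """
    predictors = list(stack) if predictors is None else list(predictors)
    ref = stack[predictors[0]]
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    rows, cols = ref.transform.index_of(lons, lats)
    nr, nc = ref.shape
    off = (rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)
    if off.any():
        raise ValueError(f"points off-grid at rows {np.nonzero(off)[0].tolist()}")
    X = np.column_stack([stack[name].values[rows, cols] for name in predictors])
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValueError(f"points on nodata cells at rows {np.nonzero(bad)[0].tolist()}")
    return X


def _training_xy(training: pd.DataFrame, stack, predictors, response="sr87_86"):
    X = extract_at_points(stack, training["lon"], training["lat"], predictors)
    y = training[response].to_numpy(dtype=float)
    return X, y


def _default_mtry(p: int) -> int:
    return max(1, int(np.ceil(p / 3)))


def _make_forest(p, n_trees, seed, **kw):
    # regression-convention hyperparameters: mtry = ceil(p/3), terminal node
    # size 5 (needed for meaningful terminal-node response distributions)
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=_default_mtry(p),
        min_samples_leaf=5,
        random_state=seed,
        n_jobs=1,
        **kw,
    )


def select_predictors(
    training: pd.DataFrame,
    stack: dict[str, RasterGrid],
    threshold_frac: float = 0.05,
    *,
    n_trees: int = 500,
    seed: int = 0,
    response: str = "sr87_86",
) -> list[str]:
    """Rank candidate predictors by permutation importance and keep the
    informative ones (importance >= threshold_frac * max importance).

    A lightweight stand-in for stepwise variable-selection procedures: fits a
    preliminary forest on all candidates and permutes each predictor to
    measure its contribution.  Always retains at least one predictor.
    """
    candidates = list(stack)
    if not candidates:
        raise ValueError("empty predictor stack")
    if len(candidates) < 2:
        return candidates
    n = len(training)
    if n < 5 * len(candidates):
        warnings.warn(
            f"only {n} training points for {len(candidates)} candidates; "
            "importance ranking may be unstable",
            stacklevel=2,
        )
    X, y = _training_xy(training, stack, candidates, response)
    # held-out permutation importance: training-set importance rewards
    # overfit splits on uninformative predictors
    rng = np.random.default_rng(seed)
    holdout = np.zeros(n, dtype=bool)
    holdout[rng.choice(n, size=max(n // 3, 1), replace=False)] = True
    forest = _make_forest(X.shape[1], n_trees, seed).fit(X[~holdout], y[~holdout])
    imp = permutation_importance(
        forest, X[holdout], y[holdout], n_repeats=10, random_state=seed, n_jobs=1
    ).importances_mean
    top = imp.max()
    if top <= 0:
        return [candidates[int(np.argmax(imp))]]
    keep = [name for name, v in zip(candidates, imp) if v >= threshold_frac * top]
    return keep or [candidates[int(np.argmax(imp))]]


def fit_isoscape(
    training: pd.DataFrame,
    stack: dict[str, RasterGrid],
    predictors: list[str],
    n_trees: int = 1000,
    seed: int = 0,
    *,
    response: str = "sr87_86",
) -> IsoscapeModel:
    """Fit the random-forest isoscape on point training data.

    Every training point must fall on a non-nodata cell of every selected
    predictor; offenders are rejected by row index.  Deterministic given the
    seed.  Training responses and design matrix are retained on the model to
    support quantile (uncertainty) prediction.
    """
    X, y = _training_xy(training, stack, predictors, response)
    forest = _make_forest(X.shape[1], n_trees, seed, oob_score=True).fit(X, y)
    return IsoscapeModel(
        predictor_names=list(predictors),
        forest=forest,
        training_n=len(y),
        seed=seed,
        y_train=y,
        X_train=X,
        oob_r2=float(forest.oob_score_),
    )


def cross_validate(
    training: pd.DataFrame,
    stack: dict[str, RasterGrid],
    predictors: list[str],
    k: int = 10,
    seed: int = 0,
    *,
    n_trees: int = 1000,
    response: str = "sr87_86",
) -> CVReport:
    """k-fold cross-validation with a simple random partition by seed.

    Reports per-fold RMSE plus pooled RMSE and R2 (1 - SS_res/SS_tot) over
    the out-of-fold predictions.
    """
    n = len(training)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k may not exceed the number of training samples")
    X, y = _training_xy(training, stack, predictors, response)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(np.arange(n) % k)
    preds = np.empty(n)
    per_fold = []
    for f in range(k):
        test = folds == f
        forest = _make_forest(X.shape[1], n_trees, seed).fit(X[~test], y[~test])
        preds[test] = forest.predict(X[test])
        per_fold.append(float(np.sqrt(np.mean((preds[test] - y[test]) ** 2))))
    resid = preds - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return CVReport(
        k=k,
        fold_assignments=folds,
        predictions=preds,
        per_fold_rmse=per_fold,
        rmse=rmse,
        r2=r2,
        seed=seed,
    )


def predict_surface(model: IsoscapeModel, stack: dict[str, RasterGrid]) -> RasterGrid:
    """Per-cell ensemble-mean prediction over the stack footprint."""
    X, mask = _stack_matrix(stack, model.predictor_names)
    ref = stack[model.predictor_names[0]]
    out = np.full(ref.shape, np.nan)
    out[mask] = model.forest.predict(X)
    return ref.copy_with(out, quantity="sr_isoscape", **model.metadata())


def _qrf_weights_quantiles(model, X_query, qs, batch=None):
    """Meinshausen QRF quantiles for query points.

    For each tree, a query point inherits weight 1/|leaf| on every training
    observation sharing its terminal node; weights are averaged over trees and
    the weighted empirical quantile of the training responses is returned.
    """
    y = model.y_train
    order = np.argsort(y)
    y_sorted = y[order]
    n_train = y.size
    n_query = X_query.shape[0]
    leaves_train = model.forest.apply(model.X_train)  # (n_train, n_trees)
    leaves_query = model.forest.apply(X_query)  # (n_query, n_trees)
    W = np.zeros((n_query, n_train))
    for t in range(leaves_train.shape[1]):
        lt = leaves_train[:, t]
        lq = leaves_query[:, t]
        uniq, inv = np.unique(lt, return_inverse=True)
        counts = np.bincount(inv)
        # training indices grouped by leaf, contiguous after argsort
        t_order = np.argsort(inv, kind="stable")
        t_bounds = np.concatenate(([0], np.cumsum(counts)))
        # query indices grouped the same way
        pos = np.searchsorted(uniq, lq)
        pos_c = np.clip(pos, 0, uniq.size - 1)
        matched = uniq[pos_c] == lq
        q_idx = np.nonzero(matched)[0]
        leaf_of_q = pos_c[q_idx]
        q_order = np.argsort(leaf_of_q, kind="stable")
        q_sorted = q_idx[q_order]
        leaf_sorted = leaf_of_q[q_order]
        starts = np.searchsorted(leaf_sorted, np.arange(uniq.size), side="left")
        ends = np.searchsorted(leaf_sorted, np.arange(uniq.size), side="right")
        for li in np.nonzero(ends > starts)[0]:
            members = t_order[t_bounds[li] : t_bounds[li + 1]]
            W[np.ix_(q_sorted[starts[li] : ends[li]], members)] += 1.0 / counts[li]
    W /= leaves_train.shape[1]
    # weighted quantiles on the sorted responses
    Ws = W[:, order]
    cum = np.cumsum(Ws, axis=1)
    total = cum[:, -1][:, None]
    cum = cum / np.where(total > 0, total, 1.0)
    out = np.empty((n_query, len(qs)))
    for j, q in enumerate(qs):
        idx = np.argmax(cum >= q, axis=1)
        out[:, j] = y_sorted[idx]
    return out


def uncertainty_surface(
    model: IsoscapeModel,
    stack: dict[str, RasterGrid],
    q_low: float = 0.16,
    q_high: float = 0.84,
) -> RasterGrid:
    """Per-cell (q_high - q_low)/2 quantile spread: a ~68% half-interval map.

    Nonnegative everywhere by construction (quantiles are monotone in q).
    """
    if not (0 < q_low < q_high < 1):
        raise ValueError("need 0 < q_low < q_high < 1")
    if model.X_train is None or model.y_train is None:
        raise ValueError("model lacks retained training data; quantile mode unavailable")
    X, mask = _stack_matrix(stack, model.predictor_names)
    qvals = _qrf_weights_quantiles(model, X, (q_low, q_high))
    spread = (qvals[:, 1] - qvals[:, 0]) / 2.0
    ref = stack[model.predictor_names[0]]
    out = np.full(ref.shape, np.nan)
    out[mask] = spread
    return ref.copy_with(out, quantity="sr_isoscape_error", q_low=q_low, q_high=q_high)


def site_variability_diagnostics(
    training: pd.DataFrame,
    error_raster: RasterGrid | None = None,
    *,
    coord_tol: float = 1e-6,
    response: str = "sr87_86",
):
    """Per-site replicate statistics and their regressions.

    Groups training samples by exact coordinate match (to ``coord_tol``
    degrees, for float round-trip safety), computes each replicated site's
    mean and SD, optionally extracts the modelled error at the site, and
    regresses SD on mean, error on mean and SD on error (OLS R2 each).
    Returns ``(site_table, stats_dict)``; both empty if no site has
    replicates.
    """
    df = training.copy()
    decimals = max(0, int(round(-np.log10(coord_tol))))
    df["_lon"] = df["lon"].round(decimals)
    df["_lat"] = df["lat"].round(decimals)
    grouped = df.groupby(["_lon", "_lat"])[response].agg(["mean", "std", "count"])
    sites = grouped[grouped["count"] >= 2].reset_index()
    if sites.empty:
        warnings.warn("no replicated sites; diagnostics empty", stacklevel=2)
        return pd.DataFrame(), {}
    sites = sites.rename(
        columns={"_lon": "lon", "_lat": "lat", "mean": "site_mean", "std": "site_sd", "count": "n"}
    )
    stats: dict[str, float] = {}

    def _r2(x, y):
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return float(res.rsquared), float(res.pvalues[1])

    stats["r2_sd_vs_mean"], stats["p_sd_vs_mean"] = _r2(
        sites["site_mean"].to_numpy(), sites["site_sd"].to_numpy()
    )
    if error_raster is not None:
        err = [
            error_raster.value_at(lo, la) if error_raster.contains(lo, la) else np.nan
            for lo, la in zip(sites["lon"], sites["lat"])
        ]
        sites["extracted_error"] = err
        ok = sites["extracted_error"].notna()
        if ok.sum() >= 3:
            stats["r2_error_vs_mean"], stats["p_error_vs_mean"] = _r2(
                sites.loc[ok, "site_mean"].to_numpy(), sites.loc[ok, "extracted_error"].to_numpy()
            )
            stats["r2_sd_vs_error"], stats["p_sd_vs_error"] = _r2(
                sites.loc[ok, "extracted_error"].to_numpy(), sites.loc[ok, "site_sd"].to_numpy()
            )
            diff = sites.loc[ok, "site_sd"] - sites.loc[ok, "extracted_error"]
            stats["mean_sd_minus_error"] = float(diff.mean())
            stats["sd_sd_minus_error"] = float(diff.std())
    return sites, stats


def load_oxygen_isoscape(
    raster: RasterGrid, constant_sd: float = 1.0
) -> tuple[RasterGrid, RasterGrid]:
    """Ingest a precipitation d18O surface with a constant per-pixel
    uncertainty (default a conservative 1 permil); values pass through
    unchanged and the error raster shares the nodata footprint."""
    if constant_sd <= 0:
        raise ValueError("constant_sd must be positive")
    err = np.where(raster.valid_mask(), constant_sd, np.nan)
    return (
        raster.copy_with(raster.values.copy(), quantity="o_isoscape"),
        raster.copy_with(err, quantity="o_isoscape_error", constant_sd=constant_sd),
    )
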