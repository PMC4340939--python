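"""Year-specific random-forest abundance models.

One regression forest is fitted per survey year to the segment-level
detection-corrected pair counts.  Variable selection follows the model
improvement ratio: importances are rescaled so the top variable equals 1,
candidate models retain all variables at or above each threshold in a
0.0-1.0 grid, and the candidate with the lowest out-of-bag MSE wins (ties
go to the smaller model).  Model significance is assessed by refitting on
response permutations; fit quality is summarized from out-of-bag residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor


@dataclass
class ForestParams:
    """Regression-forest hyperparameters (classical regression defaults:
    1000 trees, mtry = floor(p/3), minimum node size 5 — i.e. nodes of 5+
    rows may still split, so terminal leaves can be smaller)."""

    n_trees: int = 1000
    min_node_size: int = 5
    min_rows: int = 30


@dataclass
class FittedForest:
    estimator: RandomForestRegressor
    variables: list[str]
    oob_pred: np.ndarray
    oob_mse: float
    oob_variance_explained: float  # percent
    importances: pd.Series | None  # raw permutation importances
    seed: int


@dataclass
class YearModel:
    """A selected per-year abundance model."""

    year: int
    variables: list[str]  # training column order — prediction inputs must match
    scaled_importances: pd.Series  # top variable = 1, descending
    forest: RandomForestRegressor
    oob_pred: np.ndarray
    oob_mse: float
    oob_variance_explained: float
    seed: int
    selection_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_variables(self) -> int:
        return len(self.variables)


@dataclass
class FitSummary:
    year: int
    rmse: float
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float


def fit_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    params: ForestParams | None = None,
    seed: int = 0,
    compute_importance: bool = True,
) -> FittedForest:
    """Fit a regression forest and return out-of-bag statistics.

    ``oob_variance_explained = 100 * (1 - MSE_oob / Var(y))`` with the
    sample variance (n-1 divisor), as the original forest toolchain reports
    it; it can be negative when the model is worse than the mean.
    """
    params = params or ForestParams()
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) < params.min_rows:
        raise ValueError(f"need at least {params.min_rows} rows, got {len(X)}")
    if np.var(y) == 0:
        raise ValueError("degenerate response: y is constant")
    if X.isna().any().any():
        raise ValueError("X contains missing values")
    p = X.shape[1]
    est = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=max(1, p // 3),
        min_samples_split=params.min_node_size,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        est.fit(X.to_numpy(), y)
    oob_pred = est.oob_prediction_
    oob_mse = float(np.mean((oob_pred - y) ** 2))
    var_y = float(np.var(y, ddof=1))
    ove = 100.0 * (1.0 - oob_mse / var_y)
    importances = None
    if compute_importance:
        importances = oob_permutation_importance(est, X.to_numpy(), y, list(X.columns), seed=seed + 1)
    return FittedForest(
        estimator=est,
        variables=list(X.columns),
        oob_pred=oob_pred,
        oob_mse=oob_mse,
        oob_variance_explained=ove,
        importances=importances,
        seed=seed,
    )


def oob_permutation_importance(
    est: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    seed: int = 0,
) -> pd.Series:
    """Out-of-bag permutation importance (mean MSE increase).

    For every tree, the squared error on its own out-of-bag samples is
    compared with the error after permuting one predictor within those
    samples; a variable's importance is the mean increase across trees.
    This is the importance the classical forest implementations report for
    regression, and it discriminates collinear predictors far better than
    permuting on the training set as a whole.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    all_idx = np.arange(n)
    deltas = np.zeros((est.n_estimators, X.shape[1]))
    for t, (tree, sampled) in enumerate(zip(est.estimators_, est.estimators_samples_)):
        oob = np.setdiff1d(all_idx, sampled)
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        base_mse = np.mean((tree.predict(X_oob) - y[oob]) ** 2)
        for j in range(X.shape[1]):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(len(oob)), j]
            deltas[t, j] = np.mean((tree.predict(X_perm) - y[oob]) ** 2) - base_mse
    return pd.Series(deltas.mean(axis=0), index=names).sort_values(ascending=False)


def scale_importance(raw: pd.Series) -> pd.Series:
    """Rescale importances so the top variable equals 1.

    Every value is divided by the maximum; ordering is preserved.  Negative
    permutation importances (pure noise) floor at 0 before scaling.
    """
    raw = pd.Series(raw, dtype=float)
    if len(raw) == 0:
        raise ValueError("no importances to scale")
    clipped = raw.clip(lower=0.0)
    top = clipped.max()
    if top <= 0:
        raise ValueError("all importances are zero")
    return (clipped / top).sort_values(ascending=False)


def select_model_mir(
    X: pd.DataFrame,
    y: np.ndarray,
    params: ForestParams | None = None,
    seed: int = 0,
    year: int = 0,
    thresholds: np.ndarray | None = None,
) -> YearModel:
    """Model-improvement-ratio selection.

    Fit the full forest; rescale its importances (top = 1); for each
    threshold in a 0.0..1.0 grid (step 0.1) retain the variables whose
    scaled importance meets the threshold and refit; select the candidate
    with the lowest out-of-bag MSE, breaking ties toward fewer variables.
    The winner is refitted as the returned :class:`YearModel`, whose
    reported importances are rescaled within the selected model.
    """
    params = params or ForestParams()
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.01, 0.1), 10)
    full = fit_forest(X, y, params, seed)
    mir = scale_importance(full.importances)

    candidates: list[tuple[float, list[str], FittedForest]] = []
    seen: set[frozenset] = set()
    for t in thresholds:
        vars_t = [v for v in mir.index if mir[v] >= t - 1e-12]
        if not vars_t:
            continue
        key = frozenset(vars_t)
        if key in seen:
            continue
        seen.add(key)
        if key == frozenset(full.variables):
            fitted = full
        else:
            fitted = fit_forest(X[vars_t], y, params, seed, compute_importance=False)
        candidates.append((float(t), vars_t, fitted))
    if not candidates:
        warnings.warn("model selection retained no variables at any threshold; using full model")
        candidates = [(0.0, list(X.columns), full)]

    table = pd.DataFrame(
        {
            "threshold": [t for t, _, _ in candidates],
            "n_variables": [len(v) for _, v, _ in candidates],
            "oob_mse": [f.oob_mse for _, _, f in candidates],
        }
    )
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i][2].oob_mse, len(candidates[i][1])))
    _, best_vars, best_fit = candidates[order[0]]
    if best_fit.importances is None:
        best_fit.importances = oob_permutation_importance(
            best_fit.estimator, X[best_vars].to_numpy(), np.asarray(y, dtype=float), best_vars, seed=seed + 1
        )
    scaled = scale_importance(best_fit.importances)
    return YearModel(
        year=year,
        variables=list(best_fit.variables),
        scaled_importances=scaled,
        forest=best_fit.estimator,
        oob_pred=best_fit.oob_pred,
        oob_mse=best_fit.oob_mse,
        oob_variance_explained=best_fit.oob_variance_explained,
        seed=seed,
        selection_table=table,
    )


def permutation_significance(
    X: pd.DataFrame,
    y: np.ndarray,
    observed_variance_explained: float,
    B: int = 99,
    params: ForestParams | None = None,
    seed: int = 0,
) -> float:
    """Permutation test of model significance.

    The forest is refitted on B random permutations of the response;
    ``p = (1 + #{null variance explained >= observed}) / (B + 1)``.
    The strongest attainable p is therefore 1/(B+1).
    """
    if B < 19:
        raise ValueError("B must be at least 19")
    params = params or ForestParams()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    exceed = 0
    for b in range(B):
        y_perm = rng.permutation(y)
        null_fit = fit_forest(X, y_perm, params, seed=seed + 1 + b, compute_importance=False)
        if null_fit.oob_variance_explained >= observed_variance_explained:
            exceed += 1
    return (1 + exceed) / (B + 1)


def goodness_of_fit(oob_pred: np.ndarray, observed: np.ndarray, year: int = 0) -> FitSummary:
    """Out-of-bag residual summary: residual = predicted - observed.

    Reports RMSE on the count scale and the five-number summary plus mean
    of the residuals (quantiles by linear interpolation).
    """
    oob_pred = np.asarray(oob_pred, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if oob_pred.shape != observed.shape:
        raise ValueError("length mismatch between predictions and observations")
    if len(oob_pred) < 2:
        raise ValueError("need at least 2 observations")
    r = oob_pred - observed
    q1, med, q3 = np.quantile(r, [0.25, 0.5, 0.75])
    return FitSummary(
        year=year,
        rmse=float(np.sqrt(np.mean(r**2))),
        min=float(r.min()),
        q1=float(q1),
        median=float(med),
        mean=float(r.mean()),
        q3=float(q3),
        max=float(r.max()),
    )


def functional_response(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Loess functional-response curve of pair counts against pond counts.

    Locally weighted polynomial regression (degree 2, tricube kernel) with
    the neighborhood spanning ``span`` of the data, evaluated on an even
    grid over [0, max(x)].  Returns ``(grid, fitted)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    if len(x) < 20:
        raise ValueError("need at least 20 points")
    if x.max() <= 0:
        raise ValueError("x range must be positive")
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    grid = np.linspace(0.0, x.max(), n_grid)
    fitted = np.empty(n_grid)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        d_max = np.partition(d, k - 1)[k - 1]
        if d_max <= 0:
            fitted[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / d_max) ** 3, 0.0, None) ** 3
        use = w > 0
        if np.unique(x[use]).size <= degree:
            fitted[i] = np.average(y[use], weights=w[use])
            continue
        coef = np.polynomial.polynomial.polyfit(x[use] - g, y[use], deg=degree, w=np.sqrt(w[use]))
        fitted[i] = coef[0]
    return grid, fitted


def year_model_summary(models: list[YearModel], top_n: int = 5) -> pd.DataFrame:
    """Per-year summary table: variance explained, model size, top variables."""
    rows = []
    for m in models:
        row = {
            "year": m.year,
            "pct_var_explained": m.oob_variance_explained,
            "n_variables": m.n_variables,
        }
        for rank, (name, value) in enumerate(m.scaled_importances.head(top_n).items(), start=1):
            row[f"var{rank}"] = name
            row[f"var{rank}_importance"] = round(float(value), 2)
        rows.append(row)
    return pd.DataFrame(rows)
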