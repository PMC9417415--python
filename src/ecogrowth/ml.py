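"""Predicting growth parameters from medium composition.

Features are log10-transformed component concentrations; responses are one
of the three growth parameters.  A zoo of regressors (gradient-boosted
trees, k-NN, feed-forward network, random forest, SVR, multiple linear
regression and a linear-stacked ensemble) is evaluated under fivefold
nested cross-validation with inner grid search, models are compared by
one-way ANOVA with Scheffe pairwise contrasts, gradient-boosted-tree
feature importances are averaged across folds to rank the decision-making
components, and multimodal parameter distributions are split at a
kernel-density trough so prediction can be re-run per subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelmax, argrelmin
from sklearn.ensemble import (GradientBoostingRegressor, RandomForestRegressor,
                              StackingRegressor)
from sklearn.linear_model import LinearRegression
from sklearn.metrics import (explained_variance_score, mean_absolute_error,
                             mean_squared_error, r2_score)
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVR

from .synthetic import MediumDesign

logger = logging.getLogger(__name__)

N_FOLDS = 5
N_ESTIMATORS = 300


@dataclass
class FeatureTable:
    """Log-concentration features with one growth parameter as response."""

    X: pd.DataFrame
    y: pd.Series
    parameter: str


@dataclass
class ModelEvaluation:
    """Per-outer-fold metrics and selected hyperparameters for one model."""

    model: str
    fold_metrics: pd.DataFrame        # rows = outer folds
    best_params: list = field(default_factory=list)


@dataclass
class ImportanceProfile:
    """Fold-averaged gradient-boosted-tree feature importances."""

    parameter: str
    mean: pd.Series                   # per-component, sums to 1
    per_fold: pd.DataFrame            # rows = folds


@dataclass
class SplitResult:
    """Outcome of splitting a bimodal parameter distribution at a KDE trough."""

    separable: bool
    threshold: float | None = None
    low_ids: pd.Index | None = None
    high_ids: pd.Index | None = None


def build_features(
    design: MediumDesign,
    params: pd.DataFrame,
    parameter: str,
    pseudo_decades: float = 1.0,
) -> FeatureTable:
    """Assemble the log-concentration feature matrix for one parameter.

    Zero concentrations map to one ``pseudo_decades`` below the component's
    smallest positive level (log10 scale).  Rows whose response is flagged
    unreliable or missing are dropped; components that are never positive
    are dropped with a warning.
    """
    if parameter not in params.columns:
        raise ValueError(f"parameter {parameter!r} not in the parameters table")
    common = design.combinations.index.intersection(params.index)
    conc = design.combinations.loc[common]
    y = params.loc[common, parameter]
    flag_col = f"flag_{parameter}"
    keep = ~y.isna()
    if flag_col in params.columns:
        keep &= ~params.loc[common, flag_col].astype(bool)
    conc, y = conc[keep], y[keep]

    features = {}
    for name in conc.columns:
        col = conc[name].to_numpy(float)
        positive = col[col > 0]
        if len(positive) == 0:
            logger.warning("component %r never positive; column dropped", name)
            continue
        fill = np.log10(positive.min()) - pseudo_decades
        with np.errstate(divide="ignore"):
            logged = np.where(col > 0, np.log10(np.where(col > 0, col, 1.0)), fill)
        features[name] = logged
    X = pd.DataFrame(features, index=conc.index)
    return FeatureTable(X=X, y=y.astype(float), parameter=parameter)


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------

def _pow2(lo: int, hi: int, step: int = 2) -> list[float]:
    return [2.0 ** e for e in range(lo, hi + 1, step)]


def make_model(name: str, seed: int = 0, n_estimators: int = N_ESTIMATORS):
    """Estimator + default hyperparameter grid for one model-zoo entry.

    Grids follow common practice for this model family: boosted trees search
    learning rate 0.001-0.5 and depth {2,3,4,5} at 300 estimators; k-NN
    searches 1-4 neighbours; the feed-forward network searches four layer
    layouts; SVR searches C/gamma/epsilon over powers of two.  Scaling
    (standardisation for k-NN/NN/linear, min-max for SVR) happens inside
    the pipeline so it is re-fit per training fold.
    """
    if name == "gbdt":
        est = GradientBoostingRegressor(random_state=0, n_estimators=n_estimators)
        grid = {"learning_rate": list(np.round(np.arange(0.001, 0.5001, 0.005), 3)),
                "max_depth": [2, 3, 4, 5]}
    elif name == "knn":
        est = Pipeline([("scale", StandardScaler()), ("model", KNeighborsRegressor())])
        grid = {"model__n_neighbors": [1, 2, 3, 4]}
    elif name == "nn":
        est = Pipeline([("scale", StandardScaler()),
                        ("model", MLPRegressor(solver="adam", alpha=0.001,
                                               max_iter=2000, random_state=seed))])
        grid = {"model__hidden_layer_sizes": [(100, 100, 100), (100, 100),
                                              (50, 50), (50, 50, 50)]}
    elif name == "rf":
        est = RandomForestRegressor(random_state=0, n_estimators=n_estimators)
        grid = {"max_depth": [2, 3, 4]}
    elif name == "svm":
        est = Pipeline([("scale", MinMaxScaler()), ("model", SVR(kernel="rbf"))])
        grid = {"model__C": _pow2(-5, 10), "model__gamma": _pow2(-20, 10),
                "model__epsilon": _pow2(-10, 0)}
    elif name == "linear":
        est = Pipeline([("scale", StandardScaler()), ("model", LinearRegression())])
        grid = {}
    elif name == "ensemble":
        base = [
            ("gbdt", GradientBoostingRegressor(random_state=0,
                                               n_estimators=n_estimators)),
            ("knn", Pipeline([("scale", StandardScaler()),
                              ("model", KNeighborsRegressor(n_neighbors=3))])),
            ("rf", RandomForestRegressor(random_state=0, n_estimators=n_estimators)),
        ]
        est = StackingRegressor(estimators=base, final_estimator=LinearRegression())
        grid = {}
    else:
        raise ValueError(f"unknown model {name!r}; choose from gbdt, knn, nn, rf, "
                         "svm, linear, ensemble")
    return est, grid


def compute_metrics(y_true, y_pred) -> dict:
    """R2, MSE, RMSE, MAE and explained-variance score.

    A constant ``y_true`` leaves R2 and the explained-variance score
    undefined (NaN).
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("y_true and y_pred must share a length of at least 2")
    mse = mean_squared_error(y_true, y_pred)
    out = {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": mean_absolute_error(y_true, y_pred),
    }
    if np.all(y_true == y_true[0]):
        out["r2"] = np.nan
        out["explained_variance"] = np.nan
    else:
        out["r2"] = r2_score(y_true, y_pred)
        out["explained_variance"] = explained_variance_score(y_true, y_pred)
    return out


def nested_cv_evaluate(
    features: FeatureTable,
    model: str = "gbdt",
    grid: dict | None = None,
    seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
) -> ModelEvaluation:
    """Fivefold nested cross-validation of one model.

    Outer fivefold split (shuffled under ``seed``); the inner fivefold grid
    search sees only the outer training rows, so hyperparameter selection
    never touches the test fold.  Metrics are computed on each outer test
    fold; folds with a constant training response are skipped with a
    warning.
    """
    X, y = features.X.to_numpy(float), features.y.to_numpy(float)
    if len(y) < N_FOLDS * N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS * N_FOLDS} rows for nested "
                         f"{N_FOLDS}x{N_FOLDS}-fold cross-validation")
    estimator, default_grid = make_model(model, seed=seed, n_estimators=n_estimators)
    grid = default_grid if grid is None else grid
    outer = KFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    rows, chosen = [], []
    for fold, (tr, te) in enumerate(outer.split(X)):
        if np.all(y[tr] == y[tr][0]):
            logger.warning("outer fold %d skipped: constant training response", fold)
            continue
        if grid:
            inner = KFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
            search = GridSearchCV(estimator, grid, cv=inner, n_jobs=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(X[tr], y[tr])
            fitted, params = search.best_estimator_, search.best_params_
        else:
            from sklearn.base import clone
            fitted = clone(estimator)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted.fit(X[tr], y[tr])
            params = {}
        metrics = compute_metrics(y[te], fitted.predict(X[te]))
        metrics["fold"] = fold
        rows.append(metrics)
        chosen.append(params)
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    return ModelEvaluation(model=model, fold_metrics=fold_metrics, best_params=chosen)


def scheffe_compare(metric_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Scheffe's multiple-comparison procedure across models.

    ``metric_table`` has one column per model and one row per fold (one
    metric).  A one-way ANOVA across models is followed by Scheffe pairwise
    contrasts at level ``alpha``: the pair statistic
    ``(m_i - m_j)^2 / (MSW * (1/n_i + 1/n_j))`` is significant when it
    reaches ``(k - 1) * F_crit(alpha; k - 1, N - k)``.  With zero
    within-group variance everywhere the procedure is degenerate and
    significance is left undefined.
    """
    groups = {m: metric_table[m].dropna().to_numpy(float) for m in metric_table.columns}
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups.values()):
        raise ValueError("need at least 2 models with at least 2 folds each")
    n_total = sum(len(g) for g in groups.values())
    grand = np.concatenate(list(groups.values())).mean()
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    df_b, df_w = k - 1, n_total - k
    msw = ss_within / df_w
    degenerate = msw == 0
    f_global = np.nan if degenerate else (ss_between / df_b) / msw
    f_crit = stats.f.ppf(1 - alpha, df_b, df_w)
    rows = []
    names = list(groups)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[names[i]], groups[names[j]]
            diff = gi.mean() - gj.mean()
            if degenerate:
                statistic, significant = np.nan, None
            else:
                statistic = diff ** 2 / (msw * (1 / len(gi) + 1 / len(gj)))
                significant = bool(statistic >= df_b * f_crit)
            rows.append({"model_a": names[i], "model_b": names[j],
                         "mean_difference": diff, "statistic": statistic,
                         "critical_value": df_b * f_crit,
                         "significant": significant, "degenerate": degenerate})
    result = pd.DataFrame(rows)
    result.attrs["f_global"] = f_global
    result.attrs["f_critical"] = f_crit
    return result


#: Default grid for the fold-averaged importance runs (learning rate
#: 0.01-0.5 in steps of 0.01, depth 2-5 as for the nested evaluation).
IMPORTANCE_GRID = {"learning_rate": list(np.round(np.arange(0.01, 0.5001, 0.01), 2)),
                   "max_depth": [2, 3, 4, 5]}


def gbdt_importance(
    features: FeatureTable,
    grid: dict | None = None,
    seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
) -> ImportanceProfile:
    """Fold-averaged impurity importances of a gradient-boosted tree model.

    For each of five folds a boosted-tree regressor is fitted on the
    training rows (hyperparameters by inner fivefold grid search) and its
    impurity-based feature importances recorded; the per-component mean
    across folds is the importance profile.  Importances are normalised to
    sum to one per fold.
    """
    X, y = features.X.to_numpy(float), features.y.to_numpy(float)
    if len(y) < N_FOLDS * N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS * N_FOLDS} rows")
    grid = IMPORTANCE_GRID if grid is None else grid
    outer = KFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (tr, _te) in enumerate(outer.split(X)):
        if np.all(y[tr] == y[tr][0]):
            logger.warning("fold %d skipped: constant training response", fold)
            continue
        base = GradientBoostingRegressor(random_state=0, n_estimators=n_estimators)
        if grid:
            inner = KFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
            search = GridSearchCV(base, grid, cv=inner, n_jobs=1)
            search.fit(X[tr], y[tr])
            fitted = search.best_estimator_
        else:
            base.fit(X[tr], y[tr])
            fitted = base
        imp = np.asarray(fitted.feature_importances_, float)
        total = imp.sum()
        imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
        per_fold.append(pd.Series(imp, index=features.X.columns, name=fold))
    table = pd.DataFrame(per_fold)
    return ImportanceProfile(parameter=features.parameter,
                             mean=table.mean(axis=0), per_fold=table)


def split_bimodal(values, bw: float = 0.3, grid_points: int = 1000) -> SplitResult:
    """Split a bimodal distribution at its kernel-density trough.

    A Gaussian KDE (bandwidth factor ``bw``) is evaluated on an
    equal-probability grid of ``grid_points`` quantiles spanning the data
    range; the threshold is the interior density minimum between the two
    largest modes.  Unimodal or degenerate data yield a not-separable
    result rather than a split.  Values at or below the threshold form the
    low subset.
    """
    series = values if isinstance(values, pd.Series) else pd.Series(np.asarray(values, float))
    vals = series.to_numpy(float)
    if len(vals) < 20:
        raise ValueError("need at least 20 values to attempt a split")
    if np.ptp(vals) == 0:
        return SplitResult(separable=False)
    kde = stats.gaussian_kde(vals, bw_method=bw)
    grid = np.unique(np.quantile(vals, np.linspace(0.0, 1.0, grid_points)))
    density = kde(grid)
    maxima = list(argrelmax(density)[0])
    if density[0] > density[1]:
        maxima.insert(0, 0)
    if density[-1] > density[-2]:
        maxima.append(len(density) - 1)
    if len(maxima) < 2:
        return SplitResult(separable=False)
    top_two = sorted(sorted(maxima, key=lambda i: -density[i])[:2])
    lo_m, hi_m = top_two
    interior = [i for i in argrelmin(density)[0] if lo_m < i < hi_m]
    if not interior:
        return SplitResult(separable=False)
    trough = min(interior, key=lambda i: density[i])
    threshold = float(grid[trough])
    low = series.index[vals <= threshold]
    high = series.index[vals > threshold]
    return SplitResult(separable=True, threshold=threshold,
                       low_ids=low, high_ids=high)
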