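"""Explanatory and predictive regression statistics for leg-force features.

Two model families are implemented on top of the paddler-bout feature
table:

* a *predictive* model of maximal velocity from force characteristics —
  exhaustive BIC subset selection over candidate predictors, seeded
  k-fold cross-validation of the prediction-error SD, and a built-in
  published coefficient set for direct prediction; and
* *explanatory* models of each force characteristic on velocity,
  optionally adjusted for paddler group (age/sex level) as a categorical
  covariate.

Supporting machinery: Pearson correlation matrix for multicollinearity
screening, case-resampling bootstrap percentile CIs, and numeric residual
diagnostics (residual-vs-fitted, normal Q-Q quantiles, Cook's distance,
per-paddler residual grouping).

OLS fitting and influence measures are delegated to statsmodels; the BIC
used for subset search is the Gaussian profile form
``n * ln(RSS / n) + p * ln(n)`` with ``p`` counting intercept and slopes
(any monotone-equivalent variant selects the same subset).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import FeatureRecord, records_to_frame

logger = logging.getLogger("kayakforce")

__all__ = [
    "LinearModelFit",
    "CrossValidationResult",
    "CorrelationMatrix",
    "EstimationError",
    "pearson_matrix",
    "fit_ols",
    "select_model_bic",
    "predict_vmax",
    "cross_validate",
    "explanatory_fit",
    "bootstrap_ci",
    "diagnostics",
    "BUILTIN_MODELS",
]

#: Canonical feature-table predictor names for the velocity models.
PREDICTOR_NAMES = (
    "peak_force_n",
    "impulse_10s_ns",
    "stroke_rate_spm",
    "mean_force_n",
    "impulse_cycle_ns",
)

#: Built-in prediction models.  "published2021" carries the published
#: maximal-velocity equation
#: Vmax = 0.0045 * Fpeak + 0.0017 * J10s + 0.05 * SR + 7.62 (km/h).
BUILTIN_MODELS: dict[str, dict] = {
    "published2021": {
        "response": "velocity_kmh",
        "coefficients": {
            "peak_force_n": 0.0045,
            "impulse_10s_ns": 0.0017,
            "stroke_rate_spm": 0.05,
        },
        "intercept": 7.62,
    }
}


class EstimationError(ValueError):
    """A model could not be estimated (e.g. rank-deficient design)."""


@dataclass
class LinearModelFit:
    """An OLS fit with its statistics, diagnostics, and stored design."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    conf_int: dict[str, tuple[float, float]]
    bootstrap_conf_int: dict[str, tuple[float, float]] | None
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_dof: tuple[int, int]
    f_pvalue: float
    bic: float
    n_obs: int
    residuals: np.ndarray
    fitted: np.ndarray
    cooks_distance: np.ndarray
    leverage: np.ndarray
    design: pd.DataFrame = field(repr=False)
    design_columns: list[str] = field(default_factory=list)
    p_values: dict[str, float] = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predict the response for new rows of the feature table."""
        out = np.full(len(table), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            if name not in table.columns:
                raise ValueError(f"missing predictor column {name!r}")
            out = out + coef * table[name].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class CrossValidationResult:
    """Held-out predictions and the prediction-error SD from k-fold CV."""

    observed: np.ndarray
    predicted: np.ndarray
    fold_assignment: np.ndarray
    prediction_sd: float
    k: int
    seed: int


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    degenerate: list[str]


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if len(table) and isinstance(table[0], FeatureRecord):
        return records_to_frame(table)
    return pd.DataFrame(table)


def pearson_matrix(table, variables: list[str]) -> CorrelationMatrix:
    """Pearson correlation matrix over complete cases.

    Zero-variance variables are flagged and their correlations reported
    as missing (NaN) rather than silently zero.
    """
    df = _as_frame(table)[list(variables)].dropna()
    if len(df) < 3:
        raise EstimationError(f"need >= 3 complete records, have {len(df)}")
    degenerate = [v for v in variables if np.std(df[v].to_numpy()) == 0]
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if a in degenerate or b in degenerate:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(df[a], df[b])
            r[i, j], p[i, j] = float(res.statistic), float(res.pvalue)
    if degenerate:
        logger.warning("zero-variance variable(s): %s", ", ".join(degenerate))
    idx = list(variables)
    return CorrelationMatrix(
        variables=idx,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        degenerate=degenerate,
    )


def _design_matrix(df: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Numeric design with dummy-coded categoricals, no intercept column."""
    cols = {}
    for name in predictors:
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def fit_ols(table, response: str, predictors: list[str]) -> LinearModelFit:
    """Ordinary least squares of ``response`` on ``predictors``.

    Categorical predictors (e.g. ``group``) are dummy-coded with the
    first level as reference.  Raises :class:`EstimationError` on a
    rank-deficient design, naming the collinear columns.
    """
    df = _as_frame(table).dropna(subset=[response, *predictors])
    y = df[response].to_numpy(dtype=float)
    X = _design_matrix(df, list(predictors))
    n, k = len(y), X.shape[1]
    if n <= k + 1:
        raise EstimationError(
            f"n={n} observations cannot identify {k + 1} parameters"
        )
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = _collinear_columns(Xc)
        raise EstimationError(
            f"rank-deficient design (rank {rank} < {Xc.shape[1]}); "
            f"collinear column(s): {', '.join(collinear)}"
        )
    res = sm.OLS(y, Xc).fit()

    names = list(X.columns)
    ci = res.conf_int(alpha=0.05)
    conf = {nm: (float(ci.loc[nm, 0]), float(ci.loc[nm, 1])) for nm in names}
    conf["intercept"] = (float(ci.loc["const", 0]), float(ci.loc["const", 1]))
    pvals = {nm: float(res.pvalues[nm]) for nm in names}
    pvals["intercept"] = float(res.pvalues["const"])

    rss = float(np.sum(res.resid ** 2))
    p_total = k + 1
    bic = _bic_from_rss(rss, n, p_total)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        influence = res.get_influence()
        cooks = influence.cooks_distance[0]
        leverage = influence.hat_matrix_diag

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else float(res.rsquared)
    adj_r2 = 0.0 if ss_tot == 0 else float(res.rsquared_adj)

    return LinearModelFit(
        response=response,
        predictors=list(predictors),
        coefficients={nm: float(res.params[nm]) for nm in names},
        intercept=float(res.params["const"]),
        conf_int=conf,
        bootstrap_conf_int=None,
        r_squared=r2,
        adj_r_squared=adj_r2,
        f_statistic=float(res.fvalue) if np.isfinite(res.fvalue) else np.nan,
        f_dof=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue) if np.isfinite(res.fvalue) else np.nan,
        bic=bic,
        n_obs=n,
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        cooks_distance=np.asarray(cooks, dtype=float),
        leverage=np.asarray(leverage, dtype=float),
        design=df,
        design_columns=names,
        p_values=pvals,
    )


def _bic_from_rss(rss: float, n: int, p: int) -> float:
    # Guard the log for interpolating (zero-residual) fits.
    return n * np.log(max(rss, 1e-300) / n) + p * np.log(n)


def _collinear_columns(Xc: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank — the collinear set."""
    A = Xc.to_numpy()
    full = np.linalg.matrix_rank(A)
    out = []
    for j, name in enumerate(Xc.columns):
        if name == "const":
            continue
        reduced = np.delete(A, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(name)
    return out or [c for c in Xc.columns if c != "const"]


def select_model_bic(table, response: str,
                     candidate_predictors: list[str]) -> LinearModelFit:
    """Exhaustive minimum-BIC search over non-empty predictor subsets.

    Ties are broken toward fewer predictors, then lexicographically.
    Subsets that fail to fit (rank deficiency) are skipped with a warning.
    At most 15 candidates are accepted so the 2^k - 1 enumeration stays
    cheap.
    """
    cands = list(candidate_predictors)
    if not cands:
        raise ValueError("no candidate predictors")
    if len(cands) > 15:
        raise ValueError(f"too many candidates for exhaustive search: {len(cands)}")
    best: tuple | None = None
    for size in range(1, len(cands) + 1):
        for subset in itertools.combinations(sorted(cands), size):
            try:
                fit = fit_ols(table, response, list(subset))
            except EstimationError as exc:
                logger.warning("subset %s skipped: %s", subset, exc)
                continue
            key = (fit.bic, size, subset)
            if best is None or key < best[0]:
                best = (key, fit)
    if best is None:
        raise EstimationError("no candidate subset could be fitted")
    return best[1]


def predict_vmax(record, model="published2021") -> float:
    """Predict maximal velocity (km/h) from a feature record.

    ``model`` is a :class:`LinearModelFit`, a built-in model name, or a
    dict with ``coefficients`` and ``intercept``.  Raises a validation
    error naming any missing predictor.
    """
    if isinstance(model, str):
        try:
            model = BUILTIN_MODELS[model]
        except KeyError:
            raise ValueError(
                f"unknown built-in model {model!r}; "
                f"available: {sorted(BUILTIN_MODELS)}"
            ) from None
    if isinstance(model, LinearModelFit):
        coeffs, intercept = model.coefficients, model.intercept
    else:
        coeffs, intercept = model["coefficients"], model["intercept"]

    if isinstance(record, FeatureRecord):
        values = {
            "peak_force_n": record.peak_force_n,
            "impulse_10s_ns": record.impulse_10s_ns,
            "stroke_rate_spm": record.stroke_rate_spm,
            "mean_force_n": record.mean_force_n,
            "impulse_cycle_ns": record.impulse_cycle_ns,
        }
    else:
        values = dict(record)
    out = float(intercept)
    for name, coef in coeffs.items():
        if name not in values or values[name] is None:
            raise ValueError(f"missing predictor {name!r} in record")
        out += coef * float(values[name])
    return out


def cross_validate(table, response: str, predictors: list[str], k: int = 5,
                   seed: int = 0, loo: bool = False) -> CrossValidationResult:
    """Seeded k-fold cross-validation of the OLS prediction error.

    The sample is randomly partitioned into ``k`` folds whose sizes
    differ by at most one; each fold is predicted from a model fitted on
    the other k-1 folds.  ``prediction_sd`` is the sample SD of the
    held-out errors (observed - predicted).  ``loo=True`` switches to
    leave-one-out (k = n).
    """
    df = _as_frame(table).dropna(subset=[response, *predictors]).reset_index(drop=True)
    n = len(df)
    if loo:
        k = n
    if n < 2 * k and not loo:
        raise ValueError(f"need n >= 2k observations for {k}-fold CV, have {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = fold

    predicted = np.empty(n)
    for fold in range(k):
        test = folds == fold
        fit = fit_ols(df.loc[~test], response, predictors)
        predicted[test] = fit.predict(df.loc[test])
    observed = df[response].to_numpy(dtype=float)
    errors = observed - predicted
    return CrossValidationResult(
        observed=observed,
        predicted=predicted,
        fold_assignment=folds,
        prediction_sd=float(np.std(errors, ddof=1)),
        k=k,
        seed=seed,
    )


def explanatory_fit(table, feature: str, adjusted: bool = False,
                    velocity: str = "velocity_kmh",
                    group: str = "group") -> LinearModelFit:
    """Explanatory model: force characteristic regressed on velocity.

    ``adjusted=True`` adds paddler group (age/sex level) as a
    dummy-coded categorical covariate; with a single group present the
    fit degenerates to the univariate model with a warning.  The
    velocity slope and its 95% CI live in ``fit.coefficients[velocity]``
    and ``fit.conf_int[velocity]``.
    """
    df = _as_frame(table)
    predictors = [velocity]
    if adjusted:
        if group in df.columns and df[group].nunique() > 1:
            predictors.append(group)
        else:
            logger.warning(
                "adjusted fit requested but a single group is present; "
                "falling back to the univariate model"
            )
    return fit_ols(df, feature, predictors)


def bootstrap_ci(table, response: str, predictors: list[str],
                 n_reps: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap percentile CIs for OLS coefficients.

    Rows are resampled with replacement ``n_reps`` times; each resample
    is refitted and the empirical 2.5/97.5 percentiles of every
    coefficient (and the intercept) are returned.  A resample with a
    rank-deficient design is redrawn, at most 10 times before erroring.
    """
    df = _as_frame(table).dropna(subset=[response, *predictors]).reset_index(drop=True)
    n = len(df)
    if n < 10:
        raise ValueError(f"need n >= 10 for the bootstrap, have {n}")
    y = df[response].to_numpy(dtype=float)
    X = _design_matrix(df, list(predictors))
    names = ["intercept", *X.columns]
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise EstimationError("rank-deficient design")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_reps, A.shape[1]))
    for rep in range(n_reps):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            Ab = A[idx]
            if np.linalg.matrix_rank(Ab) == A.shape[1]:
                draws[rep] = np.linalg.lstsq(Ab, y[idx], rcond=None)[0]
                break
            if attempt == 10:
                raise EstimationError(
                    "rank-deficient bootstrap resample persisted after 10 redraws"
                )
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        name: (
            float(np.percentile(draws[:, j], lo)),
            float(np.percentile(draws[:, j], hi)),
        )
        for j, name in enumerate(names)
    }


def diagnostics(fit: LinearModelFit, paddler_col: str = "paddler_id") -> dict:
    """Numeric residual diagnostics sufficient to draw the standard plots.

    Returns a dict with:

    * ``residual_vs_fitted`` — DataFrame of fitted values and residuals;
    * ``qq`` — DataFrame of theoretical normal quantiles vs ordered
      standardized residuals;
    * ``cooks_distance`` — per-observation Cook's distance;
    * ``by_paddler`` — residuals grouped per paddler (if the design
      carries paddler ids), for inspecting the correlated-bout design.
    """
    resid = fit.residuals
    sd = np.std(resid, ddof=1) if len(resid) > 1 else 1.0
    std_resid = resid / sd if sd > 0 else resid
    osm, osr = stats.probplot(std_resid, dist="norm", fit=False)
    out = {
        "residual_vs_fitted": pd.DataFrame(
            {"fitted": fit.fitted, "residual": resid}
        ),
        "qq": pd.DataFrame(
            {"theoretical_quantile": osm, "ordered_residual": osr}
        ),
        "cooks_distance": pd.Series(fit.cooks_distance, name="cooks_distance"),
        "leverage": pd.Series(fit.leverage, name="leverage"),
    }
    if paddler_col in fit.design.columns:
        out["by_paddler"] = pd.DataFrame(
            {
                paddler_col: fit.design[paddler_col].to_numpy(),
                "residual": resid,
            }
        )
    return out


def fit_to_dict(fit: LinearModelFit) -> dict:
    """JSON-serializable summary of a fit (for the model file the CLI writes)."""
    return {
        "response": fit.response,
        "predictors": fit.predictors,
        "coefficients": fit.coefficients,
        "intercept": fit.intercept,
        "conf_int": {k: list(v) for k, v in fit.conf_int.items()},
        "bootstrap_conf_int": (
            {k: list(v) for k, v in fit.bootstrap_conf_int.items()}
            if fit.bootstrap_conf_int else None
        ),
        "r_squared": fit.r_squared,
        "adj_r_squared": fit.adj_r_squared,
        "f_statistic": fit.f_statistic,
        "f_dof": list(fit.f_dof),
        "f_pvalue": fit.f_pvalue,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
    }
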