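"""Phenotype-predictive OTU selection.

An L1-penalised (lasso) regression of the phenotype on standardized OTU
relative abundances shrinks uninformative coefficients to exactly zero; the
penalty strength lambda is tuned by repeated k-fold cross-validation over a
log-spaced grid.  The OTUs retaining nonzero coefficients are then refit in
an ordinary (reduced) GLM, whose per-OTU coefficient signs and Wald p-values
give the direction and strength of each OTU-phenotype link.

The lasso solves, for design matrix X (n x p) and response y,

    min_b  (1/2n) ||y - Xb||^2 + lambda ||b||_1

so lambda_max = max_j |x_j . (y - mean y)| / n is the smallest penalty that
zeroes every coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .exceptions import DataError
from .io_tables import OtuTable, PhenotypeVector

__all__ = [
    "LassoFit",
    "PhenotypeModel",
    "prepare_predictors",
    "make_lambda_grid",
    "tune_lambda",
    "select_predictive_otus",
    "fit_reduced_glm",
]

DEFAULT_K_FOLDS = 5
DEFAULT_N_REPEATS = 500
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-4


@dataclass(frozen=True)
class LassoFit:
    """Cross-validated lasso fit over a lambda grid.

    ``cv_table`` holds one row per lambda (grid order, descending) with the
    mean and variance of held-out squared error over repeats x folds.
    ``coefficients`` are the full-data refit at ``selected_lambda``.
    """

    lambda_grid: np.ndarray
    selected_lambda: float
    coefficients: pd.Series
    intercept: float
    cv_table: pd.DataFrame
    selection_rule: str

    def __post_init__(self) -> None:
        if not np.any(np.isclose(self.lambda_grid, self.selected_lambda)):
            raise DataError("selected_lambda must come from the grid")


@dataclass(frozen=True)
class PhenotypeModel:
    """Signed reduced-GLM links between selected OTUs and the phenotype."""

    selected_otus: list[str]
    coefficients: pd.Series
    pvalues: pd.Series
    signs: pd.Series  # "positive" | "negative" per selected OTU
    family: str = "gaussian-identity"

    def __post_init__(self) -> None:
        for otu in self.selected_otus:
            coef = self.coefficients[otu]
            want = "positive" if coef >= 0 else "negative"
            if self.signs[otu] != want:
                raise DataError(f"sign of {otu} inconsistent with its coefficient")


def prepare_predictors(table: OtuTable) -> pd.DataFrame:
    """Standardized relative abundances (mean 0, sd 1 per OTU).

    Standardization puts all OTUs on the same penalty scale; constant OTUs
    are left at zero rather than divided by a zero sd.
    """
    rel = table.relative_abundance()
    centered = rel - rel.mean(axis=0)
    sd = rel.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return centered / sd


def make_lambda_grid(x: np.ndarray, y: np.ndarray,
                     n_lambda: int = DEFAULT_N_LAMBDA,
                     min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO) -> np.ndarray:
    """Log-spaced grid from lambda_max down to min_ratio * lambda_max."""
    n = x.shape[0]
    resid = y - y.mean()
    lambda_max = np.abs(x.T @ resid).max() / n
    if lambda_max <= 0:
        raise DataError("all predictors are orthogonal to the response")
    return np.geomspace(lambda_max, lambda_max * min_ratio, n_lambda)


def _coerce_xy(x: pd.DataFrame | np.ndarray,
               y: PhenotypeVector | pd.Series | np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        names = [str(c) for c in x.columns]
        xv = x.to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        names = [f"x{i}" for i in range(xv.shape[1])]
    if isinstance(y, PhenotypeVector):
        yv = y.values.to_numpy(dtype=float)
    elif isinstance(y, pd.Series):
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    if xv.shape[0] != yv.shape[0]:
        raise DataError(f"{xv.shape[0]} predictor rows vs {yv.shape[0]} responses")
    return xv, yv, names


def _fit_at_lambda(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    if lam <= 0:  # ordinary least squares limit
        xc = np.column_stack([np.ones(len(y)), x])
        beta = np.linalg.lstsq(xc, y, rcond=None)[0]
        return beta[1:], float(beta[0])
    model = Lasso(alpha=lam, max_iter=100_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model.coef_, float(model.intercept_)


def tune_lambda(x: pd.DataFrame | np.ndarray,
                y: PhenotypeVector | pd.Series | np.ndarray,
                k_folds: int = DEFAULT_K_FOLDS,
                n_repeats: int = DEFAULT_N_REPEATS,
                grid: np.ndarray | None = None,
                seed: int = 0,
                selection_rule: str = "min_mean") -> LassoFit:
    """Repeated k-fold cross-validation of the lasso penalty.

    selection_rule: "min_mean" picks the lambda with the lowest mean held-out
    squared error; "min_variance" picks the lambda whose held-out error is
    most stable across folds/repeats; "one_se" picks the sparsest model
    within one standard error of the minimum.  Ties break toward the larger
    lambda (sparser model) because the grid is ordered descending.
    """
    xv, yv, names = _coerce_xy(x, y)
    n = len(yv)
    if np.std(yv) == 0:
        raise DataError("phenotype is constant; nothing to regress")
    if k_folds > n:
        raise DataError(f"k_folds={k_folds} exceeds n={n} samples")
    if k_folds < 2:
        raise DataError("k_folds must be >= 2")
    if grid is None:
        grid = make_lambda_grid(xv, yv)
    grid = np.asarray(sorted(np.asarray(grid, dtype=float), reverse=True))
    rng = np.random.default_rng(seed)
    positive_grid = grid[grid > 0]
    fold_mse = np.zeros((n_repeats * k_folds, len(grid)))
    row = 0
    for _ in range(n_repeats):
        kf = KFold(n_splits=k_folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        for train, test in kf.split(xv):
            xt, yt = xv[train], yv[train]
            if len(positive_grid):
                # lasso_path fits no intercept; center, then restore it
                xm, ym = xt.mean(axis=0), yt.mean()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, coefs, _ = lasso_path(xt - xm, yt - ym,
                                             alphas=positive_grid,
                                             max_iter=10_000, tol=1e-6)
                intercepts = ym - xm @ coefs
                pred = xv[test] @ coefs + intercepts  # (n_test, n_alphas)
                mse_pos = ((yv[test, None] - pred) ** 2).mean(axis=0)
            else:
                mse_pos = np.empty(0)
            mse = np.empty(len(grid))
            pos = 0
            for gi, lam in enumerate(grid):
                if lam > 0:
                    mse[gi] = mse_pos[pos]
                    pos += 1
                else:
                    coef, icpt = _fit_at_lambda(xt, yt, 0.0)
                    mse[gi] = ((yv[test] - (xv[test] @ coef + icpt)) ** 2).mean()
            fold_mse[row] = mse
            row += 1
    mean_mse = fold_mse.mean(axis=0)
    var_mse = fold_mse.var(axis=0, ddof=1) if fold_mse.shape[0] > 1 else np.zeros(len(grid))
    cv_table = pd.DataFrame({"lambda": grid, "mean_cv_error": mean_mse,
                             "var_cv_error": var_mse})
    if selection_rule == "min_mean":
        best = int(np.argmin(mean_mse))
    elif selection_rule == "min_variance":
        best = int(np.argmin(var_mse))
    elif selection_rule == "one_se":
        # largest lambda whose mean CV error is within one standard error of
        # the minimum; the standard guard against CV-min overselection (a
        # whole-sample chance correlation appears in every fold, so the CV
        # curve can dip at interior lambda even for pure-noise responses)
        i = int(np.argmin(mean_mse))
        se = float(np.sqrt(var_mse[i] / fold_mse.shape[0]))
        best = int(np.where(mean_mse <= mean_mse[i] + se)[0].min())
    else:
        raise DataError(f"unknown selection_rule: {selection_rule!r}")
    selected = float(grid[best])
    coef, intercept = _fit_at_lambda(xv, yv, selected)
    return LassoFit(
        lambda_grid=grid,
        selected_lambda=selected,
        coefficients=pd.Series(coef, index=names),
        intercept=intercept,
        cv_table=cv_table,
        selection_rule=selection_rule,
    )


def select_predictive_otus(fit: LassoFit) -> list[str]:
    """Ids with nonzero lasso coefficient, ranked by |coefficient| descending.

    Predictors are standardized upstream, so the coefficient magnitude is the
    standardized importance.
    """
    coef = fit.coefficients
    nonzero = coef[coef != 0.0]
    return list(nonzero.reindex(nonzero.abs().sort_values(ascending=False).index).index)


def fit_reduced_glm(x_sel: pd.DataFrame,
                    y: PhenotypeVector | pd.Series | np.ndarray,
                    family: str = "gaussian-identity") -> PhenotypeModel:
    """Reduced GLM of the phenotype on the selected OTUs only.

    Gaussian family with identity link (continuous phenotypes such as yield).
    Rank-deficient designs drop aliased columns with a warning.
    """
    if family != "gaussian-identity":
        raise DataError(f"unsupported GLM family: {family!r}")
    if not isinstance(x_sel, pd.DataFrame):
        x_sel = pd.DataFrame(np.asarray(x_sel, dtype=float))
    if x_sel.shape[1] < 1:
        raise DataError("fit_reduced_glm needs at least one selected OTU")
    xv, yv, names = _coerce_xy(x_sel, y)
    if len(yv) <= len(names) + 1:
        raise DataError(
            f"n={len(yv)} samples cannot support {len(names)} predictors + intercept"
        )
    keep = list(range(xv.shape[1]))
    design = np.column_stack([np.ones(len(yv)), xv])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # greedy drop of aliased columns, keeping earlier ones
        keep = []
        cols = [np.ones(len(yv))]
        for j in range(xv.shape[1]):
            trial = np.column_stack(cols + [xv[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(xv[:, j])
                keep.append(j)
        dropped = [names[j] for j in range(xv.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased predictors: {dropped}", RuntimeWarning)
        xv = xv[:, keep]
    used = [names[j] for j in keep]
    model = sm.GLM(yv, sm.add_constant(xv, has_constant="add"),
                   family=sm.families.Gaussian())
    res = model.fit()
    coefs = pd.Series(res.params[1:], index=used)
    pvals = pd.Series(res.pvalues[1:], index=used)
    signs = pd.Series(["positive" if c >= 0 else "negative" for c in coefs], index=used)
    return PhenotypeModel(
        selected_otus=used,
        coefficients=coefs,
        pvalues=pvals,
        signs=signs,
        family=family,
    )


def empty_phenotype_model() -> PhenotypeModel:
    """Model with no selected OTUs (lasso selected nothing)."""
    empty = pd.Series(dtype=float)
    return PhenotypeModel(selected_otus=[], coefficients=empty,
                          pvalues=empty, signs=pd.Series(dtype=object))
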