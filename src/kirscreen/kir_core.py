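"""Per-cytokine KiR modeling: elastic-net fitting, LOOCV penalty selection,
the alpha sweep, informative-kinase calling, model gating and out-of-panel
prediction.

The regression setting
----------------------
Each drug in a kinase-inhibitor screen has a known inhibition fingerprint:
the residual activity (percent of uninhibited control, 0--100) it leaves in
each of p kinases. Regressing a measured phenotype -- here, the level of a
secreted factor relative to the LPS-only control -- on these fingerprints
across the n screened drugs deconvolves which kinases drive the phenotype.
Because n << p, the fit is an elastic net:

    min_{b0, b}  (1/2n) sum_i (y_i - b0 - x_i . b)^2
                 + lam * [ (1-a)/2 ||b||_2^2 + a ||b||_1 ]

with the mixing parameter ``a`` (``alpha`` below) swept over eleven evenly
spaced values from 0 to 1 inclusive and the penalty ``lam`` selected per
alpha by leave-one-out cross-validation over drugs. Predictors are
standardized to zero mean / unit variance internally; coefficients are
reported on the original residual-activity scale.

Kinases with a positive coefficient in at least one selected model with
a > 0 are called *informative* (a=0 is ridge and is always dense, so it is
excluded from hit calling). A model is *accepted* when its LOOCV
predictions achieve nRMSE < 0.1 and Pearson r > 0.85 against the measured
responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._solver import enet_coordinate_descent_path

logger = logging.getLogger(__name__)

#: convergence tolerance of the coordinate-descent solver: a full pass must
#: move no standardized coefficient by more than this.
DEFAULT_SOLVER_TOL = 1e-8
#: looser tolerance used while scanning LOOCV folds along the penalty path;
#: the reported full-data solutions are always polished at the tight one.
DEFAULT_SCAN_TOL = 1e-5
DEFAULT_MAX_ITER = 100_000

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))
#: alpha floor used inside the lambda_max formula so the grid stays finite
#: as alpha -> 0 (glmnet convention).
ALPHA_FLOOR = 0.05
POSITIVE_COEF_TOL = 1e-8
NRMSE_THRESHOLD = 0.1
PEARSON_THRESHOLD = 0.85


class InsufficientDataError(ValueError):
    """Fewer drugs than the minimum needed to fit and cross-validate."""


class DegenerateResponseError(ValueError):
    """Response vector has zero variance; no model can be scored."""


@dataclass(frozen=True)
class ElasticNetSolution:
    """Selected elastic-net fit for one alpha.

    Coefficients are on the original predictor scale (per unit residual
    activity); ``loocv_predictions`` are the single-left-out predictions at
    the selected lambda, aligned with the training drugs.
    """

    alpha: float
    lam: float
    intercept: float
    coefficients: pd.Series
    loocv_mse: float
    loocv_predictions: np.ndarray

    @property
    def nonzero_kinases(self) -> set[str]:
        c = self.coefficients
        return set(c.index[np.abs(c.to_numpy()) > POSITIVE_COEF_TOL])


@dataclass(frozen=True)
class ModelQuality:
    nrmse: float
    pearson_r: float
    accepted: bool
    reason: str = ""


@dataclass
class KiRModel:
    """All alpha-sweep solutions for one secreted factor, plus diagnostics."""

    cytokine_id: str
    solutions: list[ElasticNetSolution]
    quality: ModelQuality = None  # type: ignore[assignment]
    informative_kinases: set[str] = field(default_factory=set)

    @property
    def best_solution(self) -> ElasticNetSolution:
        """Solution with the lowest LOOCV MSE across the full alpha grid
        (including alpha=0); used for quality scoring and prediction."""
        return min(self.solutions, key=lambda s: s.loocv_mse)

    @property
    def alpha_grid(self) -> tuple[float, ...]:
        return tuple(s.alpha for s in self.solutions)


# ---------------------------------------------------------------------------
# standardization helpers
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"k{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray):
    """Column means/sds (population sd, glmnet convention) and the mask of
    non-constant columns. Constant columns are dropped from the fit and get
    coefficient zero."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, mean, sd, keep


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which the elastic net is fully sparse, computed
    on standardized predictors; alpha is floored to avoid divergence."""
    Xs, _, _, keep = _standardize(np.asarray(X, dtype=float))
    if not keep.any():
        return 1.0
    yc = y - y.mean()
    a = max(float(alpha), ALPHA_FLOOR)
    lam = float(np.max(np.abs(Xs.T @ yc)) / (len(y) * a))
    return lam if lam > 0 else 1.0


def make_lambda_grid(
    X, y, alpha: float, n_lambdas: int = 100, lambda_min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced decreasing penalty grid from lambda_max down to
    lambda_min_ratio * lambda_max."""
    Xm, _ = _as_matrix(X)
    lmax = lambda_max(Xm, np.asarray(y, dtype=float), alpha)
    return np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)


# ---------------------------------------------------------------------------
# path fitting
# ---------------------------------------------------------------------------

def _fit_path_std(Xs: np.ndarray, yc: np.ndarray, alpha: float,
                  lambda_grid: np.ndarray,
                  tol: float = DEFAULT_SOLVER_TOL,
                  max_iter: int = DEFAULT_MAX_ITER,
                  b_init: np.ndarray | None = None) -> np.ndarray:
    """Coefficient path on standardized X / centered y; returns (p_kept, L).

    alpha = 0 is solved in closed form through the SVD (exact ridge);
    alpha > 0 by warm-started coordinate descent.
    """
    n = Xs.shape[0]
    if alpha == 0.0:
        U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
        Uty = U.T @ yc
        shrink = d[:, None] * Uty[:, None] / (d[:, None] ** 2 + n * lambda_grid[None, :])
        return Vt.T @ shrink
    if b_init is None:
        b_init = np.zeros(Xs.shape[1])
    return enet_coordinate_descent_path(
        np.ascontiguousarray(Xs), np.ascontiguousarray(yc, dtype=np.float64),
        float(alpha), np.ascontiguousarray(lambda_grid, dtype=np.float64),
        float(tol), max_iter,
        np.ascontiguousarray(b_init, dtype=np.float64))


def fit_elastic_net(X, y, alpha: float, lambda_grid,
                    tol: float = DEFAULT_SOLVER_TOL,
                    max_iter: int = DEFAULT_MAX_ITER) -> list[ElasticNetSolution]:
    """Fit the elastic-net path at one alpha over a decreasing lambda grid.

    Returns one solution per lambda, coefficients back-transformed to the
    original predictor scale. LOOCV fields are NaN/empty here; they are
    populated by :func:`loocv_select`.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.ndim != 1 or len(lambda_grid) == 0:
        raise ValueError("lambda_grid must be a non-empty 1-D sequence")
    if len(lambda_grid) > 1 and not np.all(np.diff(lambda_grid) < 0):
        raise ValueError("lambda_grid must be strictly decreasing")
    Xm, kinase_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 drugs, got {n}")

    Xs, mean, sd, keep = _standardize(Xm)
    if not keep.all():
        dropped = [kinase_ids[j] for j in np.flatnonzero(~keep)]
        logger.warning("dropping %d constant predictor column(s): %s",
                       len(dropped), dropped[:5])
    ym = y.mean()
    coefs_std = _fit_path_std(Xs, y - ym, alpha, lambda_grid, tol, max_iter)

    out = []
    for i, lam in enumerate(lambda_grid):
        b = np.zeros(p)
        b[keep] = coefs_std[:, i] / sd[keep]
        intercept = ym - float(b @ mean)
        out.append(ElasticNetSolution(
            alpha=float(alpha), lam=float(lam), intercept=intercept,
            coefficients=pd.Series(b, index=kinase_ids),
            loocv_mse=float("nan"), loocv_predictions=np.empty(0),
        ))
    return out


def penalized_objective(X, y, alpha: float, lam: float,
                        intercept: float, coef: np.ndarray) -> float:
    """Value of the elastic-net objective (standardized-predictor form) at a
    candidate solution; used by optimality checks."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, mean, sd, keep = _standardize(Xm)
    coef = np.asarray(coef, dtype=float)
    b_std = coef[keep] * sd[keep]
    b0_std = intercept + float(coef @ mean) - y.mean()
    resid = (y - y.mean()) - b0_std - Xs @ b_std
    n = len(y)
    return float(
        resid @ resid / (2 * n)
        + lam * ((1 - alpha) / 2 * b_std @ b_std + alpha * np.abs(b_std).sum())
    )


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def loocv_path_mse(X, y, alpha: float, lambda_grid,
                   tol: float = DEFAULT_SOLVER_TOL,
                   max_iter: int = DEFAULT_MAX_ITER) -> tuple[np.ndarray, np.ndarray]:
    """LOOCV mean squared error for every lambda in the grid.

    Folds are the individual drugs, in order, no shuffling: for each drug i
    the path is refit on the remaining n-1 drugs (restandardized) and drug
    i's response predicted at every lambda.

    Returns ``(mse, predictions)`` with shapes (L,) and (n, L).
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    n, p = Xm.shape
    if n < 3:
        raise InsufficientDataError(f"LOOCV needs >= 3 drugs, got {n}")
    preds = np.empty((n, len(lambda_grid)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = Xm[mask], y[mask]
        Xs, mean, sd, keep = _standardize(Xtr)
        ym = ytr.mean()
        coefs = _fit_path_std(Xs, ytr - ym, alpha, lambda_grid, tol, max_iter)
        if keep.any():
            xi = (Xm[i, keep] - mean[keep]) / sd[keep]
            preds[i] = ym + xi @ coefs
        else:
            preds[i] = ym
    mse = ((preds - y[:, None]) ** 2).mean(axis=0)
    return mse, preds


def loocv_select(X, y, alpha: float, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-3, lambda_grid=None,
                 tol: float = DEFAULT_SOLVER_TOL,
                 scan_tol: float | None = None,
                 max_iter: int = DEFAULT_MAX_ITER) -> ElasticNetSolution:
    """Select the penalty by LOOCV and return the full-data fit there.

    The lambda minimizing LOOCV MSE wins; exact ties go to the larger
    lambda (the sparser model). The returned solution carries the LOOCV MSE
    and the n single-left-out predictions at the selected lambda.

    ``scan_tol`` (default: ``tol``) is the solver tolerance for the fold
    scans and the path warm-up; the returned full-data solution is always
    polished at ``tol``.
    """
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(X, y, alpha, n_lambdas, lambda_min_ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if scan_tol is None:
        scan_tol = tol
    mse, preds = loocv_path_mse(X, y, alpha, lambda_grid, scan_tol, max_iter)
    best = int(np.argmin(mse))  # grid is decreasing: first minimum = largest lam

    Xm, kinase_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, mean, sd, keep = _standardize(Xm)
    ym = y.mean()
    if keep.any():
        path_std = _fit_path_std(Xs, y - ym, alpha, lambda_grid[: best + 1],
                                 scan_tol, max_iter)
        b_std = _fit_path_std(Xs, y - ym, alpha, lambda_grid[best: best + 1],
                              tol, max_iter, b_init=path_std[:, -1])[:, 0]
    else:
        b_std = np.empty(0)
    b = np.zeros(Xm.shape[1])
    b[keep] = b_std / sd[keep]
    return ElasticNetSolution(
        alpha=float(alpha), lam=float(lambda_grid[best]),
        intercept=ym - float(b @ mean),
        coefficients=pd.Series(b, index=kinase_ids),
        loocv_mse=float(mse[best]), loocv_predictions=preds[:, best],
    )


# ---------------------------------------------------------------------------
# model assembly, gating, hit calling
# ---------------------------------------------------------------------------

def evaluate_model(y, loocv_predictions,
                   nrmse_threshold: float = NRMSE_THRESHOLD,
                   pearson_threshold: float = PEARSON_THRESHOLD,
                   normalization: str = "range") -> ModelQuality:
    """Score a model by its LOOCV predictions.

    nRMSE is the root mean squared error normalized by the observed response
    range (``normalization='mean'`` divides by the mean instead). Acceptance
    requires nRMSE below 0.1 *and* Pearson r above 0.85. A constant response
    (zero range) or constant predictions make the score undefined and the
    model is rejected with an explicit reason.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(loocv_predictions, dtype=float)
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    denom = float(y.max() - y.min()) if normalization == "range" else float(y.mean())
    if denom == 0:
        return ModelQuality(nrmse=float("nan"), pearson_r=float("nan"),
                            accepted=False, reason="constant response")
    nrmse = rmse / denom
    if np.std(yhat) == 0 or np.std(y) == 0:
        return ModelQuality(nrmse=nrmse, pearson_r=float("nan"),
                            accepted=False, reason="constant predictions")
    r = float(stats.pearsonr(y, yhat).statistic)
    accepted = (nrmse < nrmse_threshold) and (r > pearson_threshold)
    return ModelQuality(nrmse=nrmse, pearson_r=r, accepted=accepted)


def call_informative_kinases(model: KiRModel,
                             tol: float = POSITIVE_COEF_TOL) -> set[str]:
    """Kinases with coefficient > tol in the selected solution of at least
    one alpha > 0. The dense alpha=0 (pure ridge) solution never counts."""
    hits: set[str] = set()
    for sol in model.solutions:
        if sol.alpha == 0.0:
            continue
        c = sol.coefficients
        hits |= set(c.index[c.to_numpy() > tol])
    return hits


def fit_kir_model(X, y, cytokine_id: str = "",
                  alpha_grid=DEFAULT_ALPHA_GRID,
                  n_lambdas: int = 100, lambda_min_ratio: float = 1e-3,
                  nrmse_threshold: float = NRMSE_THRESHOLD,
                  pearson_threshold: float = PEARSON_THRESHOLD,
                  tol: float = DEFAULT_SOLVER_TOL,
                  scan_tol: float = DEFAULT_SCAN_TOL) -> KiRModel:
    """Full KiR sweep for one secreted factor: one LOOCV-selected solution
    per alpha, quality from the best solution's LOOCV predictions, and the
    informative-kinase set."""
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise DegenerateResponseError(
            f"response {cytokine_id!r} has zero variance")
    solutions = [
        loocv_select(X, y, a, n_lambdas=n_lambdas,
                     lambda_min_ratio=lambda_min_ratio, tol=tol,
                     scan_tol=scan_tol)
        for a in alpha_grid
    ]
    model = KiRModel(cytokine_id=cytokine_id, solutions=solutions)
    model.quality = evaluate_model(
        y, model.best_solution.loocv_predictions,
        nrmse_threshold=nrmse_threshold, pearson_threshold=pearson_threshold)
    model.informative_kinases = call_informative_kinases(model)
    return model


def fit_kir_models(X: pd.DataFrame, Y: pd.DataFrame,
                   **kwargs) -> dict[str, KiRModel]:
    """Fit one KiR model per response column; constant-response factors are
    skipped with a logged reason rather than fitted."""
    if not X.index.equals(Y.index):
        raise ValueError("drug ids of X and Y do not align")
    models: dict[str, KiRModel] = {}
    for cyt in Y.columns:
        try:
            models[cyt] = fit_kir_model(X, Y[cyt].to_numpy(), cytokine_id=cyt,
                                        **kwargs)
        except DegenerateResponseError as e:
            logger.warning("skipping %s: %s", cyt, e)
    return models


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_out_of_panel(models, X_panel: pd.DataFrame,
                         include_rejected: bool = False) -> pd.DataFrame:
    """Predict factor levels for an unscreened inhibitor panel.

    Uses each cytokine's best-alpha solution (lowest LOOCV MSE). By default
    only accepted models contribute columns; ``include_rejected=True``
    predicts from every model. A panel missing a kinase that carries a
    nonzero coefficient is an error naming that kinase.
    """
    if isinstance(models, KiRModel):
        models = {models.cytokine_id: models}
    if not isinstance(models, dict):
        models = {m.cytokine_id: m for m in models}
    cols = {}
    for cyt, model in models.items():
        if not include_rejected and not model.quality.accepted:
            continue
        sol = model.best_solution
        c = sol.coefficients
        needed = c.index[np.abs(c.to_numpy()) > POSITIVE_COEF_TOL]
        missing = [k for k in needed if k not in X_panel.columns]
        if missing:
            raise KeyError(
                f"panel matrix lacks kinase(s) required by model {cyt!r}: "
                f"{sorted(missing)}")
        shared = c.index.intersection(X_panel.columns)
        cols[cyt] = sol.intercept + X_panel[shared].to_numpy() @ c[shared].to_numpy()
    return pd.DataFrame(cols, index=X_panel.index)
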