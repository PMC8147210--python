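"""Partial least squares regression via NIPALS.

The bilinear model is X = T Pᵀ + E, Y = U Qᵀ + F: X decomposes into scores T
and loadings P, the response into scores U and loadings Q, with components
chosen to maximise X-Y covariance.  NIPALS extracts one component at a time
(weight vector w, score t = Xw, loading p = Xᵀt/tᵀt, response loading q),
deflates X and y, and repeats.  The fitted model collapses to a single
linear predictor over wavelengths,

    ŷ = intercept + x · beta,      beta = W (Pᵀ W)⁻¹ q,

which is what makes pixel-wise concentration mapping cheap.

The number of latent variables is selected by leave-one-out cross-validation
RMSE; model quality is summarised by R² = 1 − SSres/SStot and by standard
errors (RMSE, in moisture percentage points) for calibration (SEC),
cross-validation (SEV) and prediction (SEP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    ConvergenceError,
    DimensionError,
    DomainError,
    SplitError,
)
from .hypercube_io import WavelengthGrid
from .preprocessing import (
    FittedPreprocess,
    PreprocessMethod,
    SpectraTable,
    fit_preprocess,
    preprocess,
)

__all__ = [
    "PLSModel",
    "ModelMetrics",
    "EvalResult",
    "split_cal_val",
    "fit_pls",
    "select_lv",
    "predict",
    "evaluate",
    "run_table1",
    "format_report",
    "model_to_json",
    "model_from_json",
]

_MAX_ITER = 500
_TOL = 1e-10


@dataclass
class PLSModel:
    """A fitted PLS decomposition plus its collapsed linear predictor."""

    n_lv: int
    x_weights: np.ndarray  # W, K x A
    x_loadings: np.ndarray  # P, K x A
    x_scores: np.ndarray  # T, N x A
    y_loadings: np.ndarray  # q, A
    y_scores: np.ndarray  # U, N x A
    x_mean: np.ndarray
    y_mean: float
    beta: np.ndarray
    intercept: float
    band_indices: np.ndarray | None = None
    method: FittedPreprocess | None = None
    grid: WavelengthGrid | None = None


@dataclass
class ModelMetrics:
    """Experiment-report row: R² and standard errors per evaluation set."""

    r2_cal: float
    sec: float
    r2_cv: float
    sev: float
    r2_pred: float
    sep: float
    n_cal: int
    n_val: int
    n_lv: int


class EvalResult(NamedTuple):
    r2: float
    se: float


def split_cal_val(
    table: SpectraTable, frac: float = 0.7, seed: int = 0
) -> tuple[SpectraTable, SpectraTable]:
    """Random calibration/validation partition of sizes round(frac·N), rest.

    Deterministic given the seed; every sample lands in exactly one side.
    """
    if not (0.0 < frac < 1.0):
        raise SplitError(f"frac must be in (0, 1), got {frac}")
    n = table.n
    if n < 2:
        raise SplitError("need at least 2 samples to split")
    n_cal = int(round(frac * n))
    if n_cal == 0 or n_cal == n:
        raise SplitError(f"split {n_cal}/{n - n_cal} leaves one side empty")
    perm = np.random.default_rng(seed).permutation(n)
    return table.take(np.sort(perm[:n_cal])), table.take(np.sort(perm[n_cal:]))


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int):
    """Run NIPALS on centred copies; returns (W, P, T, q, U, x_mean, y_mean).

    Components whose weight vector collapses to numerical zero (the residual
    carries no more covariance with y) end the extraction early.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise DimensionError("X and y disagree on the number of samples")
    if n_lv > min(n - 1, k):
        raise DomainError(f"n_lv={n_lv} exceeds min(N-1, K)={min(n - 1, k)}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = (y - y_mean)[:, None]

    W, P, T, Q, U = [], [], [], [], []
    for a in range(n_lv):
        u = yc[:, 0].copy()
        if np.linalg.norm(u) < 1e-13:
            break  # response fully explained
        t = np.zeros(n)
        for it in range(_MAX_ITER):
            w = Xc.T @ u / (u @ u)
            wn = np.linalg.norm(w)
            if wn < 1e-13:
                break
            w /= wn
            t_new = Xc @ w
            q = float(yc[:, 0] @ t_new / (t_new @ t_new))
            u = yc[:, 0] * q / (q * q) if q != 0 else yc[:, 0]
            if np.linalg.norm(t_new - t) <= _TOL * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                break
            t = t_new
        else:
            raise ConvergenceError(f"component {a + 1} did not converge in {_MAX_ITER} iterations")
        if np.linalg.norm(w) < 1e-13 or t @ t < 1e-26:
            break
        p = Xc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        yc = yc - np.outer(t, [q])
        W.append(w)
        P.append(p)
        T.append(t)
        Q.append(q)
        U.append(u)
    if not W:
        raise DomainError("no PLS component could be extracted (constant X or y)")
    return (
        np.column_stack(W),
        np.column_stack(P),
        np.column_stack(T),
        np.array(Q),
        np.column_stack(U),
        x_mean,
        y_mean,
    )


def _betas_by_count(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Regression vector for each truncation 1..A of the component set."""
    betas = []
    for a in range(1, W.shape[1] + 1):
        R = np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
        betas.append(W[:, :a] @ R)
    return betas


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 model with up to ``n_lv`` latent variables.

    X and y are mean-centred internally; predictions are available both via
    the score path and via the collapsed ``(beta, intercept)`` pair, which
    agree by construction.  If the response is exhausted before ``n_lv``
    components the extraction stops early and ``n_lv`` reflects the count
    actually extracted.
    """
    W, P, T, q, U, x_mean, y_mean = _nipals(X, y, n_lv)
    beta = _betas_by_count(W, P, q)[-1]
    intercept = y_mean - float(x_mean @ beta)
    return PLSModel(
        n_lv=W.shape[1],
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        y_scores=U,
        x_mean=x_mean,
        y_mean=y_mean,
        beta=beta,
        intercept=intercept,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict moisture (percent) as intercept + X·beta."""
    X_new = np.asarray(X_new, dtype=float)
    squeeze = X_new.ndim == 1
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.beta.shape[0]:
        raise DimensionError(
            f"X has {X_new.shape[1]} bands, model expects {model.beta.shape[0]}"
        )
    out = model.intercept + X_new @ model.beta
    return out[0] if squeeze else out


def select_lv(
    X: np.ndarray, y: np.ndarray, max_lv: int = 10
) -> tuple[int, np.ndarray, np.ndarray]:
    """Leave-one-out CV over latent-variable counts 1..max_lv.

    Returns ``(n_lv, rmse_curve, loo_predictions)`` where ``n_lv`` is the
    argmin of the curve (ties to the smaller count) and ``loo_predictions``
    is the N × max_lv matrix of held-out predictions, column a-1 for a
    components (used for the cross-validated R²/SEV at the selected count).
    A fold that exhausts the response early keeps its last available beta
    for the larger counts, so the curve is defined everywhere.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if max_lv > min(n - 2, k):
        raise DomainError(f"max_lv={max_lv} exceeds min(N-2, K)={min(n - 2, k)}")
    preds = np.empty((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        rows = idx != i
        W, P, T, q, U, x_mean, y_mean = _nipals(X[rows], y[rows], max_lv)
        betas = _betas_by_count(W, P, q)
        xi = X[i] - x_mean
        for a in range(max_lv):
            beta = betas[min(a, len(betas) - 1)]
            preds[i, a] = y_mean + xi @ beta
    rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    n_lv = int(np.argmin(rmse)) + 1  # first minimum -> smaller count on ties
    return n_lv, rmse, preds


def evaluate(y_true: np.ndarray, y_hat: np.ndarray) -> EvalResult:
    """R² = 1 − SSres/SStot and RMSE in moisture percentage points."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.shape != y_hat.shape or y_true.size < 2:
        raise DimensionError("evaluate needs two equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise DomainError("response has zero variance")
    ss_res = float(np.sum((y_true - y_hat) ** 2))
    return EvalResult(r2=1.0 - ss_res / ss_tot, se=float(np.sqrt(np.mean((y_true - y_hat) ** 2))))


def _fit_method(
    cal: SpectraTable,
    val: SpectraTable,
    method: PreprocessMethod,
    max_lv: int,
) -> tuple[PLSModel, ModelMetrics]:
    fitted = fit_preprocess(method, cal)
    cal_p = preprocess(cal, method, fitted)
    val_p = preprocess(val, method, fitted)
    n_lv, curve, loo = select_lv(cal_p.X, cal_p.y, max_lv=max_lv)
    model = fit_pls(cal_p.X, cal_p.y, n_lv)
    model.method = fitted
    model.grid = cal.grid
    cal_eval = evaluate(cal_p.y, predict(model, cal_p.X))
    cv_eval = evaluate(cal_p.y, loo[:, n_lv - 1])
    pred_eval = evaluate(val_p.y, predict(model, val_p.X))
    metrics = ModelMetrics(
        r2_cal=cal_eval.r2,
        sec=cal_eval.se,
        r2_cv=cv_eval.r2,
        sev=cv_eval.se,
        r2_pred=pred_eval.r2,
        sep=pred_eval.se,
        n_cal=cal.n,
        n_val=val.n,
        n_lv=model.n_lv,
    )
    return model, metrics


def run_table1(
    table: SpectraTable,
    methods: list[PreprocessMethod] | None = None,
    seed: int = 0,
    frac: float = 0.7,
    max_lv: int = 10,
) -> tuple[pd.DataFrame, dict[str, PLSModel]]:
    """Fit and evaluate one model per preprocessing method on a shared split.

    The default method list covers raw, mean, max and range normalisation,
    MSC, SNV and the two Savitzky-Golay derivatives.  Returns the report
    table (one row per method: split sizes, latent-variable count, R²/SE for
    calibration, cross-validation and prediction) and the fitted models.
    """
    if methods is None:
        methods = [PreprocessMethod(kind=k) for k in
                   ("raw", "mean", "max", "range", "msc", "snv", "sg1", "sg2")]
    cal, val = split_cal_val(table, frac=frac, seed=seed)
    rows, models = [], {}
    for method in methods:
        model, m = _fit_method(cal, val, method, max_lv)
        models[method.kind] = model
        rows.append(
            {
                "method": method.kind,
                "n_cal": m.n_cal,
                "n_val": m.n_val,
                "n_lv": m.n_lv,
                "r2_cal": m.r2_cal,
                "sec": m.sec,
                "r2_cv": m.r2_cv,
                "sev": m.sev,
                "r2_pred": m.r2_pred,
                "sep": m.sep,
            }
        )
    return pd.DataFrame(rows), models


def format_report(report: pd.DataFrame) -> str:
    """Human-readable experiment report (percent-point standard errors)."""
    lines = [
        f"{'Method':<8}{'nCal':>6}{'nVal':>6}{'LV':>4}"
        f"{'R2C':>8}{'SEC':>7}{'R2V':>8}{'SEV':>7}{'R2P':>8}{'SEP':>7}"
    ]
    for _, r in report.iterrows():
        lines.append(
            f"{r['method']:<8}{int(r['n_cal']):>6}{int(r['n_val']):>6}{int(r['n_lv']):>4}"
            f"{r['r2_cal']:>8.3f}{r['sec']:>7.2f}{r['r2_cv']:>8.3f}{r['sev']:>7.2f}"
            f"{r['r2_pred']:>8.3f}{r['sep']:>7.2f}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def model_to_json(model: PLSModel, path: str | Path) -> Path:
    """Persist a fitted model (arrays, preprocessing descriptor, grid)."""
    method = model.method.method if model.method is not None else None
    doc = {
        "n_lv": model.n_lv,
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "beta": model.beta.tolist(),
        "intercept": model.intercept,
        "band_indices": None if model.band_indices is None else model.band_indices.tolist(),
        "grid": None if model.grid is None else model.grid.band_centers.tolist(),
        "preprocess": None
        if method is None
        else {
            "kind": method.kind,
            "sg_window": method.sg_window,
            "sg_polyorder": method.sg_polyorder,
            "reference": None if model.method.reference is None else model.method.reference.tolist(),
            "delta": model.method.delta,
        },
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def model_from_json(path: str | Path) -> PLSModel:
    doc = json.loads(Path(path).read_text())
    method = None
    if doc["preprocess"] is not None:
        p = doc["preprocess"]
        method = FittedPreprocess(
            PreprocessMethod(kind=p["kind"], sg_window=p["sg_window"], sg_polyorder=p["sg_polyorder"]),
            reference=None if p["reference"] is None else np.array(p["reference"]),
            delta=p["delta"],
        )
    W = np.array(doc["x_weights"])
    n = W.shape[0]
    return PLSModel(
        n_lv=doc["n_lv"],
        x_weights=W,
        x_loadings=np.array(doc["x_loadings"]),
        x_scores=np.empty((0, doc["n_lv"])),
        y_loadings=np.array(doc["y_loadings"]),
        y_scores=np.empty((0, doc["n_lv"])),
        x_mean=np.array(doc["x_mean"]),
        y_mean=doc["y_mean"],
        beta=np.array(doc["beta"]),
        intercept=doc["intercept"],
        band_indices=None if doc["band_indices"] is None else np.array(doc["band_indices"], dtype=int),
        grid=None if doc["grid"] is None else WavelengthGrid(np.array(doc["grid"])),
        method=method,
    )
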