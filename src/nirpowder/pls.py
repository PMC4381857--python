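"""NIPALS partial least squares (single response) with PRESS-based
latent-variable selection.

Both X and y are mean-centered but not autoscaled: NIR absorbance channels
share units, so unit-variance scaling would only inflate noisy channels.
The number of latent variables (LVs) is chosen by leave-one-out cross
validation: PRESS(k) = sum of squared held-out residuals with k LVs, the
chosen k being the global PRESS minimum (smallest k on ties). RMSECV(k) =
sqrt(PRESS(k)/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, LineageError, ParameterError

_CONV_TOL = 1e-12
_MAX_ITER = 500


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS decomposition of centered data.

    Returns (W, P, q, k_eff): weights, x-loadings, y-loadings and the
    effective number of components extracted (may be < n_lv if the residual
    is exhausted; trailing components are zero vectors so predictions are
    constant beyond k_eff).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    scale = float(np.linalg.norm(Xc) * np.linalg.norm(yc)) or 1.0
    k_eff = 0
    for k in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale:
            break
        w /= nw
        # For a single response the weight iteration converges immediately,
        # but run the fixed-point loop per the general two-block algorithm.
        for _ in range(_MAX_ITER):
            t = X @ w
            tt = float(t @ t)
            if tt <= 0.0:
                break
            c = float(y @ t) / tt
            u = y * c
            w_new = X.T @ u
            n_new = np.linalg.norm(w_new)
            if n_new <= 1e-14 * scale:
                break
            w_new /= n_new
            if np.linalg.norm(w_new - w) < _CONV_TOL:
                w = w_new
                break
            w = w_new
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-28 * scale:
            break
        pk = X.T @ t / tt
        qk = float(y @ t) / tt
        X = X - np.outer(t, pk)
        y = y - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk
        k_eff = k + 1
    return W, P, q, k_eff


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """b = W_k (P_k^T W_k)^-1 q_k composed from the first k components."""
    if k == 0:
        return np.zeros(W.shape[0])
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


@dataclass
class PLSModel:
    """Fitted PLS calibration model.

    ``regression_vector`` composes all latent variables into a single
    predictor: yhat = (X - x_mean) @ b + y_mean. ``n_lv`` is the requested
    LV count, ``n_lv_effective`` how many carried signal.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_vector: np.ndarray
    n_lv_effective: int = 0
    lineage: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "family": "pls",
            "n_lv": self.n_lv,
            "n_lv_effective": self.n_lv_effective,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "lineage": list(map(list, self.lineage)) if self.lineage is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        lineage = d.get("lineage")
        return cls(
            n_lv=int(d["n_lv"]),
            x_mean=np.asarray(d["x_mean"], float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            regression_vector=np.asarray(d["regression_vector"], float),
            n_lv_effective=int(d.get("n_lv_effective", d["n_lv"])),
            lineage=tuple(tuple(x) for x in lineage) if lineage is not None else None,
        )


@dataclass
class LVSelectionCurve:
    """Per-candidate-LV diagnostics: RMSEC (refit), RMSECV and PRESS
    (leave-one-out), and the chosen LV count."""

    n_lv_candidates: list[int]
    rmsec: np.ndarray
    rmsecv: np.ndarray
    press: np.ndarray
    chosen_n_lv: int


def fit_pls(X_cal: np.ndarray, y_cal: np.ndarray, n_lv: int,
            lineage: tuple | None = None) -> PLSModel:
    """Fit a mean-centered NIPALS PLS model with ``n_lv`` latent variables."""
    X = np.atleast_2d(np.asarray(X_cal, float))
    y = np.asarray(y_cal, float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ParameterError("X and y have mismatched sample counts")
    if n < 3:
        raise ParameterError("PLS needs at least 3 calibration samples")
    max_lv = min(n - 1, p)
    if not (1 <= n_lv <= max_lv):
        raise ParameterError(f"n_lv must be in [1, {max_lv}], got {n_lv}")
    if np.ptp(y) == 0.0:
        raise DegenerateInputError("response is constant; PLS undefined")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, k_eff = _nipals(X - x_mean, y - y_mean, n_lv)
    b = _regression_vector(W, P, q, k_eff)
    return PLSModel(n_lv, x_mean, y_mean, W, P, q, b, k_eff, lineage)


def predict_pls(m: PLSModel, X: np.ndarray, lineage: tuple | None = None) -> np.ndarray:
    """Predict through the composed regression vector."""
    if m.lineage is not None and lineage is not None and m.lineage != lineage:
        raise LineageError(
            f"pretreatment lineage mismatch: model {m.lineage} vs data {lineage}")
    X = np.atleast_2d(np.asarray(X, float))
    return (X - m.x_mean) @ m.regression_vector + m.y_mean


def predict_pls_sequential(m: PLSModel, X: np.ndarray) -> np.ndarray:
    """Prediction by sequential score computation with deflation; must agree
    with :func:`predict_pls` to numerical precision (used as an internal
    consistency check)."""
    X = np.atleast_2d(np.asarray(X, float)) - m.x_mean
    yhat = np.full(X.shape[0], m.y_mean)
    Xr = X.copy()
    for k in range(m.n_lv_effective):
        t = Xr @ m.weights[:, k]
        Xr -= np.outer(t, m.x_loadings[:, k])
        yhat += m.y_loadings[k] * t
    return yhat


def select_lv(X_cal: np.ndarray, y_cal: np.ndarray, max_lv: int,
              lineage: tuple | None = None) -> tuple[PLSModel, LVSelectionCurve]:
    """Choose the LV count by leave-one-out PRESS and return the refitted
    model together with the full selection curve.

    For each left-out sample one NIPALS decomposition at ``max_lv`` is
    computed and truncated to every candidate k, so the LOO sweep costs n
    decompositions rather than n * max_lv.
    """
    X = np.atleast_2d(np.asarray(X_cal, float))
    y = np.asarray(y_cal, float).ravel()
    n, p = X.shape
    if max_lv < 1:
        raise ParameterError("max_lv must be >= 1")
    max_lv = min(max_lv, n - 2, p)  # n-2: LOO folds have n-1 samples
    if max_lv < 1:
        raise ParameterError("too few samples for leave-one-out LV selection")
    press = np.zeros(max_lv)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        xm, ym = Xi.mean(axis=0), float(yi.mean())
        W, P, q, k_eff = _nipals(Xi - xm, yi - ym, max_lv)
        xc = X[i] - xm
        for k in range(1, max_lv + 1):
            b = _regression_vector(W, P, q, min(k, k_eff))
            press[k - 1] += (float(xc @ b) + ym - y[i]) ** 2
    rmsecv = np.sqrt(press / n)
    chosen = int(np.argmin(press)) + 1  # first minimum = smallest k on ties

    # Full-data decomposition for RMSEC(k) and the final model.
    xm, ym = X.mean(axis=0), float(y.mean())
    W, P, q, k_eff = _nipals(X - xm, y - ym, max_lv)
    rmsec = np.empty(max_lv)
    Xc = X - xm
    for k in range(1, max_lv + 1):
        b = _regression_vector(W, P, q, min(k, k_eff))
        resid = Xc @ b + ym - y
        rmsec[k - 1] = float(np.sqrt(np.mean(resid ** 2)))
    kc = min(chosen, k_eff)
    model = PLSModel(chosen, xm, ym, W[:, :chosen], P[:, :chosen], q[:chosen],
                     _regression_vector(W, P, q, kc), kc, lineage)
    curve = LVSelectionCurve(list(range(1, max_lv + 1)), rmsec, rmsecv, press, chosen)
    return model, curve
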