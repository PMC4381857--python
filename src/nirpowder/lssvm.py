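"""Least-squares support vector machine regression with RBF kernel.

The LS-SVM replaces the SVM's epsilon-insensitive loss with squared error,
so the dual problem collapses to one linear ("saddle") system

    [[0,   1^T        ]   [b    ]   [0]
     [1,   K + I/gam  ]] [alpha] = [y],

with K(x, z) = exp(-||x - z||^2 / sig2) (denominator sig2, the LS-SVMlab
toolbox convention). ``gam`` trades training error against smoothness,
``sig2`` is the kernel width. Hyperparameters are tuned by minimizing the
exact leave-one-out MSE, computed in closed form from the full solve, with
a multi-start Nelder-Mead simplex in (log gam, log sig2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .errors import ConditioningError, LineageError, ParameterError, TuningError


def _rbf_kernel(A: np.ndarray, B: np.ndarray, sig2: float) -> np.ndarray:
    return np.exp(-cdist(A, B, metric="sqeuclidean") / sig2)


@dataclass
class LSSVMModel:
    """Fitted LS-SVM dual solution.

    ``support_values`` are the dual coefficients alpha (one per calibration
    sample); prediction is f(x) = sum_i alpha_i K(x, x_i) + b. The training
    matrix is retained for kernel evaluation.
    """

    gam: float
    sig2: float
    support_values: np.ndarray
    bias_term: float
    training_X: np.ndarray
    lineage: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "family": "lssvm",
            "gam": self.gam,
            "sig2": self.sig2,
            "support_values": self.support_values.tolist(),
            "bias_term": self.bias_term,
            "training_X": self.training_X.tolist(),
            "lineage": list(map(list, self.lineage)) if self.lineage is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        lineage = d.get("lineage")
        return cls(
            gam=float(d["gam"]),
            sig2=float(d["sig2"]),
            support_values=np.asarray(d["support_values"], float),
            bias_term=float(d["bias_term"]),
            training_X=np.asarray(d["training_X"], float),
            lineage=tuple(tuple(x) for x in lineage) if lineage is not None else None,
        )


@dataclass
class TuningResult:
    """Outcome of :func:`tune_lssvm`: best hyperparameters, the LOO-MSE
    achieved, and the evaluation trace (log10 gam, log10 sig2, loo_mse)."""

    gam: float
    sig2: float
    loo_mse: float
    trace: list[tuple[float, float, float]]


def _saddle_matrix(K: np.ndarray, gam: float) -> np.ndarray:
    n = K.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gam
    return A


def fit_lssvm(X_cal: np.ndarray, y_cal: np.ndarray, gam: float, sig2: float,
              lineage: tuple | None = None) -> LSSVMModel:
    """Solve the LS-SVM dual system for the given hyperparameters."""
    if gam <= 0 or sig2 <= 0:
        raise ParameterError("gam and sig2 must be positive")
    X = np.atleast_2d(np.asarray(X_cal, float))
    y = np.asarray(y_cal, float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ParameterError("X and y have mismatched sample counts")
    K = _rbf_kernel(X, X, sig2)
    A = _saddle_matrix(K, gam)
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"singular LS-SVM system (try smaller gam): {exc}") from None
    resid = float(np.linalg.norm(A @ sol - rhs))
    if resid > 1e-8 * max(1.0, float(np.linalg.norm(y))):
        raise ConditioningError(
            f"LS-SVM dual residual {resid:.2e} above tolerance; "
            "the system is ill-conditioned (try smaller gam)")
    return LSSVMModel(gam, sig2, sol[1:], float(sol[0]), X, lineage)


def predict_lssvm(m: LSSVMModel, X: np.ndarray, lineage: tuple | None = None) -> np.ndarray:
    """Kernel expansion over the stored training rows."""
    if m.lineage is not None and lineage is not None and m.lineage != lineage:
        raise LineageError(
            f"pretreatment lineage mismatch: model {m.lineage} vs data {lineage}")
    X = np.atleast_2d(np.asarray(X, float))
    K = _rbf_kernel(X, m.training_X, m.sig2)
    return K @ m.support_values + m.bias_term


def _loo_mse_from_D2(D2: np.ndarray, y: np.ndarray, gam: float, sig2: float) -> float:
    """Exact LOO-MSE via the inverse-diagonal leverage identity: with the
    bordered system A [b; alpha] = [0; y], the held-out residual of sample i
    is alpha_i / (A^-1)_{i+1, i+1}."""
    K = np.exp(-D2 / sig2)
    A = _saddle_matrix(K, gam)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return float("inf")
    rhs = np.concatenate(([0.0], y))
    sol = Ainv @ rhs
    diag = np.diag(Ainv)[1:]
    if np.any(np.abs(diag) < 1e-300):
        return float("inf")
    resid = sol[1:] / diag
    return float(np.mean(resid ** 2))


def loocv_mse_lssvm(X_cal: np.ndarray, y_cal: np.ndarray, gam: float, sig2: float) -> float:
    """Mean squared leave-one-out residual of the LS-SVM, in closed form
    (exact; equals the naive n-refit computation)."""
    if gam <= 0 or sig2 <= 0:
        raise ParameterError("gam and sig2 must be positive")
    X = np.atleast_2d(np.asarray(X_cal, float))
    y = np.asarray(y_cal, float).ravel()
    D2 = cdist(X, X, metric="sqeuclidean")
    return _loo_mse_from_D2(D2, y, gam, sig2)


def tune_lssvm(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-2, 1e7), (1e-1, 1e8)),
    n_grid: int = 4,
    n_starts: int = 3,
    xatol: float = 1e-3,
    maxiter: int = 200,
) -> TuningResult:
    """Tune (gam, sig2) by simplex minimization of the exact LOO-MSE.

    The LOO surface is broad and can be multimodal, so a coarse
    ``n_grid x n_grid`` log-spaced grid inside ``bounds`` is evaluated
    first and Nelder-Mead runs from the ``n_starts`` best grid points,
    converging when the simplex diameter falls below ``xatol`` in log10
    space. Fully deterministic for fixed inputs.
    """
    X = np.atleast_2d(np.asarray(X_cal, float))
    y = np.asarray(y_cal, float).ravel()
    (g_lo, g_hi), (s_lo, s_hi) = bounds
    if g_lo <= 0 or s_lo <= 0 or g_hi <= g_lo or s_hi <= s_lo:
        raise ParameterError("bounds must be positive with low < high")
    D2 = cdist(X, X, metric="sqeuclidean")
    trace: list[tuple[float, float, float]] = []
    lb = np.log10([g_lo, s_lo])
    ub = np.log10([g_hi, s_hi])

    def objective(theta: np.ndarray) -> float:
        th = np.clip(theta, lb, ub)
        penalty = float(np.sum((theta - th) ** 2))
        val = _loo_mse_from_D2(D2, y, 10.0 ** th[0], 10.0 ** th[1])
        trace.append((float(theta[0]), float(theta[1]), val))
        return val + penalty * max(val, 1.0)

    g_grid = np.linspace(lb[0], ub[0], n_grid)
    s_grid = np.linspace(lb[1], ub[1], n_grid)
    starts = []
    for lg, ls in itertools.product(g_grid, s_grid):
        val = objective(np.array([lg, ls]))
        starts.append((val, lg, ls))
    finite = [s for s in starts if np.isfinite(s[0])]
    if not finite:
        raise TuningError("LOO objective is non-finite at every grid start")
    finite.sort(key=lambda s: (s[0], s[1], s[2]))

    best_val, best_theta = finite[0][0], np.array(finite[0][1:])
    for _, lg, ls in finite[:n_starts]:
        res = minimize(objective, np.array([lg, ls]), method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": 1e-12, "maxiter": maxiter})
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_theta = float(res.fun), np.clip(res.x, lb, ub)
    return TuningResult(float(10.0 ** best_theta[0]), float(10.0 ** best_theta[1]),
                        best_val, trace)
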