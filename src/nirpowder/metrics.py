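"""Calibration-model performance indicators.

The indicator set used throughout the screening reports:

* r          - Pearson correlation between reference and predicted values
               (r_cal on the calibration set, r_pre on the validation set);
* RMSE       - sqrt(sum (C_pi - C_i)^2 / n), divisor n (not n-1); the same
               formula serves RMSEC, RMSECV and RMSEP depending on role;
* BIAS       - mean signed error, predicted minus reference;
* SD_pre     - standard deviation (n-1 divisor) of the validation-set
               reference values;
* RPD        - SD_pre / RMSEP, the relative predictive deviation; RPD > ~2-3
               marks a practically useful calibration, RPD <= 1 a model no
               better than predicting the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .lssvm import LSSVMModel, loocv_mse_lssvm, predict_lssvm
from .pls import PLSModel, predict_pls, select_lv


@dataclass
class PredictionSet:
    """Paired reference (C_i) and predicted (C_pi) vectors for one role."""

    reference: np.ndarray
    predicted: np.ndarray
    role: str = "validation"  # calibration | cross_validation | validation

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float).ravel()
        self.predicted = np.asarray(self.predicted, float).ravel()
        if self.reference.shape != self.predicted.shape:
            raise ParameterError("reference and predicted vectors differ in length")
        if self.reference.size < 2:
            raise ParameterError("a prediction set needs at least 2 samples")
        if not (np.all(np.isfinite(self.reference)) and np.all(np.isfinite(self.predicted))):
            raise ParameterError("prediction set contains NaN or Inf")
        if self.role not in ("calibration", "cross_validation", "validation"):
            raise ParameterError(f"unknown role {self.role!r}")

    @property
    def n(self) -> int:
        return self.reference.size


def correlation_r(p: PredictionSet) -> float:
    """Pearson product-moment correlation between reference and predicted."""
    if np.ptp(p.reference) == 0.0 or np.ptp(p.predicted) == 0.0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(np.corrcoef(p.reference, p.predicted)[0, 1])


def rmse(p: PredictionSet) -> float:
    """Root mean square error with divisor n (serves RMSEC/RMSECV/RMSEP)."""
    d = p.predicted - p.reference
    return float(np.sqrt(np.mean(d * d)))


def bias(p: PredictionSet) -> float:
    """Mean signed error, predicted minus reference."""
    return float(np.mean(p.predicted - p.reference))


def sd_pre(p: PredictionSet) -> float:
    """Standard deviation (n-1 divisor) of the reference values."""
    return float(np.std(p.reference, ddof=1))


def rpd(p: PredictionSet) -> float:
    """Relative predictive deviation SD_pre / RMSEP of a validation set.

    A perfect prediction (RMSEP = 0) returns ``inf`` rather than raising.
    """
    if p.role != "validation":
        raise ParameterError("RPD is defined on the validation prediction set")
    rmsep = rmse(p)
    s = sd_pre(p)
    if rmsep == 0.0:
        return float("inf")
    return s / rmsep


@dataclass
class MetricsReport:
    """One screening-table cell: the full indicator set plus the model
    descriptor (pretreatment, family, complexity) needed to regenerate the
    comparison tables from a run directory alone."""

    r_cal: float
    r_pre: float
    rmsec: float
    rmsecv: float
    rmsep: float
    bias_cal: float
    bias_pre: float
    sd_pre: float
    rpd: float
    n_cal: int
    n_val: int
    descriptor: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = dict(self.descriptor)
        row.update(
            r_cal=self.r_cal, rmsec=self.rmsec, rmsecv=self.rmsecv,
            bias_cal=self.bias_cal, r_pre=self.r_pre, rmsep=self.rmsep,
            rpd=self.rpd, bias_pre=self.bias_pre, sd_pre=self.sd_pre,
            n_cal=self.n_cal, n_val=self.n_val,
        )
        return row


def evaluate(model, X_cal, y_cal, X_val, y_val,
             rmsecv: float | None = None, descriptor: dict | None = None) -> MetricsReport:
    """Assemble the indicator set for a fitted model.

    ``rmsecv`` may be supplied from the model-selection stage (PLS LV curve,
    LS-SVM tuning); if omitted it is recomputed by the family's exact
    leave-one-out procedure on the calibration set, so PLS and LS-SVM
    reports stay comparable.
    """
    y_cal = np.asarray(y_cal, float).ravel()
    y_val = np.asarray(y_val, float).ravel()
    if y_val.size < 2:
        raise ParameterError("validation set must contain at least 2 samples")
    if isinstance(model, PLSModel):
        pred_cal = predict_pls(model, X_cal)
        pred_val = predict_pls(model, X_val)
        if rmsecv is None:
            _, curve = select_lv(X_cal, y_cal, model.n_lv)
            rmsecv = float(curve.rmsecv[model.n_lv - 1])
    elif isinstance(model, LSSVMModel):
        pred_cal = predict_lssvm(model, X_cal)
        pred_val = predict_lssvm(model, X_val)
        if rmsecv is None:
            rmsecv = float(np.sqrt(loocv_mse_lssvm(X_cal, y_cal, model.gam, model.sig2)))
    else:
        raise ParameterError(f"unknown model type {type(model).__name__}")
    cal = PredictionSet(y_cal, pred_cal, "calibration")
    val = PredictionSet(y_val, pred_val, "validation")
    return MetricsReport(
        r_cal=correlation_r(cal),
        r_pre=correlation_r(val),
        rmsec=rmse(cal),
        rmsecv=float(rmsecv),
        rmsep=rmse(val),
        bias_cal=bias(cal),
        bias_pre=bias(val),
        sd_pre=sd_pre(val),
        rpd=rpd(val),
        n_cal=cal.n,
        n_val=val.n,
        descriptor=dict(descriptor or {}),
    )
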