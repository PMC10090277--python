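"""Model-quality statistics shared by the 2D and 3D halves of the pipeline.

`loo_cv` is the deliberately naive leave-one-out loop (refit from scratch
n times); the model modules compute their cross-validated statistics with
faster algebra and are tested for exact agreement with this oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np

ROBUSTNESS_THRESHOLD = 0.5  # external-validation R² must strictly exceed this


@dataclass(frozen=True)
class ValidationReport:
    """Summary statistics for one fitted model."""

    r2: float
    q2_loo: Optional[float] = None
    r2_ext: Optional[float] = None
    robust: Optional[bool] = None
    mae_train: Optional[float] = None
    mae_test: Optional[float] = None
    n_train: int = 0
    n_test: int = 0
    y_train_mean: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def r2_score(y: np.ndarray, yhat: np.ndarray) -> float:
    """Plain coefficient of determination 1 − SSres/SStot."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("total sum of squares is zero (constant y)")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def r2_ext(
    y_test: np.ndarray, yhat_test: np.ndarray, y_train_mean: float
) -> tuple[float, bool]:
    """External-validation R²: 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ_tr)².

    The denominator centres the test activities on the *training* mean,
    so a model that merely predicts the training mean scores 0.  Returns
    the value and the robustness flag (strictly greater than 0.5).
    """
    y_test = np.asarray(y_test, float)
    yhat_test = np.asarray(yhat_test, float)
    if y_test.shape != yhat_test.shape or y_test.size < 1:
        raise ValueError("y_test and yhat_test must be equal-length, non-empty")
    denom = float(np.sum((y_test - y_train_mean) ** 2))
    if denom == 0:
        raise ValueError("all test activities equal the training mean; R²ext undefined")
    value = 1.0 - float(np.sum((y_test - yhat_test) ** 2)) / denom
    return value, value > ROBUSTNESS_THRESHOLD


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("y and yhat must be equal-length, non-empty")
    return float(np.mean(np.abs(y - yhat)))


def loo_cv(
    fit_fn: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    X: np.ndarray,
    y: np.ndarray,
) -> float:
    """Brute-force leave-one-out Q² = 1 − PRESS / Σ(y−ȳ)².

    ``fit_fn(X_train, y_train)`` must return a predictor callable.
    Refits n times, excluding each row in turn.  Serves as the oracle
    for every faster cross-validation in the package.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            predict = fit_fn(X[mask], y[mask])
            pred = float(np.asarray(predict(X[i : i + 1])).ravel()[0])
        except Exception as exc:  # noqa: BLE001 - report which fold failed
            raise RuntimeError(f"leave-one-out fit failed on fold {i}: {exc}") from exc
        press += (y[i] - pred) ** 2
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant y: Q² undefined")
    return 1.0 - press / ss_tot


def validation_report(
    y_train: np.ndarray,
    yhat_train: np.ndarray,
    y_test: np.ndarray | None = None,
    yhat_test: np.ndarray | None = None,
    q2_loo: float | None = None,
) -> ValidationReport:
    """Bundle the shared statistics for a fitted model into one report."""
    y_train = np.asarray(y_train, float)
    yhat_train = np.asarray(yhat_train, float)
    rep = {
        "r2": r2_score(y_train, yhat_train),
        "q2_loo": q2_loo,
        "mae_train": mae(y_train, yhat_train),
        "n_train": len(y_train),
        "y_train_mean": float(y_train.mean()),
    }
    if y_test is not None and len(np.asarray(y_test)) > 0:
        y_test = np.asarray(y_test, float)
        yhat_test = np.asarray(yhat_test, float)
        value, robust = r2_ext(y_test, yhat_test, float(y_train.mean()))
        rep.update(
            r2_ext=value,
            robust=robust,
            mae_test=mae(y_test, yhat_test),
            n_test=len(y_test),
        )
    return ValidationReport(**rep)
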