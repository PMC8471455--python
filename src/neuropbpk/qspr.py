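"""Quantitative structure-property relationships for the scaling factors.

Each cell line gets three regressions of ln(SC) on lipophilicity: the influx
and efflux factors (SC1, SC2) rise monotonically with logP and are modelled
as lines in ln-space by default, while the binding-correction factor SC3
shows a rise-then-fall pattern and is modelled as a parabola. Fitted models
predict scaling factors for unseen compounds from logP alone, which is what
turns the fitted PBPK model into a prospective screening tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import InvalidInputError, UndefinedResultError

__all__ = [
    "QSPRModel",
    "DrugDescriptor",
    "DEFAULT_FORMS",
    "fit_qspr",
    "predict_sc",
    "r_squared",
]

DEFAULT_FORMS = {"sc1": "linear", "sc2": "linear", "sc3": "quadratic"}


@dataclass(frozen=True)
class DrugDescriptor:
    name: str
    logp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.logp):
            raise InvalidInputError("logp must be finite")


@dataclass
class QSPRModel:
    """OLS fit of ln(SC) on logP (linear) or logP, logP^2 (quadratic)."""

    target: str  # sc1 | sc2 | sc3
    form: str  # linear | quadratic
    coefficients: np.ndarray  # intercept first
    r_squared: float
    n_points: int
    cell_line: str = ""
    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = {"linear": 2, "quadratic": 3}.get(self.form)
        if expected is None:
            raise InvalidInputError(f"unknown form: {self.form}")
        if self.coefficients.size != expected:
            raise InvalidInputError(
                f"{self.form} form needs {expected} coefficients"
            )
        if self.n_points < self.coefficients.size:
            raise InvalidInputError("more coefficients than data points")


def _design(logp: np.ndarray, form: str) -> np.ndarray:
    cols = [np.ones_like(logp), logp]
    if form == "quadratic":
        cols.append(logp**2)
    elif form != "linear":
        raise InvalidInputError(f"unknown form: {form}")
    return np.column_stack(cols)


def fit_qspr(
    sc_values,
    logp,
    form: str = "linear",
    *,
    target: str = "sc",
    cell_line: str = "",
    drugs: tuple[str, ...] = (),
) -> QSPRModel:
    """Regress ln(SC) on logP by ordinary least squares."""
    sc_values = np.asarray(sc_values, dtype=float)
    logp = np.asarray(logp, dtype=float)
    if sc_values.shape != logp.shape:
        raise InvalidInputError("sc_values and logp must have equal length")
    if np.any(sc_values <= 0):
        raise InvalidInputError("scaling factors must be > 0")
    n_coef = 2 if form == "linear" else 3
    if sc_values.size < n_coef + 1:
        raise InvalidInputError(
            f"{form} QSPR needs at least {n_coef + 1} compounds"
        )
    if np.ptp(logp) == 0:
        raise np.linalg.LinAlgError("zero variance in logP: singular design")

    y = np.log(sc_values)
    x = _design(logp, form)
    res = sm.OLS(y, x).fit()
    # constant-SC data: zero total variance, no trend to explain
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rsquared)
    return QSPRModel(
        target=target,
        form=form,
        coefficients=res.params,
        r_squared=r2,
        n_points=int(sc_values.size),
        cell_line=cell_line,
        drugs=tuple(drugs),
    )


def predict_sc(model: QSPRModel, logp: float) -> float:
    """Predicted scaling factor exp(polynomial(logP)); strictly positive."""
    powers = np.arange(model.coefficients.size)
    return float(np.exp(np.sum(model.coefficients * np.asarray(logp) ** powers)))


def r_squared(observed_lnsc, fitted_lnsc) -> float:
    """Coefficient of determination in ln-space."""
    y = np.asarray(observed_lnsc, dtype=float)
    f = np.asarray(fitted_lnsc, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise InvalidInputError("need two equal-length series of >= 2 points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedResultError("zero total sum of squares")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot
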