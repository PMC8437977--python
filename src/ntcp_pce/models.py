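"""Forward NTCP models: gEUD, probit (LKB), logistic, and TD_x inversion.

The Lyman-Kutcher-Burman (LKB) model expresses the complication probability
of a heterogeneously irradiated organ as a probit dose-response in the
generalised equivalent uniform dose,

    NTCP = Phi(t),   t = (gEUD - TD50) / (m * TD50),
    gEUD = (sum_i v_i * D_i**(1/n)) ** n,

where Phi is the standard normal CDF, TD50 the uniform whole-organ dose
giving 50% complication probability, m the steepness of the dose-response,
and n the volume-effect exponent (n -> 0: serial organ, gEUD -> max dose;
n = 1: parallel organ, gEUD = mean dose).  Setting n = 1 and driving the
probit with the mean heart dose (MHD) gives the reduced MHD-based model.

The logistic alternative is NTCP = expit(b0 + sum_j b_j * x_j) over dose
and clinical covariates.

``invert_td`` solves either family for the tolerance dose TD_x at a target
probability x; where the solution is non-positive the model never reaches
that risk level on physical doses and the distinguished value
:data:`NOT_ACHIEVED` (None) is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit, ndtr, ndtri

from .dvh import DoseVolumeHistogram
from .errors import ContractError, DomainError, MalformedInputError

#: Distinguished return of :func:`invert_td` when TD_x lies at or below 0 Gy.
NOT_ACHIEVED = None


@dataclass(frozen=True)
class LKBParameters:
    """The (n, m, TD50) triple of the LKB probit dose-response.

    ``n = 1`` marks the MHD-based reduction (gEUD degenerates to mean dose).
    """

    n: float
    m: float
    td50: float

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.m > 0 and self.td50 > 0):
            raise DomainError("LKB parameters n, m, td50 must all be > 0")

    @property
    def is_mhd_based(self) -> bool:
        return self.n == 1.0


@dataclass(frozen=True)
class LogisticModel:
    """Logistic NTCP model: intercept plus per-feature log-odds coefficients."""

    intercept: float
    coefficients: dict[str, float]
    covariance: np.ndarray | None = None  # over (intercept, *features) in order

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}

    def wald_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """95% (by default) Wald intervals for the odds ratios."""
        if self.covariance is None:
            raise ContractError("model carries no covariance matrix")
        z = ndtri(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.covariance))
        out = {}
        for i, name in enumerate(self.features, start=1):
            b = self.coefficients[name]
            out[name] = (float(np.exp(b - z * se[i])), float(np.exp(b + z * se[i])))
        return out


def geud(dvh: DoseVolumeHistogram, n: float) -> float:
    """Generalised equivalent uniform dose, (sum v_i D_i^(1/n))^n, in Gy.

    Zero-dose bins contribute nothing to the power sum (their term is 0 for
    any 1/n > 0) and are excluded, which also keeps small n numerically safe.
    """
    if n <= 0:
        raise DomainError("gEUD exponent n must be > 0")
    d = dvh.midpoints
    v = dvh.diff_volume
    mask = (d > 0) & (v > 0)
    if not mask.any():
        return 0.0
    d, v = d[mask], v[mask]
    # factor out the max dose to avoid overflow for small n
    dmax = d.max()
    s = float(np.dot(v, (d / dmax) ** (1.0 / n)))
    return float(dmax * s**n)


def geud_from_arrays(midpoints: np.ndarray, volumes: np.ndarray, n: float) -> np.ndarray:
    """Vectorised gEUD for a stack of DVHs sharing a bin grid.

    ``volumes`` has shape (n_patients, n_bins); rows are normalised
    fractional volumes.  Used by the fitting routines.
    """
    if n <= 0:
        raise DomainError("gEUD exponent n must be > 0")
    d = np.asarray(midpoints, dtype=float)
    pos = d > 0
    d = np.where(pos, d, 1.0)
    dmax = d.max()
    term = np.where(pos, (d / dmax) ** (1.0 / n), 0.0)
    s = volumes @ term
    return dmax * s**n


def probit_ntcp(dose_metric, params: LKBParameters):
    """LKB/probit NTCP: Phi((dose - TD50) / (m * TD50)).

    ``dose_metric`` is the gEUD (or the MHD for the n = 1 reduction), Gy.
    Accepts scalars or arrays.
    """
    d = np.asarray(dose_metric, dtype=float)
    t = (d - params.td50) / (params.m * params.td50)
    out = ndtr(t)
    return float(out) if np.isscalar(dose_metric) else out


def logistic_ntcp(features: Mapping[str, float], model: LogisticModel) -> float:
    """Inverse-logit of intercept + sum(coefficient * feature value)."""
    eta = model.intercept
    for name, coef in model.coefficients.items():
        if name not in features:
            raise ContractError(f"feature {name!r} missing from input")
        eta += coef * float(features[name])
    return float(expit(eta))


def invert_td(
    model: LKBParameters | LogisticModel,
    x: float,
    profile: Mapping[str, float] | None = None,
    dose_feature: str = "mhd",
) -> float | None:
    """Tolerance dose TD_x: the dose at which the model predicts probability x.

    Probit closed form TD_x = TD50 * (1 + m * Phi^-1(x)); logistic closed form
    D = (logit(x) - intercept - offset) / dose coefficient, where the offset
    comes from the non-dose covariates of ``profile``.  A multivariable
    logistic model without a declared profile is a contract violation.
    Returns :data:`NOT_ACHIEVED` when the solution is <= 0 Gy.
    """
    if not (0.0 < x < 1.0):
        raise DomainError("target probability must be in (0, 1)")
    if isinstance(model, LKBParameters):
        d = model.td50 * (1.0 + model.m * float(ndtri(x)))
    else:
        others = [f for f in model.features if f != dose_feature]
        if dose_feature not in model.coefficients:
            raise ContractError(f"model has no dose feature {dose_feature!r}")
        if others and profile is None:
            raise ContractError(
                "multivariable logistic model needs a covariate profile for TD_x"
            )
        offset = sum(model.coefficients[f] * float((profile or {})[f]) for f in others)
        d = (float(logit(x)) - model.intercept - offset) / model.coefficients[dose_feature]
    return float(d) if d > 0 else NOT_ACHIEVED


def coefficient_of_determination(y: Sequence[float], f: Sequence[float]) -> float:
    """R^2 = 1 - SS_res / SS_tot of fitted values ``f`` against observations ``y``."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise ContractError("y and f must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("R^2 undefined for constant y")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


# --- model parameter files -------------------------------------------------

def save_model(model: LKBParameters | LogisticModel, path: str | Path) -> None:
    """Serialise a model to JSON (type tag + parameters + covariate names)."""
    if isinstance(model, LKBParameters):
        obj = {"type": "lkb", "n": model.n, "m": model.m, "td50": model.td50}
    else:
        obj = {
            "type": "logistic",
            "intercept": model.intercept,
            "coefficients": dict(model.coefficients),
        }
        if model.covariance is not None:
            obj["covariance"] = np.asarray(model.covariance).tolist()
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def load_model(path: str | Path) -> LKBParameters | LogisticModel:
    obj = json.loads(Path(path).read_text())
    kind = obj.get("type")
    if kind == "lkb":
        return LKBParameters(n=obj["n"], m=obj["m"], td50=obj["td50"])
    if kind == "logistic":
        cov = obj.get("covariance")
        return LogisticModel(
            intercept=obj["intercept"],
            coefficients=dict(obj["coefficients"]),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
        )
    raise MalformedInputError(f"unknown model type {kind!r}")
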