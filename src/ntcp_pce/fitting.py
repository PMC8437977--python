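"""Maximum-likelihood estimation of NTCP models.

Two fitters live here:

* :func:`fit_lkb` — the LKB probit dose-response.  The binomial
  log-likelihood is maximised over (n, m, TD50) — or (m, TD50) with the
  volume exponent fixed, e.g. ``fix_n=1`` for the MHD-based reduction — by a
  coarse grid multi-start followed by projected gradient descent on the log
  of the parameters (which enforces positivity), with Barzilai-Borwein step
  lengths safeguarded by an Armijo backtracking line search.  Convergence is
  declared when the gradient max-norm drops below ``tol`` (default 1e-6).
  The returned optimum is never worse than the best coarse-grid point
  because descent starts there.

* :func:`fit_logistic` — binomial logistic regression, delegated to
  statsmodels (Newton-Raphson IRLS, tolerance 1e-8), wrapped to return the
  package's :class:`~ntcp_pce.models.LogisticModel` with covariance for
  Wald intervals.

:func:`forward_stepwise` builds a multivariable logistic model by adding, at
each step, the candidate with the largest likelihood-ratio improvement whose
LRT p-value (chi-square, df = 1) is below ``alpha``; ties break
lexicographically so selection is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .cohort import Cohort
from .errors import ContractError, DegenerateDataError, DomainError, SeparationError
from .models import LKBParameters, LogisticModel, geud_from_arrays, probit_ntcp

_CLIP = 1e-12

#: Default parameter box for the LKB fit: brackets published pericardium
#: estimates (n 0.35-1, TD50 41-58 Gy) with generous margins.
DEFAULT_BOUNDS = {"n": (0.05, 2.0), "m": (0.05, 2.0), "td50": (5.0, 120.0)}

#: Coarse-grid resolution (n, m, td50) for the multi-start.
GRID_SHAPE = (21, 21, 24)

DEFAULT_SEED = 20150137  # arbitrary fixed constant


@dataclass
class FitResult:
    params: LKBParameters | LogisticModel
    log_likelihood: float
    converged: bool
    iterations: int
    selected_features: list[str] | None = None
    gradient: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def binary_log_likelihood(predictions, outcomes, clip: float = _CLIP) -> float:
    """Binomial log-likelihood sum y log p + (1-y) log(1-p), in nats (<= 0)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ContractError("predictions and outcomes must have equal length")
    p = np.clip(p, clip, 1.0 - clip)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# --------------------------------------------------------------------------
# LKB probit fit
# --------------------------------------------------------------------------

def _dvh_stack(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Common-grid (midpoints, volume matrix) stack of all cohort DVHs."""
    widths = {round(p.dvh.bin_width, 9) for p in cohort}
    if len(widths) != 1:
        raise ContractError("cohort DVHs must share a bin width for joint fitting")
    w = widths.pop()
    n_bins = max(int(round(p.dvh.bin_edges[-1] / w)) for p in cohort)
    mids = (np.arange(n_bins) + 0.5) * w
    vol = np.zeros((len(cohort), n_bins))
    for i, p in enumerate(cohort):
        start = int(round(p.dvh.bin_edges[0] / w))
        vol[i, start : start + p.dvh.diff_volume.size] = p.dvh.diff_volume
    return mids, vol


def fit_lkb(
    cohort: Cohort,
    outcome: str = "any",
    fix_n: float | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = DEFAULT_SEED,
    grid_shape: tuple[int, int, int] = GRID_SHAPE,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_starts: int = 3,
) -> FitResult:
    """Maximum-likelihood LKB fit on a cohort.

    With ``fix_n`` set, only (m, TD50) are estimated; ``fix_n=1`` is the
    MHD-based model and runs directly off each record's mean heart dose, so
    DVHs are not required.  Otherwise every patient must carry a DVH.

    Returns the best local maximum found from ``n_starts`` descents seeded at
    the top coarse-grid points; ``converged`` reflects the gradient norm of
    the winning run (non-convergence returns the best iterate, flagged).
    """
    cohort.require_fittable(outcome)
    y = cohort.outcome_array(outcome).astype(float)
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}

    if fix_n is not None and fix_n <= 0:
        raise DomainError("fix_n must be > 0")

    if fix_n == 1.0 or (fix_n is None and not cohort.has_dvhs):
        if fix_n is None:
            raise ContractError("free-n LKB fit requires DVHs for every patient")
        doses_for = lambda n: cohort.mhd_array()
    else:
        if not cohort.has_dvhs:
            raise ContractError("LKB fit requires DVHs for every patient")
        mids, vol = _dvh_stack(cohort)
        doses_for = lambda n: geud_from_arrays(mids, vol, n)

    free = ("m", "td50") if fix_n is not None else ("n", "m", "td50")
    _dose_cache: dict[float, np.ndarray] = {}

    def doses_cached(n: float) -> np.ndarray:
        key = round(float(n), 12)
        if key not in _dose_cache:
            _dose_cache[key] = doses_for(n)
        return _dose_cache[key]

    def nll(theta: np.ndarray) -> float:
        # theta holds log(free params)
        vals = dict(zip(free, np.exp(theta)))
        n = fix_n if fix_n is not None else vals["n"]
        p = probit_ntcp(doses_cached(n), LKBParameters(n=n, m=vals["m"], td50=vals["td50"]))
        return -binary_log_likelihood(p, y)

    lo = np.log([bounds[f][0] for f in free])
    hi = np.log([bounds[f][1] for f in free])

    # coarse grid over the bounds (log-spaced like the descent parametrisation)
    axes = []
    sizes = dict(zip(("n", "m", "td50"), grid_shape))
    for f, l, h in zip(free, lo, hi):
        axes.append(np.linspace(l, h, sizes[f]))
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m_.ravel() for m_ in mesh], axis=1)
    grid_nll = np.array([nll(p) for p in pts])
    order = np.argsort(grid_nll)
    starts = pts[order[:n_starts]]

    best = None
    for theta0 in starts:
        theta, f_val, g, iters, conv = _descend(nll, theta0, lo, hi, tol, max_iter)
        if best is None or f_val < best[1]:
            best = (theta, f_val, g, iters, conv)
    theta, f_val, g, iters, conv = best

    vals = dict(zip(free, np.exp(theta)))
    n = fix_n if fix_n is not None else vals["n"]
    params = LKBParameters(n=float(n), m=float(vals["m"]), td50=float(vals["td50"]))
    return FitResult(
        params=params,
        log_likelihood=-f_val,
        converged=bool(conv),
        iterations=int(iters),
        gradient=-g,  # gradient of the log-likelihood w.r.t. log-params
        extras={"grid_best_ll": float(-grid_nll[order[0]]), "outcome": outcome,
                "fixed_n": fix_n, "free": free},
    )


def _num_grad(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def _descend(f, x0, lo, hi, tol, max_iter):
    """Projected gradient descent with BB step lengths and Armijo backtracking."""
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = f(x)
    g = _num_grad(f, x)
    step = 1.0
    x_prev, g_prev = None, None
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            return x, fx, g, it, True
        if x_prev is not None:
            s, yv = x - x_prev, g - g_prev
            denom = float(np.dot(s, yv))
            step = float(np.dot(s, s)) / denom if denom > 1e-18 else 1.0
            step = float(np.clip(step, 1e-8, 1e4))
        # Armijo backtracking along -g with projection onto the box
        t = step
        accepted = False
        for _ in range(60):
            x_new = np.clip(x - t * g, lo, hi)
            d = x_new - x
            if np.max(np.abs(d)) < 1e-15:
                break
            f_new = f(x_new)
            if f_new <= fx + 1e-4 * float(np.dot(g, d)):
                accepted = True
                break
            t *= 0.5
        if not accepted:
            # stuck (flat or at a boundary): report gradient as-is
            return x, fx, g, it, bool(np.max(np.abs(g)) < tol)
        x_prev, g_prev = x, g
        x, fx = x_new, f_new
        g = _num_grad(f, x)
    return x, fx, g, max_iter, False


# --------------------------------------------------------------------------
# Logistic regression
# --------------------------------------------------------------------------

def _fit_logit_arrays(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> tuple:
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, method="newton", tol=1e-8, maxiter=200)
        except Exception as exc:  # singular Hessian under separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    for w in caught:
        if "erfectSeparation" in type(w.message).__name__ or "separat" in str(w.message).lower():
            raise SeparationError("perfect separation detected; coefficients diverge")
    if np.any(np.abs(res.params) > 50):
        raise SeparationError("diverging coefficients suggest (quasi-)separation")
    return res


def fit_logistic(cohort: Cohort, features: Sequence[str], outcome: str = "any") -> FitResult:
    """Binomial logistic regression of an endpoint on the named features."""
    cohort.require_fittable(outcome)
    X = cohort.feature_frame(features)
    for f in features:
        if X[f].nunique() <= 1:
            raise DegenerateDataError(f"feature {f!r} is constant")
    y = cohort.outcome_array(outcome).astype(float)
    res = _fit_logit_arrays(X.to_numpy(), y, features)
    params = np.asarray(res.params, dtype=float)
    model = LogisticModel(
        intercept=float(params[0]),
        coefficients={f: float(b) for f, b in zip(features, params[1:])},
        covariance=np.asarray(res.cov_params(), dtype=float),
    )
    return FitResult(
        params=model,
        log_likelihood=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        iterations=int(res.mle_retvals.get("iterations", 0)),
        extras={"pvalues": {f: float(p) for f, p in zip(["const", *features], res.pvalues)},
                "outcome": outcome},
    )


def _intercept_only_ll(y: np.ndarray) -> float:
    p = y.mean()
    return binary_log_likelihood(np.full_like(y, p, dtype=float), y)


def forward_stepwise(
    cohort: Cohort,
    candidates: Sequence[str],
    outcome: str = "any",
    alpha: float = 0.05,
) -> FitResult:
    """Forward stepwise logistic selection by likelihood-ratio test.

    Starting from the intercept-only model, repeatedly add the candidate with
    the largest LRT improvement whose p-value (chi-square, df = 1) is below
    ``alpha``; stop when none qualifies.  An empty candidate list returns the
    intercept-only model.
    """
    cohort.require_fittable(outcome)
    y = cohort.outcome_array(outcome).astype(float)
    selected: list[str] = []
    current_ll = _intercept_only_ll(y)
    current_fit: FitResult | None = None

    remaining = sorted(candidates)  # lexicographic tie-break baked into scan order
    while remaining:
        best_gain, best_feat, best_fit = 0.0, None, None
        for feat in remaining:
            try:
                fit = fit_logistic(cohort, [*selected, feat], outcome)
            except SeparationError:
                continue
            gain = fit.log_likelihood - current_ll
            if gain > best_gain + 1e-12:
                best_gain, best_feat, best_fit = gain, feat, fit
        if best_feat is None:
            break
        p = float(chi2.sf(2.0 * best_gain, df=1))
        if p >= alpha:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        current_ll, current_fit = best_fit.log_likelihood, best_fit

    if current_fit is None:
        p0 = y.mean()
        model = LogisticModel(intercept=float(np.log(p0 / (1 - p0))), coefficients={})
        current_fit = FitResult(
            params=model, log_likelihood=current_ll, converged=True, iterations=0
        )
    current_fit.selected_features = selected
    return current_fit
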