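"""Discrimination, calibration, and internal validation.

Covers the TRIPOD-style internal-validation toolkit used around the NTCP
fits: ROC AUC (midrank Mann-Whitney) with stratified bootstrap percentile
CIs, the univariate p < 0.10 screen, the pairwise Pearson R^2 > 0.70
collinearity screen, bootstrap optimism correction of the AUC, the
Hosmer-Lemeshow grouped calibration test, and model-vs-model agreement by
ordinary least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from .cohort import Cohort
from .errors import ContractError, DegenerateDataError, DomainError
from .fitting import FitResult, fit_logistic
from .models import coefficient_of_determination

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    auc: float
    auc_ci: tuple[float, float] | None = None
    adjusted_auc: float | None = None
    optimism: float | None = None
    hl_chi2: float | None = None
    hl_p: float | None = None
    hl_groups: int | None = None
    calibration_bins: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "adjusted_auc": self.adjusted_auc,
            "optimism": self.optimism,
            "hl_chi2": self.hl_chi2,
            "hl_p": self.hl_p,
            "hl_groups": self.hl_groups,
            "calibration_bins": self.calibration_bins,
        }


def _auc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("AUC needs both classes present")
    r = rankdata(scores)  # midranks: ties counted 1/2
    u = float(r[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def auc(
    scores: Sequence[float],
    labels: Sequence[int],
    ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """ROC AUC as the normalised Mann-Whitney U statistic (midrank ties).

    The optional 95% CI is a stratified bootstrap percentile interval
    (events and non-events resampled separately, ``n_boot`` replicates).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ContractError("scores and labels must have equal length")
    point = _auc_point(s, y)
    if not ci:
        return point, None
    rng = np.random.default_rng(seed)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        vals[b] = _auc_point(s[idx], y[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, (float(lo), float(hi))


def univariate_screen(
    cohort: Cohort,
    candidates: Sequence[str],
    outcome: str = "any",
    p_cut: float = 0.10,
) -> tuple[list[str], dict[str, float]]:
    """Single-predictor logistic Wald screen; retain features with p < p_cut."""
    pvals: dict[str, float] = {}
    for feat in candidates:
        fit = fit_logistic(cohort, [feat], outcome)
        pvals[feat] = fit.extras["pvalues"][feat]
    retained = [f for f in candidates if pvals[f] < p_cut]
    return retained, pvals


def collinearity_screen(
    cohort: Cohort,
    features: Sequence[str],
    r2_cut: float = 0.70,
) -> list[set[str]]:
    """Group features whose pairwise squared Pearson correlation exceeds
    ``r2_cut``, by transitive closure.  Constant features are excluded with a
    warning.  Returns only clusters of size >= 2."""
    if len(features) < 2:
        raise ContractError("collinearity screen needs >= 2 features")
    X = cohort.feature_frame(features)
    usable = []
    for f in features:
        if X[f].nunique() <= 1:
            warnings.warn(f"feature {f!r} is constant; excluded from collinearity screen")
        else:
            usable.append(f)
    parent = {f: f for f in usable}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    corr = X[usable].corr(method="pearson")
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            if corr.loc[a, b] ** 2 > r2_cut:
                parent[find(a)] = find(b)
    clusters: dict[str, set[str]] = {}
    for f in usable:
        clusters.setdefault(find(f), set()).add(f)
    return [c for c in clusters.values() if len(c) >= 2]


class ModelSpec(Protocol):
    """A refittable scoring recipe, the unit of bootstrap validation."""

    def fit(self, cohort: Cohort) -> object: ...
    def predict(self, fitted: object, cohort: Cohort) -> np.ndarray: ...


@dataclass
class LogisticSpec:
    """Logistic-regression recipe over named features for one endpoint."""

    features: Sequence[str]
    outcome: str = "any"

    def fit(self, cohort: Cohort) -> FitResult:
        return fit_logistic(cohort, list(self.features), self.outcome)

    def predict(self, fitted: FitResult, cohort: Cohort) -> np.ndarray:
        X = cohort.feature_frame(list(self.features)).to_numpy()
        model = fitted.params
        eta = model.intercept + X @ np.array(
            [model.coefficients[f] for f in self.features]
        )
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class FixedScoreSpec:
    """A spec with zero estimated parameters: scores via a fixed function."""

    score_fn: Callable[[Cohort], np.ndarray]
    outcome: str = "any"

    def fit(self, cohort: Cohort) -> object:
        return None

    def predict(self, fitted: object, cohort: Cohort) -> np.ndarray:
        return np.asarray(self.score_fn(cohort), dtype=float)


def bootstrap_optimism(
    cohort: Cohort,
    model_spec: ModelSpec,
    outcome: str = "any",
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 50,
) -> dict:
    """TRIPOD-style bootstrap optimism correction of the apparent AUC.

    For each of ``B`` resamples (with replacement, cohort size, not
    stratified): refit the recipe on the resample, and take
    optimism_b = AUC(resample scores) - AUC(original cohort scores under the
    resample fit).  adjusted = apparent - mean(optimism).  Resamples with a
    single outcome class (or a failed refit) are redrawn and logged.
    """
    y = cohort.outcome_array(outcome)
    fitted = model_spec.fit(cohort)
    apparent, _ = auc(model_spec.predict(fitted, cohort), y, ci=False)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    optimisms = np.empty(B)
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                boot = Cohort(
                    [_reindexed(cohort.patients[i], k) for k, i in enumerate(idx)],
                    metadata={"bootstrap_of": cohort.metadata.get("label", "")},
                )
                try:
                    fb = model_spec.fit(boot)
                except Exception:
                    logger.info("bootstrap refit failed (rep %d, attempt %d); redrawn", b, attempt)
                    continue
                auc_boot, _ = auc(model_spec.predict(fb, boot), yb, ci=False)
                auc_orig, _ = auc(model_spec.predict(fb, cohort), y, ci=False)
                optimisms[b] = auc_boot - auc_orig
                break
            logger.info("single-class resample (rep %d, attempt %d); redrawn", b, attempt)
        else:
            raise DegenerateDataError("could not draw a usable bootstrap resample")
    mean_opt = float(optimisms.mean())
    return {
        "apparent_auc": apparent,
        "mean_optimism": mean_opt,
        "adjusted_auc": apparent - mean_opt,
        "B": B,
    }


def _reindexed(p, k):
    from dataclasses import replace

    return replace(p, patient_id=f"{p.patient_id}~b{k}")


def hosmer_lemeshow(
    predictions: Sequence[float],
    outcomes: Sequence[int],
    g: int = 10,
    df: int | None = None,
) -> tuple[float, float, int]:
    """Hosmer-Lemeshow grouped calibration test.

    Patients are ranked by predicted probability into ``g`` near-equal groups
    (ties kept in one group); chi2 sums (obs - exp)^2 / exp over both outcome
    states in each group.  Groups with zero expected count in either state
    are merged with their neighbour (logged).  The p-value uses df = g_eff - 2
    by default (``df`` overrides, e.g. df = g for externally supplied
    probabilities that were not fitted to these data).

    Returns (chi2, p, groups_used).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ContractError("predictions and outcomes must have equal length")
    if g < 3:
        raise ContractError("need at least 3 groups")
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("predictions must lie strictly in (0, 1)")
    order = np.argsort(p, kind="mergesort")
    ps, ys = p[order], y[order]
    n = p.size
    # near-equal group boundaries, pushed forward so equal predictions stay together
    bounds = [int(round(i * n / g)) for i in range(1, g)]
    adj = []
    for b in bounds:
        while 0 < b < n and ps[b] == ps[b - 1]:
            b += 1
        if adj and b <= adj[-1]:
            continue
        if b < n:
            adj.append(b)
    groups = np.split(np.arange(n), adj)
    tables = []
    for idx in groups:
        e1 = float(ps[idx].sum())
        tables.append([float(ys[idx].sum()), e1, float(idx.size)])
    # merge groups whose expected count in either state is ~0
    merged = [tables[0]]
    for o1, e1, cnt in tables[1:]:
        if min(merged[-1][1], merged[-1][2] - merged[-1][1]) < 1e-9:
            merged[-1] = [merged[-1][0] + o1, merged[-1][1] + e1, merged[-1][2] + cnt]
            logger.info("merged a Hosmer-Lemeshow group with zero expected count")
        else:
            merged.append([o1, e1, cnt])
    if min(merged[-1][1], merged[-1][2] - merged[-1][1]) < 1e-9 and len(merged) > 1:
        o1, e1, cnt = merged.pop()
        merged[-1] = [merged[-1][0] + o1, merged[-1][1] + e1, merged[-1][2] + cnt]
        logger.info("merged a Hosmer-Lemeshow group with zero expected count")
    g_eff = len(merged)
    stat = 0.0
    for o1, e1, cnt in merged:
        e0 = cnt - e1
        stat += (o1 - e1) ** 2 / e1 + ((cnt - o1) - e0) ** 2 / e0
    dof = (g_eff - 2) if df is None else df
    pval = float(chi2.sf(stat, dof)) if dof > 0 else float("nan")
    return float(stat), pval, g_eff


def calibration_bins(
    predictions: Sequence[float], outcomes: Sequence[int], g: int = 10
) -> list[dict]:
    """Per-risk-group (mean predicted, observed rate, count) summaries."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    order = np.argsort(p, kind="mergesort")
    out = []
    for idx in np.array_split(order, g):
        if idx.size == 0:
            continue
        out.append(
            {
                "mean_predicted": float(p[idx].mean()),
                "observed_rate": float(y[idx].mean()),
                "count": int(idx.size),
            }
        )
    return out


def compare_models(preds_a: Sequence[float], preds_b: Sequence[float]) -> tuple[float, float, float]:
    """OLS agreement of model B's predictions on model A's: (slope, intercept, R^2)."""
    a = np.asarray(preds_a, dtype=float)
    b = np.asarray(preds_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ContractError("need equal-length prediction vectors of length >= 3")
    if np.ptp(a) == 0:
        raise DomainError("zero variance in preds_a")
    slope, intercept = np.polyfit(a, b, 1)
    r2 = coefficient_of_determination(b, slope * a + intercept)
    return float(slope), float(intercept), float(r2)


def validate_predictions(
    scores: np.ndarray,
    outcomes: np.ndarray,
    hl_groups: int = 10,
    hl_df: int | None = None,
    seed: int = 0,
    n_boot_ci: int = 2000,
) -> ValidationReport:
    """Assemble discrimination + calibration into a :class:`ValidationReport`."""
    point, ci = auc(scores, outcomes, ci=True, n_boot=n_boot_ci, seed=seed)
    in_unit = np.all((scores > 0) & (scores < 1))
    if in_unit:
        stat, pval, g_eff = hosmer_lemeshow(scores, outcomes, g=hl_groups, df=hl_df)
        bins = calibration_bins(scores, outcomes, g=hl_groups)
    else:  # raw scores (e.g. dose) support discrimination only
        stat = pval = None
        g_eff = None
        bins = []
    return ValidationReport(
        auc=point, auc_ci=ci, hl_chi2=stat, hl_p=pval, hl_groups=g_eff,
        calibration_bins=bins,
    )
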