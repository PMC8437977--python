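"""Pipeline orchestration and publication-style table rendering.

``run_pipeline`` wires the full analysis in the order the study design
prescribes: univariate screen -> collinearity screen -> forward-stepwise
logistic fit -> MHD-based probit fit (and full LKB fit when DVHs are
available) -> internal validation (bootstrap-optimism-adjusted AUC,
Hosmer-Lemeshow) -> TD/NTCP summary tables.  Every artefact is written as
JSON next to a Markdown report; the seed and configuration are echoed so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .errors import ConfigurationError, NtcpError
from .fitting import DEFAULT_SEED, fit_lkb, forward_stepwise
from .models import (
    LKBParameters,
    LogisticModel,
    NOT_ACHIEVED,
    invert_td,
    logistic_ntcp,
    probit_ntcp,
    save_model,
)
from .synthetic import SyntheticConfig, generate_cohort
from .validation import (
    LogisticSpec,
    bootstrap_optimism,
    collinearity_screen,
    univariate_screen,
    validate_predictions,
)

logger = logging.getLogger(__name__)

LOW_B_WARNING = 50

#: Reporting conventions: probabilities to 2 decimals, tolerance doses to 1.
NTCP_DECIMALS = 2
TD_DECIMALS = 1

DEFAULT_DOSE_GRID = (10.0, 20.0, 30.0, 40.0, 50.0)
DEFAULT_TD_LEVELS = (0.05, 0.10, 0.25, 0.50)


@dataclass
class AnalysisConfig:
    """Thresholds and knobs of the full pipeline (defaults = study design)."""

    cohort_csv: str | None = None  # None -> simulate a cohort
    outcomes: tuple[str, ...] = ("any", "symptomatic")
    candidate_features: tuple[str, ...] = ("mhd", "hypertension")
    univariate_p: float = 0.10
    stepwise_alpha: float = 0.05
    collinearity_r2: float = 0.70
    bootstrap_B: int = 1000
    hl_groups: int = 10
    seed: int = DEFAULT_SEED
    out_dir: str = "ntcp_report"
    fit_lkb_models: bool = True
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    td_levels: tuple[float, ...] = DEFAULT_TD_LEVELS

    def __post_init__(self) -> None:
        for name in ("univariate_p", "stepwise_alpha", "collinearity_r2"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.bootstrap_B < 1:
            raise ConfigurationError("bootstrap_B must be >= 1")
        if self.hl_groups < 3:
            raise ConfigurationError("hl_groups must be >= 3")
        for o in self.outcomes:
            if o not in ("any", "symptomatic"):
                raise ConfigurationError(f"unknown outcome {o!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outcomes", "candidate_features", "dose_grid", "td_levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _fmt_td(value: float | None) -> str:
    return "-" if value is NOT_ACHIEVED else f"{value:.{TD_DECIMALS}f}"


def _model_probability(model, dose: float, profile: Mapping[str, float] | None) -> float:
    if isinstance(model, LKBParameters):
        return probit_ntcp(dose, model)
    feats = {"mhd": dose, **(profile or {})}
    return logistic_ntcp(feats, model)


def render_td_ntcp_table(
    models: Mapping[str, LKBParameters | LogisticModel],
    doses: Sequence[float] = DEFAULT_DOSE_GRID,
    probabilities: Sequence[float] = DEFAULT_TD_LEVELS,
    profiles: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """TD_x / NTCP summary grid over the given models.

    Rows are TD levels then dose points; columns are model labels.  TD cells
    use the closed-form inversion (a dash marks a level the model never
    reaches at positive dose); NTCP cells evaluate the forward model.
    ``profiles`` supplies covariate values per model label for multivariable
    logistic models.  An empty ``probabilities`` list omits the TD section.
    """
    if not models or len(doses) == 0:
        raise ConfigurationError("need at least one model and a non-empty dose grid")
    rows = []
    for x in probabilities:
        row = {"quantity": f"TD {int(round(100 * x))}%"}
        for label, model in models.items():
            prof = (profiles or {}).get(label)
            row[label] = _fmt_td(invert_td(model, x, profile=prof))
        rows.append(row)
    for d in doses:
        row = {"quantity": f"NTCP {d:g} Gy"}
        for label, model in models.items():
            prof = (profiles or {}).get(label)
            row[label] = f"{_model_probability(model, d, prof):.{NTCP_DECIMALS}f}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("quantity")


def _df_to_markdown(df: pd.DataFrame) -> str:
    cols = [df.index.name or ""] + list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "|" + "|".join(["---"] * len(cols)) + "|"]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |")
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of in-memory results keyed by stage; artefacts land in
    ``config.out_dir``.  Idempotent given identical inputs, config, and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # config echo omits the output location so identical analyses written to
    # different directories produce byte-identical bundles
    cfg_echo = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    bundle: dict = {"config": cfg_echo}

    if config.bootstrap_B < LOW_B_WARNING:
        warnings.warn(
            f"bootstrap_B = {config.bootstrap_B} is low; optimism estimates will be noisy"
        )
        bundle["warnings"] = [f"low bootstrap_B ({config.bootstrap_B})"]

    stage = "load-cohort"
    try:
        if config.cohort_csv is None:
            cohort = generate_cohort(SyntheticConfig(seed=config.seed))
        else:
            cohort = Cohort.from_csv(config.cohort_csv)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path)
        logger.info("stage=%s n=%d sha=%s", stage, len(cohort), _sha256(cohort_path))

        results: dict = {}
        for outcome in config.outcomes:
            stage = f"screen[{outcome}]"
            retained, pvals = univariate_screen(
                cohort, list(config.candidate_features), outcome, config.univariate_p
            )
            clusters = (
                collinearity_screen(cohort, list(config.candidate_features), config.collinearity_r2)
                if len(config.candidate_features) >= 2
                else []
            )
            logger.info("stage=%s retained=%s clusters=%s", stage, retained, clusters)

            stage = f"stepwise[{outcome}]"
            step = forward_stepwise(cohort, retained, outcome, config.stepwise_alpha)
            logistic_model = step.params

            stage = f"probit[{outcome}]"
            mhd_fit = fit_lkb(cohort, outcome, fix_n=1.0, seed=config.seed)
            lkb_fit = None
            if config.fit_lkb_models and cohort.has_dvhs:
                lkb_fit = fit_lkb(cohort, outcome, seed=config.seed)

            stage = f"validate[{outcome}]"
            y = cohort.outcome_array(outcome)
            spec_features = step.selected_features or ["mhd"]
            spec = LogisticSpec(spec_features, outcome)
            fitted = spec.fit(cohort)
            preds = spec.predict(fitted, cohort)
            report = validate_predictions(
                preds, y, hl_groups=config.hl_groups, seed=config.seed
            )
            opt = bootstrap_optimism(
                cohort, spec, outcome, B=config.bootstrap_B, seed=config.seed
            )
            report.adjusted_auc = opt["adjusted_auc"]
            report.optimism = opt["mean_optimism"]

            results[outcome] = {
                "screen": {"retained": retained, "pvalues": pvals,
                           "collinear_clusters": [sorted(c) for c in clusters]},
                "stepwise": {
                    "selected": step.selected_features,
                    "log_likelihood": step.log_likelihood,
                    "intercept": logistic_model.intercept,
                    "coefficients": logistic_model.coefficients,
                    "odds_ratios": logistic_model.odds_ratios(),
                },
                "mhd_probit": {
                    "m": mhd_fit.params.m, "td50": mhd_fit.params.td50,
                    "log_likelihood": mhd_fit.log_likelihood,
                    "converged": mhd_fit.converged,
                },
                "lkb": None if lkb_fit is None else {
                    "n": lkb_fit.params.n, "m": lkb_fit.params.m,
                    "td50": lkb_fit.params.td50,
                    "log_likelihood": lkb_fit.log_likelihood,
                    "converged": lkb_fit.converged,
                },
                "validation": report.to_dict(),
            }

            save_model(logistic_model, out / f"logistic_{outcome}.json")
            save_model(mhd_fit.params, out / f"mhd_probit_{outcome}.json")
            if lkb_fit is not None:
                save_model(lkb_fit.params, out / f"lkb_{outcome}.json")

            stage = f"tables[{outcome}]"
            models = {"MHD probit": mhd_fit.params}
            profiles = {}
            if lkb_fit is not None:
                models["LKB"] = lkb_fit.params
            if logistic_model.coefficients.get("mhd"):
                models["logistic"] = logistic_model
                others = [f for f in logistic_model.features if f != "mhd"]
                if others:
                    profiles["logistic"] = {f: 0.0 for f in others}
            table = render_td_ntcp_table(
                models, config.dose_grid, config.td_levels, profiles=profiles
            )
            results[outcome]["td_ntcp_table"] = table.to_dict()
            results[outcome]["_table_md"] = _df_to_markdown(table)
    except NtcpError as exc:
        (out / "results.json").write_text(
            json.dumps({"failed_stage": stage, "error": str(exc), **_jsonable(bundle)},
                       indent=2, sort_keys=True) + "\n"
        )
        raise NtcpError(f"pipeline failed at stage {stage}: {exc}") from exc

    bundle["results"] = results
    bundle["cohort_sha"] = _sha256(out / "cohort.csv")
    (out / "results.json").write_text(
        json.dumps(_jsonable(bundle), indent=2, sort_keys=True) + "\n"
    )

    md = ["# NTCP report", "",
          f"seed: {config.seed}; n = {len(cohort)}; cohort sha: {bundle['cohort_sha']}", ""]
    for outcome, res in results.items():
        md.append(f"## Endpoint: {outcome}")
        md.append("")
        md.append(f"selected features: {res['stepwise']['selected']}")
        v = res["validation"]
        md.append(
            f"AUC {v['auc']:.3f}"
            + (f" [{v['auc_ci'][0]:.2f}-{v['auc_ci'][1]:.2f}]" if v["auc_ci"] else "")
            + (f", adjusted {v['adjusted_auc']:.3f}" if v["adjusted_auc"] is not None else "")
            + (f"; HL chi2 {v['hl_chi2']:.2f}, p {v['hl_p']:.2f}" if v["hl_chi2"] is not None else "")
        )
        md.append("")
        md.append(res["_table_md"])
        md.append("")
        md.append("TD cells marked '-' are not achieved (solution at or below 0 Gy).")
        md.append("")
    (out / "report.md").write_text("\n".join(md))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
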