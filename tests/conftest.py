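import numpy as np
import pytest

from ntcp_pce import Cohort, DoseVolumeHistogram, PatientRecord


@pytest.fixture
def hand_dvh():
    """Three-bin DVH: volumes (0.2, 0.3, 0.5) at midpoints (5, 15, 25) Gy."""
    return DoseVolumeHistogram(
        "heart", np.array([0.0, 10.0, 20.0, 30.0]), np.array([0.2, 0.3, 0.5])
    )


@pytest.fixture
def uniform_dvh():
    """All volume in the 0.1 Gy bin centred at 20 Gy."""
    return DoseVolumeHistogram("heart", np.array([19.95, 20.05]), np.array([1.0]))


def make_cohort(features: dict, y_any, y_sym=None, mhd=None) -> Cohort:
    """Assemble a cohort from raw arrays; features become covariates
    (hypertension added if absent), ``mhd`` defaults to zeros unless given
    or present in features."""
    n = len(y_any)
    y_sym = np.zeros(n, dtype=int) if y_sym is None else np.asarray(y_sym)
    if mhd is None:
        mhd = features.get("mhd", np.zeros(n))
    covs = {k: np.asarray(v, dtype=float) for k, v in features.items() if k != "mhd"}
    if "hypertension" not in covs:
        covs["hypertension"] = np.zeros(n)
    patients = [
        PatientRecord(
            patient_id=f"T{i:05d}",
            mhd=float(mhd[i]),
            outcome_any_grade=int(y_any[i]),
            outcome_symptomatic=int(y_sym[i]),
            covariates={k: float(v[i]) for k, v in covs.items()},
        )
        for i in range(n)
    ]
    return Cohort(patients)


@pytest.fixture
def small_logistic_cohort():
    """200 patients, outcome driven by a single continuous dose covariate."""
    rng = np.random.default_rng(42)
    mhd = rng.uniform(1, 60, size=200)
    p = 1 / (1 + np.exp(-(0.08 * mhd - 2.5)))
    y = (rng.uniform(size=200) < p).astype(int)
    return make_cohort({"mhd": mhd}, y, mhd=mhd)
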