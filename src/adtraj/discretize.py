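"""GAF imputation and binarization of trajectories into the analysis case table.

The downstream network learner handles discrete variables only, so every
predictor and outcome is cut to a binary indicator: age at 48 and GAF at 50
(reference-cohort medians), trajectory duration at 35 days (five weeks, the
minimum for an expected clinical effect) and sentiment means at >= 0.  Ties
land in the upper class.  Missing GAF scores are filled first by single
predictive-mean-matching imputation so the case table is complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sentiment import THEMES
from .trajectories import (AD_CLASSES, CO_MED_CLASSES, EFFECTIVE_DURATION_DAYS,
                           TreatmentTrajectory)

DX_FLAGS: tuple[str, ...] = ("dx_depression", "dx_personality", "dx_anxiety",
                             "dx_social")

#: fixed column order of the binary case table (one row per trajectory)
CASE_COLUMNS: tuple[str, ...] = (
    "sex_female", "age_ge_48",
    *(f"ad_{c}" for c in AD_CLASSES),
    *CO_MED_CLASSES,
    *DX_FLAGS,
    "gaf_ge_50", "duration_ge_5w", "continued",
    *(f"sent_{t}" for t in THEMES),
)


@dataclass(frozen=True)
class Thresholds:
    """Binarization cut points; defaults are the reference-cohort medians
    (age 48, GAF 50) and the five-week effective-duration rule."""

    age: float = 48.0
    gaf: float = 50.0
    duration_days: int = EFFECTIVE_DURATION_DAYS
    sentiment: float = 0.0


def _covariate_matrix(trajectories: Sequence[TreatmentTrajectory]) -> np.ndarray:
    rows = []
    for t in trajectories:
        rows.append([
            1.0,
            float(t.sex_female),
            float(t.age),
            *(1.0 if t.ad_class == c else 0.0 for c in AD_CLASSES[:-1]),
            *(float(t.co_medication.get(c, False)) for c in CO_MED_CLASSES),
            *(float(t.dx.get(d, False)) for d in DX_FLAGS),
            float(t.duration_days),
            float(bool(t.continued)),
            *(float(t.sentiment_means.get(th, 0.0)) for th in THEMES),
        ])
    return np.asarray(rows, dtype=float)


def impute_gaf(trajectories: Sequence[TreatmentTrajectory], seed: int = 0,
               donor_pool: int = 5) -> list[TreatmentTrajectory]:
    """Single predictive-mean-matching imputation of missing GAF scores.

    GAF is regressed on the complete covariates over observed rows (ordinary
    least squares); each missing row then receives the *observed* GAF of one
    of its ``donor_pool`` nearest neighbours in predicted mean, drawn with the
    seeded generator.  Observed values are never touched, and every imputed
    value is a member of the observed GAF set.
    """
    observed = [t for t in trajectories if t.gaf is not None]
    missing = [t for t in trajectories if t.gaf is None]
    if not observed:
        raise ValueError("cannot impute: all GAF values are missing")
    if not missing:
        return list(trajectories)

    rng = np.random.default_rng(seed)
    x_obs = _covariate_matrix(observed)
    y_obs = np.array([t.gaf for t in observed], dtype=float)
    beta, *_ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    pred_obs = x_obs @ beta
    pred_mis = _covariate_matrix(missing) @ beta

    k = min(donor_pool, len(observed))
    for t, pm in zip(missing, pred_mis):
        nearest = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
        donor = int(rng.choice(nearest))
        t.gaf = float(y_obs[donor])
        t.gaf_imputed = True
    return list(trajectories)


def binarize(trajectories: Sequence[TreatmentTrajectory],
             thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Cut every trajectory variable to {0, 1} and return the case table.

    Requires complete GAF (run :func:`impute_gaf` first).  Deterministic, and
    idempotent on the already-binary flags, which pass through unchanged.
    """
    rows = []
    for t in trajectories:
        if t.gaf is None:
            raise ValueError(f"{t.patient_id}: GAF missing; impute first")
        if t.continued is None:
            raise ValueError(f"{t.patient_id}: outcomes not derived")
        row = {
            "sex_female": int(bool(t.sex_female)),
            "age_ge_48": int(t.age >= thresholds.age),
            **{f"ad_{c}": int(t.ad_class == c) for c in AD_CLASSES},
            **{c: int(t.co_medication.get(c, False)) for c in CO_MED_CLASSES},
            **{d: int(t.dx.get(d, False)) for d in DX_FLAGS},
            "gaf_ge_50": int(t.gaf >= thresholds.gaf),
            "duration_ge_5w": int(t.duration_days >= thresholds.duration_days),
            "continued": int(bool(t.continued)),
            **{f"sent_{th}": int(t.sentiment_means.get(th, 0.0) >= thresholds.sentiment)
               for th in THEMES},
        }
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(CASE_COLUMNS), dtype=np.int8)
    assert table.isin([0, 1]).all().all(), "non-binary residue in case table"
    return table
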