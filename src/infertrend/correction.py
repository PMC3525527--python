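"""Regression correction of biased prevalence estimates.

Surveys that collect only current contraceptive status (or only time since
first union) overstate infertility prevalence.  A log-linear regression fit
on surveys with complete histories maps the biased estimate to a less-biased
one:

    ln(unbiased) ~ 1 + biased + age_midpoint [+ contraceptive_prev]

where the contraceptive-use regressor enters for secondary infertility only.
Prediction uncertainty (coefficient covariance + residual variance) is
propagated to the logit analysis scale by the delta method and carried on
the corrected observation.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import PREVALENCE_INDICATORS
from .extraction import PrevalenceObservation, compute_observation
from .simulate import SurveyDataset

__all__ = [
    "CorrectionModel",
    "fit_correction",
    "apply_correction",
    "make_correction_pairs",
]

logger = logging.getLogger(__name__)

_REGRESSORS = {
    "primary_prev": ("const", "biased", "age_mid"),
    "secondary_prev": ("const", "biased", "age_mid", "contraceptive_prev"),
}

#: Corrected prevalences at or above this are clipped (with a warning).
_CLIP = 0.99


@dataclass
class CorrectionModel:
    indicator: str
    coefficients: dict[str, float]
    residual_variance: float
    coefficient_covariance: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")
        cov = np.asarray(self.coefficient_covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("coefficient_covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError("coefficient_covariance must be positive semidefinite")
        self.coefficient_covariance = cov

    @property
    def regressors(self) -> tuple[str, ...]:
        return _REGRESSORS[self.indicator]

    def to_yaml(self, path) -> None:
        payload = {
            "indicator": self.indicator,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "residual_variance": float(self.residual_variance),
            "coefficient_covariance": self.coefficient_covariance.tolist(),
            "n_pairs": int(self.n_pairs),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            indicator=payload["indicator"],
            coefficients=payload["coefficients"],
            residual_variance=payload["residual_variance"],
            coefficient_covariance=np.asarray(payload["coefficient_covariance"]),
            n_pairs=payload["n_pairs"],
        )


def fit_correction(pairs: pd.DataFrame, indicator: str) -> CorrectionModel:
    """Ordinary least squares of ln(unbiased) on the indicator's regressors.

    ``pairs`` needs columns ``biased``, ``unbiased``, ``age_mid`` and, for
    secondary infertility, ``contraceptive_prev``.  Unbiased values must be
    positive (continuity-correct zeros upstream).
    """
    if indicator not in PREVALENCE_INDICATORS:
        raise ValueError(f"correction applies to prevalence indicators, not {indicator!r}")
    names = _REGRESSORS[indicator]
    for col in names[1:] + ("unbiased",):
        if col not in pairs.columns:
            raise ValueError(f"{indicator} correction requires column {col!r}")
    data = pairs.dropna(subset=list(names[1:]) + ["unbiased"])
    p = len(names)
    if len(data) < p + 2:
        raise ValueError(f"need at least {p + 2} pairs, got {len(data)}")
    if (data["unbiased"] <= 0).any():
        raise ValueError("unbiased values must be > 0 (continuity-correct zeros first)")

    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in names[1:]])
    y = np.log(data["unbiased"].to_numpy(float))

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    dof = max(len(data) - p, 1)
    resid_var = float(fit.ssr / dof)
    return CorrectionModel(
        indicator=indicator,
        coefficients=dict(zip(names, (float(b) for b in fit.params))),
        residual_variance=resid_var,
        coefficient_covariance=np.asarray(fit.cov_params()),
        n_pairs=len(data),
    )


def apply_correction(
    obs: PrevalenceObservation, model: CorrectionModel
) -> PrevalenceObservation:
    """Replace a biased observation's value by the regression prediction.

    Unbiased observations pass through unchanged.  The corrected observation
    carries the prediction variance (x'Vx + residual variance, mapped from
    the log to the logit scale by the delta method) in
    ``correction_variance``; the sampling variance is added later on the
    analysis scale, so total variance never decreases under correction.
    """
    if obs.indicator != model.indicator:
        raise ValueError(
            f"observation indicator {obs.indicator!r} does not match model {model.indicator!r}"
        )
    if not obs.is_biased:
        return obs

    x_parts = {"const": 1.0, "biased": obs.value, "age_mid": sum(obs.age_group) / 2.0}
    if "contraceptive_prev" in model.regressors:
        if obs.contraceptive_prev is None or np.isnan(obs.contraceptive_prev):
            raise ValueError("secondary correction needs contraceptive_prev on the observation")
        x_parts["contraceptive_prev"] = obs.contraceptive_prev
    x = np.array([x_parts[name] for name in model.regressors])
    beta = np.array([model.coefficients[name] for name in model.regressors])

    log_pred = float(x @ beta)
    var_log = float(x @ model.coefficient_covariance @ x) + model.residual_variance
    corrected = float(np.exp(log_pred))
    if corrected >= _CLIP:
        warnings.warn(
            f"corrected prevalence {corrected:.3f} clipped to {_CLIP} "
            f"({obs.indicator}, {obs.country_id}, {obs.survey_year}, {obs.age_group})",
            stacklevel=2,
        )
        logger.warning("clipped corrected prevalence %.4f", corrected)
        corrected = _CLIP

    # delta method: d logit(p) / d ln(p) = 1 / (1 - p)
    var_logit = var_log / (1.0 - corrected) ** 2

    out = copy.copy(obs)
    out.value = corrected
    out.correction_variance = obs.correction_variance + var_logit
    return out


def make_correction_pairs(
    datasets: list[SurveyDataset],
    indicator: str,
    continuity: bool = True,
) -> pd.DataFrame:
    """Build (biased, unbiased) estimate pairs from full-history surveys.

    Each survey x age group contributes one pair: the unbiased estimate uses
    the collected histories, the biased one reruns classification on the
    current-status / first-union path.  Zero prevalences are continuity-
    corrected by 0.5/denominator so the log is defined.
    """
    from .constants import AGE_GROUPS

    rows = []
    for ds in datasets:
        if not (ds.has_contraceptive_history and ds.has_current_union_duration):
            continue  # cannot supply the unbiased member of the pair
        for age_group in AGE_GROUPS:
            unbiased = compute_observation(ds, indicator, age_group, use_full_history=True)
            biased = compute_observation(ds, indicator, age_group, use_full_history=False)
            if unbiased is None or biased is None:
                continue
            u, b = unbiased.value, biased.value
            if continuity:
                if u == 0.0:
                    u = 0.5 / unbiased.raw_denominator
                if b == 0.0:
                    b = 0.5 / biased.raw_denominator
            rows.append(
                {
                    "country": ds.country_id,
                    "year": ds.survey_year,
                    "age_mid": sum(age_group) / 2.0,
                    "biased": b,
                    "unbiased": u,
                    "contraceptive_prev": unbiased.contraceptive_prev,
                }
            )
    return pd.DataFrame(rows)
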