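"""Country-withholding cross-validation of the hierarchical model.

The model is refit several times, each time dropping all data from a random
sample of 20% of the countries that have data, and the withheld observations
are compared with the refit model's predictions: RMSE in percentage points,
median relative error (pred - obs) / obs, and the share of withheld values
inside the 95% posterior-predictive interval (which includes each withheld
observation's own sampling variance and the sampled extra-variance
component).
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .model import ModelInput, ModelSpec, Posterior, fit_model, _expit

__all__ = ["CVReport", "run_cv"]


@dataclass
class CVReport:
    indicator: str
    rmse_pp: float
    median_relative_error: float
    coverage_95: float
    folds: pd.DataFrame  # one row per withheld observation

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_95 <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.rmse_pp < 0:
            raise ValueError("RMSE must be >= 0")


def _predict_withheld(post: Posterior, obs: ModelInput, rng) -> dict:
    """Posterior-predictive summary for one withheld observation."""
    mu = post._mu(obs.country_id, obs.year, obs.age_group)
    sigma = np.where(
        obs.is_national,
        post.draws["sigma_national"],
        post.draws["sigma_subnational"],
    )
    noise = rng.standard_normal(mu.size) * np.sqrt(obs.variance + sigma**2)
    p_rep = _expit(mu + noise)
    lo, hi = np.percentile(p_rep, [2.5, 97.5])
    pred = float(_expit(mu).mean())
    observed = float(_expit(obs.y))
    return {
        "country": obs.country_id,
        "year": obs.year,
        "age_lo": obs.age_group[0],
        "observed": observed,
        "predicted": pred,
        "pred_lower": float(lo),
        "pred_upper": float(hi),
        "covered": bool(lo <= observed <= hi),
        "error": pred - observed,
        "relative_error": (pred - observed) / observed if observed else np.nan,
    }


def run_cv(
    inputs: list[ModelInput],
    spec: ModelSpec,
    indicator: str,
    n_folds: int = 5,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    mode: str = "random",
    **fit_kwargs,
) -> CVReport:
    """Fit the model ``n_folds`` times, each withholding a sample of
    countries, and pool the predictive metrics.

    ``mode='random'`` draws an independent ``holdout_fraction`` sample of
    data countries each fold (the default); ``mode='partition'`` rotates
    through a disjoint partition instead.
    """
    countries = sorted({o.country_id for o in inputs})
    n_hold = max(1, int(round(holdout_fraction * len(countries))))
    if n_hold >= len(countries):
        raise ValueError("holdout would remove every country with data")

    rng = np.random.default_rng(seed)
    if mode == "random":
        folds = [
            set(rng.choice(countries, size=n_hold, replace=False))
            for _ in range(n_folds)
        ]
    elif mode == "partition":
        perm = list(rng.permutation(countries))
        folds = [set(perm[i::n_folds]) for i in range(n_folds)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    h = spec.hierarchy
    rows = []
    for fold_id, held in enumerate(folds):
        train = [o for o in inputs if o.country_id not in held]
        test = [o for o in inputs if o.country_id in held]
        train_regions = {h.region_of(o.country_id) for o in train}
        emptied = {h.region_of(c) for c in held} - train_regions
        if emptied:
            warn(
                f"fold {fold_id}: holdout empties region(s) {sorted(emptied)}; "
                "the hierarchy covers the gap",
                stacklevel=2,
            )
        post = fit_model(
            train,
            spec,
            indicator,
            seed=seed + 1000 * (fold_id + 1),
            **fit_kwargs,
        )
        pred_rng = np.random.default_rng(seed + 5000 + fold_id)
        for obs in test:
            row = _predict_withheld(post, obs, pred_rng)
            row["fold"] = fold_id
            rows.append(row)

    detail = pd.DataFrame(rows)
    if detail.empty:
        raise RuntimeError("cross-validation produced no withheld observations")
    rmse_pp = float(np.sqrt(np.mean(detail["error"] ** 2)) * 100.0)
    med_rel = float(np.nanmedian(detail["relative_error"]))
    coverage = float(detail["covered"].mean())
    return CVReport(
        indicator=indicator,
        rmse_pp=rmse_pp,
        median_relative_error=med_rel,
        coverage_95=coverage,
        folds=detail,
    )
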