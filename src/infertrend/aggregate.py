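"""Posterior-draw arithmetic: all-women percentages, population-weighted
aggregates, uncertainty summaries, trends with posterior probabilities, and
couples-affected counts.

All operations act draw-by-draw; summarisation (mean, 2.5th-97.5th
percentiles with linear interpolation between order statistics) happens
last.  Ties in the trend direction count as non-increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AggregateEstimate",
    "all_women_percent",
    "aggregate_weighted",
    "summarize_draws",
    "compute_trend",
    "couples_affected",
    "SIGNIFICANCE_PP",
]

#: posterior-probability bar above which a trend is called significant
SIGNIFICANCE_PP = 0.975


@dataclass(frozen=True)
class AggregateEstimate:
    quantity: str
    mean: float
    lower_95: float
    upper_95: float
    scope: str = ""
    pp_increase: float | None = None

    def __post_init__(self) -> None:
        if not (self.lower_95 - 1e-12 <= self.mean <= self.upper_95 + 1e-12):
            raise ValueError("mean must lie inside the 95% interval")
        if self.pp_increase is not None and not 0.0 <= self.pp_increase <= 1.0:
            raise ValueError("pp_increase must be in [0, 1]")

    @property
    def significant(self) -> bool | None:
        """Trend significance: pp of the estimated direction > 0.975."""
        if self.pp_increase is None:
            return None
        return (
            self.pp_increase > SIGNIFICANCE_PP
            or (1.0 - self.pp_increase) > SIGNIFICANCE_PP
        )


def _check_draws(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("draws must be a non-empty 1-d vector")
    return arr


def all_women_percent(prev_draws, exposure_draws) -> np.ndarray:
    """Per-draw product of child-seeking prevalence and exposed proportion."""
    p = _check_draws(prev_draws)
    e = _check_draws(exposure_draws)
    if p.shape != e.shape:
        raise ValueError(f"mismatched draw lengths: {p.shape} vs {e.shape}")
    return p * e


def aggregate_weighted(draws_by_cell, weights) -> np.ndarray:
    """Population-weighted mean across cells, within each draw.

    ``draws_by_cell`` has shape (n_draws, n_cells); ``weights`` length
    n_cells, non-negative, not all zero.  Cells excluded from an aggregate
    (e.g. China for secondary infertility) are simply not passed in.
    """
    arr = np.asarray(draws_by_cell, dtype=float)
    w = np.asarray(weights, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != w.size:
        raise ValueError("draws_by_cell must be (n_draws, n_cells) matching weights")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return arr @ (w / total)


def summarize_draws(draws, quantity: str = "", scope: str = "") -> AggregateEstimate:
    """Mean and 2.5th-97.5th percentile interval of a draw vector."""
    arr = _check_draws(draws)
    if arr.size < 2:
        raise ValueError("need at least 2 draws to summarise")
    lo, hi = np.percentile(arr, [2.5, 97.5])  # linear order-statistic interpolation
    return AggregateEstimate(
        quantity=quantity,
        mean=float(arr.mean()),
        lower_95=float(lo),
        upper_95=float(hi),
        scope=scope,
    )


def compute_trend(draws_start, draws_end, quantity: str = "", scope: str = "") -> AggregateEstimate:
    """Per-draw difference end - start, with pp of an increase.

    ``pp_increase`` is the fraction of draws with a strictly positive
    difference, so tied draws count toward non-increase.
    """
    a = _check_draws(draws_start)
    b = _check_draws(draws_end)
    if a.shape != b.shape:
        raise ValueError(f"mismatched draw lengths: {a.shape} vs {b.shape}")
    diff = b - a
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return AggregateEstimate(
        quantity=quantity,
        mean=float(diff.mean()),
        lower_95=float(lo),
        upper_95=float(hi),
        scope=scope,
        pp_increase=float(np.mean(diff > 0)),
    )


def couples_affected(all_women_draws_by_cell, population) -> np.ndarray:
    """Per-draw number of couples affected: sum over cells of
    fraction-affected x women in the cell.

    ``all_women_draws_by_cell``: (n_draws, n_cells) fractions in [0, 1];
    ``population``: women aged 20-44 per cell.  Returns the per-draw count
    vector; summarise with :func:`summarize_draws`.  Regional vectors sum to
    the global vector exactly because the operation is linear in the cells.
    """
    arr = np.asarray(all_women_draws_by_cell, dtype=float)
    pop = np.asarray(population, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != pop.size:
        raise ValueError("draws must be (n_draws, n_cells) matching population")
    if np.isnan(pop).any():
        raise ValueError("population contains missing cells")
    if (pop < 0).any():
        raise ValueError("population must be non-negative")
    return arr @ pop


# ---------------------------------------------------------------------------
# Report tables (Dataset S1/S2-like layouts)
# ---------------------------------------------------------------------------

def estimates_table(rows: list[AggregateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quantity": e.quantity,
                "scope": e.scope,
                "mean": e.mean,
                "lower": e.lower_95,
                "upper": e.upper_95,
                "pp_increase": e.pp_increase,
            }
            for e in rows
        ]
    )
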