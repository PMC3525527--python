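"""Shared constants: indicators, age groups, estimation window."""

from __future__ import annotations

#: The four survey indicators estimated by the pipeline.
INDICATORS = (
    "primary_prev",
    "secondary_prev",
    "primary_exposure",
    "secondary_exposure",
)

PREVALENCE_INDICATORS = ("primary_prev", "secondary_prev")
EXPOSURE_INDICATORS = ("primary_exposure", "secondary_exposure")
SECONDARY_INDICATORS = ("secondary_prev", "secondary_exposure")

#: Half-open 5-year age groups entering observations; 15-19 and 45-49 never do.
AGE_GROUPS = ((20, 25), (25, 30), (30, 35), (35, 40), (40, 45))
AGE_MIDPOINTS = tuple((lo + hi) / 2.0 for lo, hi in AGE_GROUPS)
N_AGE_GROUPS = len(AGE_GROUPS)

#: Estimation window (inclusive).  Survey data may predate the window.
YEAR_MIN = 1990
YEAR_MAX = 2010
YEARS = tuple(range(YEAR_MIN, YEAR_MAX + 1))
N_YEARS = len(YEARS)

#: Minimum contraception-free union exposure (years) in both definitions.
EXPOSURE_YEARS = 5.0

#: Surveys are dropped when the share of respondents with at least one
#: missing required response strictly exceeds this.
MISSINGNESS_LIMIT = 0.15

#: Ever-married-only surveys contribute exposure observations from this age on.
EVER_MARRIED_MIN_AGE = 30

#: Fixed standardisation of the schooling covariate shared by the surface
#: generator and the hierarchical model (years of schooling -> z-score).
EDUC_CENTER = 6.0
EDUC_SCALE = 3.0

#: Desire responses counted as desiring a(nother) child.
DESIRE_VALUES = ("wants_child", "undecided", "declared_unable", "wants_no_more")
DESIRING = frozenset({"wants_child", "undecided", "declared_unable"})


def age_group_of(age_years: int) -> tuple[int, int] | None:
    """Return the observation age group containing ``age_years``, or None."""
    for lo, hi in AGE_GROUPS:
        if lo <= age_years < hi:
            return (lo, hi)
    return None


def age_group_index(age_group: tuple[int, int]) -> int:
    try:
        return AGE_GROUPS.index(tuple(age_group))
    except ValueError:
        raise ValueError(f"unknown age group: {age_group!r}") from None
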