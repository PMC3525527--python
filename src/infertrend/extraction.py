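"""Classification of woman records into the four survey indicators, survey
screening rules, and per-age-group observation construction.

The indicator definitions
-------------------------
primary_prev
    Infertile union: no live birth despite desiring a child and >=5 y in a
    union with no contraceptive use during that time.  Fertile union: >=1
    live birth and >=5 y in the union at interview.  Prevalence =
    infertile / (infertile + fertile).
secondary_prev
    Infertile union: desires a child, >=5 y in a union since the last live
    birth with no contraceptive use during that time.  Fertile union: a live
    birth within the past 5 y and >=5 y of union following the first birth.
primary_exposure
    Exposed: currently in a union and either (not contracepting and desiring
    a child) or having had at least one live birth.  Denominator: all women.
secondary_exposure
    Exposed: >=1 live birth and currently in a union and either (not
    contracepting and desiring another child) or an additional birth within
    the past 5 y.  Denominator: all women.

Women undecided about another child or declaring themselves unable to become
pregnant are counted as desiring a child.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUPS,
    DESIRING,
    EVER_MARRIED_MIN_AGE,
    EXPOSURE_INDICATORS,
    EXPOSURE_YEARS,
    INDICATORS,
    MISSINGNESS_LIMIT,
    PREVALENCE_INDICATORS,
    SECONDARY_INDICATORS,
    age_group_of,
)
from .simulate import SurveyDataset, WomanRecord

__all__ = [
    "ClassificationStatus",
    "PrevalenceObservation",
    "ScreeningDecision",
    "classify_woman",
    "compute_observation",
    "screen_survey",
    "extract_observations",
    "contraceptive_prevalence",
    "EXCLUSION_REASONS",
]

#: Fixed, ordered exclusion-reason vocabulary.
EXCLUSION_REASONS = (
    "missing_data",
    "not_in_union",
    "insufficient_exposure",
    "contraception_use",
    "no_desire",
    "no_live_birth",
)

INFERTILE = "infertile_union"
FERTILE = "fertile_union"
EXCLUDED = "excluded"
EXPOSED = "exposed"
NOT_EXPOSED = "not_exposed"


@dataclass(frozen=True, slots=True)
class ClassificationStatus:
    status: str
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.status == EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason present iff status is excluded")


def _excluded(reason: str) -> ClassificationStatus:
    return ClassificationStatus(EXCLUDED, reason)


def _desires(desire: str | None) -> bool | None:
    if desire is None:
        return None
    return desire in DESIRING


def _union_clock(record: WomanRecord, use_full_history: bool):
    """Years of exposure in union: current-union duration when collected,
    else time since first union (a biased proxy)."""
    if use_full_history and record.years_in_current_union is not None:
        return record.years_in_current_union
    return record.years_since_first_union


def _no_contraception_5y(record: WomanRecord, use_full_history: bool):
    """True when no contraceptive use during the exposure window; falls back
    on current status (a biased proxy) when history was not collected."""
    if use_full_history and record.contraception_last_5y is not None:
        return not record.contraception_last_5y
    if record.current_contraception is None:
        return None
    return not record.current_contraception


def classify_woman(
    record: WomanRecord, indicator: str, has_full_history: bool = True
) -> ClassificationStatus:
    """Deterministically classify one record for one indicator.

    ``has_full_history=False`` forces the biased decision path (current
    contraceptive status, first-union clock) even when the history fields are
    present; this is how correction-training pairs are built.
    """
    if indicator == "primary_prev":
        return _classify_primary_prev(record, has_full_history)
    if indicator == "secondary_prev":
        return _classify_secondary_prev(record, has_full_history)
    if indicator == "primary_exposure":
        return _classify_primary_exposure(record)
    if indicator == "secondary_exposure":
        return _classify_secondary_exposure(record)
    raise ValueError(f"unknown indicator {indicator!r}")


def _classify_primary_prev(r: WomanRecord, full: bool) -> ClassificationStatus:
    if r.in_union is None:
        return _excluded("missing_data")
    if not r.in_union:
        return _excluded("not_in_union")
    dur = _union_clock(r, full)
    if dur is None:
        return _excluded("missing_data")
    if dur < EXPOSURE_YEARS:
        return _excluded("insufficient_exposure")
    if r.n_live_births >= 1:
        return ClassificationStatus(FERTILE)
    nc = _no_contraception_5y(r, full)
    if nc is None:
        return _excluded("missing_data")
    if not nc:
        return _excluded("contraception_use")
    wants = _desires(r.desire)
    if wants is None:
        return _excluded("missing_data")
    if not wants:
        return _excluded("no_desire")
    return ClassificationStatus(INFERTILE)


def _classify_secondary_prev(r: WomanRecord, full: bool) -> ClassificationStatus:
    if r.in_union is None:
        return _excluded("missing_data")
    if not r.in_union:
        return _excluded("not_in_union")
    if r.n_live_births == 0:
        return _excluded("no_live_birth")
    dur = _union_clock(r, full)
    ysl = r.years_since_last_birth
    if dur is None or ysl is None:
        return _excluded("missing_data")
    if ysl < EXPOSURE_YEARS:
        # recent birth: fertile if >=5 y of union following the first birth
        ysf = r.years_since_first_birth
        if ysf is None:
            return _excluded("missing_data")
        if ysf >= EXPOSURE_YEARS and dur >= EXPOSURE_YEARS:
            return ClassificationStatus(FERTILE)
        return _excluded("insufficient_exposure")
    if dur < EXPOSURE_YEARS:
        return _excluded("insufficient_exposure")
    nc = _no_contraception_5y(r, full)
    if nc is None:
        return _excluded("missing_data")
    if not nc:
        return _excluded("contraception_use")
    wants = _desires(r.desire)
    if wants is None:
        return _excluded("missing_data")
    if not wants:
        return _excluded("no_desire")
    return ClassificationStatus(INFERTILE)


def _classify_primary_exposure(r: WomanRecord) -> ClassificationStatus:
    # a missing field only excludes the record when the status actually
    # depends on it: exposed via (no contraception AND desires a child) or
    # via a demonstrated live birth
    if r.in_union is None:
        return _excluded("missing_data")
    if not r.in_union:
        return ClassificationStatus(NOT_EXPOSED)
    if r.n_live_births >= 1:
        return ClassificationStatus(EXPOSED)
    wants = _desires(r.desire)
    if wants is False:
        return ClassificationStatus(NOT_EXPOSED)
    if r.current_contraception is None:
        return _excluded("missing_data")
    if r.current_contraception:
        return ClassificationStatus(NOT_EXPOSED)
    if wants is None:
        return _excluded("missing_data")
    return ClassificationStatus(EXPOSED)


def _classify_secondary_exposure(r: WomanRecord) -> ClassificationStatus:
    if r.in_union is None:
        return _excluded("missing_data")
    if not r.in_union or r.n_live_births == 0:
        return ClassificationStatus(NOT_EXPOSED)
    # an additional live birth within the past 5 y decides on its own
    ysl = r.years_since_last_birth
    additional_recent: bool | None = False
    if r.n_live_births >= 2:
        additional_recent = None if ysl is None else ysl < EXPOSURE_YEARS
    if additional_recent:
        return ClassificationStatus(EXPOSED)
    wants = _desires(r.desire)
    if wants is False:
        branch1: bool | None = False
    elif r.current_contraception is None:
        branch1 = None
    elif r.current_contraception:
        branch1 = False
    elif wants is None:
        branch1 = None
    else:
        branch1 = True
    if branch1:
        return ClassificationStatus(EXPOSED)
    if branch1 is None or additional_recent is None:
        return _excluded("missing_data")
    return ClassificationStatus(NOT_EXPOSED)


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceObservation:
    """One (survey, indicator, age group) data point."""

    indicator: str
    country_id: str
    survey_year: int
    age_group: tuple[int, int]
    value: float
    effective_n: float
    is_national: bool
    is_biased: bool
    raw_numerator: int
    raw_denominator: int
    #: survey-level contraceptive-use prevalence (regressor for the
    #: secondary-infertility correction)
    contraceptive_prev: float | None = None
    #: correction-uncertainty component on the logit scale (set by the bias
    #: correction; 0 for unbiased observations)
    correction_variance: float = 0.0
    #: True when the ratio used survey weights (value then differs from the
    #: raw unweighted counts)
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.raw_denominator > 0 and not self.weighted:
            expected = self.raw_numerator / self.raw_denominator
            # the value may have been bias-corrected away from the raw ratio
            if not self.is_biased and abs(self.value - expected) > 1e-9:
                raise ValueError("value inconsistent with raw counts")
        if self.effective_n <= 0:
            raise ValueError("effective_n must be positive")
        if self.effective_n > self.raw_denominator + 1e-9:
            raise ValueError("effective_n cannot exceed raw_denominator")


def contraceptive_prevalence(dataset: SurveyDataset) -> float:
    """Share of women aged 20-44 currently using contraception."""
    used = total = 0
    for r in dataset.records:
        if age_group_of(r.age_years) is None or r.current_contraception is None:
            continue
        total += 1
        used += bool(r.current_contraception)
    return used / total if total else float("nan")


def compute_observation(
    dataset: SurveyDataset,
    indicator: str,
    age_group: tuple[int, int],
    use_full_history: bool = True,
    weighted: bool = False,
) -> PrevalenceObservation | None:
    """Build the observation for one indicator and age group.

    Returns None (the caller logs it) when the classified denominator is
    empty.  ``weighted=True`` uses survey weights in the ratio and a Kish
    effective size; the default is unweighted counts.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    lo, hi = age_group
    if indicator in PREVALENCE_INDICATORS:
        num_status, den_statuses = INFERTILE, (INFERTILE, FERTILE)
    else:
        num_status, den_statuses = EXPOSED, (EXPOSED, NOT_EXPOSED)

    num = den = 0
    wnum = wden = wden2 = 0.0
    for rec in dataset.records:
        if not (lo <= rec.age_years < hi):
            continue
        st = classify_woman(rec, indicator, has_full_history=use_full_history)
        if st.status not in den_statuses:
            continue
        den += 1
        wden += rec.survey_weight
        wden2 += rec.survey_weight**2
        if st.status == num_status:
            num += 1
            wnum += rec.survey_weight

    if den == 0:
        return None
    if weighted:
        value = wnum / wden
        effective = min((wden**2 / wden2), float(den)) / dataset.design_effect
    else:
        value = num / den
        effective = min(den / dataset.design_effect, float(den))

    biased = indicator in PREVALENCE_INDICATORS and (
        not use_full_history
        or not dataset.has_contraceptive_history
        or not dataset.has_current_union_duration
    )
    return PrevalenceObservation(
        indicator=indicator,
        country_id=dataset.country_id,
        survey_year=dataset.survey_year,
        age_group=(lo, hi),
        value=value,
        effective_n=effective,
        is_national=dataset.is_national,
        is_biased=biased,
        raw_numerator=num,
        raw_denominator=den,
        contraceptive_prev=contraceptive_prevalence(dataset),
        weighted=weighted,
    )


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningDecision:
    included: bool
    reason: str | None
    usable_age_groups: tuple[tuple[int, int], ...]
    missing_share: float


def _missing_required(rec: WomanRecord, indicator: str, dataset: SurveyDataset) -> bool:
    """At least one response required for this indicator is missing.

    Fields a survey does not collect by design (contraceptive history,
    current-union duration) are not counted as missing responses; the biased
    fallback handles them.
    """
    if rec.in_union is None or rec.current_contraception is None or rec.desire is None:
        return True
    if indicator in PREVALENCE_INDICATORS:
        if rec.in_union:
            clock = (
                rec.years_in_current_union
                if dataset.has_current_union_duration
                else rec.years_since_first_union
            )
            if clock is None and rec.years_since_first_union is None:
                return True
        if dataset.has_contraceptive_history and rec.contraception_last_5y is None:
            return True
    if indicator in SECONDARY_INDICATORS and rec.n_live_births >= 1:
        if rec.years_since_last_birth is None or rec.years_since_first_birth is None:
            return True
    return False


def screen_survey(
    dataset: SurveyDataset,
    indicator: str,
    china_countries: frozenset[str] | set[str] = frozenset(),
) -> ScreeningDecision:
    """Apply the survey-level inclusion rules for one indicator.

    * drop the survey when the share of respondents missing a required
      response strictly exceeds 15%;
    * ever-married-only surveys contribute exposure observations only for
      age groups at 30 y and older;
    * countries under the China rule yield no secondary-infertility
      observations.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")

    if indicator in SECONDARY_INDICATORS and dataset.country_id in china_countries:
        return ScreeningDecision(False, "china_rule", (), 0.0)

    in_window = [r for r in dataset.records if age_group_of(r.age_years) is not None]
    if not in_window:
        return ScreeningDecision(False, "no_respondents", (), 1.0)
    n_missing = sum(_missing_required(r, indicator, dataset) for r in in_window)
    share = n_missing / len(in_window)
    if share > MISSINGNESS_LIMIT:
        return ScreeningDecision(False, "missingness", (), share)

    usable = AGE_GROUPS
    if dataset.ever_married_only and indicator in EXPOSURE_INDICATORS:
        usable = tuple(g for g in AGE_GROUPS if g[0] >= EVER_MARRIED_MIN_AGE)
    return ScreeningDecision(True, None, usable, share)


def extract_observations(
    datasets: list[SurveyDataset],
    china_countries: frozenset[str] | set[str] = frozenset(),
    weighted: bool = False,
) -> tuple[list[PrevalenceObservation], pd.DataFrame]:
    """Screen every survey and build all usable observations.

    Returns the observations plus a screening/omission log (one row per
    survey x indicator, and per empty-denominator cell)."""
    observations: list[PrevalenceObservation] = []
    log_rows = []
    for ds in datasets:
        for indicator in INDICATORS:
            decision = screen_survey(ds, indicator, china_countries)
            log_rows.append(
                {
                    "country": ds.country_id,
                    "year": ds.survey_year,
                    "indicator": indicator,
                    "included": decision.included,
                    "reason": decision.reason,
                    "missing_share": decision.missing_share,
                }
            )
            if not decision.included:
                continue
            for age_group in decision.usable_age_groups:
                obs = compute_observation(ds, indicator, age_group, weighted=weighted)
                if obs is None:
                    log_rows.append(
                        {
                            "country": ds.country_id,
                            "year": ds.survey_year,
                            "indicator": indicator,
                            "included": False,
                            "reason": f"empty_denominator_{age_group[0]}_{age_group[1]}",
                            "missing_share": decision.missing_share,
                        }
                    )
                    continue
                observations.append(obs)
    return observations, pd.DataFrame(log_rows)


def observations_to_frame(observations: list[PrevalenceObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(
            {
                "indicator": o.indicator,
                "country": o.country_id,
                "year": o.survey_year,
                "age_lo": o.age_group[0],
                "age_hi": o.age_group[1],
                "value": o.value,
                "effective_n": o.effective_n,
                "is_national": o.is_national,
                "is_biased": o.is_biased,
                "raw_numerator": o.raw_numerator,
                "raw_denominator": o.raw_denominator,
                "contraceptive_prev": o.contraceptive_prev,
                "correction_variance": o.correction_variance,
            }
        )
    return pd.DataFrame(rows)
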