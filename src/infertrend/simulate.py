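"""Synthetic survey-data generator with known ground truth.

Everything downstream (classification, bias correction, hierarchical
modelling, aggregation, cross-validation) is exercised against datasets
produced here, so the generator plants records whose classification is known
by construction and records the true prevalence surface it sampled from.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import (
    AGE_GROUPS,
    EDUC_CENTER,
    EDUC_SCALE,
    INDICATORS,
    N_AGE_GROUPS,
    YEAR_MAX,
    YEAR_MIN,
    YEARS,
    age_group_of,
)

__all__ = [
    "HierarchySpec",
    "SurfaceParams",
    "TrueSurface",
    "WomanRecord",
    "SurveyDesign",
    "SurveyDataset",
    "ContextTables",
    "generate_hierarchy",
    "generate_true_surface",
    "generate_survey",
    "generate_context",
]


# ---------------------------------------------------------------------------
# Geographic hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierarchySpec:
    """Country -> subregion -> region mapping with a High-Income flag.

    Exactly one region may be flagged high income; the flag switches on the
    region-specific age pattern for exposure to primary infertility in the
    hierarchical model.
    """

    countries: tuple[str, ...]
    country_to_subregion: dict[str, str]
    subregion_to_region: dict[str, str]
    high_income_region: str | None = None

    def __post_init__(self) -> None:
        for c in self.countries:
            if c not in self.country_to_subregion:
                raise ValueError(f"country {c!r} has no subregion")
        for s in self.country_to_subregion.values():
            if s not in self.subregion_to_region:
                raise ValueError(f"subregion {s!r} has no region")
        if (
            self.high_income_region is not None
            and self.high_income_region not in self.regions
        ):
            raise ValueError(f"unknown high-income region {self.high_income_region!r}")

    @property
    def subregions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.country_to_subregion[c] for c in self.countries))

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.subregion_to_region[s] for s in self.subregions))

    def subregion_of(self, country: str) -> str:
        return self.country_to_subregion[country]

    def region_of(self, country: str) -> str:
        return self.subregion_to_region[self.country_to_subregion[country]]

    def is_high_income(self, country: str) -> bool:
        return self.region_of(country) == self.high_income_region

    def countries_in_subregion(self, subregion: str) -> tuple[str, ...]:
        return tuple(c for c in self.countries if self.subregion_of(c) == subregion)

    def to_yaml(self, path) -> None:
        payload = {
            "countries": list(self.countries),
            "country_to_subregion": dict(self.country_to_subregion),
            "subregion_to_region": dict(self.subregion_to_region),
            "high_income_region": self.high_income_region,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "HierarchySpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            countries=tuple(payload["countries"]),
            country_to_subregion=payload["country_to_subregion"],
            subregion_to_region=payload["subregion_to_region"],
            high_income_region=payload.get("high_income_region"),
        )


def generate_hierarchy(
    n_regions: int,
    n_subregions_per_region: int,
    n_countries_per_subregion: int,
    seed: int = 0,
) -> HierarchySpec:
    """Build a balanced hierarchy with deterministic labels.

    The seed only selects which region carries the High-Income flag; the
    structure and labels are fully determined by the counts.
    """
    if min(n_regions, n_subregions_per_region, n_countries_per_subregion) < 1:
        raise ValueError("all hierarchy counts must be >= 1")
    rng = np.random.default_rng(seed)
    countries: list[str] = []
    c2s: dict[str, str] = {}
    s2r: dict[str, str] = {}
    for r in range(n_regions):
        region = f"R{r + 1}"
        for s in range(n_subregions_per_region):
            sub = f"{region}S{s + 1}"
            s2r[sub] = region
            for c in range(n_countries_per_subregion):
                country = f"{sub}C{c + 1}"
                countries.append(country)
                c2s[country] = sub
    hi = f"R{int(rng.integers(n_regions)) + 1}"
    return HierarchySpec(
        countries=tuple(countries),
        country_to_subregion=c2s,
        subregion_to_region=s2r,
        high_income_region=hi,
    )


# ---------------------------------------------------------------------------
# True prevalence surface
# ---------------------------------------------------------------------------

def _default_intercepts() -> dict[str, float]:
    # logit scale; roughly 4% / 10% prevalence, 55% / 25% exposure.  Kept
    # high enough that survey cells have double-digit numerators at
    # realistic survey sizes, where the logit-normal observation model is a
    # good approximation.
    return {
        "primary_prev": -3.2,
        "secondary_prev": -2.2,
        "primary_exposure": 0.2,
        "secondary_exposure": -1.1,
    }


def _default_age_offsets() -> dict[str, tuple[float, ...]]:
    # primary infertility elevated at 20-24; secondary rising with age
    return {
        "primary_prev": (0.30, 0.0, -0.10, -0.12, -0.12),
        "secondary_prev": (-1.20, -0.60, 0.0, 0.55, 1.10),
        "primary_exposure": (0.15, 0.0, -0.10, -0.25, -0.45),
        "secondary_exposure": (-0.30, 0.0, 0.05, -0.10, -0.35),
    }


def _default_slopes() -> dict[str, float]:
    # per decade, logit scale
    return {
        "primary_prev": -0.15,
        "secondary_prev": 0.05,
        "primary_exposure": -0.10,
        "secondary_exposure": -0.15,
    }


@dataclass
class SurfaceParams:
    """Generative settings for :func:`generate_true_surface`."""

    intercepts: dict[str, float] = field(default_factory=_default_intercepts)
    age_offsets: dict[str, tuple[float, ...]] = field(default_factory=_default_age_offsets)
    global_slopes: dict[str, float] = field(default_factory=_default_slopes)
    sd_region: float = 0.20
    sd_subregion: float = 0.12
    sd_country: float = 0.12
    sd_region_slope: float = 0.05
    educ_coefs: dict[str, float] = field(default_factory=lambda: {k: 0.0 for k in INDICATORS})
    #: extra age offsets added in the High-Income region for primary exposure
    high_income_age_offsets: tuple[float, ...] = (-0.60, -0.30, 0.10, 0.20, 0.20)

    def validate(self) -> None:
        for name in ("sd_region", "sd_subregion", "sd_country", "sd_region_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for ind in INDICATORS:
            if len(self.age_offsets[ind]) != N_AGE_GROUPS:
                raise ValueError(f"age_offsets[{ind}] must have {N_AGE_GROUPS} entries")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrueSurface:
    """True probability per (indicator, country, year, age group).

    ``values[ind]`` has shape (n_countries, n_years, n_age_groups) with years
    1990..2010.  ``effects`` retains the sampled random effects so tests can
    check moments and the model-recovery experiments know the truth.
    """

    hierarchy: HierarchySpec
    params: SurfaceParams
    seed: int
    values: dict[str, np.ndarray]
    effects: dict[str, dict]

    def value(self, indicator: str, country: str, year: int, age_group) -> float:
        ci = self.hierarchy.countries.index(country)
        yi = int(year) - YEAR_MIN
        if not 0 <= yi < len(YEARS):
            raise ValueError(f"year {year} outside {YEAR_MIN}-{YEAR_MAX}")
        ai = AGE_GROUPS.index(tuple(age_group))
        return float(self.values[indicator][ci, yi, ai])


def generate_true_surface(
    hierarchy: HierarchySpec,
    params: SurfaceParams | None = None,
    seed: int = 0,
    context: "ContextTables | None" = None,
) -> TrueSurface:
    """Sample a nested-effects surface on the logit scale.

    The linear predictor mirrors the estimation model: nested country /
    subregion / region intercept deviations, a region slope drawn around the
    global slope, fixed age offsets, and optionally the standardised
    schooling covariate when ``context`` is supplied.
    """
    params = params or SurfaceParams()
    params.validate()
    rng = np.random.default_rng(seed)

    regions = hierarchy.regions
    subregions = hierarchy.subregions
    countries = hierarchy.countries
    t = (np.array(YEARS) - 2000.0) / 10.0  # decades centred at 2000

    values: dict[str, np.ndarray] = {}
    effects: dict[str, dict] = {}
    for ind in INDICATORS:
        re_region = dict(zip(regions, rng.normal(0.0, params.sd_region, len(regions))))
        re_sub = {
            s: re_region[hierarchy.subregion_to_region[s]]
            + rng.normal(0.0, params.sd_subregion)
            for s in subregions
        }
        re_country = {
            c: re_sub[hierarchy.subregion_of(c)] + rng.normal(0.0, params.sd_country)
            for c in countries
        }
        slope_region = {
            r: params.global_slopes[ind] + rng.normal(0.0, params.sd_region_slope)
            for r in regions
        }
        ages = np.asarray(params.age_offsets[ind])

        arr = np.empty((len(countries), len(YEARS), N_AGE_GROUPS))
        for ci, c in enumerate(countries):
            lin = params.intercepts[ind] + re_country[c] + slope_region[hierarchy.region_of(c)] * t
            if context is not None and params.educ_coefs.get(ind, 0.0) != 0.0:
                educ_z = np.array(
                    [context.education_z(c, y) for y in YEARS]
                )
                lin = lin + params.educ_coefs[ind] * educ_z
            grid = lin[:, None] + ages[None, :]
            if ind == "primary_exposure" and hierarchy.is_high_income(c):
                grid = grid + np.asarray(params.high_income_age_offsets)[None, :]
            arr[ci] = _expit(grid)
        values[ind] = arr
        effects[ind] = {
            "region": re_region,
            "subregion": re_sub,
            "country": re_country,
            "region_slope": slope_region,
        }

    return TrueSurface(hierarchy=hierarchy, params=params, seed=seed, values=values, effects=effects)


# ---------------------------------------------------------------------------
# Woman-level records and surveys
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class WomanRecord:
    """One survey respondent's reproductive variables."""

    age_years: int
    in_union: bool
    years_since_first_union: float | None = None
    years_in_current_union: float | None = None
    n_live_births: int = 0
    years_since_first_birth: float | None = None
    years_since_last_birth: float | None = None
    current_contraception: bool | None = False
    contraception_last_5y: bool | None = None
    desire: str | None = "wants_child"
    survey_weight: float = 1.0

    def validate(self) -> None:
        if not 15 <= self.age_years <= 49:
            raise ValueError("age_years must be in 15..49")
        if self.n_live_births == 0 and (
            self.years_since_first_birth is not None
            or self.years_since_last_birth is not None
        ):
            raise ValueError("birth-timing fields must be missing when n_live_births == 0")
        if (
            self.years_since_first_birth is not None
            and self.years_since_last_birth is not None
            and self.years_since_last_birth > self.years_since_first_birth + 1e-9
        ):
            raise ValueError("years_since_last_birth must not exceed years_since_first_birth")
        if (
            self.years_in_current_union is not None
            and self.years_since_first_union is not None
            and self.years_in_current_union > self.years_since_first_union + 1e-9
        ):
            raise ValueError("years_in_current_union must not exceed years_since_first_union")
        if self.survey_weight <= 0:
            raise ValueError("survey_weight must be positive")


@dataclass(frozen=True)
class SurveyDesign:
    """Design flags controlling which fields a survey collects."""

    is_national: bool = True
    ever_married_only: bool = False
    has_contraceptive_history: bool = True
    has_current_union_duration: bool = True
    design_effect: float = 1.0
    #: share of respondents whose desire response is missing at random
    missing_rate: float = 0.0
    #: scale of the planted bias archetypes (past contraceptive users and
    #: remarried women).  They are present in every survey with truthful
    #: fields; the bias only surfaces when a survey does not collect the
    #: history field and classification falls back on current status or the
    #: first-union clock.
    bias_fraction: float = 0.8
    #: sd (logit scale) of independent survey-level perturbations of each
    #: cell's true value — study-design noise that the estimation model
    #: absorbs with its extra variance components.  0 disables it, making
    #: the survey exactly unbiased for the surface.
    survey_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.design_effect <= 0:
            raise ValueError("design_effect must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SurveyDataset:
    """A generated (or loaded) woman-level survey."""

    records: list[WomanRecord]
    country_id: str
    survey_year: int
    is_national: bool = True
    ever_married_only: bool = False
    has_contraceptive_history: bool = True
    has_current_union_duration: bool = True
    design_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.ever_married_only:
            for rec in self.records:
                if rec.years_since_first_union is None:
                    raise ValueError(
                        "ever_married_only survey contains a record with no union history"
                    )

    def __len__(self) -> int:
        return len(self.records)

    # -- CSV round trip (column dictionary documented in the README) --------
    _COLUMNS = (
        "age_years",
        "in_union",
        "years_since_first_union",
        "years_in_current_union",
        "n_live_births",
        "years_since_first_birth",
        "years_since_last_birth",
        "current_contraception",
        "contraception_last_5y",
        "desire",
        "survey_weight",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in self._COLUMNS} for r in self.records],
            columns=list(self._COLUMNS),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "SurveyDataset":
        df = pd.read_csv(path)

        def _opt(v, cast):
            return None if pd.isna(v) else cast(v)

        records = [
            WomanRecord(
                age_years=int(row.age_years),
                in_union=bool(row.in_union),
                years_since_first_union=_opt(row.years_since_first_union, float),
                years_in_current_union=_opt(row.years_in_current_union, float),
                n_live_births=int(row.n_live_births),
                years_since_first_birth=_opt(row.years_since_first_birth, float),
                years_since_last_birth=_opt(row.years_since_last_birth, float),
                current_contraception=_opt(row.current_contraception, bool),
                contraception_last_5y=_opt(row.contraception_last_5y, bool),
                desire=_opt(row.desire, str),
                survey_weight=float(row.survey_weight),
            )
            for row in df.itertuples()
        ]
        return cls(records=records, **meta)


# Archetype labels used by the generator (kept on no record; listed here for
# the tests that introspect generation).
_ARCHETYPES = (
    "primary_infertile",        # A
    "secondary_infertile",      # B1
    "secondary_fertile",        # B2
    "exposed_parent_short_union",  # D: exposure-1 only
    "unexposed",                # C
    "bias_contraception",       # E: planted current-status bias (primary)
    "bias_contraception_parous",   # E2: planted current-status bias (secondary)
    "bias_union_duration",      # F: planted first-union bias
)

# age-group weights for the planted bias: stronger at younger ages
_BIAS_AGE_WEIGHT = np.array([1.5, 1.2, 1.0, 0.7, 0.5])


def _cell_probs(p1, p2, e1, e2, bias_w, design: SurveyDesign):
    """Archetype probabilities for one age-group cell.

    The bias archetypes E/E2/F are planted in every survey with truthful
    history fields, so full-history classification excludes them (leaving
    the cell's true values recoverable) while the current-status or
    first-union fallback mis-classifies them, inflating apparent infertility
    more at younger ages.  Masses are budgeted so that under full-history
    classification:  infertile/(infertile+fertile) = p1 and p2,
    P(exposed-1) = e1,  P(exposed-2) = e2.
    """
    bf = design.bias_fraction * bias_w
    pE2 = bf * p2 * e2          # parous past-users: secondary-infertile lookalikes
    pB = e2 - pE2               # primary-fertile mass stays e2 (B + E2)
    pB1 = pB * p2
    pB2 = pB - pB1
    pA = p1 / (1.0 - p1) * e2
    pE = bf * pA                # childless past-users
    pF = bf * pA                # remarried: long first-union, short current union
    pD = max(e1 - (pA + pB + pE2 + pE + pF), 0.0)
    pC = max(1.0 - (pA + pB + pD + pE + pE2 + pF), 0.0)
    probs = np.array([pA, pB1, pB2, pD, pC, pE, pE2, pF])
    return probs / probs.sum()


def _synthesize_record(arch: str, age: int, rng, design: SurveyDesign) -> WomanRecord:
    """Build one record for an archetype; field values beyond the planted
    classification outcome are jittered for realism."""
    u = rng.uniform

    def rec(**kw) -> WomanRecord:
        base = dict(
            age_years=age,
            in_union=True,
            years_since_first_union=None,
            years_in_current_union=None,
            n_live_births=0,
            years_since_first_birth=None,
            years_since_last_birth=None,
            current_contraception=False,
            contraception_last_5y=False,
            desire="wants_child",
            survey_weight=1.0,
        )
        base.update(kw)
        return WomanRecord(**base)

    max_union = max(age - 15.0, 6.0)
    if arch == "primary_infertile":
        dur = 5.0 + u(0.0, min(8.0, max_union - 5.0))
        desire = rng.choice(
            ["wants_child", "undecided", "declared_unable"], p=[0.7, 0.2, 0.1]
        )
        return rec(
            years_in_current_union=dur,
            years_since_first_union=dur + u(0.0, 2.0),
            desire=str(desire),
        )
    if arch == "secondary_infertile":
        ysl = 5.0 + u(0.0, 5.0)
        ysf = ysl + u(0.0, 4.0)
        dur = ysl + u(0.0, 3.0)
        return rec(
            years_in_current_union=dur,
            years_since_first_union=dur + u(0.0, 2.0),
            n_live_births=int(1 + rng.integers(0, 2)),
            years_since_first_birth=ysf,
            years_since_last_birth=ysl,
        )
    if arch == "secondary_fertile":
        ysl = u(0.0, 4.5)
        ysf = 5.0 + u(0.0, 6.0)
        dur = ysf + u(0.0, 3.0)
        return rec(
            years_in_current_union=dur,
            years_since_first_union=dur + u(0.0, 2.0),
            n_live_births=2,
            years_since_first_birth=ysf,
            years_since_last_birth=ysl,
        )
    if arch == "exposed_parent_short_union":
        # both union clocks < 5 y so neither decision path classifies her
        ysl = 5.0 + u(0.0, 4.0)
        dur = u(1.0, 4.0)
        return rec(
            years_in_current_union=dur,
            years_since_first_union=dur + u(0.0, 4.8 - dur),
            n_live_births=1,
            years_since_first_birth=ysl + u(0.0, 2.0),
            years_since_last_birth=ysl,
            current_contraception=True,
            contraception_last_5y=True,
            desire="wants_no_more",
        )
    if arch == "unexposed":
        if design.ever_married_only or rng.uniform() < 0.35:
            # in a union but contracepting with no child and no desire
            dur = 5.0 + u(0.0, 5.0)
            return rec(
                years_in_current_union=dur,
                years_since_first_union=dur + u(0.0, 2.0),
                current_contraception=True,
                contraception_last_5y=True,
                desire="wants_no_more",
            )
        return rec(in_union=False, current_contraception=False, desire="wants_child")
    if arch == "bias_contraception":
        # used contraception within 5 y but not currently; looks primary
        # infertile when only current status is observed
        dur = 5.0 + u(0.0, 6.0)
        return rec(
            years_in_current_union=dur,
            years_since_first_union=dur + u(0.0, 2.0),
            current_contraception=False,
            contraception_last_5y=True,
        )
    if arch == "bias_contraception_parous":
        ysl = 5.0 + u(0.0, 4.0)
        dur = ysl + u(0.0, 3.0)
        return rec(
            years_in_current_union=dur,
            years_since_first_union=dur + u(0.0, 2.0),
            n_live_births=1,
            years_since_first_birth=ysl + u(0.0, 3.0),
            years_since_last_birth=ysl,
            current_contraception=False,
            contraception_last_5y=True,
        )
    if arch == "bias_union_duration":
        # remarried: long first-union clock, short current union
        return rec(
            years_in_current_union=u(1.0, 4.5),
            years_since_first_union=5.0 + u(0.0, 5.0),
        )
    raise ValueError(f"unknown archetype {arch!r}")


def generate_survey(
    surface: TrueSurface,
    country_id: str,
    survey_year: int,
    n_women: int,
    design: SurveyDesign | None = None,
    seed: int = 0,
) -> SurveyDataset:
    """Draw a woman-level survey whose classified indicators are unbiased for
    the surface's cell values (when the design collects full histories)."""
    if n_women <= 0:
        raise ValueError("n_women must be positive")
    if country_id not in surface.hierarchy.countries:
        raise ValueError(f"country {country_id!r} not in surface hierarchy")
    if not YEAR_MIN <= survey_year <= YEAR_MAX:
        raise ValueError(f"survey_year {survey_year} outside surface support")
    design = design or SurveyDesign()
    rng = np.random.default_rng(seed)

    ci = surface.hierarchy.countries.index(country_id)
    yi = survey_year - YEAR_MIN
    cell_probs = []
    for ai in range(N_AGE_GROUPS):
        cell = [
            surface.values[ind][ci, yi, ai]
            for ind in ("primary_prev", "secondary_prev",
                        "primary_exposure", "secondary_exposure")
        ]
        if design.survey_effect_sd > 0:
            shifts = rng.normal(0.0, design.survey_effect_sd, size=4)
            cell = [_expit(np.log(p / (1 - p)) + s) for p, s in zip(cell, shifts)]
        p1, p2, e1, e2 = cell
        cell_probs.append(_cell_probs(p1, p2, e1, e2, _BIAS_AGE_WEIGHT[ai], design))

    records: list[WomanRecord] = []
    ages = rng.integers(20, 45, size=n_women)
    arch_draws = rng.uniform(size=n_women)
    for k in range(n_women):
        age = int(ages[k])
        ai = (age - 20) // 5
        probs = cell_probs[ai]
        arch = _ARCHETYPES[int(np.searchsorted(np.cumsum(probs), arch_draws[k]))]
        rec = _synthesize_record(arch, age, rng, design)
        if design.missing_rate > 0 and rng.uniform() < design.missing_rate:
            rec.desire = None
        if not design.has_contraceptive_history:
            rec.contraception_last_5y = None
        if not design.has_current_union_duration:
            rec.years_in_current_union = None
        if design.ever_married_only and rec.years_since_first_union is None:
            # replace never-in-union women: draw ever-married unexposed
            rec = _synthesize_record("unexposed", age, rng, design)
            if not design.has_contraceptive_history:
                rec.contraception_last_5y = None
            if not design.has_current_union_duration:
                rec.years_in_current_union = None
        if design.design_effect > 1.0:
            rec.survey_weight = float(rng.lognormal(0.0, 0.5))
        records.append(rec)

    return SurveyDataset(
        records=records,
        country_id=country_id,
        survey_year=int(survey_year),
        is_national=design.is_national,
        ever_married_only=design.ever_married_only,
        has_contraceptive_history=design.has_contraceptive_history,
        has_current_union_duration=design.has_current_union_duration,
        design_effect=design.design_effect,
    )


# ---------------------------------------------------------------------------
# Context tables: schooling covariate and female population counts
# ---------------------------------------------------------------------------

@dataclass
class ContextTables:
    """Education (country, year) and female population (country, year, age)."""

    education: pd.DataFrame  # columns: country, year, years_schooling
    population: pd.DataFrame  # columns: country, year, age_lo, age_hi, population
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._educ = {
            (r.country, int(r.year)): float(r.years_schooling)
            for r in self.education.itertuples()
        }
        self._pop = {
            (r.country, int(r.year), (int(r.age_lo), int(r.age_hi))): float(r.population)
            for r in self.population.itertuples()
        }

    def education_years(self, country: str, year: int) -> float:
        year = min(max(int(year), YEAR_MIN), YEAR_MAX)  # clamp outside window
        return self._educ[(country, year)]

    def education_z(self, country: str, year: int) -> float:
        return (self.education_years(country, year) - EDUC_CENTER) / EDUC_SCALE

    def population_of(self, country: str, year: int, age_group) -> float:
        return self._pop[(country, int(year), tuple(age_group))]


def generate_context(
    hierarchy: HierarchySpec,
    seed: int = 0,
    educ_slope_max: float = 3.0,
    pop_scale: float = 5e5,
) -> ContextTables:
    """Smooth schooling trajectories and positive population counts for every
    country-year (-age group).  Set ``educ_slope_max=0`` for flat education."""
    rng = np.random.default_rng(seed)
    educ_rows = []
    pop_rows = []
    for country in hierarchy.countries:
        base = rng.uniform(2.0, 10.0)
        slope = rng.uniform(0.0, educ_slope_max)
        pop_base = rng.uniform(0.2, 2.0) * pop_scale
        growth = rng.uniform(0.0, 0.02)
        age_shape = rng.dirichlet(np.full(N_AGE_GROUPS, 20.0))
        for year in YEARS:
            frac = (year - YEAR_MIN) / (YEAR_MAX - YEAR_MIN)
            educ_rows.append(
                {"country": country, "year": year, "years_schooling": base + slope * frac}
            )
            for ai, (lo, hi) in enumerate(AGE_GROUPS):
                pop_rows.append(
                    {
                        "country": country,
                        "year": year,
                        "age_lo": lo,
                        "age_hi": hi,
                        "population": pop_base * age_shape[ai] * (1.0 + growth) ** (year - YEAR_MIN),
                    }
                )
    education = pd.DataFrame(educ_rows)
    population = pd.DataFrame(pop_rows)
    metadata = {
        "population_total": float(population["population"].sum()),
        "population_total_2010": float(
            population.loc[population["year"] == 2010, "population"].sum()
        ),
        "seed": int(seed),
    }
    return ContextTables(education=education, population=population, metadata=metadata)
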