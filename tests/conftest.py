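"""Shared fixtures: small synthetic experiments reused across test modules."""

import numpy as np
import pytest

import infertrend as it
from infertrend.constants import YEARS


@pytest.fixture(scope="session")
def hierarchy():
    return it.generate_hierarchy(3, 2, 3, seed=1)


@pytest.fixture(scope="session")
def context(hierarchy):
    return it.generate_context(hierarchy, seed=2)


@pytest.fixture(scope="session")
def surface(hierarchy, context):
    params = it.SurfaceParams()
    params.educ_coefs = {k: -0.3 for k in params.educ_coefs}
    return it.generate_true_surface(hierarchy, params=params, seed=3, context=context)


@pytest.fixture(scope="session")
def small_survey(surface, hierarchy):
    """A modest full-history national survey for unit tests."""
    return it.generate_survey(surface, hierarchy.countries[0], 2005, 4000, seed=7)


@pytest.fixture(scope="session")
def survey_datasets(surface, hierarchy):
    """Three surveys per country at 4,000 women each (fast, unit-test scale)."""
    rng = np.random.default_rng(11)
    datasets = []
    for c in hierarchy.countries:
        for year in rng.choice(YEARS, size=3, replace=False):
            datasets.append(
                it.generate_survey(surface, c, int(year), 4000, seed=int(rng.integers(2**31)))
            )
    return datasets


@pytest.fixture(scope="session")
def observations(survey_datasets):
    obs, _ = it.extract_observations(survey_datasets)
    return obs


def random_woman(rng) -> it.WomanRecord:
    """Draw a random (not necessarily realistic) woman record covering the
    classification decision space, including missing-field patterns."""

    def maybe(value, p_missing=0.15):
        return None if rng.uniform() < p_missing else value

    in_union = bool(rng.uniform() < 0.75)
    n_births = int(rng.choice([0, 1, 2, 3], p=[0.35, 0.3, 0.2, 0.15]))
    first_union = maybe(float(rng.uniform(0, 25)), 0.2) if in_union else None
    current_union = None
    if in_union and first_union is not None and rng.uniform() > 0.3:
        current_union = float(rng.uniform(0, first_union))
    ysl = ysf = None
    if n_births:
        ysl = maybe(float(rng.uniform(0, 20)), 0.15)
        if ysl is not None:
            ysf = maybe(ysl + float(rng.uniform(0, 10)), 0.15)
        else:
            ysf = maybe(float(rng.uniform(0, 25)), 0.15)
            if ysf is not None:
                ysl = None
    return it.WomanRecord(
        age_years=int(rng.integers(15, 50)),
        in_union=in_union,
        years_since_first_union=first_union,
        years_in_current_union=current_union,
        n_live_births=n_births,
        years_since_first_birth=ysf,
        years_since_last_birth=ysl,
        current_contraception=maybe(bool(rng.uniform() < 0.4), 0.1),
        contraception_last_5y=maybe(bool(rng.uniform() < 0.5), 0.4),
        desire=maybe(
            str(rng.choice(["wants_child", "undecided", "declared_unable", "wants_no_more"])),
            0.1,
        ),
        survey_weight=float(rng.uniform(0.2, 3.0)),
    )
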