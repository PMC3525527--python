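import numpy as np
import pytest

import infertrend as it
from infertrend.constants import AGE_GROUPS, INDICATORS
from infertrend.extraction import (
    EXCLUSION_REASONS,
    contraceptive_prevalence,
    observations_to_frame,
)
from infertrend.simulate import SurveyDataset, WomanRecord

from conftest import random_woman
from oracle_classify import oracle_status


def woman(**kw) -> WomanRecord:
    base = dict(
        age_years=27,
        in_union=True,
        years_in_current_union=6.0,
        years_since_first_union=7.0,
        n_live_births=0,
        current_contraception=False,
        contraception_last_5y=False,
        desire="wants_child",
    )
    base.update(kw)
    return WomanRecord(**base)


class TestClassifyWoman:
    def test_primary_infertile_definitional(self):
        st = it.classify_woman(woman(), "primary_prev")
        assert st.status == "infertile_union"
        assert st.exclusion_reason is None

    def test_primary_fertile_definitional(self):
        st = it.classify_woman(
            woman(n_live_births=1, years_since_first_birth=4.0, years_since_last_birth=4.0),
            "primary_prev",
        )
        assert st.status == "fertile_union"

    def test_primary_short_union_excluded(self):
        st = it.classify_woman(
            woman(years_in_current_union=3.0, years_since_first_union=3.0), "primary_prev"
        )
        assert st.status == "excluded"
        assert st.exclusion_reason == "insufficient_exposure"

    def test_undecided_and_declared_unable_count_as_desiring(self):
        for desire in ("undecided", "declared_unable"):
            st = it.classify_woman(woman(desire=desire), "primary_prev")
            assert st.status == "infertile_union"

    def test_no_desire_excluded(self):
        st = it.classify_woman(woman(desire="wants_no_more"), "primary_prev")
        assert st.exclusion_reason == "no_desire"

    def test_contraception_excluded(self):
        st = it.classify_woman(woman(contraception_last_5y=True), "primary_prev")
        assert st.exclusion_reason == "contraception_use"

    def test_missing_desire_routes_to_missing_data(self):
        st = it.classify_woman(woman(desire=None), "primary_prev")
        assert st.exclusion_reason == "missing_data"

    def test_secondary_infertile_definitional(self):
        st = it.classify_woman(
            woman(
                n_live_births=1,
                years_since_last_birth=6.0,
                years_since_first_birth=8.0,
                years_in_current_union=9.0,
                years_since_first_union=10.0,
            ),
            "secondary_prev",
        )
        assert st.status == "infertile_union"

    def test_secondary_fertile_needs_recent_birth_and_union_after_first(self):
        st = it.classify_woman(
            woman(
                n_live_births=2,
                years_since_last_birth=2.0,
                years_since_first_birth=7.0,
                years_in_current_union=8.0,
                years_since_first_union=9.0,
            ),
            "secondary_prev",
        )
        assert st.status == "fertile_union"
        # recent birth but first birth only 3 y ago: insufficient exposure
        st = it.classify_woman(
            woman(
                n_live_births=2,
                years_since_last_birth=2.0,
                years_since_first_birth=3.0,
                years_in_current_union=8.0,
                years_since_first_union=9.0,
            ),
            "secondary_prev",
        )
        assert st.exclusion_reason == "insufficient_exposure"

    def test_biased_path_uses_current_status(self):
        rec = woman(contraception_last_5y=True, current_contraception=False)
        assert it.classify_woman(rec, "primary_prev", has_full_history=True).status == "excluded"
        assert (
            it.classify_woman(rec, "primary_prev", has_full_history=False).status
            == "infertile_union"
        )

    def test_first_union_fallback_when_duration_missing(self):
        rec = woman(years_in_current_union=None, years_since_first_union=8.0)
        assert it.classify_woman(rec, "primary_prev").status == "infertile_union"

    def test_exposure_definitional(self):
        assert it.classify_woman(woman(), "primary_exposure").status == "exposed"
        assert (
            it.classify_woman(woman(in_union=False, years_in_current_union=None,
                                    years_since_first_union=None), "primary_exposure").status
            == "not_exposed"
        )
        # parent in union is exposed regardless of contraception
        st = it.classify_woman(
            woman(n_live_births=1, years_since_first_birth=3.0, years_since_last_birth=3.0,
                  current_contraception=True, contraception_last_5y=True,
                  desire="wants_no_more"),
            "primary_exposure",
        )
        assert st.status == "exposed"

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError):
            it.classify_woman(woman(), "tertiary_prev")

    def test_exclusion_reasons_from_fixed_vocabulary(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            rec = random_woman(rng)
            for ind in INDICATORS:
                st = it.classify_woman(rec, ind)
                if st.status == "excluded":
                    assert st.exclusion_reason in EXCLUSION_REASONS

    @pytest.mark.parametrize("indicator", INDICATORS)
    def test_oracle_equivalence(self, indicator):
        # dual implementation: flat transcribed predicates vs decision tree
        rng = np.random.default_rng(hash(indicator) % 2**32)
        for _ in range(1000):
            rec = random_woman(rng)
            got = it.classify_woman(rec, indicator).status
            want = oracle_status(rec, indicator)
            assert got == want, rec


def make_dataset(records, **meta) -> SurveyDataset:
    base = dict(country_id="C1", survey_year=2000)
    base.update(meta)
    return SurveyDataset(records=records, **base)


class TestComputeObservation:
    def test_ratio_definition(self):
        records = [woman() for _ in range(2)] + [
            woman(n_live_births=1, years_since_first_birth=3.0, years_since_last_birth=3.0)
            for _ in range(98)
        ]
        obs = it.compute_observation(make_dataset(records), "primary_prev", (25, 30))
        assert obs.value == pytest.approx(0.02)
        assert obs.raw_denominator == 100
        assert obs.raw_numerator == 2

    def test_zero_numerator(self):
        records = [
            woman(n_live_births=1, years_since_first_birth=3.0, years_since_last_birth=3.0)
            for _ in range(50)
        ]
        obs = it.compute_observation(make_dataset(records), "primary_prev", (25, 30))
        assert obs.value == 0.0

    def test_empty_denominator_returns_none(self):
        records = [woman(in_union=False, years_in_current_union=None,
                         years_since_first_union=None)]
        assert it.compute_observation(make_dataset(records), "primary_prev", (25, 30)) is None

    def test_design_effect_halves_effective_n(self):
        records = [woman() for _ in range(2)] + [
            woman(n_live_births=1, years_since_first_birth=3.0, years_since_last_birth=3.0)
            for _ in range(98)
        ]
        obs = it.compute_observation(
            make_dataset(records, design_effect=2.0), "primary_prev", (25, 30)
        )
        assert obs.effective_n == pytest.approx(50.0)

    def test_design_effect_matches_cluster_simulation(self):
        # oracle for the effective-n convention: sampling 50 clusters of two
        # perfectly correlated respondents carries the information of a
        # simple random sample of 50, i.e. denominator / design-effect 2
        rng = np.random.default_rng(0)
        p = 0.3
        reps = 20000
        cluster_means = rng.binomial(1, p, size=(reps, 50)).mean(axis=1)
        var_clustered = cluster_means.var()  # each cluster contributes twice
        assert var_clustered == pytest.approx(p * (1 - p) / 50, rel=0.05)

    def test_permutation_invariance(self, small_survey):
        shuffled = SurveyDataset(
            records=list(reversed(small_survey.records)),
            country_id=small_survey.country_id,
            survey_year=small_survey.survey_year,
        )
        for ind in INDICATORS:
            a = it.compute_observation(small_survey, ind, (30, 35))
            b = it.compute_observation(shuffled, ind, (30, 35))
            assert a.value == b.value and a.raw_denominator == b.raw_denominator

    def test_monotonicity(self):
        records = [woman() for _ in range(3)] + [
            woman(n_live_births=1, years_since_first_birth=3.0, years_since_last_birth=3.0)
            for _ in range(40)
        ]
        base = it.compute_observation(make_dataset(records), "primary_prev", (25, 30)).value
        more_inf = it.compute_observation(
            make_dataset(records + [woman()]), "primary_prev", (25, 30)
        ).value
        more_fert = it.compute_observation(
            make_dataset(records + [woman(n_live_births=1, years_since_first_birth=2.0,
                                          years_since_last_birth=2.0)]),
            "primary_prev",
            (25, 30),
        ).value
        assert more_inf >= base >= more_fert

    def test_partition_of_statuses(self, small_survey):
        for ind in ("primary_prev", "secondary_prev"):
            counts = {"infertile_union": 0, "fertile_union": 0, "excluded": 0}
            for rec in small_survey.records:
                counts[it.classify_woman(rec, ind).status] += 1
            assert sum(counts.values()) == len(small_survey.records)

    def test_biased_flag_follows_design(self, surface, hierarchy):
        ds = it.generate_survey(
            surface, hierarchy.countries[0], 2000, 2000,
            design=it.SurveyDesign(has_contraceptive_history=False), seed=0,
        )
        obs = it.compute_observation(ds, "primary_prev", (25, 30))
        assert obs.is_biased
        exp = it.compute_observation(ds, "primary_exposure", (25, 30))
        assert not exp.is_biased

    def test_weighted_option(self):
        records = [woman(survey_weight=2.0), woman(survey_weight=1.0)] + [
            woman(n_live_births=1, years_since_first_birth=3.0, years_since_last_birth=3.0,
                  survey_weight=1.0)
            for _ in range(7)
        ]
        obs = it.compute_observation(make_dataset(records), "primary_prev", (25, 30),
                                     weighted=True)
        assert obs.value == pytest.approx(3.0 / 10.0)


class TestScreenSurvey:
    def _survey_with_missing(self, share, n=100):
        n_missing = int(round(share * n))
        records = [woman(desire=None) for _ in range(n_missing)] + [
            woman() for _ in range(n - n_missing)
        ]
        return make_dataset(records)

    def test_sixteen_percent_excluded(self):
        dec = it.screen_survey(self._survey_with_missing(0.16), "primary_prev")
        assert not dec.included
        assert dec.reason == "missingness"

    def test_fifteen_percent_included_strict_boundary(self):
        dec = it.screen_survey(self._survey_with_missing(0.15), "primary_prev")
        assert dec.included

    def test_ever_married_age_mask(self, surface, hierarchy):
        ds = it.generate_survey(
            surface, hierarchy.countries[0], 2000, 500,
            design=it.SurveyDesign(ever_married_only=True), seed=1,
        )
        dec = it.screen_survey(ds, "primary_exposure")
        assert (20, 25) not in dec.usable_age_groups
        assert (25, 30) not in dec.usable_age_groups
        assert (30, 35) in dec.usable_age_groups
        # prevalence indicators keep all age groups
        dec_prev = it.screen_survey(ds, "primary_prev")
        assert dec_prev.usable_age_groups == AGE_GROUPS

    def test_china_rule(self):
        ds = make_dataset([woman() for _ in range(10)], country_id="CHN")
        for ind in ("secondary_prev", "secondary_exposure"):
            dec = it.screen_survey(ds, ind, china_countries={"CHN"})
            assert not dec.included and dec.reason == "china_rule"
        assert it.screen_survey(ds, "primary_prev", china_countries={"CHN"}).included

    def test_extract_observations_logs(self, survey_datasets):
        obs, log = it.extract_observations(survey_datasets[:4])
        assert len(obs) > 0
        assert {"country", "year", "indicator", "included", "reason"} <= set(log.columns)
        frame = observations_to_frame(obs)
        assert (frame["value"] >= 0).all() and (frame["value"] <= 1).all()
        assert (frame["effective_n"] <= frame["raw_denominator"]).all()


def test_contraceptive_prevalence(small_survey):
    cp = contraceptive_prevalence(small_survey)
    manual = np.mean(
        [
            bool(r.current_contraception)
            for r in small_survey.records
            if 20 <= r.age_years < 45 and r.current_contraception is not None
        ]
    )
    assert cp == pytest.approx(manual)
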