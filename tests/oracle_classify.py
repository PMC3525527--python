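"""Brute-force classification oracle, written as a literal transcription of
the indicator definitions as flat boolean predicates.

Deliberately independent of the package's decision-tree implementation:
every predicate is evaluated eagerly from the record's fields, with the same
fallback conventions (current-union clock preferred, current contraceptive
status when the 5-year history is unavailable) and missing-field handling
(a predicate that cannot be evaluated makes the record 'excluded:
missing_data' for prevalence, or excluded for exposure, unless the status is
already decided by predicates that could be evaluated).
"""

UNKNOWN = object()


def _desires(rec):
    if rec.desire is None:
        return UNKNOWN
    return rec.desire in ("wants_child", "undecided", "declared_unable")


def _union_years(rec, full):
    if full and rec.years_in_current_union is not None:
        return rec.years_in_current_union
    if rec.years_since_first_union is not None:
        return rec.years_since_first_union
    return UNKNOWN


def _no_contra_5y(rec, full):
    if full and rec.contraception_last_5y is not None:
        return not rec.contraception_last_5y
    if rec.current_contraception is not None:
        return not rec.current_contraception
    return UNKNOWN


def _and(*values):
    """Three-valued conjunction: False dominates UNKNOWN."""
    if any(v is False for v in values):
        return False
    if any(v is UNKNOWN for v in values):
        return UNKNOWN
    return True


def oracle_primary_prev(rec, full=True):
    if rec.in_union is None:
        return "excluded"
    u5 = UNKNOWN if _union_years(rec, full) is UNKNOWN else _union_years(rec, full) >= 5
    infertile = _and(
        rec.in_union,
        rec.n_live_births == 0,
        u5,
        _no_contra_5y(rec, full),
        _desires(rec),
    )
    fertile = _and(rec.in_union, rec.n_live_births >= 1, u5)
    if infertile is True:
        return "infertile_union"
    if fertile is True:
        return "fertile_union"
    if infertile is UNKNOWN or fertile is UNKNOWN:
        return "excluded"  # missing data
    return "excluded"


def oracle_secondary_prev(rec, full=True):
    if rec.in_union is None:
        return "excluded"
    uy = _union_years(rec, full)
    u5 = UNKNOWN if uy is UNKNOWN else uy >= 5
    ysl = rec.years_since_last_birth
    ysf = rec.years_since_first_birth
    last5 = UNKNOWN if ysl is None else ysl >= 5
    recent = UNKNOWN if ysl is None else ysl < 5
    first5 = UNKNOWN if ysf is None else ysf >= 5
    infertile = _and(
        rec.in_union,
        rec.n_live_births >= 1,
        last5,
        u5,
        _no_contra_5y(rec, full),
        _desires(rec),
    )
    fertile = _and(rec.in_union, rec.n_live_births >= 1, recent, first5, u5)
    if infertile is True:
        return "infertile_union"
    if fertile is True:
        return "fertile_union"
    return "excluded"


def oracle_primary_exposure(rec):
    if rec.in_union is None:
        return "excluded"
    nc = (
        UNKNOWN
        if rec.current_contraception is None
        else not rec.current_contraception
    )
    branch1 = _and(rec.in_union, nc, _desires(rec))
    branch2 = _and(rec.in_union, rec.n_live_births >= 1)
    if branch1 is True or branch2 is True:
        return "exposed"
    if branch1 is UNKNOWN or branch2 is UNKNOWN:
        return "excluded"
    return "not_exposed"


def oracle_secondary_exposure(rec):
    if rec.in_union is None:
        return "excluded"
    nc = (
        UNKNOWN
        if rec.current_contraception is None
        else not rec.current_contraception
    )
    branch1 = _and(rec.n_live_births >= 1, rec.in_union, nc, _desires(rec))
    additional_recent = (
        UNKNOWN
        if (rec.n_live_births >= 2 and rec.years_since_last_birth is None)
        else rec.n_live_births >= 2
        and rec.years_since_last_birth is not None
        and rec.years_since_last_birth < 5
    )
    branch2 = _and(rec.in_union, additional_recent)
    if branch1 is True or branch2 is True:
        return "exposed"
    if branch1 is UNKNOWN or branch2 is UNKNOWN:
        return "excluded"
    return "not_exposed"


def oracle_status(rec, indicator, full=True):
    if indicator == "primary_prev":
        return oracle_primary_prev(rec, full)
    if indicator == "secondary_prev":
        return oracle_secondary_prev(rec, full)
    if indicator == "primary_exposure":
        return oracle_primary_exposure(rec)
    if indicator == "secondary_exposure":
        return oracle_secondary_exposure(rec)
    raise ValueError(indicator)
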