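"""Bayesian hierarchical space-time-age model, one fit per indicator.

Likelihood (logit scale, per observation i):

    y_i ~ Normal(mu_i, v_i + sigma_extra(i)^2)

with v_i the known sampling + correction variance and sigma_extra one of two
estimated components (national vs subnational sources).  Linear predictor:

    mu_i = a_country(i) + b_region(i) * t_i + gamma * educ_i + age_offset_i

where t is in decades centred at 2000, country intercepts are nested
Normal deviations through subregion, region and global levels, region slopes
are Normal deviations around a global slope, age offsets are indicator
variables (reference group 20-24), and exposure to primary infertility gets
an extra age-offset set in the High-Income region.

Everything is conditionally conjugate in the location parameters, so the
sampler is a blocked Gibbs scheme; standard-deviation components get
stepping-out slice updates on the log scale (Half-Normal priors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUPS,
    N_AGE_GROUPS,
    YEAR_MAX,
    YEAR_MIN,
    YEARS,
    age_group_index,
)
from .extraction import PrevalenceObservation
from .simulate import ContextTables, HierarchySpec

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ModelInput",
    "Posterior",
    "ConvergenceError",
    "assemble_inputs",
    "fit_model",
    "predict_prevalence",
]


class ConvergenceError(RuntimeError):
    """Raised (under strict mode) when chains fail the R-hat criterion."""


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

@dataclass
class ModelInput:
    """One transformed observation on the analysis scale."""

    indicator: str
    country_id: str
    year: int
    age_group: tuple[int, int]
    y: float
    variance: float
    is_national: bool
    #: retained so the sampling variance can be re-evaluated at model-
    #: predicted prevalences during fitting (see fit_model)
    effective_n: float = 0.0
    correction_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be > 0")


def assemble_inputs(
    observations: list[PrevalenceObservation], link: str = "logit"
) -> list[ModelInput]:
    """Transform observations to the analysis scale with their sampling
    variances.

    Observations carrying raw counts use the empirical logit,
    y = ln((x + 1/2) / (n - x + 1/2)), with sampling variance
    (1/(x + 1/2) + 1/(n - x + 1/2)) inflated by the design effect
    n / effective_n; this continuity-corrects zeros/ones by construction
    (equivalent to adding half a success and half a failure) and is nearly
    unbiased at small counts, where the plain delta method is not.
    Bias-corrected observations, whose value is a regression prediction
    rather than a count ratio, use the delta-method form
    var ~= 1 / (effective_n * p * (1 - p)) at the (continuity-corrected)
    corrected value.  Correction variance (already on the logit scale) adds
    to the sampling variance.
    """
    if link != "logit":
        raise ValueError(f"unsupported link {link!r}")
    out = []
    for obs in observations:
        if obs.effective_n <= 0:
            raise ValueError("effective_n must be positive")
        p = obs.value
        den = obs.raw_denominator if obs.raw_denominator > 0 else obs.effective_n
        raw_ratio = den > 0 and abs(p - obs.raw_numerator / den) < 1e-12
        if raw_ratio:
            x = obs.raw_numerator
            y = float(np.log((x + 0.5) / (den - x + 0.5)))
            var_sampling = (1.0 / (x + 0.5) + 1.0 / (den - x + 0.5)) * (
                den / obs.effective_n
            )
        else:
            if p <= 0.0:
                p = 0.5 / den
            elif p >= 1.0:
                p = 1.0 - 0.5 / den
            y = float(_logit(p))
            var_sampling = 1.0 / (obs.effective_n * p * (1.0 - p))
        out.append(
            ModelInput(
                indicator=obs.indicator,
                country_id=obs.country_id,
                year=obs.survey_year,
                age_group=obs.age_group,
                y=y,
                variance=float(var_sampling + obs.correction_variance),
                is_national=obs.is_national,
                effective_n=float(obs.effective_n),
                correction_variance=float(obs.correction_variance),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Weakly informative defaults; all scales on the logit scale."""

    fixed_effect_sd: float = 2.0
    sd_scale_country: float = 1.0
    sd_scale_subregion: float = 1.0
    sd_scale_region: float = 1.0
    sd_scale_slope: float = 0.5
    sd_scale_national: float = 0.5
    sd_scale_subnational: float = 1.0


#: names of clampable standard-deviation components
_SD_COMPONENTS = (
    "tau_country",
    "tau_subregion",
    "tau_region",
    "tau_slope",
    "sigma_national",
    "sigma_subnational",
)


@dataclass
class ModelSpec:
    hierarchy: HierarchySpec
    context: ContextTables | None = None
    use_education: bool = True
    priors: PriorConfig = field(default_factory=PriorConfig)
    #: clamp named sd components to fixed values (skips their updates);
    #: mainly for degenerate/oracle tests
    fixed_sds: dict[str, float] = field(default_factory=dict)
    high_income_age_offsets: bool = True
    rhat_limit: float = 1.05

    def __post_init__(self) -> None:
        for k in self.fixed_sds:
            if k not in _SD_COMPONENTS:
                raise ValueError(f"unknown sd component {k!r}")

    @property
    def has_education(self) -> bool:
        return self.use_education and self.context is not None


# ---------------------------------------------------------------------------
# Slice sampler (univariate, stepping out + shrinkage)
# ---------------------------------------------------------------------------

def _slice_sample(x0, logpdf, rng, w=1.0, max_steps=50):
    logy = logpdf(x0) + np.log(rng.uniform())
    u = rng.uniform() * w
    lo, hi = x0 - u, x0 + (w - u)
    steps = max_steps
    while steps > 0 and logpdf(lo) > logy:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logpdf(hi) > logy:
        hi += w
        steps -= 1
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class Posterior:
    """Retained MCMC draws for one indicator plus prediction machinery."""

    indicator: str
    hierarchy: HierarchySpec
    spec: ModelSpec
    draws: dict[str, np.ndarray]
    n_chains: int
    diagnostics: pd.DataFrame
    converged: bool

    @property
    def n_draws(self) -> int:
        return self.draws["mu0"].shape[0]

    def _educ_z(self, country: str, year: int) -> float:
        if not self.spec.has_education:
            return 0.0
        return self.spec.context.education_z(country, year)

    def _mu(self, country: str, year: float, age_group) -> np.ndarray:
        h = self.hierarchy
        ci = h.countries.index(country)
        ri = h.regions.index(h.region_of(country))
        ai = age_group_index(age_group)
        t = (year - 2000.0) / 10.0
        mu = self.draws["a_country"][:, ci] + self.draws["b_region"][:, ri] * t
        if self.spec.has_education:
            mu = mu + self.draws["gamma"] * self._educ_z(country, int(year))
        if ai > 0:
            mu = mu + self.draws["delta_age"][:, ai - 1]
        if (
            self.indicator == "primary_exposure"
            and self.spec.high_income_age_offsets
            and h.is_high_income(country)
            and ai > 0
        ):
            mu = mu + self.draws["delta_age_hi"][:, ai - 1]
        return mu

    def predict(self, country: str, year: int, age_group) -> np.ndarray:
        """Draw vector of predicted prevalence for one cell (1990-2010)."""
        if not YEAR_MIN <= year <= YEAR_MAX:
            raise ValueError(f"year {year} outside estimation window")
        age_group_index(age_group)  # validates
        return _expit(self._mu(country, year, age_group))

    def predict_grid(self, countries=None) -> np.ndarray:
        """(n_draws, n_countries, n_years, n_age_groups) prevalence array."""
        countries = list(countries or self.hierarchy.countries)
        out = np.empty((self.n_draws, len(countries), len(YEARS), N_AGE_GROUPS))
        for ci, c in enumerate(countries):
            for yi, year in enumerate(YEARS):
                base = self._mu(c, year, AGE_GROUPS[0])
                for ai in range(N_AGE_GROUPS):
                    mu = base if ai == 0 else self._mu(c, year, AGE_GROUPS[ai])
                    out[:, ci, yi, ai] = _expit(mu)
        return out


def predict_prevalence(posterior: Posterior, indicator: str, country: str, year: int, age_group):
    """Functional wrapper around :meth:`Posterior.predict`."""
    if indicator != posterior.indicator:
        raise ValueError(
            f"posterior is for {posterior.indicator!r}, not {indicator!r}"
        )
    return posterior.predict(country, year, age_group)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _prepare_design(inputs: list[ModelInput], spec: ModelSpec, indicator: str):
    h = spec.hierarchy
    countries = list(h.countries)
    subregions = list(h.subregions)
    regions = list(h.regions)
    c_index = {c: i for i, c in enumerate(countries)}
    s_index = {s: i for i, s in enumerate(subregions)}
    r_index = {r: i for i, r in enumerate(regions)}

    sub_of_country = np.array([s_index[h.subregion_of(c)] for c in countries])
    reg_of_sub = np.array([r_index[h.subregion_to_region[s]] for s in subregions])
    reg_of_country = reg_of_sub[sub_of_country]

    n = len(inputs)
    c_idx = np.empty(n, dtype=int)
    t = np.empty(n)
    y = np.empty(n)
    v = np.empty(n)
    nat = np.empty(n, dtype=bool)
    age_idx = np.empty(n, dtype=int)
    educ = np.zeros(n)
    for i, obs in enumerate(inputs):
        if obs.indicator != indicator:
            raise ValueError("mixed indicators in model inputs")
        if obs.country_id not in c_index:
            raise ValueError(f"country {obs.country_id!r} not in hierarchy")
        c_idx[i] = c_index[obs.country_id]
        t[i] = (obs.year - 2000.0) / 10.0
        y[i] = obs.y
        v[i] = obs.variance
        nat[i] = obs.is_national
        age_idx[i] = age_group_index(obs.age_group)
        if spec.has_education:
            educ[i] = spec.context.education_z(obs.country_id, obs.year)

    r_idx = reg_of_country[c_idx]

    hi_region = np.zeros(len(countries), dtype=bool)
    if spec.high_income_age_offsets and indicator == "primary_exposure":
        hi_region = np.array([h.is_high_income(c) for c in countries])
    hi_obs = hi_region[c_idx]

    # fixed-effect block: education + age dummies (+ HI age dummies)
    cols = []
    names = []
    if spec.has_education:
        cols.append(educ)
        names.append("gamma")
    for a in range(1, N_AGE_GROUPS):
        cols.append((age_idx == a).astype(float))
        names.append(f"delta_age_{a}")
    use_hi = hi_region.any()
    if use_hi:
        for a in range(1, N_AGE_GROUPS):
            cols.append(((age_idx == a) & hi_obs).astype(float))
            names.append(f"delta_age_hi_{a}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    return {
        "countries": countries,
        "subregions": subregions,
        "regions": regions,
        "sub_of_country": sub_of_country,
        "reg_of_sub": reg_of_sub,
        "reg_of_country": reg_of_country,
        "c_idx": c_idx,
        "r_idx": r_idx,
        "t": t,
        "y": y,
        "v": v,
        "nat": nat,
        "X": X,
        "block_names": names,
        "use_hi": use_hi,
        "has_educ": spec.has_education,
    }


def _run_chain(design, spec: ModelSpec, n_keep: int, n_warmup: int, thin: int, rng):
    """One MCMC chain.

    Given the variance components the model is jointly Gaussian, so all
    location parameters (country/subregion/region/global intercepts, region
    and global slopes, education and age effects) are drawn in a single
    exact multivariate-normal update from their full conditional; this
    avoids the slow mixing that one-at-a-time updates suffer along the
    correlated intercept/trend/covariate directions.  The six
    standard-deviation components then get slice updates.
    """
    pr = spec.priors
    C = len(design["countries"])
    S = len(design["subregions"])
    R = len(design["regions"])
    y, v, t, X = design["y"], design["v"], design["t"], design["X"]
    c_idx, r_idx, nat = design["c_idx"], design["r_idx"], design["nat"]
    sub_of_country, reg_of_sub = design["sub_of_country"], design["reg_of_sub"]
    n_obs = len(y)
    k = X.shape[1]

    fixed = spec.fixed_sds

    # -- parameter layout of the joint location vector ---------------------
    i_c = np.arange(C)
    i_s = C + np.arange(S)
    i_r = C + S + np.arange(R)
    i_mu0 = C + S + R
    i_b = i_mu0 + 1 + np.arange(R)
    i_bg = i_mu0 + 1 + R
    i_blk = i_bg + 1 + np.arange(k)
    m = i_bg + 1 + k

    # fixed design matrix A: y ~ N(A theta, V)
    A = np.zeros((n_obs, m))
    A[np.arange(n_obs), i_c[c_idx]] = 1.0
    A[np.arange(n_obs), i_b[r_idx]] = t
    if k:
        A[:, i_blk] = X

    # Gaussian-chain prior: list of (child, parent, sd-name) differences
    pairs = (
        [(i_c[c], i_s[sub_of_country[c]], "tau_country") for c in range(C)]
        + [(i_s[s], i_r[reg_of_sub[s]], "tau_subregion") for s in range(S)]
        + [(i_r[r], i_mu0, "tau_region") for r in range(R)]
        + [(i_b[r], i_bg, "tau_slope") for r in range(R)]
    )
    prior_prec_fixed = 1.0 / pr.fixed_effect_sd**2

    state = {
        "theta": np.zeros(m),
        "tau_country": fixed.get("tau_country", 0.3),
        "tau_subregion": fixed.get("tau_subregion", 0.3),
        "tau_region": fixed.get("tau_region", 0.3),
        "tau_slope": fixed.get("tau_slope", 0.1),
        "sigma_national": fixed.get("sigma_national", 0.1),
        "sigma_subnational": fixed.get("sigma_subnational", 0.2),
    }

    kept = {
        "mu0": np.empty(n_keep),
        "beta_g": np.empty(n_keep),
        "a_region": np.empty((n_keep, R)),
        "a_subregion": np.empty((n_keep, S)),
        "a_country": np.empty((n_keep, C)),
        "b_region": np.empty((n_keep, R)),
        "theta": np.empty((n_keep, k)),
        "tau_country": np.empty(n_keep),
        "tau_subregion": np.empty(n_keep),
        "tau_region": np.empty(n_keep),
        "tau_slope": np.empty(n_keep),
        "sigma_national": np.empty(n_keep),
        "sigma_subnational": np.empty(n_keep),
    }

    def total_var():
        sig = np.where(nat, state["sigma_national"], state["sigma_subnational"])
        return v + sig**2

    tau_prior_scale = {
        "tau_country": pr.sd_scale_country,
        "tau_subregion": pr.sd_scale_subregion,
        "tau_region": pr.sd_scale_region,
        "tau_slope": pr.sd_scale_slope,
    }
    _TAU_FLOOR = 1e-4

    def build_P() -> np.ndarray:
        P = np.zeros((m, m))
        for child, parent, name in pairs:
            q = 1.0 / max(state[name], _TAU_FLOOR) ** 2
            P[child, child] += q
            P[parent, parent] += q
            P[child, parent] -= q
            P[parent, child] -= q
        P[i_mu0, i_mu0] += prior_prec_fixed
        P[i_bg, i_bg] += prior_prec_fixed
        if k:
            P[i_blk, i_blk] += prior_prec_fixed
        return P

    n_iter = n_warmup + n_keep * thin
    for it in range(n_iter):
        w = 1.0 / total_var()
        AtWA = (A * w[:, None]).T @ A
        b = A.T @ (w * y)

        # ---- hierarchy sd components: collapsed slice updates -----------
        # The location vector is integrated out analytically, so these
        # draws come from the marginal posterior of each sd given the data
        # and the other components; this sidesteps the funnel that cripples
        # conditional updates when a variance is small.
        def marginal_logpost(name, scale):
            def lp(logsd):
                state[name] = float(np.exp(logsd))
                P = build_P()
                Q = AtWA + P
                try:
                    cP = np.linalg.cholesky(P)
                    cQ = np.linalg.cholesky(Q)
                except np.linalg.LinAlgError:
                    return -np.inf
                logdetP = 2.0 * np.sum(np.log(np.diag(cP)))
                logdetQ = 2.0 * np.sum(np.log(np.diag(cQ)))
                u = np.linalg.solve(cQ, b)
                marg = 0.5 * (logdetP - logdetQ + u @ u)
                sd2 = np.exp(2.0 * logsd)
                return marg - 0.5 * sd2 / scale**2 + logsd

            return lp

        for name, scale in tau_prior_scale.items():
            if name in fixed:
                continue
            lp = marginal_logpost(name, scale)
            cur = np.log(state[name])
            state[name] = float(np.exp(_slice_sample(cur, lp, rng)))

        # ---- joint draw of all location parameters ----------------------
        Q = AtWA + build_P()
        L = np.linalg.cholesky(Q)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(m))
        state["theta"] = theta

        a_country = theta[i_c]
        a_subregion = theta[i_s]
        a_region = theta[i_r]
        b_region = theta[i_b]

        # ---- observation-level extra sds: conditional slice updates -----
        mu = A @ theta
        sq = (y - mu) ** 2
        for name, mask, scale in (
            ("sigma_national", nat, pr.sd_scale_national),
            ("sigma_subnational", ~nat, pr.sd_scale_subnational),
        ):
            if name in fixed or not mask.any():
                continue
            vm, sqm = v[mask], sq[mask]

            def lp(logsd, vm=vm, sqm=sqm, scale=scale):
                tot = vm + np.exp(2.0 * logsd)
                return (
                    -0.5 * float(np.sum(np.log(tot) + sqm / tot))
                    - 0.5 * np.exp(2.0 * logsd) / scale**2
                    + logsd
                )

            state[name] = float(np.exp(_slice_sample(np.log(state[name]), lp, rng)))

        if it >= n_warmup and (it - n_warmup) % thin == 0:
            j = (it - n_warmup) // thin
            kept["mu0"][j] = theta[i_mu0]
            kept["beta_g"][j] = theta[i_bg]
            kept["a_region"][j] = a_region
            kept["a_subregion"][j] = a_subregion
            kept["a_country"][j] = a_country
            kept["b_region"][j] = b_region
            kept["theta"][j] = theta[i_blk]
            for key in ("tau_country", "tau_subregion", "tau_region",
                        "tau_slope", "sigma_national", "sigma_subnational"):
                kept[key][j] = state[key]

    return kept


def fit_model(
    inputs: list[ModelInput],
    spec: ModelSpec,
    indicator: str,
    seed: int = 0,
    n_retained: int = 1600,
    n_chains: int = 4,
    n_warmup: int = 500,
    thin: int = 1,
    strict: bool = False,
    refine_variance: bool = True,
) -> Posterior:
    """Fit the hierarchical model for one indicator by blocked Gibbs MCMC.

    ``n_retained`` draws are kept in total across ``n_chains`` chains after
    discarding ``n_warmup`` iterations per chain.  Convergence is declared
    when the split potential-scale-reduction factor of every monitored
    parameter is below ``spec.rhat_limit``; failure raises
    :class:`ConvergenceError` under ``strict`` and otherwise emits a warning
    recorded in the diagnostics table.

    ``refine_variance`` runs a short pilot fit and re-evaluates each
    observation's binomial sampling variance at the pilot's predicted
    prevalence instead of at the noisy observed proportion.  Evaluating the
    variance at the observed count makes randomly high cells look more
    precise and randomly low ones less so, which tilts the precision-
    weighted fit upward; the refinement removes that endogeneity.
    """
    if not inputs:
        raise ValueError("need at least one observation for the indicator")
    if n_retained % n_chains:
        raise ValueError("n_retained must be divisible by n_chains")

    if refine_variance and all(o.effective_n > 0 for o in inputs):
        pilot = fit_model(
            inputs, spec, indicator, seed=seed + 77,
            n_retained=400, n_chains=2, n_warmup=max(200, n_warmup // 2),
            thin=1, strict=False, refine_variance=False,
        )
        refined = []
        for o in inputs:
            p_hat = float(
                np.clip(pilot._mu(o.country_id, o.year, o.age_group).mean(), -10, 10)
            )
            p_hat = float(_expit(p_hat))
            var = 1.0 / (o.effective_n * p_hat * (1.0 - p_hat)) + o.correction_variance
            refined.append(
                ModelInput(
                    indicator=o.indicator, country_id=o.country_id, year=o.year,
                    age_group=o.age_group, y=o.y, variance=var,
                    is_national=o.is_national, effective_n=o.effective_n,
                    correction_variance=o.correction_variance,
                )
            )
        inputs = refined

    design = _prepare_design(inputs, spec, indicator)
    n_keep = n_retained // n_chains

    root = np.random.SeedSequence(seed)
    chains = [
        _run_chain(design, spec, n_keep, n_warmup, thin, np.random.default_rng(s))
        for s in root.spawn(n_chains)
    ]

    draws: dict[str, np.ndarray] = {}
    for key in chains[0]:
        draws[key] = np.concatenate([ch[key] for ch in chains], axis=0)

    # unpack the fixed-effect block into named arrays
    names = design["block_names"]
    theta = draws.pop("theta")
    if design["has_educ"]:
        draws["gamma"] = theta[:, names.index("gamma")]
    else:
        draws["gamma"] = np.zeros(theta.shape[0])
    da = np.zeros((theta.shape[0], N_AGE_GROUPS - 1))
    for a in range(1, N_AGE_GROUPS):
        nm = f"delta_age_{a}"
        if nm in names:
            da[:, a - 1] = theta[:, names.index(nm)]
    draws["delta_age"] = da
    dh = np.zeros((theta.shape[0], N_AGE_GROUPS - 1))
    if design["use_hi"]:
        for a in range(1, N_AGE_GROUPS):
            dh[:, a - 1] = theta[:, names.index(f"delta_age_hi_{a}")]
    draws["delta_age_hi"] = dh

    diagnostics = _diagnose(chains, design, n_chains, n_keep)
    max_rhat = float(diagnostics["rhat"].max())
    converged = bool(max_rhat < spec.rhat_limit)
    if not converged:
        msg = (
            f"MCMC for {indicator!r} failed convergence: max R-hat "
            f"{max_rhat:.3f} >= {spec.rhat_limit}"
        )
        if strict:
            raise ConvergenceError(msg)
        warnings.warn(msg, stacklevel=2)

    return Posterior(
        indicator=indicator,
        hierarchy=spec.hierarchy,
        spec=spec,
        draws=draws,
        n_chains=n_chains,
        diagnostics=diagnostics,
        converged=converged,
    )


def _diagnose(chains, design, n_chains: int, n_keep: int) -> pd.DataFrame:
    import arviz as az

    monitored: dict[str, np.ndarray] = {}
    for key in ("mu0", "beta_g", "tau_country", "tau_subregion", "tau_region",
                "tau_slope", "sigma_national", "sigma_subnational"):
        monitored[key] = np.stack([ch[key] for ch in chains])
    theta = np.stack([ch["theta"] for ch in chains])  # (chain, draw, k)
    for j, nm in enumerate(design["block_names"]):
        monitored[nm] = theta[:, :, j]
    br = np.stack([ch["b_region"] for ch in chains])
    for ri, region in enumerate(design["regions"]):
        monitored[f"b_region_{region}"] = br[:, :, ri]
    ac = np.stack([ch["a_country"] for ch in chains])
    # monitor a handful of country intercepts (first, middle, last)
    for ci in sorted({0, ac.shape[2] // 2, ac.shape[2] - 1}):
        monitored[f"a_country_{design['countries'][ci]}"] = ac[:, :, ci]

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in monitored.items():
            if np.allclose(arr.std(), 0.0):  # clamped or degenerate
                rhat, ess = 1.0, float(arr.size)
            else:
                rhat = float(az.rhat(arr))
                ess = float(az.ess(arr))
            rows.append({"parameter": name, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows)
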