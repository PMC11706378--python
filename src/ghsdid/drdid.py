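"""Doubly-robust difference-in-differences estimation on the coverage panel.

The estimand is the average treatment effect on the treated (ATT) of
crossing a health-security score cutoff, on childhood immunization coverage
measured in percentage points. For a (base year, target year) pair the
estimator combines

* an inverse-probability-of-treatment weight built from a logistic
  propensity model on the categorical covariates (income group, WHO region),
  and
* an outcome-regression adjustment: a least-squares model of the coverage
  change ``dY = Y_target - Y_base`` fitted among controls,

so the ATT estimate is consistent if either model is correctly specified:

    ATT = E_w1[dY - mu(X)] - E_w0[dY - mu(X)],

with ``w1`` uniform over treated units and ``w0`` proportional to
``p(X)/(1-p(X))`` over controls. Standard errors come from the estimator's
asymptotic linear (influence-function) representation, including the
first-step corrections for the estimated propensity and outcome models,
aggregated to country clusters.

Analysis units default to country-vaccine series (12 per country) with all
variance clustered at the country level; a country-mean unit is available as
an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import EstimationError, ValidationError
from .panel_io import Panel
from .scores import TreatmentAssignment

logger = logging.getLogger(__name__)

#: propensity scores are clipped into this interval
PS_CLIP = (0.001, 0.999)

#: default covariates entering both working models
DEFAULT_COVARIATES = ("income_group", "who_region")

_Z95 = 1.959963984540054  # normal 97.5% quantile


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class UnitDesign:
    """Analysis units prepared for 2x2 fits.

    ``Y`` is units x years (NaN = missing), ``X`` the dummy design with a
    leading intercept column (reference level = alphabetically first per
    factor), ``cluster`` integer country codes per unit.
    """

    Y: np.ndarray
    years: tuple[int, ...]
    d: np.ndarray
    X: np.ndarray
    cluster: np.ndarray
    cluster_ids: tuple[str, ...]
    columns: tuple[str, ...]

    @property
    def n_units(self) -> int:
        return len(self.d)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise ValidationError(f"year {year} is outside the panel window {self.years}")


def dummy_design(covariates: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    """Expand categorical covariates to an intercept + dummy matrix.

    Levels are sorted alphabetically and the first is the reference.
    """
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names: list[str] = ["intercept"]
    for cov in covariates.columns:
        levels = sorted(covariates[cov].astype(str).unique())
        for level in levels[1:]:
            cols.append((covariates[cov].astype(str) == level).to_numpy(float))
            names.append(f"{cov}[{level}]")
    return np.column_stack(cols), tuple(names)


def build_design(
    panel: Panel,
    assignment: TreatmentAssignment,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    unit: str = "country-vaccine",
) -> UnitDesign:
    """Pivot the panel into per-unit year series with treatment and dummies."""
    obs = panel.observations
    assigned = assignment.treated | assignment.control
    obs = obs[obs["iso3"].isin(assigned)]
    if obs.empty:
        raise EstimationError("no panel observations for the assigned countries")

    if unit == "country-mean":
        series = (
            obs[~obs["is_missing"]]
            .groupby(["iso3", "year"])["coverage"]
            .mean()
            .reset_index()
        )
        series["unit_key"] = series["iso3"]
    elif unit == "country-vaccine":
        series = obs[~obs["is_missing"]].copy()
        series["unit_key"] = series["iso3"] + ":" + series["vaccine"]
    else:
        raise ValidationError(f"unknown analysis unit {unit!r}")

    wide = series.pivot(index="unit_key", columns="year", values="coverage")
    years = tuple(int(y) for y in sorted(wide.columns))
    wide = wide[list(years)]
    iso3 = pd.Series(wide.index.str.split(":").str[0], index=wide.index)

    attrs = panel.attributes.set_index("iso3")
    missing_attr = [c for c in covariates if c not in attrs.columns]
    if missing_attr:
        raise ValidationError(f"attribute table lacks covariate columns {missing_attr}")
    X, columns = dummy_design(attrs.loc[iso3, list(covariates)]) if covariates else (
        np.ones((len(wide), 1)),
        ("intercept",),
    )

    cluster_ids = tuple(sorted(iso3.unique()))
    cluster_code = {c: k for k, c in enumerate(cluster_ids)}
    return UnitDesign(
        Y=wide.to_numpy(float),
        years=years,
        d=iso3.isin(assignment.treated).to_numpy(),
        X=X,
        cluster=iso3.map(cluster_code).to_numpy(int),
        cluster_ids=cluster_ids,
        columns=columns,
    )


# ---------------------------------------------------------------------------
# working models
# ---------------------------------------------------------------------------


@dataclass
class PropensityFit:
    """Fitted treatment probabilities, clipped into PS_CLIP."""

    ps: np.ndarray
    converged: bool
    n_clipped: int


def _fit_ps_arrays(X: np.ndarray, d: np.ndarray) -> PropensityFit:
    if d.all() or not d.any():
        raise EstimationError("propensity model needs both treated and control units")
    if X.shape[1] == 1:  # intercept only: closed form
        raw = np.full(len(d), d.mean())
    else:
        # mild L2 stabilisation keeps cells without treated units finite
        # (quasi-separation) instead of failing; their propensities land
        # below the clip bound.
        model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[:, 1:], d)
        converged = model.n_iter_[0] < model.max_iter
        raw = model.predict_proba(X[:, 1:])[:, 1]
        ps = np.clip(raw, *PS_CLIP)
        if not np.isfinite(raw).all():
            raise EstimationError("propensity model produced non-finite probabilities")
        return PropensityFit(ps=ps, converged=bool(converged), n_clipped=int((raw != ps).sum()))
    ps = np.clip(raw, *PS_CLIP)
    return PropensityFit(ps=ps, converged=True, n_clipped=int((raw != ps).sum()))


def fit_propensity(covariates: pd.DataFrame, treated: Sequence[bool]) -> PropensityFit:
    """Fit the logistic propensity model on categorical covariates.

    Probabilities are clipped to [0.001, 0.999]; covariate cells with no
    treated units yield clipped near-zero propensities rather than failure.
    """
    X, _ = dummy_design(covariates)
    return _fit_ps_arrays(X, np.asarray(treated, bool))


def fit_outcome_delta(
    covariates: pd.DataFrame, delta_y: Sequence[float]
) -> "OutcomeDeltaFit":
    """Least-squares fit of the outcome change on dummies, among controls.

    Returns a fit whose :meth:`OutcomeDeltaFit.predict` evaluates the model
    for any units sharing the covariate scheme (treated included).
    """
    X, columns = dummy_design(covariates)
    dy = np.asarray(delta_y, float)
    if len(dy) < X.shape[1]:
        raise EstimationError(
            f"need at least {X.shape[1]} control units to fit {X.shape[1]} coefficients"
        )
    beta, rank = _ols(X, dy)
    return OutcomeDeltaFit(beta=beta, columns=columns, rank=rank)


@dataclass
class OutcomeDeltaFit:
    beta: np.ndarray
    columns: tuple[str, ...]
    rank: int

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X, columns = dummy_design(covariates)
        if columns != self.columns:
            raise ValidationError("covariate scheme differs from the fitted design")
        return X @ self.beta


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "outcome-delta design is rank deficient (%d < %d); aliased columns "
            "resolved by the minimum-norm solution",
            rank,
            X.shape[1],
        )
    return beta, int(rank)


# ---------------------------------------------------------------------------
# 2x2 doubly-robust ATT
# ---------------------------------------------------------------------------


@dataclass
class AttEstimate:
    """A single (base year, target year) ATT with clustered inference.

    ``influence`` maps country -> its cluster-summed influence contribution
    (already scaled by 1/n), so ``var = G/(G-1) * sum_c influence_c**2``.
    """

    target_year: int
    base_year: int
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    influence: pd.Series
    n_units: int
    n_treated: int
    n_control: int
    n_dropped: int = 0

    @property
    def significant_positive(self) -> bool:
        return self.ci_lo > 0.0


def _dr_att_arrays(
    dy: np.ndarray,
    d: np.ndarray,
    X: np.ndarray,
    ps: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Core doubly-robust ATT and per-unit influence values.

    Implements the traditional doubly-robust panel estimator: IPW weights
    from ``ps``, outcome model fit among controls, and the asymptotic
    linear representation with corrections for both first-step fits.
    """
    n = len(dy)
    w1 = d.astype(float)
    wc = ps * (1.0 - w1) / (1.0 - ps)

    ctrl = ~d
    beta, _ = _ols(X[ctrl], dy[ctrl])
    mu = X @ beta
    resid = dy - mu

    m_w1 = w1.mean()
    m_wc = wc.mean()
    if m_w1 == 0:
        raise EstimationError("no treated units remain in this 2x2 comparison")
    if m_wc == 0:
        raise EstimationError("no control units remain in this 2x2 comparison")
    eta_t = (w1 * resid).mean() / m_w1
    eta_c = (wc * resid).mean() / m_wc
    att = eta_t - eta_c

    # outcome-model linear representation: beta_hat - beta ~ mean_i l_ols_i
    or_resid = np.where(ctrl, resid, 0.0)
    A = (X[ctrl].T @ X[ctrl]) / n
    l_ols = (or_resid[:, None] * X) @ np.linalg.pinv(A)

    # propensity linear representation (logit score x inverse Hessian)
    score_ps = ((d - ps)[:, None]) * X
    H = (X * (ps * (1 - ps))[:, None]).T @ X / n
    r_ps = score_ps @ np.linalg.pinv(H)

    M1 = (w1[:, None] * X).mean(axis=0)
    M2 = ((wc * (resid - eta_c))[:, None] * X).mean(axis=0)
    M3 = (wc[:, None] * X).mean(axis=0)

    inf_treat = (w1 * resid - w1 * eta_t - l_ols @ M1) / m_w1
    inf_cont = (wc * resid - wc * eta_c + r_ps @ M2 - l_ols @ M3) / m_wc
    return float(att), inf_treat - inf_cont


def _cluster_se(inf: np.ndarray, cluster: np.ndarray, n_clusters: int) -> tuple[float, np.ndarray]:
    n = len(inf)
    sums = np.bincount(cluster, weights=inf, minlength=n_clusters) / n
    g = int((np.bincount(cluster, minlength=n_clusters) > 0).sum())
    factor = g / (g - 1) if g > 1 else 1.0
    return float(np.sqrt(factor * np.sum(sums**2))), sums


def dr_att_2x2(
    panel: Panel,
    assignment: TreatmentAssignment,
    base_year: int,
    target_year: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    unit: str = "country-vaccine",
    design: UnitDesign | None = None,
    ps_cache: dict | None = None,
) -> AttEstimate:
    """Doubly-robust ATT of treatment on the coverage change base->target.

    Units missing either year are dropped pairwise (with a tally); the
    propensity model may be shared across year pairs through ``ps_cache``
    keyed by the retained-unit mask.
    """
    if design is None:
        design = build_design(panel, assignment, covariates, unit)
    ib, it = design.year_index(base_year), design.year_index(target_year)
    dy_full = design.Y[:, it] - design.Y[:, ib]
    keep = np.isfinite(dy_full)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "2x2 %s->%s: dropped %d units missing a year", base_year, target_year, n_dropped
        )
    dy, d, X, cl = dy_full[keep], design.d[keep], design.X[keep], design.cluster[keep]
    if not d.any():
        raise EstimationError("all treated units were dropped for missingness")
    if d.all():
        raise EstimationError("all control units were dropped for missingness")

    key = keep.tobytes()
    if ps_cache is not None and key in ps_cache:
        ps = ps_cache[key]
    else:
        ps = _fit_ps_arrays(X, d).ps
        if ps_cache is not None:
            ps_cache[key] = ps

    att, inf = _dr_att_arrays(dy, d, X, ps)
    se, sums = _cluster_se(inf, cl, len(design.cluster_ids))
    influence = pd.Series(sums, index=list(design.cluster_ids))
    treated_countries = {design.cluster_ids[c] for c in np.unique(cl[d])}
    control_countries = {design.cluster_ids[c] for c in np.unique(cl[~d])}
    return AttEstimate(
        target_year=target_year,
        base_year=base_year,
        estimate=att,
        se=se,
        ci_lo=att - _Z95 * se,
        ci_hi=att + _Z95 * se,
        influence=influence,
        n_units=int(keep.sum()),
        n_treated=len(treated_countries),
        n_control=len(control_countries),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# event study, averaging, pre-trend test
# ---------------------------------------------------------------------------


@dataclass
class PretrendResult:
    statistic: float
    p_value: float
    df: int
    df_denom: float = float("inf")


@dataclass
class DidFit:
    """Full event-study fit: yearly post ATTs, placebo pre ATTs, the pooled
    2020-2022 effect, and the joint parallel pre-trend test."""

    post_effects: dict[int, AttEstimate]
    placebo_effects: dict[int, AttEstimate]
    average_effect: AttEstimate | None
    pretrend: PretrendResult | None
    n_treated: int
    n_control: int
    n_units: int
    valid: bool = True
    reason: str = ""

    @property
    def pretrend_p(self) -> float:
        return self.pretrend.p_value if self.pretrend is not None else float("nan")


def pretrend_test(placebo_effects: Sequence[AttEstimate]) -> PretrendResult:
    """Joint Wald test that all placebo (pre-period) ATTs are zero.

    The joint covariance comes from the stacked country-cluster influence
    contributions. Because a modest number of treated countries carries
    most of that variance, the plain chi-square reference overrejects;
    the statistic is therefore referred to a Hotelling-type F distribution
    whose denominator degrees of freedom come from a Satterthwaite-style
    effective cluster count (the chi-square is the limiting case). A
    singular covariance falls back to the pseudo-inverse with
    correspondingly reduced degrees of freedom.
    """
    if not placebo_effects:
        raise EstimationError("pre-trend test needs at least one placebo estimate")
    theta = np.array([e.estimate for e in placebo_effects])
    countries = sorted(set().union(*(e.influence.index for e in placebo_effects)))
    psi = np.column_stack(
        [e.influence.reindex(countries, fill_value=0.0).to_numpy() for e in placebo_effects]
    )
    g = len(countries)
    V = (g / (g - 1)) * (psi.T @ psi) if g > 1 else psi.T @ psi
    df = len(theta)
    if np.allclose(theta, 0.0) and np.allclose(V, 0.0):
        return PretrendResult(statistic=0.0, p_value=1.0, df=df)
    rank = np.linalg.matrix_rank(V, tol=1e-12 * max(1.0, np.abs(V).max()))
    if rank < df:
        logger.warning("singular placebo covariance; using pseudo-inverse with df=%d", rank)
        stat = float(theta @ np.linalg.pinv(V) @ theta)
        df = int(rank)
    else:
        stat = float(theta @ np.linalg.solve(V, theta))
    stat = max(stat, 0.0)
    if df == 0:
        return PretrendResult(statistic=stat, p_value=1.0, df=0)
    # effective cluster count: variance of V-hat is driven by the clusters
    # with the largest influence norms
    q = np.sum(psi**2, axis=1)
    q_sum = q.sum()
    nu = (q_sum**2 / np.sum(q**2)) if q_sum > 0 else float(g)
    if nu > df + 1:
        f_stat = stat * (nu - df + 1) / (nu * df)
        p = float(stats.f.sf(f_stat, df, nu - df + 1))
    else:
        p = float(stats.chi2.sf(stat, df))
    return PretrendResult(statistic=stat, p_value=p, df=df, df_denom=float(nu))


def _average_effect(effects: Sequence[AttEstimate]) -> AttEstimate:
    est = float(np.mean([e.estimate for e in effects]))
    countries = sorted(set().union(*(e.influence.index for e in effects)))
    psi = np.column_stack(
        [e.influence.reindex(countries, fill_value=0.0).to_numpy() for e in effects]
    ).mean(axis=1)
    g = len(countries)
    factor = g / (g - 1) if g > 1 else 1.0
    se = float(np.sqrt(factor * np.sum(psi**2)))
    return AttEstimate(
        target_year=effects[-1].target_year,
        base_year=effects[0].base_year,
        estimate=est,
        se=se,
        ci_lo=est - _Z95 * se,
        ci_hi=est + _Z95 * se,
        influence=pd.Series(psi, index=countries),
        n_units=effects[0].n_units,
        n_treated=effects[0].n_treated,
        n_control=effects[0].n_control,
    )


def estimate_did(
    panel: Panel,
    assignment: TreatmentAssignment,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    unit: str = "country-vaccine",
) -> DidFit:
    """Fit the full event study for one treatment assignment.

    Post effects use the last pre-pandemic year as base (2019 -> each of the
    post years); placebo effects use a rolling t-1 base across the pre
    years. The averaged post effect is the unweighted mean of the yearly
    ATTs with variance from the averaged influence functions.
    """
    design = build_design(panel, assignment, covariates, unit)
    pre_years = [y for y in design.years if y not in assignment.post_years]
    post_years = [y for y in design.years if y in assignment.post_years]
    if len(pre_years) < 2 or not post_years:
        raise ValidationError(
            f"need >=2 pre and >=1 post years, got {len(pre_years)} pre / {len(post_years)} post"
        )
    base = max(pre_years)
    ps_cache: dict = {}
    kwargs = dict(covariates=covariates, unit=unit, design=design, ps_cache=ps_cache)
    try:
        post = {y: dr_att_2x2(panel, assignment, base, y, **kwargs) for y in post_years}
        placebo = {
            y: dr_att_2x2(panel, assignment, y - 1, y, **kwargs) for y in pre_years[1:]
        }
        pretrend = pretrend_test(list(placebo.values()))
        average = _average_effect(list(post.values()))
    except EstimationError as exc:
        return DidFit(
            post_effects={},
            placebo_effects={},
            average_effect=None,
            pretrend=None,
            n_treated=assignment.n_treated,
            n_control=assignment.n_control,
            n_units=design.n_units,
            valid=False,
            reason=str(exc),
        )
    n_treated = len({c for c in assignment.treated if c in design.cluster_ids})
    n_control = len({c for c in assignment.control if c in design.cluster_ids})
    return DidFit(
        post_effects=post,
        placebo_effects=placebo,
        average_effect=average,
        pretrend=pretrend,
        n_treated=n_treated,
        n_control=n_control,
        n_units=design.n_units,
    )


def compare_period_means(
    panel: Panel, period_a: Iterable[int], period_b: Iterable[int]
) -> tuple[float, float]:
    """Welch two-sample t-test of observation-level coverage between periods."""
    obs = panel.observations[~panel.observations["is_missing"]]
    a = obs.loc[obs["year"].isin(set(period_a)), "coverage"].to_numpy()
    b = obs.loc[obs["year"].isin(set(period_b)), "coverage"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each period needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# cluster bootstrap (alternative inference)
# ---------------------------------------------------------------------------


def cluster_bootstrap_se(
    panel: Panel,
    assignment: TreatmentAssignment,
    base_year: int,
    target_year: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    unit: str = "country-vaccine",
    n_boot: int = 199,
    seed: int = 0,
) -> float:
    """Country-cluster bootstrap standard error of a 2x2 ATT.

    Countries are resampled with replacement and both working models are
    refitted per draw; degenerate draws (single-group) are redrawn.
    """
    design = build_design(panel, assignment, covariates, unit)
    ib, it = design.year_index(base_year), design.year_index(target_year)
    dy_full = design.Y[:, it] - design.Y[:, ib]
    keep = np.isfinite(dy_full)
    dy, d, X, cl = dy_full[keep], design.d[keep], design.X[keep], design.cluster[keep]

    order = np.argsort(cl, kind="stable")
    dy, d, X, cl = dy[order], d[order], X[order], cl[order]
    present = np.unique(cl)
    starts = np.searchsorted(cl, present)
    stops = np.searchsorted(cl, present, side="right")
    slices = {c: slice(a, b) for c, a, b in zip(present, starts, stops)}

    rng = np.random.default_rng(seed)
    draws = []
    attempts = 0
    while len(draws) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        picked = rng.choice(present, size=len(present), replace=True)
        idx = np.concatenate([np.arange(slices[c].start, slices[c].stop) for c in picked])
        db = d[idx]
        if db.all() or not db.any():
            continue
        ps = _fit_ps_arrays(X[idx], db).ps
        att, _ = _dr_att_arrays(dy[idx], db, X[idx], ps)
        draws.append(att)
    if len(draws) < n_boot:
        raise EstimationError("cluster bootstrap could not complete enough valid draws")
    return float(np.std(draws, ddof=1))
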