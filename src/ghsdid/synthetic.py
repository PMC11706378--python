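"""Synthetic panels with the statistical structure the analysis assumes.

The generator emulates the study panel — 191 countries x 12 vaccines x
2015-2022 — from a two-way fixed-effect data-generating process:

    Coverage_it = alpha + gamma_t + delta_i + X_i' beta
                  + sum_{t in post} tau_t * 1[score_i >= s*] * 1[year = t]
                  + slope(score_i) * (t - 2019) * 1[t < 2020]
                  + eps_it,   eps_it ~ N(0, sigma^2),

clipped to the [0, 100] coverage scale. Treatment (the planted effect
``tau_t`` per post year) attaches to countries whose composite score clears
the threshold ``s*``; the composite score itself is generated from a
96-sub-indicator hierarchy whose level is shifted by income group, so that
income confounds both the score and (through ``beta`` and the post-period
income trend) the outcome. Optional pre-trend violations — a differential
pre-2020 slope by score band — let tests exercise the parallel-trends gate.

Everything is deterministic given the seed: the same ``SyntheticTruth``
yields byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel_io import (
    COVERAGE_COLUMNS,
    GOVERNANCE_COLUMNS,
    INCOME_GROUPS,
    Panel,
    PanelSummary,
)
from .scores import HierarchySpec, ScoreHierarchy

logger = logging.getLogger(__name__)

#: the 12 antigen codes of the study panel, after exclusions
DEFAULT_VACCINES = (
    "BCG",
    "DTP1",
    "DTP3",
    "HEPB3",
    "HEPBB",
    "HIB3",
    "MCV1",
    "MCV2",
    "PCV3",
    "POL3",
    "RCV1",
    "ROTAC",
)

#: stylized WHO-region marginals (counts out of 191 analysis countries)
_REGION_WEIGHTS = {
    "Africa": 47,
    "Americas": 35,
    "Eastern Mediterranean": 21,
    "Europe": 53,
    "Southeast Asia": 10,
    "Western Pacific": 25,
}

#: income-group mix within each region (stylized, sums to 1 per region)
_INCOME_BY_REGION = {
    "Africa": (0.00, 0.10, 0.40, 0.50),
    "Americas": (0.40, 0.40, 0.20, 0.00),
    "Eastern Mediterranean": (0.25, 0.30, 0.30, 0.15),
    "Europe": (0.75, 0.20, 0.05, 0.00),
    "Southeast Asia": (0.00, 0.30, 0.60, 0.10),
    "Western Pacific": (0.30, 0.30, 0.30, 0.10),
}

#: signed unit shift of the composite-score level per income group; the
#: confounding strength multiplies this
_INCOME_SCORE_FACTOR = {
    "High": 1.0,
    "Upper-Middle": 1.0 / 3.0,
    "Lower-Middle": -1.0 / 3.0,
    "Low": -1.0,
}

#: governance level by income group (the -2.5..2.5 scale)
_INCOME_GOVERNANCE = {"High": 1.2, "Upper-Middle": 0.1, "Lower-Middle": -0.5, "Low": -1.0}


def default_hierarchy() -> HierarchySpec:
    """A composite-score tree at the scale of the published index.

    Six categories hold 6/6/7/6/6/6 = 37 indicators; the first 22
    indicators hold 3 sub-indicators and the rest 2, for 96 leaves. Node
    ids follow the ``c``, ``c.i``, ``c.i.s`` convention; the immunization
    indicator conventionally sits at ``1.6``.
    """
    parents: dict[str, str | None] = {"overall": None}
    levels: dict[str, str] = {"overall": "overall"}
    indicator_counts = (6, 6, 7, 6, 6, 6)
    indicators: list[str] = []
    for c, n_ind in enumerate(indicator_counts, start=1):
        cat = f"cat{c}"
        parents[cat] = "overall"
        levels[cat] = "category"
        for i in range(1, n_ind + 1):
            ind = f"{c}.{i}"
            parents[ind] = cat
            levels[ind] = "indicator"
            indicators.append(ind)
    assert len(indicators) == 37
    for k, ind in enumerate(indicators):
        n_sub = 3 if k < 22 else 2
        for s in range(1, n_sub + 1):
            sub = f"{ind}.{s}"
            parents[sub] = ind
            levels[sub] = "sub-indicator"
    spec = HierarchySpec(parents=parents, levels=levels)
    assert len(spec.leaves()) == 96
    return spec


#: node id of the vaccination-coverage indicator removed before analysis
VACCINATION_INDICATOR = "1.6"


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of the simulated panel (the planted truth).

    Defaults describe the study conditions: a 0-100 coverage scale centred
    near 85, a mild common upward pre-trend, pandemic-year dips, planted
    protective effects (0.74, 1.23, 0.76) for countries above score 57,
    income-linked levels and post-period declines, and iid Gaussian noise.
    """

    alpha: float = 85.0
    year_effects: Mapping[int, float] = field(
        default_factory=lambda: {
            2015: -0.8,
            2016: -0.6,
            2017: -0.4,
            2018: -0.2,
            2019: 0.0,
            2020: -2.3,
            2021: -3.7,
            2022: -2.9,
        }
    )
    country_sd: float = 3.0
    vaccine_sd: float = 2.0
    tau: Mapping[int, float] = field(
        default_factory=lambda: {2020: 0.74, 2021: 1.23, 2022: 0.76}
    )
    beta_income: Mapping[str, float] = field(
        default_factory=lambda: {"High": 3.0, "Upper-Middle": 0.0, "Lower-Middle": -3.0, "Low": -7.0}
    )
    beta_region: Mapping[str, float] = field(default_factory=dict)
    income_post_trend: Mapping[str, float] = field(
        default_factory=lambda: {"High": 0.0, "Upper-Middle": -0.5, "Lower-Middle": -1.0, "Low": -1.5}
    )
    noise_sd: float = 3.0
    score_threshold: float = 57.0
    confounding: float = 12.0
    score_mean: float = 38.0
    score_sd: float = 12.0
    pretrend_slope: float = 0.0
    pretrend_bands: tuple[tuple[float, float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    def slope_of_score(self, score: np.ndarray) -> np.ndarray:
        """Differential pre-2020 slope implied by the score (pp/year)."""
        slope = np.zeros_like(score, dtype=float)
        if self.pretrend_slope:
            slope += self.pretrend_slope * (score >= self.score_threshold)
        if self.pretrend_bands:
            for lo, hi, s in self.pretrend_bands:
                slope += s * ((score >= lo) & (score < hi))
        return slope


def _iso3_codes(n: int) -> list[str]:
    """Deterministic synthetic ISO3-like codes ZAA, ZAB, ..."""
    if n > 676:
        raise ValidationError("at most 676 synthetic countries supported")
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return ["Z" + letters[k // 26] + letters[k % 26] for k in range(n)]


def generate_attributes(
    n_countries: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw country attributes with a realistic region-income mix.

    Regions follow the study's marginal distribution; income groups are
    drawn conditionally on region; governance indicators are income-linked
    with Gaussian scatter, truncated to [-2.5, 2.5].
    """
    regions = list(_REGION_WEIGHTS)
    weights = np.array([_REGION_WEIGHTS[r] for r in regions], float)
    region = rng.choice(regions, size=n_countries, p=weights / weights.sum())
    income = np.empty(n_countries, dtype=object)
    for r in regions:
        mask = region == r
        income[mask] = rng.choice(INCOME_GROUPS, size=mask.sum(), p=_INCOME_BY_REGION[r])
    frame = pd.DataFrame(
        {"iso3": _iso3_codes(n_countries), "income_group": income, "who_region": region}
    )
    base = frame["income_group"].map(_INCOME_GOVERNANCE).to_numpy(float)
    for col in GOVERNANCE_COLUMNS:
        frame[col] = np.clip(base + rng.normal(0.0, 0.5, n_countries), -2.5, 2.5)
    return frame


def generate_scores(
    attributes: pd.DataFrame,
    spec: HierarchySpec | None = None,
    confounding: float = 12.0,
    rng: np.random.Generator | None = None,
    score_mean: float = 38.0,
    score_sd: float = 12.0,
    concentration: float = 10.0,
) -> ScoreHierarchy:
    """Generate the hierarchical composite scores for a set of countries.

    Each country gets a latent capacity level ``score_mean +
    confounding * income_shift + N(0, score_sd)``; its 96 sub-indicators
    are Beta-shaped draws on [0, 100] around that level, and all parents
    aggregate by equal-weight means. ``confounding = 0`` makes the score
    distribution independent of income group.
    """
    spec = spec or default_hierarchy()
    rng = rng if rng is not None else np.random.default_rng(0)
    shift = attributes["income_group"].map(_INCOME_SCORE_FACTOR).to_numpy(float)
    latent = score_mean + confounding * shift + rng.normal(0.0, score_sd, len(attributes))
    m = np.clip(latent / 100.0, 0.02, 0.98)
    leaves = spec.leaves()
    a = m * concentration
    b = (1.0 - m) * concentration
    draws = 100.0 * rng.beta(a[:, None], b[:, None], size=(len(attributes), len(leaves)))
    leaf_values = pd.DataFrame(draws, index=attributes["iso3"].to_numpy(), columns=list(leaves))
    leaf_values.index.name = "iso3"
    return ScoreHierarchy.aggregate_from_leaves(spec, leaf_values)


def generate_panel(
    truth: SyntheticTruth,
    n_countries: int = 191,
    n_vaccines: int = 12,
    years: Sequence[int] = tuple(range(2015, 2023)),
    attributes: pd.DataFrame | None = None,
    scores: pd.Series | None = None,
) -> tuple[Panel, ScoreHierarchy | None]:
    """Generate a full coverage panel plus assignment-ready scores.

    Returns ``(panel, hierarchy)``; when explicit per-country ``scores`` are
    supplied the hierarchy slot is ``None`` and the given scores drive the
    planted effect. Coverage is clipped to [0, 100]; a clipping rate above
    1% logs a warning and above 10% raises, since heavy clipping would bias
    the planted effects.
    """
    years = tuple(int(y) for y in years)
    post = sorted(set(truth.tau) & set(years))
    pre = [y for y in years if y not in truth.tau]
    if len(pre) < 2 or not post:
        raise ValidationError("years must span >=2 pre and >=1 post periods")
    missing_gamma = [y for y in years if y not in truth.year_effects]
    if missing_gamma:
        raise ValidationError(f"year_effects undefined for {missing_gamma}")

    rng = np.random.default_rng(truth.seed)
    if attributes is None:
        attributes = generate_attributes(n_countries, rng)
    hierarchy: ScoreHierarchy | None = None
    if scores is None:
        hierarchy = generate_scores(
            attributes,
            confounding=truth.confounding,
            rng=rng,
            score_mean=truth.score_mean,
            score_sd=truth.score_sd,
        )
        scores = hierarchy.score("overall")
    scores = scores.reindex(attributes["iso3"]).astype(float)
    if scores.isna().any():
        raise ValidationError("every country needs a score")

    if n_vaccines <= len(DEFAULT_VACCINES):
        vaccines = DEFAULT_VACCINES[:n_vaccines]
    else:
        vaccines = DEFAULT_VACCINES + tuple(
            f"VAX{k:02d}" for k in range(len(DEFAULT_VACCINES) + 1, n_vaccines + 1)
        )

    n_c, n_v, n_y = len(attributes), n_vaccines, len(years)
    delta = rng.normal(0.0, truth.country_sd, n_c)
    nu = rng.normal(0.0, truth.vaccine_sd, n_v)
    gamma = np.array([truth.year_effects[y] for y in years])
    year_arr = np.array(years, float)

    beta_inc = attributes["income_group"].map(truth.beta_income).fillna(0.0).to_numpy(float)
    beta_reg = (
        attributes["who_region"].map(truth.beta_region).fillna(0.0).to_numpy(float)
        if truth.beta_region
        else np.zeros(n_c)
    )
    inc_trend = (
        attributes["income_group"].map(truth.income_post_trend).fillna(0.0).to_numpy(float)
    )
    treated = scores.to_numpy() >= truth.score_threshold
    slope = truth.slope_of_score(scores.to_numpy())

    tau_by_year = np.array([truth.tau.get(y, 0.0) for y in years])
    is_post = np.array([y in truth.tau for y in years], float)
    pre_ramp = np.where(year_arr < 2020, year_arr - 2019.0, 0.0)

    # country x year systematic part, broadcast over vaccines
    cy = (
        truth.alpha
        + gamma[None, :]
        + delta[:, None]
        + (beta_inc + beta_reg)[:, None]
        + inc_trend[:, None] * is_post[None, :]
        + treated[:, None] * tau_by_year[None, :]
        + slope[:, None] * pre_ramp[None, :]
    )
    values = cy[:, None, :] + nu[None, :, None]
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=(n_c, n_v, n_y))

    clipped = (values < 0.0) | (values > 100.0)
    clip_rate = float(clipped.mean())
    if clip_rate > 0.10:
        raise ValidationError(
            f"parameterization forces {100 * clip_rate:.1f}% of coverage values out of [0, 100]"
        )
    if clip_rate > 0.01:
        logger.warning("coverage clipping rate %.2f%% exceeds 1%%", 100 * clip_rate)
    values = np.clip(values, 0.0, 100.0)

    iso3 = attributes["iso3"].to_numpy()
    obs = pd.DataFrame(
        {
            "iso3": np.repeat(iso3, n_v * n_y),
            "vaccine": np.tile(np.repeat(list(vaccines), n_y), n_c),
            "year": np.tile(years, n_c * n_v),
            "coverage": values.ravel(),
            "is_missing": False,
        }
    )
    summary = PanelSummary(
        n_rows_in=len(obs),
        n_kept=len(obs),
        n_countries=n_c,
        n_vaccines=n_v,
        n_missing=0,
    )
    panel = Panel(
        observations=obs[list(COVERAGE_COLUMNS)],
        attributes=attributes.reset_index(drop=True),
        year_window=(min(years), max(years)),
        vaccine_set=tuple(sorted(vaccines)),
        summary=summary,
    )
    return panel, hierarchy


def inject_missingness(
    panel: Panel,
    cells: Sequence[tuple[str, str, int]] | None = None,
    rate: float | None = None,
    seed: int = 0,
) -> Panel:
    """Flag explicit cells, or a random fraction of cells, as missing.

    ``cells`` is a list of (iso3, vaccine, year) keys; alternatively a
    ``rate`` in [0, 0.05] flags that fraction of cells uniformly at random
    (deterministic per seed). Returns a new panel; the count is logged.
    """
    obs = panel.observations.copy()
    if cells is not None:
        index = pd.MultiIndex.from_frame(obs[["iso3", "vaccine", "year"]])
        target = pd.MultiIndex.from_tuples(list(cells), names=["iso3", "vaccine", "year"])
        locs = index.get_indexer(target)
        if (locs < 0).any():
            bad = target[locs < 0][0]
            raise ValidationError(f"cell {tuple(bad)} is not in the panel")
        obs.iloc[locs, obs.columns.get_loc("is_missing")] = True
        obs.iloc[locs, obs.columns.get_loc("coverage")] = np.nan
    elif rate is not None:
        if not 0.0 <= rate <= 0.05:
            raise ValidationError("missingness rate must lie in [0, 0.05]")
        rng = np.random.default_rng(seed)
        flag = rng.random(len(obs)) < rate
        obs.loc[flag, "is_missing"] = True
        obs.loc[flag, "coverage"] = np.nan
    else:
        raise ValidationError("provide either explicit cells or a rate")

    n_missing = int(obs["is_missing"].sum())
    logger.info(
        "flagged %d of %d cells missing (%.2f%%)",
        n_missing,
        len(obs),
        100.0 * n_missing / len(obs),
    )
    summary = replace_summary(panel.summary, n_missing=n_missing)
    return Panel(
        observations=obs,
        attributes=panel.attributes,
        year_window=panel.year_window,
        vaccine_set=panel.vaccine_set,
        summary=summary,
    )


def replace_summary(summary: PanelSummary, **changes) -> PanelSummary:
    out = PanelSummary(
        n_rows_in=summary.n_rows_in,
        n_kept=summary.n_kept,
        n_countries=summary.n_countries,
        n_vaccines=summary.n_vaccines,
        n_missing=summary.n_missing,
        dropped=dict(summary.dropped),
    )
    for key, value in changes.items():
        setattr(out, key, value)
    return out
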