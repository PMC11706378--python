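"""Sliding-cutoff treatment assignment sweep.

For every cutoff on a grid (0-100 step 1 for composite scores, -2.5..2.5
step 0.1 for governance indicators) the sweep assigns treatment, applies two
gates — non-degenerate group sizes and the parallel pre-trend test — fits
the event-study DiD where possible, and reports the minimum qualifying
cutoff: the smallest cutoff whose fit passes both gates and shows a
significantly positive average post-period effect. This is the procedure
that localizes the lowest score at which a protective effect is observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .drdid import DEFAULT_COVARIATES, DidFit, estimate_did
from .errors import DegenerateAssignmentError, EstimationError, ValidationError
from .panel_io import Panel
from .scores import assign_treatment, percentile_of_cutoff

logger = logging.getLogger(__name__)

GATE_OK = "ok"
GATE_DEGENERATE = "degenerate_groups"
GATE_PRETREND = "pretrend_fail"
GATE_FIT_ERROR = "fit_error"


@dataclass(frozen=True)
class SweepGates:
    """Gate thresholds: minimum countries per group and the pre-trend alpha.

    A cutoff passes the pre-trend gate when the joint placebo test's
    p-value is >= ``pretrend_alpha``.
    """

    min_group: int = 5
    pretrend_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pretrend_alpha < 1.0:
            raise ValidationError("pretrend_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SweepGrid:
    lo: float = 0.0
    hi: float = 100.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("grid step must be positive")

    def cutoffs(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        return np.round(self.lo + self.step * np.arange(n + 1), 10)


@dataclass
class SweepRecord:
    """Outcome of one cutoff: gate status and (when fitted) the DiD fit."""

    cutoff: float
    percentile: float
    gate_status: str
    n_treated: int = 0
    n_control: int = 0
    fit: DidFit | None = None


@dataclass
class SweepResult:
    score_id: str
    grid: SweepGrid
    records: list[SweepRecord]
    min_qualifying_cutoff: float | None
    n_countries: int

    def to_frame(self) -> pd.DataFrame:
        """Supplementary-table shaped output: one row per cutoff."""
        rows = []
        for rec in self.records:
            row: dict = {
                "score_id": self.score_id,
                "cutoff": rec.cutoff,
                "percentile": rec.percentile,
                "gate_status": rec.gate_status,
                "n_treated": rec.n_treated,
                "n_control": rec.n_control,
                "avg_est": np.nan,
                "avg_lo": np.nan,
                "avg_hi": np.nan,
                "pretrend_p": np.nan,
            }
            fit = rec.fit
            if fit is not None and fit.valid:
                avg = fit.average_effect
                row.update(avg_est=avg.estimate, avg_lo=avg.ci_lo, avg_hi=avg.ci_hi)
                row["pretrend_p"] = fit.pretrend_p
                for year, eff in fit.post_effects.items():
                    row[f"est_{year}"] = eff.estimate
                    row[f"lo_{year}"] = eff.ci_lo
                    row[f"hi_{year}"] = eff.ci_hi
            rows.append(row)
        return pd.DataFrame(rows)


def _qualifies(record: SweepRecord, rule: str) -> bool:
    if record.gate_status != GATE_OK or record.fit is None or not record.fit.valid:
        return False
    if rule == "average":
        return record.fit.average_effect.significant_positive
    if rule == "any-year":
        return any(e.significant_positive for e in record.fit.post_effects.values())
    raise ValidationError(f"unknown significance rule {rule!r}")


def find_min_qualifying(
    records: Sequence[SweepRecord], significance_rule: str = "average"
) -> float | None:
    """Smallest cutoff passing all gates with a significantly positive effect.

    ``significance_rule`` is ``"average"`` (the pooled 2020-2022 effect's
    CI must sit above zero, the default) or ``"any-year"``.
    """
    for record in records:  # records are sorted by cutoff
        if _qualifies(record, significance_rule):
            return record.cutoff
    return None


def sweep(
    scores: pd.Series,
    panel: Panel,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    grid: SweepGrid | None = None,
    gates: SweepGates | None = None,
    score_id: str = "overall",
    post_years: Iterable[int] = (2020, 2021, 2022),
    significance_rule: str = "average",
    unit: str = "country-vaccine",
) -> SweepResult:
    """Run the sliding-cutoff procedure over the whole grid.

    Per cutoff: assign treatment; if either group has fewer than
    ``gates.min_group`` countries the record is ``degenerate_groups``;
    otherwise the event study is fitted and the pre-trend gate applied
    (``pretrend_fail`` retains the fit for diagnostics). Deterministic
    given inputs.
    """
    grid = grid or SweepGrid()
    gates = gates or SweepGates()
    scores = scores.dropna()
    records: list[SweepRecord] = []
    for cutoff in grid.cutoffs():
        _, pct = percentile_of_cutoff(scores, cutoff)
        try:
            assignment = assign_treatment(
                scores, cutoff, post_years=post_years, score_id=score_id
            )
        except DegenerateAssignmentError:
            records.append(
                SweepRecord(cutoff=float(cutoff), percentile=pct, gate_status=GATE_DEGENERATE)
            )
            continue
        if min(assignment.n_treated, assignment.n_control) < gates.min_group:
            records.append(
                SweepRecord(
                    cutoff=float(cutoff),
                    percentile=pct,
                    gate_status=GATE_DEGENERATE,
                    n_treated=assignment.n_treated,
                    n_control=assignment.n_control,
                )
            )
            continue
        try:
            fit = estimate_did(panel, assignment, covariates=covariates, unit=unit)
        except (EstimationError, ValidationError) as exc:
            logger.info("cutoff %s: fit error: %s", cutoff, exc)
            records.append(
                SweepRecord(
                    cutoff=float(cutoff),
                    percentile=pct,
                    gate_status=GATE_FIT_ERROR,
                    n_treated=assignment.n_treated,
                    n_control=assignment.n_control,
                )
            )
            continue
        if not fit.valid:
            status = GATE_FIT_ERROR
        elif fit.pretrend_p < gates.pretrend_alpha:
            status = GATE_PRETREND
        else:
            status = GATE_OK
        records.append(
            SweepRecord(
                cutoff=float(cutoff),
                percentile=pct,
                gate_status=status,
                n_treated=assignment.n_treated,
                n_control=assignment.n_control,
                fit=fit if fit.valid else None,
            )
        )
    return SweepResult(
        score_id=score_id,
        grid=grid,
        records=records,
        min_qualifying_cutoff=find_min_qualifying(records, significance_rule),
        n_countries=int(scores.size),
    )


GOVERNANCE_GRID = SweepGrid(lo=-2.5, hi=2.5, step=0.1)


def sweep_governance(
    panel: Panel,
    governance_scores: pd.Series,
    grid: SweepGrid | None = None,
    gates: SweepGates | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    score_id: str = "governance",
    significance_rule: str = "average",
    unit: str = "country-vaccine",
) -> SweepResult:
    """Sweep a World Bank governance indicator on the -2.5..2.5 scale.

    Countries lacking the indicator are dropped (with a tally); the
    indicator must be present for at least 90% of panel countries.
    """
    grid = grid or GOVERNANCE_GRID
    countries = pd.Index(panel.attributes["iso3"])
    scores = governance_scores.reindex(countries)
    n_missing = int(scores.isna().sum())
    if n_missing:
        logger.info("governance indicator missing for %d countries; dropped", n_missing)
    if len(countries) and 1.0 - n_missing / len(countries) < 0.90:
        raise ValidationError(
            f"governance indicator present for fewer than 90% of countries "
            f"({len(countries) - n_missing}/{len(countries)})"
        )
    return sweep(
        scores.dropna(),
        panel,
        covariates=covariates,
        grid=grid,
        gates=gates,
        score_id=score_id,
        significance_rule=significance_rule,
        unit=unit,
    )
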