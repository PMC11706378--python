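"""Result artifacts: group summaries, smoothed effect-vs-cutoff curves,
and formatted result tables.

Display rounding is two decimals throughout, matching how the estimates are
conventionally reported; CSV output keeps full floating precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .drdid import DidFit
from .errors import ValidationError
from .panel_io import Panel
from .scores import TreatmentAssignment
from .sweep import SweepResult

logger = logging.getLogger(__name__)

#: default reporting periods: pre-pandemic pooled, each post year, full span
DEFAULT_PERIODS: Mapping[str, tuple[int, ...]] = {
    "2015-2019": tuple(range(2015, 2020)),
    "2020": (2020,),
    "2021": (2021,),
    "2022": (2022,),
    "2015-2022": tuple(range(2015, 2023)),
}


def summarize_groups(
    panel: Panel,
    assignment: TreatmentAssignment,
    periods: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Observation-level coverage mean/SD per group and period.

    Returns one row per (group, period) with n, mean, sd; a group-period
    with no observations reports n=0 and a single observation reports its
    mean with sd marked n/a (NaN).
    """
    periods = periods or DEFAULT_PERIODS
    obs = panel.observations[~panel.observations["is_missing"]]
    group = np.where(obs["iso3"].isin(assignment.treated), "treated", "control")
    rows = []
    for name, years in periods.items():
        in_period = obs["year"].isin(set(years))
        for g in ("treated", "control"):
            values = obs.loc[in_period & (group == g), "coverage"]
            rows.append(
                {
                    "group": g,
                    "period": name,
                    "n": int(values.size),
                    "mean": float(values.mean()) if values.size else np.nan,
                    "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def crosstab_attributes(panel: Panel, assignment: TreatmentAssignment) -> pd.DataFrame:
    """Income-group and WHO-region counts by treatment group."""
    attrs = panel.attributes.copy()
    attrs["group"] = np.where(attrs["iso3"].isin(assignment.treated), "treated", "control")
    pieces = []
    for col in ("income_group", "who_region"):
        tab = attrs.groupby([col, "group"]).size().unstack(fill_value=0)
        tab.index.name = "level"
        tab = tab.reset_index()
        tab.insert(0, "attribute", col)
        pieces.append(tab)
    return pd.concat(pieces, ignore_index=True)


@dataclass
class LoessCurve:
    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray


def loess_trend(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
) -> LoessCurve:
    """Local polynomial (tricube-weighted) smoother with pointwise SEs.

    At each input point a weighted polynomial of the given degree is fit
    over the ``span`` fraction of nearest neighbours; pointwise standard
    errors follow the linear-smoother variance form with the residual scale
    estimated from the smoother's residual degrees of freedom. Windows too
    small for a ``degree``-order fit are widened with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("x and y must be one-dimensional and equally long")
    n = len(x)
    if n < degree + 2:
        raise ValidationError(f"need at least degree+2={degree + 2} points, got {n}")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        logger.warning("span %.2f gives %d-point windows; widening to %d", span, k, degree + 2)
        k = degree + 2
    k = min(k, n)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    L = np.zeros((n, n))  # smoother matrix on the sorted grid
    for i in range(n):
        dist = np.abs(xs - xs[i])
        h = np.partition(dist, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).eps
        w = np.clip(1.0 - (dist / h) ** 3, 0.0, None) ** 3
        idx = np.flatnonzero(w > 0)
        B = np.vander(xs[idx] - xs[i], degree + 1, increasing=True)
        Wb = w[idx][:, None] * B
        # row of the hat matrix: e0' (B'WB)^-1 B'W
        coef_map = np.linalg.pinv(B.T @ Wb) @ Wb.T
        L[i, idx] = coef_map[0]
    fitted_s = L @ ys
    resid = ys - fitted_s
    # residual degrees of freedom of a linear smoother
    df_resid = n - 2 * np.trace(L) + np.trace(L @ L.T)
    df_resid = max(df_resid, 1.0)
    sigma2 = float(resid @ resid) / df_resid
    se_s = np.sqrt(sigma2 * np.einsum("ij,ij->i", L, L))

    fitted = np.empty(n)
    se = np.empty(n)
    fitted[order] = fitted_s
    se[order] = se_s
    return LoessCurve(x=x, fitted=fitted, se=se)


def _fmt(value: float) -> str:
    return "n/a" if value is None or not np.isfinite(value) else f"{value:.2f}"


def _effect_cell(est: float, lo: float, hi: float) -> str:
    star = "*" if lo > 0 else ""
    return f"{_fmt(est)}{star}({_fmt(lo)}, {_fmt(hi)})"


def render_tables(
    fits: Mapping[str, DidFit],
    cutoffs: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Render DiD fits as a results table (CSV frame + formatted text).

    One row per model: averaged and yearly effects with 95% CIs (an
    asterisk marks CIs excluding zero), the pre-trend p-value, and — when
    ``cutoffs`` maps the model name to (cutoff, percentile) — the cutoff
    column. Returns (full-precision frame, 2-decimal text table).
    """
    rows = []
    for name, fit in fits.items():
        if not fit.valid:
            rows.append({"model": name, "note": f"invalid: {fit.reason}"})
            continue
        avg = fit.average_effect
        row = {
            "model": name,
            "avg_est": avg.estimate,
            "avg_lo": avg.ci_lo,
            "avg_hi": avg.ci_hi,
        }
        for year, eff in sorted(fit.post_effects.items()):
            row[f"est_{year}"] = eff.estimate
            row[f"lo_{year}"] = eff.ci_lo
            row[f"hi_{year}"] = eff.ci_hi
        row["pretrend_p"] = fit.pretrend_p
        row["n_treated"] = fit.n_treated
        row["n_control"] = fit.n_control
        if cutoffs and name in cutoffs:
            row["cutoff"], row["percentile"] = cutoffs[name]
        rows.append(row)
    frame = pd.DataFrame(rows)

    lines = []
    header = ["model", "average (2020-2022)", "2020", "2021", "2022", "pretrend p", "cutoff(pct)"]
    lines.append("\t".join(header))
    for _, row in frame.iterrows():
        if "note" in row and isinstance(row.get("note"), str) and row.get("note"):
            lines.append(f"{row['model']}\t{row['note']}")
            continue
        cells = [str(row["model"]), _effect_cell(row["avg_est"], row["avg_lo"], row["avg_hi"])]
        for year in (2020, 2021, 2022):
            if f"est_{year}" in row and np.isfinite(row.get(f"est_{year}", np.nan)):
                cells.append(
                    _effect_cell(row[f"est_{year}"], row[f"lo_{year}"], row[f"hi_{year}"])
                )
            else:
                cells.append("n/a")
        cells.append(_fmt(row["pretrend_p"]))
        if "cutoff" in row and np.isfinite(row.get("cutoff", np.nan)):
            cells.append(f"{row['cutoff']:g}({row['percentile']:.2f})")
        else:
            cells.append("n/a")
        lines.append("\t".join(cells))
    return frame, "\n".join(lines) + "\n"


def sweep_curve(result: SweepResult, span: float = 0.75, degree: int = 2) -> pd.DataFrame:
    """Effect-vs-cutoff curve data with a local-polynomial trendline.

    Only cutoffs with a fitted average effect enter; the returned frame
    carries the raw estimates, CI bounds, smoothed trend and pointwise SE.
    """
    frame = result.to_frame()
    fitted = frame.dropna(subset=["avg_est"])
    if len(fitted) < degree + 2:
        raise ValidationError("too few fitted cutoffs for a trendline")
    curve = loess_trend(fitted["cutoff"].to_numpy(), fitted["avg_est"].to_numpy(), span, degree)
    out = fitted[["cutoff", "percentile", "gate_status", "avg_est", "avg_lo", "avg_hi"]].copy()
    out["trend"] = curve.fitted
    out["trend_se"] = curve.se
    return out.reset_index(drop=True)
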