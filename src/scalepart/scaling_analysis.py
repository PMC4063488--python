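"""Cross-scale analysis: per-scale summaries, explained-variance-on-CV
regressions, and the affinity-vs-variability simulation experiment.

Two elements jointly determine how strongly an environmental variable group
structures species composition: the species' ecological *affinity* to it and
the group's spatial *variability* within the sampling grids.  The regression
of per-scale mean exclusive explained variance on per-scale mean coefficient
of variation (CV) separates the two: a strong positive relationship says the
group's impact tracks its variability (constant per-unit effect), while high
explained variance at low CV indicates strong affinity.

Regression points are per-scale means (one point per scale), matching the
degrees of freedom (1, n−2) reporting convention for an n-scale series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ordination import PartitionResult

logger = logging.getLogger(__name__)


@dataclass
class ScaleSummary:
    """Per-scale means over qualifying grids."""

    scale_index: int
    n_grids: int
    mean_pct: dict[str, float]
    sd_pct: dict[str, float]
    mean_cv: dict[str, float]
    mean_joint_pct: float
    mean_total_inertia: float


@dataclass
class RegressionResult:
    """OLS of per-scale mean explained variance on per-scale mean CV."""

    group: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    df: tuple[int, int]
    n_points: int


def group_cv_per_grid(
    cvs: pd.DataFrame, groups: dict[str, tuple[str, ...]]
) -> pd.DataFrame:
    """Grid-level group CV: unweighted mean of member-variable CVs.

    Undefined (NaN) member CVs are excluded from the mean; a grid where every
    member CV is undefined gets NaN for that group.
    """
    rows = []
    for (grid_id, scale), sub in cvs.groupby(["grid_id", "scale"], sort=True):
        per_var = sub.set_index("variable")["cv"]
        for gname, members in groups.items():
            vals = per_var.reindex(list(members)).to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "grid_id": grid_id,
                    "scale": scale,
                    "group": gname,
                    "cv": float(vals.mean()) if vals.size else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def summarize_scale(
    partitions: list[PartitionResult],
    grid_cvs: pd.DataFrame,
    scale_index: int,
) -> ScaleSummary | None:
    """Aggregate one scale's qualifying grids to scale-level means.

    ``grid_cvs`` holds grid-level group CVs (see :func:`group_cv_per_grid`)
    for this scale.  Uses sample (n−1) standard deviations, 0 for a single
    grid.  Returns None when no grid qualifies at this scale (the scale is
    omitted from the cross-scale analysis, with a logged reason).
    """
    if not partitions:
        logger.info("scale %d omitted: no qualifying sampling grids", scale_index)
        return None
    group_names = list(partitions[0].exclusive_pct)
    mean_pct, sd_pct, mean_cv = {}, {}, {}
    for g in group_names:
        vals = np.array([p.exclusive_pct[g] for p in partitions], dtype=float)
        mean_pct[g] = float(vals.mean())
        sd_pct[g] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        sub = grid_cvs[(grid_cvs["group"] == g) & (grid_cvs["scale"] == scale_index)]
        cv_vals = sub["cv"].to_numpy(dtype=float)
        cv_vals = cv_vals[np.isfinite(cv_vals)]
        mean_cv[g] = float(cv_vals.mean()) if cv_vals.size else float("nan")
    return ScaleSummary(
        scale_index=scale_index,
        n_grids=len(partitions),
        mean_pct=mean_pct,
        sd_pct=sd_pct,
        mean_cv=mean_cv,
        mean_joint_pct=float(np.mean([p.joint_pct for p in partitions])),
        mean_total_inertia=float(np.mean([p.total_inertia for p in partitions])),
    )


def summary_table(summaries: list[ScaleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"scale": s.scale_index, "n_grids": s.n_grids, "joint_pct": s.mean_joint_pct}
        for g in s.mean_pct:
            row[f"{g}_pct"] = s.mean_pct[g]
            row[f"{g}_pct_sd"] = s.sd_pct[g]
            row[f"{g}_cv"] = s.mean_cv[g]
        rows.append(row)
    return pd.DataFrame(rows)


def regress_variance_on_cv(
    summaries: list[ScaleSummary], group: str
) -> RegressionResult:
    """OLS of per-scale mean exclusive percent (y) on per-scale mean group CV (x).

    Reports slope, intercept, R², and the F-test p-value with degrees of
    freedom (1, n−2).  Requires at least 3 scales with defined values; a
    constant predictor raises (zero-variance predictor).
    """
    pts = [
        (s.mean_cv[group], s.mean_pct[group])
        for s in summaries
        if np.isfinite(s.mean_cv.get(group, np.nan))
        and np.isfinite(s.mean_pct.get(group, np.nan))
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 scales with defined CV and explained variance for {group!r}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError(f"zero-variance predictor: CV of {group!r} is constant across scales")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        group=group,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        df=(1, int(model.df_resid)),
        n_points=len(pts),
    )


def regression_table(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "df1": r.df[0],
                "df2": r.df[1],
                "n_points": r.n_points,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Affinity-vs-variability experiment
# ---------------------------------------------------------------------------


def run_affinity_experiment(
    base_config,
    cv_levels: list[float],
    seed: int,
    focal_group: str = "lulc",
    group_affinity: dict[str, float] | None = None,
    **pipeline_kwargs,
):
    """Hold affinity fixed, vary the focal group's landscape variability.

    For each level (an LULC ``patch_scale`` value, the knob that moves the
    focal group's CV), a fresh landscape and community are generated with the
    *same* niche affinities, the full multi-scale pipeline runs, and the
    level's mean focal-group CV and exclusive explained variance are
    recorded.  If affinity is the only thing that matters, the focal percent
    stays flat across levels; if variability matters (the constant per-unit-
    effect reading), it rises with CV.

    Returns ``(table, regression, spearman_rho)`` where ``table`` has one row
    per (level, scale) and the regression/correlation are computed on the
    per-level means.  Levels yielding zero qualifying grids are flagged and
    skipped in the regression.
    """
    from .pipeline import run_study  # local import: pipeline imports this module

    if len(cv_levels) < 3:
        raise ValueError("need at least 3 variability levels")
    if group_affinity is None:
        group_affinity = {"climate": 1.0, focal_group: 1.0}

    rows = []
    for level_ix, patch_scale in enumerate(cv_levels):
        config = replace(base_config, patch_scale=float(patch_scale))
        res = run_study(config, group_affinity=group_affinity, seed=seed, **pipeline_kwargs)
        if not res.summaries:
            logger.warning(
                "level patch_scale=%s: zero qualifying grids at every scale; flagged",
                patch_scale,
            )
            rows.append(
                {
                    "level": level_ix,
                    "patch_scale": patch_scale,
                    "scale": np.nan,
                    "n_grids": 0,
                    "focal_cv": np.nan,
                    "focal_pct": np.nan,
                }
            )
            continue
        for s in res.summaries:
            rows.append(
                {
                    "level": level_ix,
                    "patch_scale": patch_scale,
                    "scale": s.scale_index,
                    "n_grids": s.n_grids,
                    "focal_cv": s.mean_cv[focal_group],
                    "focal_pct": s.mean_pct[focal_group],
                }
            )
    table = pd.DataFrame(rows)

    per_level = (
        table.dropna(subset=["focal_cv", "focal_pct"])
        .groupby("level")[["focal_cv", "focal_pct"]]
        .mean()
    )
    if len(per_level) < 3:
        raise ValueError("fewer than 3 usable variability levels")
    rho = float(
        stats.spearmanr(per_level["focal_cv"], per_level["focal_pct"]).statistic
    )
    x = per_level["focal_cv"].to_numpy()
    y = per_level["focal_pct"].to_numpy()
    model = sm.OLS(y, sm.add_constant(x)).fit()
    regression = RegressionResult(
        group=focal_group,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        df=(1, int(model.df_resid)),
        n_points=len(per_level),
    )
    return table, regression, rho
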