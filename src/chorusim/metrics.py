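"""Dependent variables, pooled summaries, effect sizes and α-weighted fitness.

The simulation's dependent variables are the pulse number of the male a
female mates (quality proxy), the distance she travels, the number of
distinct males she targets, and whether she mates at all.  This module pools
outcome rows into grouped means with 95% confidence intervals, computes
Cohen's d contrasts, delegates the factorial ANOVA/Tukey reporting to
statsmodels, and evaluates the nightly fitness measure

    fitness = (1 - α) · (MeanPN - MinPN) / (MaxPN - MinPN)
              + α · (1 - (MeanDist - MinDist) / (MaxDist - MinDist))

where α ∈ [0, 1] weighs travel cost against mate quality, the PN extremes are
taken over mated males in the entire outcome database, the distance extremes
over all females, and unmated females contribute mate quality 0 to MeanPN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "summarize",
    "cohens_d",
    "FitnessParams",
    "fitness",
    "fitness_by_group",
    "anova_report",
    "tukey_hsd",
]

logger = logging.getLogger(__name__)

_Z95 = 1.96  # normal-approximation 95% CI on pooled female-level values


def _mean_ci(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return np.nan, np.nan
    m = float(values.mean())
    if values.size < 2:
        return m, np.nan
    half = _Z95 * float(values.std(ddof=1)) / np.sqrt(values.size)
    return m, half


#: columns that identify one simulated night within a pooled outcome table
SIM_KEYS = ("strategy", "pop_mean", "n_females", "distribution", "seed")


def _pooled(g: pd.DataFrame, col: str, mated_only: bool, weighting: str,
            sim_keys: Sequence[str]) -> tuple[float, float]:
    d = g[g["mated"]] if mated_only else g
    if weighting == "female":
        return _mean_ci(d[col].to_numpy(float))
    per_sim = d.groupby(list(sim_keys), sort=False, observed=True)[col].mean()
    return _mean_ci(per_sim.to_numpy(float))


def summarize(
    outcomes: pd.DataFrame,
    group_by: Sequence[str] = ("strategy_class",),
    mated_only_pn: bool = True,
    mated_only_dist: bool = False,
    weighting: str = "simulation",
    sim_keys: Sequence[str] = SIM_KEYS,
) -> pd.DataFrame:
    """Grouped means (± 95% CI half-widths) of the dependent variables.

    The simulated night is the replicate unit: with the default
    ``weighting="simulation"`` each run contributes its per-run mean, so a
    20-female night carries the same weight as a 5-female night.
    ``weighting="female"`` pools raw female rows instead (runs with more
    females then weigh more).  Mate pulse number is averaged over mated
    females only by default (the reporting convention for mate-quality
    tables); set ``mated_only_dist`` to restrict the distance average to
    mated females as well, e.g. to separate travel cost from the one-step
    exits of threshold females who never find an acceptable male.
    """
    if outcomes.empty:
        raise ValueError("outcome table is empty")
    if weighting not in ("simulation", "female"):
        raise ValueError("weighting must be 'simulation' or 'female'")
    if weighting == "simulation":
        sim_keys = [c for c in sim_keys if c in outcomes.columns]
        if not sim_keys:
            raise ValueError("no simulation-identifying columns present; "
                             "use weighting='female'")
    rows = []
    for keys, g in outcomes.groupby(list(group_by), sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        mean_pn, ci_pn = _pooled(g, "mate_pulsenumber", mated_only_pn,
                                 weighting, sim_keys)
        mean_dist, ci_dist = _pooled(g, "distance_cm", mated_only_dist,
                                     weighting, sim_keys)
        mean_tg, ci_tg = _pooled(g, "n_targets", False, weighting, sim_keys)
        pct, _ = _pooled(g.assign(_m=g["mated"].astype(float)), "_m", False,
                         weighting, sim_keys)
        rows.append({
            **dict(zip(group_by, keys)),
            "n": len(g),
            "n_mated": int(g["mated"].sum()),
            "mean_pulsenumber": mean_pn,
            "ci_pulsenumber": ci_pn,
            "mean_distance_cm": mean_dist,
            "ci_distance_cm": ci_dist,
            "mean_n_targets": mean_tg,
            "ci_n_targets": ci_tg,
            "percent_mated": 100.0 * pct,
        })
    return pd.DataFrame(rows)


def cohens_d(group_a: Iterable[float], group_b: Iterable[float]) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    pooled_var = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ZeroDivisionError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class FitnessParams:
    """α plus the normalisation extremes taken over the whole outcome
    database: pulse-number extremes over mated males, distance extremes over
    all females."""

    alpha: float
    min_pn: float
    max_pn: float
    min_dist: float
    max_dist: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not (self.max_pn > self.min_pn and self.max_dist > self.min_dist):
            raise ValueError("degenerate normalisation extremes")

    @classmethod
    def from_outcomes(cls, outcomes: pd.DataFrame,
                      alpha: float) -> "FitnessParams":
        mated_pn = outcomes.loc[outcomes["mated"], "mate_pulsenumber"]
        return cls(
            alpha=alpha,
            min_pn=float(mated_pn.min()),
            max_pn=float(mated_pn.max()),
            min_dist=float(outcomes["distance_cm"].min()),
            max_dist=float(outcomes["distance_cm"].max()),
        )


def fitness(params: FitnessParams, mean_pn: float, mean_dist: float) -> float:
    """Convex combination of normalised mate quality and reversed normalised
    travel distance; increasing in quality, decreasing in distance."""
    q = (mean_pn - params.min_pn) / (params.max_pn - params.min_pn)
    c = (mean_dist - params.min_dist) / (params.max_dist - params.min_dist)
    return (1.0 - params.alpha) * q + params.alpha * (1.0 - c)


def fitness_by_group(
    outcomes: pd.DataFrame,
    alphas: Iterable[float],
    group_by: Sequence[str] = ("strategy_class",),
    weighting: str = "simulation",
    sim_keys: Sequence[str] = SIM_KEYS,
) -> pd.DataFrame:
    """Fitness per group over a grid of α values.

    MeanPN counts unmated females as mate quality 0 (the lost-opportunity
    penalty); MeanDist pools all females; the normalisation extremes come
    from the full table, so groups share one scale.  Weighting follows the
    same convention as :func:`summarize`.
    """
    if weighting == "simulation":
        sim_keys = [c for c in sim_keys if c in outcomes.columns]
        if not sim_keys:
            raise ValueError("no simulation-identifying columns present; "
                             "use weighting='female'")
    base = outcomes.assign(_pn0=outcomes["mate_pulsenumber"].fillna(0.0))
    rows = []
    for alpha in alphas:
        params = FitnessParams.from_outcomes(outcomes, alpha)
        for keys, g in base.groupby(list(group_by), sort=True):
            if not isinstance(keys, tuple):
                keys = (keys,)
            mean_pn, _ = _pooled(g, "_pn0", False, weighting, sim_keys)
            mean_dist, _ = _pooled(g, "distance_cm", False, weighting,
                                   sim_keys)
            rows.append({
                **dict(zip(group_by, keys)),
                "alpha": alpha,
                "mean_pn": mean_pn,
                "mean_dist": mean_dist,
                "fitness": fitness(params, mean_pn, mean_dist),
            })
    return pd.DataFrame(rows)


_FACTOR_SHORT = {
    "strategy": "sp",
    "n_females": "nf",
    "distribution": "md",
    "pop_mean": "mp",
}


def anova_report(
    outcomes: pd.DataFrame,
    dv: str,
    factors: Sequence[str] = ("strategy", "n_females", "distribution",
                              "pop_mean"),
    max_order: int | None = None,
) -> pd.DataFrame:
    """Factorial ANOVA table (factor, df, F, p) for one dependent variable.

    Thin reporting layer over statsmodels OLS + sequential (type I) ANOVA,
    with all factors categorical and interactions up to ``max_order`` (full
    factorial by default).  Factors with a single observed level are dropped
    with a warning; rows with a missing dependent variable (e.g. mate pulse
    number of unmated females) are excluded.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = outcomes.dropna(subset=[dv]).copy()
    keep = []
    for f in factors:
        if data[f].nunique() < 2:
            logger.warning("factor %r has one level; excluded", f)
        else:
            keep.append(f)
    if not keep:
        raise ValueError("no factor with at least two levels")
    terms = [f"C({f})" for f in keep]
    formula = f"{dv} ~ " + ("*".join(terms) if max_order is None else
                            f"({' + '.join(terms)}) ** {max_order}")
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        columns={"df": "df", "F": "F_value", "PR(>F)": "p"}).reset_index(
        names="term")
    for f in keep:
        table["term"] = table["term"].str.replace(f"C({f})", _FACTOR_SHORT.get(f, f),
                                                  regex=False)
    return table[["term", "df", "F_value", "p"]]


def tukey_hsd(outcomes: pd.DataFrame, dv: str, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one factor (statsmodels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = outcomes.dropna(subset=[dv])
    res = pairwise_tukeyhsd(data[dv].to_numpy(float),
                            data[factor].astype(str).to_numpy())
    return pd.DataFrame(res.summary().data[1:],
                        columns=res.summary().data[0])
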