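"""Desk-scale replication of the study's headline statistics.

Runs the default factorial design restricted to each strategy class at a
reduced replicate count (20 per cell instead of 100, i.e. 14,400 runs in
total across the four classes) and recomputes the pooled summary statistics:
class-level mate pulse number, distance traveled, number of males targeted,
percent of females mating, the best-of-5 vs best-of-1 and θ=24 vs random
mate-quality contrasts, and the competition-driven distance increase from 5
to 20 females.  Statistics follow the per-simulation weighting convention of
:func:`chorusim.metrics.summarize`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import summarize
from .strategies import Strategy
from .sweep import SweepConfig, run_sweep

__all__ = ["desk_sweeps", "headline_statistics"]

CLASS_STRATEGIES: dict[str, tuple[Strategy, ...]] = {
    "min_threshold": tuple(Strategy("min_threshold", t) for t in (6, 12, 18, 24)),
    "best_of_n": tuple(Strategy("best_of_n", n) for n in range(1, 6)),
    "random": (Strategy("random"),),
    "best_of_n_no_switch": tuple(
        Strategy("best_of_n_no_switch", n) for n in range(1, 6)),
}


def desk_sweeps(base_seed: int = 0,
                replicates: int = 20) -> dict[str, pd.DataFrame]:
    """Run the per-class sweeps over the full default grid of male population
    means, female counts and spatial distributions."""
    out = {}
    for name, strats in CLASS_STRATEGIES.items():
        sweep = SweepConfig(strategies=strats, replicates=replicates,
                            base_seed=base_seed)
        out[name] = run_sweep(sweep)
    return out


def _stat(value: float, frame: pd.DataFrame) -> dict:
    return {"value": float(np.round(value, 4)), "n": int(len(frame))}


def headline_statistics(sweeps: dict[str, pd.DataFrame]) -> dict[str, dict]:
    """Pooled summary statistics from the per-class sweep tables.

    Returns a mapping of descriptive names to ``{"value": ..., "n": ...}``
    where ``n`` is the number of female rows feeding the statistic.
    """
    mt, bn = sweeps["min_threshold"], sweeps["best_of_n"]
    rd, ns = sweeps["random"], sweeps["best_of_n_no_switch"]

    s_mt = summarize(mt).iloc[0]
    s_mt_mated = summarize(mt, mated_only_dist=True).iloc[0]
    s_bn = summarize(bn).iloc[0]
    s_rd = summarize(rd).iloc[0]
    s_ns = summarize(ns).iloc[0]

    by_n = summarize(bn, group_by=["param"]).set_index("param")
    pn1, pn5 = by_n.loc[1, "mean_pulsenumber"], by_n.loc[5, "mean_pulsenumber"]

    by_theta = summarize(mt, group_by=["param"]).set_index("param")
    pn_theta24 = by_theta.loc[24, "mean_pulsenumber"]
    pn_random = s_rd["mean_pulsenumber"]

    by_nf = summarize(bn, group_by=["n_females"]).set_index("n_females")
    d5, d20 = by_nf.loc[5, "mean_distance_cm"], by_nf.loc[20, "mean_distance_cm"]

    return {
        "threshold_mate_pulsenumber": _stat(s_mt["mean_pulsenumber"], mt),
        "threshold_percent_mated": _stat(s_mt["percent_mated"], mt),
        "best_of_n_distance_cm": _stat(s_bn["mean_distance_cm"], bn),
        "best_of_n_targets": _stat(s_bn["mean_n_targets"], bn),
        "random_distance_cm": _stat(s_rd["mean_distance_cm"], rd),
        "threshold_mated_only_distance_cm": _stat(
            s_mt_mated["mean_distance_cm"], mt[mt["mated"]]),
        "best_of_5_vs_1_quality_gain_pct": _stat(
            100.0 * (pn5 - pn1) / pn1, bn),
        "threshold24_vs_random_quality_gain_pct": _stat(
            100.0 * (pn_theta24 - pn_random) / pn_random,
            mt[mt["param"] == 24]),
        "best_of_n_distance_increase_pct": _stat(
            100.0 * (d20 - d5) / d5,
            bn[bn["n_females"].isin((5, 20))]),
        "no_switch_targets": _stat(s_ns["mean_n_targets"], ns),
        "no_switch_distance_cm": _stat(s_ns["mean_distance_cm"], ns),
    }
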