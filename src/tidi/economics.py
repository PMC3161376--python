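"""Economic post-processing of PSA results.

Given per-draw cost and effect vectors for a set of mutually exclusive
alternatives (strategy x treatment combinations), this module computes

* incremental net monetary benefit, ``INMB = lambda * dE - dC``, with
  empirical percentile intervals over the PSA draws;
* the ICER efficiency frontier, excluding dominated and extendedly
  dominated alternatives so the surviving incremental cost-effectiveness
  ratios are strictly increasing;
* cost-effectiveness acceptability curves (CEAC): at each willingness-to-
  pay threshold, the probability that each alternative maximises net
  monetary benefit, with exact ties split equally;
* incremental clinical outcomes and cost per clinical unit (means of
  draws, not per-draw ratios, to avoid ratio instability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import PSAResult

Alternative = tuple[str, str]


def _vectors(psa: PSAResult, alt: Alternative, column: str) -> np.ndarray:
    if alt not in psa.outcomes:
        raise KeyError(f"alternative {alt} not present in PSA result")
    return psa.outcomes[alt][column].to_numpy()


@dataclass(frozen=True)
class InmbResult:
    mean: float
    interval: tuple[float, float]
    per_draw: np.ndarray


def inmb(psa: PSAResult, a: Alternative, b: Alternative, lam: float) -> InmbResult:
    """Incremental net monetary benefit of ``a`` vs ``b`` at threshold ``lam``.

    Per draw, ``INMB = lam * (E_a - E_b) - (C_a - C_b)`` with effects
    measured in QALYs; the interval is the empirical 2.5/97.5 percentile
    band over draws.
    """
    if lam < 0:
        raise ValueError("willingness-to-pay lambda must be >= 0")
    d_e = _vectors(psa, a, "qaly") - _vectors(psa, b, "qaly")
    d_c = _vectors(psa, a, "cost") - _vectors(psa, b, "cost")
    per_draw = lam * d_e - d_c
    lo, hi = np.percentile(per_draw, [2.5, 97.5])
    return InmbResult(mean=float(per_draw.mean()), interval=(float(lo), float(hi)),
                      per_draw=per_draw)


def frontier(
    mean_costs: Mapping[Hashable, float],
    mean_effects: Mapping[Hashable, float],
) -> pd.DataFrame:
    """ICER efficiency frontier with dominance and extended dominance.

    Alternatives are sorted by ascending mean cost (ties by descending
    effect, then input order).  An alternative is *dominated* if another
    costs no more and yields at least as much effect (ties on both: the
    one listed first is kept).  Remaining alternatives are *extendedly
    dominated* — removed iteratively — while the ICER of the step reaching
    them exceeds (or equals) the ICER of the following step, leaving
    strictly increasing ICERs along the frontier.

    Returns a table with columns ``alternative, cost, effect, status,
    icer`` where status is one of ``frontier, dominated,
    extendedly_dominated`` and ``icer`` is the incremental ratio vs the
    previous frontier point (NaN for the cheapest point and for excluded
    rows).
    """
    alts = list(mean_costs)
    if not alts:
        raise ValueError("frontier requires at least one alternative")
    if set(alts) != set(mean_effects):
        raise ValueError("mean_costs and mean_effects must cover the same alternatives")
    costs = {a: float(mean_costs[a]) for a in alts}
    effects = {a: float(mean_effects[a]) for a in alts}
    if not all(np.isfinite(list(costs.values()) + list(effects.values()))):
        raise ValueError("frontier requires finite means")
    order = {a: i for i, a in enumerate(alts)}

    status = {a: "frontier" for a in alts}
    # strict dominance (tie on both axes: keep the alternative listed first)
    for a in alts:
        for b in alts:
            if a == b or status[a] != "frontier":
                continue
            cb, ca = costs[b], costs[a]
            eb, ea = effects[b], effects[a]
            if (cb < ca and eb >= ea) or (cb <= ca and eb > ea):
                status[a] = "dominated"
            elif cb == ca and eb == ea and order[b] < order[a]:
                status[a] = "dominated"

    def sort_key(a):
        return (costs[a], -effects[a], order[a])

    candidates = sorted((a for a in alts if status[a] == "frontier"), key=sort_key)

    # extended dominance: drop interior points until ICERs strictly increase
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            prev_, cur, nxt = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_in = (costs[cur] - costs[prev_]) / (effects[cur] - effects[prev_])
            icer_out = (costs[nxt] - costs[cur]) / (effects[nxt] - effects[cur])
            if icer_in >= icer_out:
                status[cur] = "extendedly_dominated"
                candidates.pop(i)
                changed = True
                break

    icers: dict[Hashable, float] = {}
    for prev_, cur in zip(candidates, candidates[1:]):
        icers[cur] = (costs[cur] - costs[prev_]) / (effects[cur] - effects[prev_])

    rows = [
        {
            "alternative": a,
            "cost": costs[a],
            "effect": effects[a],
            "status": status[a],
            "icer": icers.get(a, np.nan),
        }
        for a in sorted(alts, key=sort_key)
    ]
    return pd.DataFrame(rows)


def ceac(psa: PSAResult, lambda_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a threshold grid.

    At each lambda, each alternative's probability is the fraction of
    draws in which its net monetary benefit ``lam * E - C`` is maximal;
    exact ties split equally among the tied set, so the probabilities sum
    to 1 at every threshold by construction.
    """
    if psa.n_sims < 2:
        raise ValueError("CEAC requires a stochastic PSA with n_sims >= 2")
    grid = np.asarray(
        psa.options.lambda_grid if lambda_grid is None else lambda_grid, dtype=float
    )
    alts = psa.alternatives
    effects = np.column_stack([_vectors(psa, a, "qaly") for a in alts])
    costs = np.column_stack([_vectors(psa, a, "cost") for a in alts])

    probs = np.empty((grid.size, len(alts)))
    for i, lam in enumerate(grid):
        nmb = lam * effects - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    df = pd.DataFrame(probs, columns=pd.MultiIndex.from_tuples(alts), index=grid)
    df.index.name = "lambda"
    return df


def ceac_long(ceac_df: pd.DataFrame) -> pd.DataFrame:
    """CEAC in long format: lambda, strategy, treatment, probability."""
    long = ceac_df.stack([0, 1], future_stack=True).rename("probability").reset_index()
    long.columns = ["lambda", "strategy", "treatment", "probability"]
    return long


def incremental_clinical(
    psa: PSAResult,
    a: Alternative,
    b: Alternative,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Mean incremental clinical outcomes of ``a`` vs ``b`` with cost per unit.

    Cost per unit is the ratio of mean increments, ``dCost / |dk|``,
    reported only when ``|dk| > eps``; otherwise the ratio is flagged
    undefined.
    """
    if a == b:
        raise ValueError("alternatives must differ")
    d_cost = float(np.mean(_vectors(psa, a, "cost") - _vectors(psa, b, "cost")))
    rows = []
    for k in psa.outcome_names:
        if k == "cost":
            continue
        dk = float(np.mean(_vectors(psa, a, k) - _vectors(psa, b, k)))
        defined = abs(dk) > eps
        rows.append(
            {
                "outcome": k,
                "delta": dk,
                "delta_cost": d_cost,
                "cost_per_unit": d_cost / abs(dk) if defined else np.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EconSummary:
    """Bundle of the economic post-processing tables for one PSA run."""

    comparator: str
    means: pd.DataFrame     # per-alternative mean cost/effect/clinical outcomes
    incrementals: pd.DataFrame  # vs the comparator strategy, same treatment
    inmb_table: pd.DataFrame    # lambda x alternative mean INMB with 95% interval
    icer_table: pd.DataFrame    # frontier with exclusion labels
    ceac_table: pd.DataFrame    # lambda x alternative probabilities


def summarize(
    psa: PSAResult,
    comparator: str = "1",
    inmb_lambdas: Sequence[float] = (10000.0, 20000.0, 30000.0),
) -> EconSummary:
    """Standard post-processing bundle.

    ``comparator`` is a strategy id; incremental tables compare each
    (strategy, treatment) against (comparator, same treatment).  The
    frontier treats every combination as a mutually exclusive alternative.
    CEAC is computed only for stochastic runs (n_sims >= 2).
    """
    alts = psa.alternatives
    if comparator not in {s for s, _ in alts}:
        raise KeyError(f"comparator strategy {comparator!r} not in PSA result")

    means = pd.DataFrame(
        {alt: psa.outcomes[alt].mean() for alt in alts}
    ).T.rename_axis(["strategy", "treatment"])

    inc_rows = []
    for s, t in alts:
        if s == comparator:
            continue
        inc = incremental_clinical(psa, (s, t), (comparator, t))
        inc.insert(0, "strategy", s)
        inc.insert(1, "treatment", t)
        inc_rows.append(inc)
    incrementals = (
        pd.concat(inc_rows, ignore_index=True) if inc_rows else pd.DataFrame()
    )

    inmb_rows = []
    for lam in inmb_lambdas:
        for s, t in alts:
            if s == comparator:
                continue
            r = inmb(psa, (s, t), (comparator, t), lam)
            inmb_rows.append(
                {
                    "lambda": lam, "strategy": s, "treatment": t,
                    "inmb_mean": r.mean, "inmb_low": r.interval[0],
                    "inmb_high": r.interval[1],
                }
            )
    inmb_table = pd.DataFrame(inmb_rows)

    icer_table = frontier(
        {alt: float(means.loc[alt, "cost"]) for alt in alts},
        {alt: float(means.loc[alt, "qaly"]) for alt in alts},
    )
    ceac_table = ceac(psa) if psa.n_sims >= 2 else pd.DataFrame()
    return EconSummary(
        comparator=comparator,
        means=means,
        incrementals=incrementals,
        inmb_table=inmb_table,
        icer_table=icer_table,
        ceac_table=ceac_table,
    )
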