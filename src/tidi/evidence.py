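"""Bias-adjusted random-effects meta-analysis of log odds ratios.

Evidence on treatment effectiveness enters a decision model as a pooled
odds ratio. This module synthesises 2x2 trial tables (or precomputed
log-OR / SE pairs) under a random-effects model, with two interchangeable
engines:

* ``dl`` -- the DerSimonian-Laird method-of-moments fit, instantaneous and
  deterministic, suited to interactive re-runs;
* ``bayes`` -- a Gibbs-sampled normal-normal hierarchical model with a
  uniform prior on the between-study SD, which carries full posterior
  uncertainty through to the decision model.

Before pooling, each study's estimate may be adjusted for elicited
*internal* biases (lack of rigor) and *external* biases (limited relevance
to the target question), each acting either *additively* on the log odds
ratio or *proportionally* on the treatment effect.  Multiple assessors'
elicitations for the same bias are pooled as an equal-weight mixture; the
per-study adjustment propagates the pooled bias distributions by a
first-order delta method.  Every bias class, every study and every
assessor can be toggled in :class:`MetaConfig`, so "what if we drop study
S3 / ignore external biases / trust only assessor A1" questions are one
re-run away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z95 = 1.96  # conventional normal quantile for 95% intervals

NATURES = ("internal", "external")
ACTIONS = ("additive", "proportional")
METHODS = ("dl", "bayes")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study:
    """One trial, as a 2x2 table of counts or a precomputed (y, se) pair.

    Exactly one input mode must be used: either all four counts
    (``events_trt``, ``n_trt``, ``events_ctl``, ``n_ctl``) or the pair
    (``y``, ``se``) on the log odds ratio scale.  Supplying both is
    rejected rather than prioritised, to avoid silent inconsistency.
    """

    id: str
    label: str = ""
    events_trt: int | None = None
    n_trt: int | None = None
    events_ctl: int | None = None
    n_ctl: int | None = None
    y: float | None = None
    se: float | None = None
    included: bool = True

    def __post_init__(self) -> None:
        counts = (self.events_trt, self.n_trt, self.events_ctl, self.n_ctl)
        has_counts = all(c is not None for c in counts)
        any_counts = any(c is not None for c in counts)
        has_ys = self.y is not None and self.se is not None
        any_ys = self.y is not None or self.se is not None
        if any_counts and not has_counts:
            raise ValueError(f"study {self.id!r}: incomplete 2x2 counts")
        if has_counts and any_ys:
            raise ValueError(
                f"study {self.id!r}: supply counts OR (y, se), not both"
            )
        if not has_counts and not has_ys:
            raise ValueError(f"study {self.id!r}: no usable input (counts or y/se)")
        if has_counts:
            for name, val in zip(("events_trt", "n_trt", "events_ctl", "n_ctl"), counts):
                if val < 0:
                    raise ValueError(f"study {self.id!r}: {name} < 0")
            if self.events_trt > self.n_trt or self.events_ctl > self.n_ctl:
                raise ValueError(f"study {self.id!r}: events exceed arm size")
        if has_ys and self.se <= 0:
            raise ValueError(f"study {self.id!r}: se must be > 0")

    @property
    def has_counts(self) -> bool:
        return self.events_trt is not None


@dataclass(frozen=True)
class BiasElicitation:
    """One assessor's elicited distribution for one bias on one study.

    ``mean`` is a log-OR shift for additive biases and a multiplicative
    factor on the treatment effect for proportional biases.
    """

    assessor_id: str
    study_id: str
    bias_id: str
    nature: str
    action: str
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.nature not in NATURES:
            raise ValueError(f"nature must be one of {NATURES}, got {self.nature!r}")
        if self.action not in ACTIONS:
            raise ValueError(f"action must be one of {ACTIONS}, got {self.action!r}")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.action == "proportional" and self.mean == 0:
            raise ValueError("proportional bias mean must be nonzero")


@dataclass
class MCMCOptions:
    iterations: int = 5000  # retained draws after burn-in
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


@dataclass
class Priors:
    """Vague default priors: mu ~ Normal(0, 1e4), tau ~ Uniform(0, 5)."""

    mu_mean: float = 0.0
    mu_var: float = 1.0e4
    tau_upper: float = 5.0

    def __post_init__(self) -> None:
        if self.mu_var <= 0:
            raise ValueError("mu_var must be positive")
        if self.tau_upper < 0:
            raise ValueError("tau_upper must be non-negative")


@dataclass
class MetaConfig:
    """Interactive switches for one meta-analysis run.

    ``selected_study_ids`` / ``selected_assessor_ids`` of ``None`` mean
    "all available"; nature and action toggles are independent filters on
    the elicited biases.
    """

    selected_study_ids: set[str] | None = None
    include_internal: bool = True
    include_external: bool = True
    include_additive: bool = True
    include_proportional: bool = True
    selected_assessor_ids: set[str] | None = None
    method: str = "dl"
    mcmc: MCMCOptions = field(default_factory=MCMCOptions)
    priors: Priors = field(default_factory=Priors)
    continuity: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.selected_study_ids is not None and not self.selected_study_ids:
            raise ValueError("selected_study_ids must be non-empty when given")
        if self.mcmc.burn_in >= self.mcmc.iterations + self.mcmc.burn_in + 1:
            raise ValueError("invalid mcmc settings")
        if self.continuity < 0:
            raise ValueError("continuity must be >= 0")

    @property
    def any_bias(self) -> bool:
        return (self.include_internal or self.include_external) and (
            self.include_additive or self.include_proportional
        )


@dataclass(frozen=True)
class PooledBias:
    """Assessor-pooled distribution for one bias acting on one study."""

    study_id: str
    bias_id: str
    action: str
    mean: float
    variance: float
    n_assessors: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("pooled variance must be >= 0")
        if self.n_assessors < 1:
            raise ValueError("n_assessors must be positive")


@dataclass(frozen=True)
class AdjustedStudy:
    """A study estimate after bias adjustment.

    ``alpha``/``var_alpha`` summarise the total additive bias, ``pi``/
    ``var_pi`` the total proportional factor; ``y_adj``/``var_adj`` are the
    delta-method mean and variance of the bias-corrected log odds ratio.
    """

    study_id: str
    y_adj: float
    var_adj: float
    alpha: float = 0.0
    var_alpha: float = 0.0
    pi: float = 1.0
    var_pi: float = 0.0

    def __post_init__(self) -> None:
        if self.var_adj <= 0:
            raise ValueError("var_adj must be positive")
        if self.pi == 0:
            raise ValueError("total proportional factor must be nonzero")


@dataclass
class MetaResult:
    """Pooled estimate plus per-study detail, on log-OR and OR scales."""

    per_study: list[tuple[str, float, float, tuple[float, float]]]
    mu_point: float
    mu_interval: tuple[float, float]
    tau_point: float
    method: str
    mu_samples: np.ndarray | None = None
    unadjusted_companion: "MetaResult | None" = None

    @property
    def or_point(self) -> float:
        return float(math.exp(self.mu_point))

    @property
    def or_interval(self) -> tuple[float, float]:
        lo, hi = self.mu_interval
        return (float(math.exp(lo)), float(math.exp(hi)))

    @property
    def k(self) -> int:
        return len(self.per_study)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_log_or(study: Study, continuity: float = 0.5) -> tuple[float, float]:
    """Log odds ratio and its SE from a study's 2x2 table.

    The continuity correction is added to all four cells, and only when at
    least one cell is zero (Haldane-Anscombe convention).  Studies supplied
    directly as (y, se) pass through unchanged.
    """
    if not study.has_counts:
        return float(study.y), float(study.se)
    if continuity < 0:
        raise ValueError("continuity must be >= 0")
    a = study.events_trt
    b = study.n_trt - study.events_trt
    c = study.events_ctl
    d = study.n_ctl - study.events_ctl
    for arm, (ev, nonev) in (("treatment", (a, b)), ("control", (c, d))):
        if ev == 0 and nonev == 0:
            raise ValueError(
                f"study {study.id!r}: {arm} arm has no events and no "
                "non-events (empty margin); cannot estimate a log OR"
            )
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + continuity
    a_, b_, c_, d_ = cells
    y = math.log((a_ * d_) / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return y, se


def pool_assessors(
    elicitations: Sequence[BiasElicitation],
    config: MetaConfig,
    known_study_ids: Iterable[str] | None = None,
) -> list[PooledBias]:
    """Pool per-assessor bias elicitations into one distribution per
    (study, bias).

    The K selected assessors' Normal(m_a, v_a) components form an
    equal-weight mixture; the pooled mean and variance are the mixture
    moments::

        m_bar = mean(m_a)
        v_bar = mean(v_a + m_a^2) - m_bar^2

    Biases whose nature or action is deselected in ``config`` are dropped
    entirely; a (study, bias) pair elicited only by deselected assessors is
    dropped with a logged warning rather than an error.
    """
    if known_study_ids is not None:
        known = set(known_study_ids)
        for e in elicitations:
            if e.study_id not in known:
                raise ValueError(
                    f"elicitation by {e.assessor_id!r} references unknown "
                    f"study {e.study_id!r}"
                )

    def nature_ok(n: str) -> bool:
        return config.include_internal if n == "internal" else config.include_external

    def action_ok(a: str) -> bool:
        return config.include_additive if a == "additive" else config.include_proportional

    groups: dict[tuple[str, str], list[BiasElicitation]] = {}
    retained_keys: list[tuple[str, str]] = []
    for e in elicitations:
        if not (nature_ok(e.nature) and action_ok(e.action)):
            continue
        if config.selected_study_ids is not None and e.study_id not in config.selected_study_ids:
            continue
        key = (e.study_id, e.bias_id)
        if key not in groups:
            groups[key] = []
            retained_keys.append(key)
        groups[key].append(e)

    pooled: list[PooledBias] = []
    for key in retained_keys:
        group = groups[key]
        actions = {e.action for e in group}
        if len(actions) > 1:
            raise ValueError(
                f"bias {key[1]!r} on study {key[0]!r} elicited with "
                "inconsistent actions across assessors"
            )
        selected = [
            e
            for e in group
            if config.selected_assessor_ids is None
            or e.assessor_id in config.selected_assessor_ids
        ]
        if not selected:
            logger.warning(
                "bias %r on study %r has no selected assessor; dropped", key[1], key[0]
            )
            continue
        m = np.array([e.mean for e in selected])
        v = np.array([e.variance for e in selected])
        m_bar = float(m.mean())
        v_bar = float(np.mean(v + m**2) - m_bar**2)
        v_bar = max(v_bar, 0.0)  # guard tiny negative rounding
        pooled.append(
            PooledBias(
                study_id=key[0],
                bias_id=key[1],
                action=actions.pop(),
                mean=m_bar,
                variance=v_bar,
                n_assessors=len(selected),
            )
        )
    return pooled


def adjust_study(
    study_id: str,
    y: float,
    se: float,
    additive: Sequence[PooledBias] = (),
    proportional: Sequence[PooledBias] = (),
) -> AdjustedStudy:
    """Bias-correct one study estimate by the delta method.

    The target estimand is ``(y* - A) / P`` where ``A`` is the sum of the
    additive biases and ``P`` the product of the proportional factors, all
    independent.  First-order propagation gives::

        alpha   = sum of additive means         sigma2_A  = sum of additive variances
        pi      = product of proportional means sigma2_pi = pi^2 * sum(v_b / m_b^2)
        y_adj   = (y - alpha) / pi
        var_adj = (se^2 + sigma2_A) / pi^2  +  (y - alpha)^2 * sigma2_pi / pi^4
    """
    if se <= 0:
        raise ValueError("se must be positive")
    alpha = float(sum(b.mean for b in additive))
    var_alpha = float(sum(b.variance for b in additive))
    pi = 1.0
    rel_var = 0.0
    for b in proportional:
        if b.mean == 0:
            raise ValueError(
                f"proportional bias {b.bias_id!r} on study {study_id!r} has "
                "pooled mean 0; adjustment would divide by zero"
            )
        pi *= b.mean
        rel_var += b.variance / b.mean**2
    var_pi = pi**2 * rel_var
    y_adj = (y - alpha) / pi
    var_adj = (se**2 + var_alpha) / pi**2 + (y - alpha) ** 2 * var_pi / pi**4
    return AdjustedStudy(
        study_id=study_id,
        y_adj=y_adj,
        var_adj=var_adj,
        alpha=alpha,
        var_alpha=var_alpha,
        pi=pi,
        var_pi=var_pi,
    )


def _per_study_rows(
    adjusted: Sequence[AdjustedStudy],
) -> list[tuple[str, float, float, tuple[float, float]]]:
    rows = []
    for s in adjusted:
        half = Z95 * math.sqrt(s.var_adj)
        rows.append((s.study_id, s.y_adj, s.var_adj, (s.y_adj - half, s.y_adj + half)))
    return rows


def dl_meta(adjusted: Sequence[AdjustedStudy]) -> MetaResult:
    """DerSimonian-Laird random-effects synthesis.

    Method-of-moments heterogeneity estimate from Cochran's Q, then an
    inverse-variance pooled mean under weights 1/(v_i + tau2).
    """
    if not adjusted:
        raise ValueError("dl_meta requires at least one study")
    y = np.array([s.y_adj for s in adjusted])
    v = np.array([s.var_adj for s in adjusted])
    k = len(y)
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se_mu = float(np.sum(w_star) ** -0.5)
    return MetaResult(
        per_study=_per_study_rows(adjusted),
        mu_point=mu,
        mu_interval=(mu - Z95 * se_mu, mu + Z95 * se_mu),
        tau_point=math.sqrt(tau2),
        method="dl",
    )


def _slice_sample_tau(
    rng: np.random.Generator,
    tau0: float,
    k: int,
    sum_sq: float,
    tau_upper: float,
    max_shrink: int = 1000,
) -> float:
    """One shrinkage slice-sampling update of tau on (0, tau_upper].

    Target density (up to a constant) is tau^-k * exp(-S / (2 tau^2)) from
    the Normal(mu, tau^2) layer, times the Uniform(0, tau_upper) prior.
    The support is bounded, so the slice interval starts as the whole
    support and shrinks toward the current point; no stepping out needed.
    """

    def log_f(t: float) -> float:
        return -k * math.log(t) - sum_sq / (2.0 * t * t)

    log_y = log_f(tau0) + math.log(rng.uniform())
    lo, hi = 0.0, tau_upper
    for _ in range(max_shrink):
        t = rng.uniform(lo, hi)
        if t > 0 and log_f(t) >= log_y:
            return t
        if t < tau0:
            lo = t
        else:
            hi = t
    raise RuntimeError(
        "tau slice sampler failed to find an acceptable point after "
        f"{max_shrink} shrink steps (tau0={tau0:.3g}, S={sum_sq:.3g})"
    )


def bayes_meta(adjusted: Sequence[AdjustedStudy], config: MetaConfig) -> MetaResult:
    """Bayesian random-effects synthesis by Gibbs sampling.

    Model::

        y_i   ~ Normal(theta_i, v_i)        (v_i = var_adj, known)
        theta_i ~ Normal(mu, tau^2)
        mu    ~ Normal(mu_mean, mu_var)
        tau   ~ Uniform(0, tau_upper)

    theta_i and mu have conjugate normal full conditionals; tau is updated
    by shrinkage slice sampling on its bounded support.  Point estimates
    are posterior medians with central 95% intervals; the retained mu
    draws are kept for downstream propagation into the decision model.
    """
    if not adjusted:
        raise ValueError("bayes_meta requires at least one study")
    y = np.array([s.y_adj for s in adjusted])
    v = np.array([s.var_adj for s in adjusted])
    k = len(y)
    pr = config.priors
    mc = config.mcmc
    if mc.iterations <= 0 or mc.burn_in < 0:
        raise ValueError("non-positive mcmc settings")
    rng = np.random.default_rng(mc.seed)

    fixed_tau_zero = pr.tau_upper == 0.0
    if k == 1 and not fixed_tau_zero:
        logger.warning("single study: between-study SD tau fixed at 0")
        fixed_tau_zero = True

    n_total = mc.burn_in + mc.iterations
    mu_draws = np.empty(n_total)
    tau_draws = np.empty(n_total)

    if fixed_tau_zero:
        # theta_i == mu: the model collapses to a conjugate normal mean
        # problem; draw mu i.i.d. from its exact posterior.
        prec = np.sum(1.0 / v) + 1.0 / pr.mu_var
        mean = (np.sum(y / v) + pr.mu_mean / pr.mu_var) / prec
        mu_draws[:] = rng.normal(mean, prec**-0.5, size=n_total)
        tau_draws[:] = 0.0
    else:
        mu = float(np.sum(y / v) / np.sum(1.0 / v))
        tau = max(float(np.std(y)), 1e-3)
        theta = y.copy()
        for it in range(n_total):
            # theta_i | rest
            prec_i = 1.0 / v + 1.0 / tau**2
            mean_i = (y / v + mu / tau**2) / prec_i
            theta = rng.normal(mean_i, prec_i**-0.5)
            # mu | rest
            prec_mu = k / tau**2 + 1.0 / pr.mu_var
            mean_mu = (np.sum(theta) / tau**2 + pr.mu_mean / pr.mu_var) / prec_mu
            mu = float(rng.normal(mean_mu, prec_mu**-0.5))
            # tau | rest
            sum_sq = float(np.sum((theta - mu) ** 2))
            tau = _slice_sample_tau(rng, tau, k, sum_sq, pr.tau_upper)
            mu_draws[it] = mu
            tau_draws[it] = tau

    mu_kept = mu_draws[mc.burn_in :]
    tau_kept = tau_draws[mc.burn_in :]
    lo, hi = np.percentile(mu_kept, [2.5, 97.5])
    return MetaResult(
        per_study=_per_study_rows(adjusted),
        mu_point=float(np.median(mu_kept)),
        mu_interval=(float(lo), float(hi)),
        tau_point=float(np.median(tau_kept)),
        method="bayes",
        mu_samples=mu_kept.copy(),
    )


def _subset_studies(studies: Sequence[Study], config: MetaConfig) -> list[Study]:
    subset = [s for s in studies if s.included]
    if config.selected_study_ids is not None:
        missing = config.selected_study_ids - {s.id for s in studies}
        if missing:
            raise ValueError(f"selected unknown study ids: {sorted(missing)}")
        subset = [s for s in subset if s.id in config.selected_study_ids]
    if not subset:
        raise ValueError("study subset is empty")
    return subset


def run_meta(
    studies: Sequence[Study],
    elicitations: Sequence[BiasElicitation] = (),
    config: MetaConfig | None = None,
) -> MetaResult:
    """Full pipeline: subset -> pool assessors -> adjust -> synthesise.

    The unadjusted companion (same subset, no bias adjustment, same method
    and seed) is always computed and attached, mirroring the grayed-out
    comparison overlay of an interactive forest plot.  Given identical
    inputs and seed the result is reproducible bit-for-bit.
    """
    config = config or MetaConfig()
    subset = _subset_studies(studies, config)
    raw = {s.id: compute_log_or(s, config.continuity) for s in subset}

    pooled = pool_assessors(elicitations, config, known_study_ids=[s.id for s in studies])
    by_study: dict[str, list[PooledBias]] = {}
    for b in pooled:
        by_study.setdefault(b.study_id, []).append(b)

    adjusted: list[AdjustedStudy] = []
    unadjusted: list[AdjustedStudy] = []
    for s in subset:
        y, se = raw[s.id]
        biases = by_study.get(s.id, [])
        adjusted.append(
            adjust_study(
                s.id,
                y,
                se,
                additive=[b for b in biases if b.action == "additive"],
                proportional=[b for b in biases if b.action == "proportional"],
            )
        )
        unadjusted.append(AdjustedStudy(study_id=s.id, y_adj=y, var_adj=se**2))

    def synthesise(adj: list[AdjustedStudy]) -> MetaResult:
        if config.method == "dl":
            return dl_meta(adj)
        return bayes_meta(adj, config)

    result = synthesise(adjusted)
    result.unadjusted_companion = synthesise(unadjusted)
    return result


def forest_data(result: MetaResult) -> pd.DataFrame:
    """Forest-plot table on the OR scale, adjusted and unadjusted variants.

    One row per study plus a ``pooled`` row; study weight shares are the
    normalised random-effects weights 1/(v_i + tau2) and sum to 1.
    """

    def rows(res: MetaResult, variant: str) -> list[dict]:
        v = np.array([r[2] for r in res.per_study])
        w = 1.0 / (v + res.tau_point**2)
        shares = w / w.sum()
        out = []
        for (sid, y, _, (lo, hi)), share in zip(res.per_study, shares):
            out.append(
                {
                    "row": sid,
                    "variant": variant,
                    "or": math.exp(y),
                    "or_low": math.exp(lo),
                    "or_high": math.exp(hi),
                    "weight": float(share),
                }
            )
        lo, hi = res.or_interval
        out.append(
            {
                "row": "pooled",
                "variant": variant,
                "or": res.or_point,
                "or_low": lo,
                "or_high": hi,
                "weight": 1.0,
            }
        )
        return out

    all_rows = rows(result, "adjusted")
    if result.unadjusted_companion is not None:
        all_rows += rows(result.unadjusted_companion, "unadjusted")
    return pd.DataFrame(all_rows)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

STUDY_COLUMNS = [
    "id", "label", "events_trt", "n_trt", "events_ctl", "n_ctl", "y", "se", "included",
]
ELICITATION_COLUMNS = [
    "assessor_id", "study_id", "bias_id", "nature", "action", "mean", "variance",
]


def read_studies(path: str | Path) -> list[Study]:
    df = pd.read_csv(path, dtype={"id": str, "label": str})
    studies = []
    for rec in df.to_dict("records"):
        def opt_int(x):
            return None if pd.isna(x) else int(x)

        def opt_float(x):
            return None if pd.isna(x) else float(x)

        studies.append(
            Study(
                id=str(rec["id"]),
                label="" if pd.isna(rec.get("label")) else str(rec["label"]),
                events_trt=opt_int(rec.get("events_trt")),
                n_trt=opt_int(rec.get("n_trt")),
                events_ctl=opt_int(rec.get("events_ctl")),
                n_ctl=opt_int(rec.get("n_ctl")),
                y=opt_float(rec.get("y")),
                se=opt_float(rec.get("se")),
                included=bool(rec.get("included", True)),
            )
        )
    return studies


def write_studies(studies: Sequence[Study], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": s.id,
                "label": s.label,
                "events_trt": s.events_trt,
                "n_trt": s.n_trt,
                "events_ctl": s.events_ctl,
                "n_ctl": s.n_ctl,
                "y": s.y,
                "se": s.se,
                "included": s.included,
            }
            for s in studies
        ],
        columns=STUDY_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_elicitations(path: str | Path) -> list[BiasElicitation]:
    df = pd.read_csv(path, dtype=str)
    return [
        BiasElicitation(
            assessor_id=rec["assessor_id"],
            study_id=rec["study_id"],
            bias_id=rec["bias_id"],
            nature=rec["nature"],
            action=rec["action"],
            mean=float(rec["mean"]),
            variance=float(rec["variance"]),
        )
        for rec in df.to_dict("records")
    ]


def write_elicitations(elicitations: Sequence[BiasElicitation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "assessor_id": e.assessor_id,
                "study_id": e.study_id,
                "bias_id": e.bias_id,
                "nature": e.nature,
                "action": e.action,
                "mean": e.mean,
                "variance": e.variance,
            }
            for e in elicitations
        ],
        columns=ELICITATION_COLUMNS,
    )
    df.to_csv(path, index=False)
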