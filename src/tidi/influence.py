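"""One-way influence analysis (tornado plots).

Decision models take dozens of inputs; a tornado plot ranks them by how
much swinging each one alone — low to high over a plausible range —
moves a chosen economic outcome (INMB or a pairwise ICER).  The widest
bars sit at the top.  A stochastic reference bar (the same outcome's mean
and 95% interval from a full PSA) can be attached for comparison, so the
one-way swings can be read against the overall decision uncertainty.

Two variants are provided:

* :func:`tornado` — fully deterministic: each parameter is set to its low
  and high value in turn with all others at central values;
* :func:`stochastic_tornado` — conditional-fixing: each parameter is
  pinned at its low/high quantile while all others are sampled, and the
  bar endpoints are the conditional mean outcomes.  For models nonlinear
  in their parameters this captures interaction-averaged influence that
  the deterministic variant misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .economics import inmb
from .engine import (
    ModelDefinition,
    ParameterSpec,
    PSAResult,
    RunOptions,
    quantile,
    run_model,
)

#: bars narrower than this fraction of the outcome scale are dropped from
#: plots (kept in tables)
PLOT_WIDTH_FLOOR = 1e-12


@dataclass(frozen=True)
class OutcomeSelector:
    """Selects the scalar economic outcome a tornado is computed for.

    ``kind`` is ``"inmb"`` or ``"icer"``; the outcome compares
    ``strategy`` against ``comparator`` for one ``treatment``, at
    willingness-to-pay ``lam`` (INMB only).
    """

    kind: str
    strategy: str
    comparator: str
    treatment: str
    lam: float = 20000.0

    def __post_init__(self) -> None:
        if self.kind not in ("inmb", "icer"):
            raise ValueError("kind must be 'inmb' or 'icer'")
        if self.kind == "inmb" and self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def label(self) -> str:
        base = (
            f"strategy {self.strategy} vs {self.comparator}, "
            f"treatment {self.treatment}"
        )
        if self.kind == "inmb":
            return f"INMB, {base}, lambda={self.lam:g}"
        return f"ICER, {base}"

    def _check(self, model: ModelDefinition) -> None:
        strategies = {s for s, _ in model.strategies}
        treatments = {t for t, _ in model.treatments}
        for s in (self.strategy, self.comparator):
            if s not in strategies:
                raise KeyError(f"unknown strategy {s!r}")
        if self.treatment not in treatments:
            raise KeyError(f"unknown treatment {self.treatment!r}")

    def deltas(self, outcomes) -> tuple[float, float]:
        """(dCost, dEffect) of strategy vs comparator from one outcome record."""
        a = outcomes[(self.strategy, self.treatment)]
        b = outcomes[(self.comparator, self.treatment)]
        return a["cost"] - b["cost"], a["qaly"] - b["qaly"]

    def value(self, outcomes) -> float:
        d_cost, d_eff = self.deltas(outcomes)
        if self.kind == "inmb":
            return self.lam * d_eff - d_cost
        if d_eff == 0:
            return np.nan
        return d_cost / d_eff

    def psa_value(self, psa: PSAResult) -> tuple[float, tuple[float, float] | None]:
        """Mean (and 95% interval, INMB only) of the outcome over PSA draws.

        Per-draw ICERs are unstable near dEffect = 0, so for ICER outcomes
        the ratio of mean increments is reported without an interval.
        """
        a = (self.strategy, self.treatment)
        b = (self.comparator, self.treatment)
        if self.kind == "inmb":
            r = inmb(psa, a, b, self.lam)
            return r.mean, r.interval
        d_c = (psa.outcomes[a]["cost"] - psa.outcomes[b]["cost"]).mean()
        d_e = (psa.outcomes[a]["qaly"] - psa.outcomes[b]["qaly"]).mean()
        return (float(d_c / d_e) if d_e != 0 else np.nan), None


@dataclass(frozen=True)
class TornadoBar:
    parameter: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float
    base_outcome: float
    interpretable: bool = True  # False when an ICER's dEffect changes sign

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


@dataclass
class TornadoResult:
    bars: list[TornadoBar]
    base_outcome: float
    outcome_label: str
    reference: tuple[float, tuple[float, float] | None] | None = None

    def sorted_bars(self) -> list[TornadoBar]:
        return sorted(self.bars, key=lambda b: (-b.width, b.parameter))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "parameter": b.parameter,
                    "low_value": b.low_value,
                    "high_value": b.high_value,
                    "outcome_low": b.outcome_low,
                    "outcome_high": b.outcome_high,
                    "width": b.width,
                    "interpretable": b.interpretable,
                }
                for b in self.sorted_bars()
            ]
        )


def _ranges(model: ModelDefinition) -> list[tuple[ParameterSpec, float, float]]:
    """One-way range per parameter: explicit low/high if given, else the
    2.5/97.5 quantiles.  Point parameters without an explicit range are
    skipped (they cannot move)."""
    out = []
    for p in model.parameters:
        if p.low is not None and p.high is not None:
            out.append((p, float(p.low), float(p.high)))
        elif p.distribution != "point":
            out.append((p, quantile(p, 0.025), quantile(p, 0.975)))
    return out


def _icer_interpretable(
    selector: OutcomeSelector, outcomes_low, outcomes_high
) -> bool:
    if selector.kind != "icer":
        return True
    _, d_e_low = selector.deltas(outcomes_low)
    _, d_e_high = selector.deltas(outcomes_high)
    return bool(np.sign(d_e_low) == np.sign(d_e_high) != 0)


def tornado(
    model: ModelDefinition,
    selector: OutcomeSelector,
    options: RunOptions | None = None,
) -> TornadoResult:
    """Deterministic one-way tornado.

    Each parameter in turn is set to its low then high value with every
    other parameter held at its central value; the bar spans the two
    outcome values.  Bars are sorted by descending width, ties broken by
    parameter name.  When ``options`` requests stochastic mode, a PSA
    reference bar is attached from an unconditional run.
    """
    selector._check(model)
    base_record = model.central_record()
    base = selector.value(model.outcome_fn(base_record))

    bars = []
    for spec, lo, hi in _ranges(model):
        rec_lo = dict(base_record, **{spec.name: lo})
        rec_hi = dict(base_record, **{spec.name: hi})
        out_lo = model.outcome_fn(rec_lo)
        out_hi = model.outcome_fn(rec_hi)
        bars.append(
            TornadoBar(
                parameter=spec.name,
                low_value=lo,
                high_value=hi,
                outcome_low=selector.value(out_lo),
                outcome_high=selector.value(out_hi),
                base_outcome=base,
                interpretable=_icer_interpretable(selector, out_lo, out_hi),
            )
        )
    result = TornadoResult(
        bars=sorted(bars, key=lambda b: (-b.width, b.parameter)),
        base_outcome=base,
        outcome_label=selector.label(),
    )
    if options is not None and options.mode == "stochastic":
        psa = run_model(model, options)
        result.reference = selector.psa_value(psa)
    return result


def stochastic_tornado(
    model: ModelDefinition,
    selector: OutcomeSelector,
    options: RunOptions,
) -> TornadoResult:
    """Conditional-fixing stochastic tornado.

    For each parameter, a seeded PSA is run with that parameter replaced
    by a point mass at its low (then high) quantile while all other
    parameters are sampled as usual; the bar endpoints are the conditional
    mean outcomes.  All conditional runs reuse the same seed (common
    random numbers), so bar widths are not inflated by sampling noise
    between runs.  The reference bar is the unconditional PSA mean with
    its 95% interval.
    """
    if options.mode != "stochastic":
        raise ValueError("stochastic_tornado requires stochastic run options")
    selector._check(model)
    base = selector.value(model.outcome_fn(model.central_record()))

    reference_psa = run_model(model, options)
    reference = selector.psa_value(reference_psa)

    bars = []
    for spec, lo, hi in _ranges(model):
        endpoints = []
        for val in (lo, hi):
            pinned = model.replace_parameter(
                ParameterSpec(spec.name, "point", {"value": val})
            )
            psa = run_model(pinned, options)
            endpoints.append(selector.psa_value(psa)[0])
        bars.append(
            TornadoBar(
                parameter=spec.name,
                low_value=lo,
                high_value=hi,
                outcome_low=endpoints[0],
                outcome_high=endpoints[1],
                base_outcome=base,
                interpretable=not (
                    selector.kind == "icer"
                    and (np.isnan(endpoints[0]) or np.isnan(endpoints[1]))
                ),
            )
        )
    return TornadoResult(
        bars=sorted(bars, key=lambda b: (-b.width, b.parameter)),
        base_outcome=base,
        outcome_label=selector.label(),
        reference=reference,
    )
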