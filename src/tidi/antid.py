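"""Anti-D prophylaxis fixture decision model.

RhD-negative women carrying an RhD-positive fetus can become sensitized
(develop anti-D antibodies), putting subsequent RhD-positive pregnancies
at risk of hemolytic disease of the newborn (HDN).  Routine antenatal
anti-D prophylaxis (AADP) reduces the sensitization rate.  This module
ships a compact, openly synthetic decision-tree model of that setting so
the whole toolchain — evidence synthesis, PSA, economics, influence
analysis — can be exercised end to end with known arithmetic:

* three strategies: (1) no routine AADP, conventional management;
  (2) AADP for primigravidae only; (3) AADP for all RhD-negative
  pregnant women;
* four anti-D products that share a single effectiveness odds ratio and
  differ only in cost per dose;
* a single subsequent-pregnancy stage at lag ``t_lag`` stands in for the
  full multi-pregnancy cascade, which is enough to exercise discounting
  and incremental logic.

It is a fixture in the spirit of the published anti-D appraisal models,
not a reproduction of any of them; its default parameter values are
deliberately round and fully documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .engine import (
    ModelDefinition,
    ParameterSpec,
    Record,
    register_outcome,
)
from .evidence import MetaResult

STRATEGIES = (
    ("1", "No routine AADP (conventional management)"),
    ("2", "AADP to primigravidae only"),
    ("3", "AADP to all RhD-negative pregnant women"),
)

#: four products sharing one effectiveness OR; only dose cost differs
TREATMENTS = (
    ("partobulin", "Partobulin"),
    ("rhophylac", "Rhophylac"),
    ("dgam", "D-Gam"),
    ("winrho", "WinRho"),
)

#: cost per dose by product (currency units; fixture values)
DEFAULT_DOSE_COSTS = {
    "partobulin": 27.5,
    "rhophylac": 35.0,
    "dgam": 22.0,
    "winrho": 40.0,
}

CLINICAL_OUTCOMES = ("sensitizations", "affected", "losses")


@dataclass(frozen=True)
class AntiDParameters:
    """Inputs of the fixture model, with documented defaults.

    Probabilities are per pregnancy; costs are in currency units; QALY and
    life-year losses are per event; discount rates are annual.
    """

    s0: float = 0.0095          # sensitization probability without AADP
    or_eff: float = 0.4         # odds ratio of sensitization under AADP
    p_prim: float = 0.4         # proportion primigravidae
    p_subseq: float = 0.7       # P(subsequent RhD+ pregnancy | sensitized)
    p_affected: float = 0.6     # P(fetus affected by HDN | sensitized, subsequent)
    p_loss: float = 0.05        # P(fetal loss | affected)
    q_affected: float = 2.0     # QALY loss per affected fetus
    q_loss: float = 25.0        # QALY loss per fetal loss
    ly_loss: float = 75.0       # life-years lost per fetal loss
    d_eff: float = 0.035        # annual discount rate, effects
    d_cost: float = 0.035       # annual discount rate, costs
    t_lag: float = 2.0          # years to the subsequent pregnancy
    n_doses: int = 2            # doses per covered pregnancy
    c_dose: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_COSTS)
    )
    c_admin: float = 5.0        # administration cost per dose
    c_sens: float = 2900.0      # lifetime management cost per sensitized woman
    c_hdn: float = 15000.0      # cost per affected fetus
    cohort: int = 100000        # women per run

    def __post_init__(self) -> None:
        for name in ("s0", "p_prim", "p_subseq", "p_affected", "p_loss"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.or_eff <= 0:
            raise ValueError("or_eff must be > 0")
        for name in ("q_affected", "q_loss", "ly_loss", "c_admin", "c_sens", "c_hdn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rate in ("d_eff", "d_cost"):
            v = getattr(self, name := rate)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.t_lag <= 0 or self.n_doses <= 0 or self.cohort <= 0:
            raise ValueError("t_lag, n_doses and cohort must be positive")
        for t, c in self.c_dose.items():
            if c < 0:
                raise ValueError(f"c_dose[{t!r}] must be >= 0")


def antid_outcomes(
    params: AntiDParameters,
    treatments: tuple[str, ...] = tuple(t for t, _ in TREATMENTS),
) -> dict[tuple[str, str], Record]:
    """Evaluate the decision tree for every (strategy, treatment) pair.

    Coverage is 0, ``p_prim`` and 1 for strategies 1-3.  The treated-group
    sensitization probability applies the odds ratio on the logit scale:
    ``p_treated = expit(logit(s0) + ln or_eff)``.  Downstream events are::

        sens     = cohort * [cov * p_treated + (1 - cov) * s0]
        affected = sens * p_subseq * p_affected * (1 + d_eff)^-t_lag
        lost     = affected * p_loss

    QALYs are reported as negative losses so "more is better" holds for
    every effect outcome; ``ly`` likewise.  Costs combine prophylaxis
    (coverage * doses * (dose + administration)) with discounted
    sensitization-management and HDN costs.
    """
    p = params
    for t in treatments:
        if t not in p.c_dose:
            raise KeyError(f"unknown treatment id {t!r} (no dose cost)")
    p_treated = float(expit(logit(p.s0) + np.log(p.or_eff)))
    delta_e = (1 + p.d_eff) ** (-p.t_lag)
    delta_c = (1 + p.d_cost) ** (-p.t_lag)
    coverage = {"1": 0.0, "2": p.p_prim, "3": 1.0}

    out: dict[tuple[str, str], Record] = {}
    for strat, cov in coverage.items():
        sens = p.cohort * (cov * p_treated + (1 - cov) * p.s0)
        affected = sens * p.p_subseq * p.p_affected * delta_e
        lost = affected * p.p_loss
        qaly_loss = affected * p.q_affected + lost * p.q_loss
        ly_lost = lost * p.ly_loss
        downstream = sens * p.c_sens * delta_c + affected * p.c_hdn * delta_c
        for t in treatments:
            prophylaxis = p.cohort * cov * p.n_doses * (p.c_dose[t] + p.c_admin)
            out[(strat, t)] = {
                "cost": prophylaxis + downstream,
                "qaly": -qaly_loss,
                "ly": -ly_lost,
                "sensitizations": sens,
                "affected": affected,
                "losses": lost,
            }
    return out


def _record_to_params(record: Record) -> AntiDParameters:
    c_dose = {t: float(record[f"c_dose_{t}"]) for t, _ in TREATMENTS}
    scalar = {
        f.name: record[f.name]
        for f in fields(AntiDParameters)
        if f.name not in ("c_dose", "n_doses", "cohort") and f.name in record
    }
    return AntiDParameters(
        c_dose=c_dose,
        n_doses=int(round(record.get("n_doses", 2))),
        cohort=int(round(record.get("cohort", 100000))),
        **scalar,
    )


def antid_outcome_fn(record: Record) -> dict[tuple[str, str], Record]:
    """Engine-facing adapter: flat parameter record -> outcome records."""
    return antid_outcomes(_record_to_params(record))


register_outcome("antid", antid_outcome_fn)


def antid_model() -> ModelDefinition:
    """Fixture model definition with PSA distributions.

    Every distribution's mean equals the corresponding
    :class:`AntiDParameters` default, so the deterministic run of this
    definition reproduces ``antid_outcomes(AntiDParameters())`` exactly.
    Spread choices are round, plausible magnitudes for this kind of
    early-pregnancy screening model.
    """
    d = AntiDParameters()
    sigma_or = 0.2
    specs = [
        ParameterSpec("s0", "beta", {"alpha": 9.5, "beta": 990.5},
                      description="baseline sensitization probability"),
        ParameterSpec("or_eff", "lognormal",
                      {"mu": float(np.log(d.or_eff) - sigma_or**2 / 2), "sigma": sigma_or},
                      description="effectiveness odds ratio (shared by all products)"),
        ParameterSpec("p_prim", "beta", {"alpha": 40.0, "beta": 60.0},
                      description="proportion primigravidae"),
        ParameterSpec("p_subseq", "beta", {"alpha": 70.0, "beta": 30.0},
                      description="P(subsequent RhD+ pregnancy | sensitized)"),
        ParameterSpec("p_affected", "beta", {"alpha": 60.0, "beta": 40.0},
                      description="P(HDN-affected fetus | sensitized)"),
        ParameterSpec("p_loss", "beta", {"alpha": 5.0, "beta": 95.0},
                      description="P(fetal loss | affected)"),
        ParameterSpec("q_affected", "gamma", {"shape": 16.0, "rate": 8.0},
                      description="QALY loss per affected fetus"),
        ParameterSpec("q_loss", "gamma", {"shape": 25.0, "rate": 1.0},
                      description="QALY loss per fetal loss"),
        ParameterSpec("ly_loss", "point", {"value": d.ly_loss},
                      description="life-years lost per fetal loss"),
        ParameterSpec("d_eff", "point", {"value": d.d_eff}, low=0.0, high=0.07,
                      description="annual discount rate, effects"),
        ParameterSpec("d_cost", "point", {"value": d.d_cost}, low=0.0, high=0.07,
                      description="annual discount rate, costs"),
        ParameterSpec("t_lag", "point", {"value": d.t_lag},
                      description="years to subsequent pregnancy"),
        ParameterSpec("n_doses", "point", {"value": float(d.n_doses)},
                      description="doses per covered pregnancy"),
        ParameterSpec("c_admin", "gamma", {"shape": 25.0, "rate": 5.0},
                      description="administration cost per dose"),
        ParameterSpec("c_sens", "gamma", {"shape": 100.0, "rate": 100.0 / d.c_sens},
                      description="lifetime management cost per sensitized woman"),
        ParameterSpec("c_hdn", "gamma", {"shape": 100.0, "rate": 100.0 / d.c_hdn},
                      description="cost per HDN-affected fetus"),
        ParameterSpec("cohort", "point", {"value": float(d.cohort)},
                      description="women per run"),
    ]
    for t, label in TREATMENTS:
        specs.append(
            ParameterSpec(
                f"c_dose_{t}", "point", {"value": DEFAULT_DOSE_COSTS[t]},
                description=f"cost per dose, {label}",
            )
        )
    return ModelDefinition(
        name="antid",
        parameters=tuple(specs),
        strategies=STRATEGIES,
        treatments=TREATMENTS,
        outcome_fn=antid_outcome_fn,
    )


def attach_effectiveness(
    model: ModelDefinition,
    meta_result: MetaResult,
    mode: str = "deterministic",
    parameter: str = "or_eff",
) -> ModelDefinition:
    """Load a meta-analysis result into the decision model.

    Deterministic mode replaces the effectiveness parameter's central
    value with the synthesis point estimate on the OR scale (posterior
    median OR for the Bayesian method, DL point for the moment method).
    Stochastic mode preserves posterior uncertainty by registering
    ``exp(mu draws)`` as an empirical block; when only a DL fit is
    available a lognormal approximation from its point and SE is used
    instead, with a logged notice.
    """
    import logging

    logger = logging.getLogger(__name__)
    if mode == "deterministic":
        return model.replace_parameter(
            ParameterSpec(
                parameter, "point", {"value": meta_result.or_point},
                description="effectiveness OR from evidence synthesis",
                source=f"meta-analysis ({meta_result.method})",
            )
        )
    if meta_result.mu_samples is not None:
        or_samples = np.exp(meta_result.mu_samples)
        return model.replace_parameter(
            ParameterSpec(
                parameter, "empirical",
                {"samples": [float(x) for x in or_samples], "block": "effectiveness"},
                description="posterior OR draws from evidence synthesis",
                source="meta-analysis (bayes)",
            )
        )
    lo, hi = meta_result.mu_interval
    se = (hi - lo) / (2 * 1.96)
    logger.warning(
        "stochastic handoff from a DL fit: using lognormal(mu=%.4f, sigma=%.4f) "
        "approximation for %r", meta_result.mu_point, se, parameter,
    )
    return model.replace_parameter(
        ParameterSpec(
            parameter, "lognormal", {"mu": meta_result.mu_point, "sigma": se},
            description="effectiveness OR, lognormal approximation of the DL fit",
            source="meta-analysis (dl)",
        )
    )


def data_dir() -> Path:
    """Directory of the packaged fixture inputs (antid.yaml, CSVs)."""
    return Path(__file__).parent / "data"


def load_packaged_model() -> ModelDefinition:
    from .engine import load_model

    return load_model(data_dir() / "antid.yaml")
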