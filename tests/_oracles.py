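"""Independent arithmetic oracles shared across test modules.

These deliberately re-derive results with plain arithmetic and share no
code with the package under test.
"""

import math

from tidi.antid import TREATMENTS, AntiDParameters


def hand_oracle(p: AntiDParameters) -> dict:
    """Step-by-step evaluation of the anti-D decision tree."""
    logit_s0 = math.log(p.s0 / (1 - p.s0))
    logit_trt = logit_s0 + math.log(p.or_eff)
    p_treated = 1 / (1 + math.exp(-logit_trt))
    de = (1 + p.d_eff) ** (-p.t_lag)
    dc = (1 + p.d_cost) ** (-p.t_lag)
    out = {}
    for strat, cov in (("1", 0.0), ("2", p.p_prim), ("3", 1.0)):
        sens = p.cohort * (cov * p_treated + (1 - cov) * p.s0)
        affected = sens * p.p_subseq * p.p_affected * de
        lost = affected * p.p_loss
        for trt, _ in TREATMENTS:
            cost = (
                p.cohort * cov * p.n_doses * (p.c_dose[trt] + p.c_admin)
                + sens * p.c_sens * dc
                + affected * p.c_hdn * dc
            )
            out[(strat, trt)] = {
                "cost": cost,
                "qaly": -(affected * p.q_affected + lost * p.q_loss),
                "ly": -(lost * p.ly_loss),
                "sensitizations": sens,
                "affected": affected,
                "losses": lost,
            }
    return out
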