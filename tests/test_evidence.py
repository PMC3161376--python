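"""Meta-analysis: log-OR extraction, bias pooling/adjustment, DL and Bayes fits."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidi.evidence import (
    AdjustedStudy,
    BiasElicitation,
    MCMCOptions,
    MetaConfig,
    PooledBias,
    Priors,
    Study,
    adjust_study,
    bayes_meta,
    compute_log_or,
    dl_meta,
    forest_data,
    pool_assessors,
    run_meta,
)

# ---------------------------------------------------------------------------
# Study construction and log-OR extraction
# ---------------------------------------------------------------------------


def test_study_rejects_mixed_and_missing_inputs():
    with pytest.raises(ValueError, match="not both"):
        Study(id="s", events_trt=1, n_trt=10, events_ctl=2, n_ctl=10, y=0.1, se=0.2)
    with pytest.raises(ValueError, match="no usable input"):
        Study(id="s")
    with pytest.raises(ValueError, match="se must be > 0"):
        Study(id="s", y=0.1, se=0.0)
    with pytest.raises(ValueError, match="events exceed"):
        Study(id="s", events_trt=11, n_trt=10, events_ctl=2, n_ctl=10)


@pytest.mark.parametrize(
    "counts, expected_y, expected_se",
    [
        # symmetric table forces y = 0; Woolf SE over cells (10, 90, 10, 90)
        ((10, 100, 10, 100), 0.0, math.sqrt(2 * (1 / 10 + 1 / 90))),
        # hand arithmetic: ln((5*40)/(45*10)) = ln(4/9)
        (
            (5, 50, 10, 50),
            math.log(4 / 9),
            math.sqrt(1 / 5 + 1 / 45 + 1 / 10 + 1 / 40),
        ),
        # continuity rule: all four cells get +0.5 because one cell is zero
        (
            (0, 20, 5, 20),
            math.log((0.5 * 15.5) / (20.5 * 5.5)),
            math.sqrt(1 / 0.5 + 1 / 20.5 + 1 / 5.5 + 1 / 15.5),
        ),
    ],
)
def test_log_or_from_counts(counts, expected_y, expected_se):
    et, nt, ec, nc = counts
    y, se = compute_log_or(Study(id="s", events_trt=et, n_trt=nt, events_ctl=ec, n_ctl=nc))
    assert y == pytest.approx(expected_y, rel=1e-12)
    assert se == pytest.approx(expected_se, rel=1e-12)


def test_log_or_no_correction_without_zero_cell():
    y, se = compute_log_or(
        Study(id="s", events_trt=5, n_trt=50, events_ctl=10, n_ctl=50), continuity=0.5
    )
    assert y == pytest.approx(math.log(4 / 9))


def test_log_or_passthrough_for_precomputed():
    assert compute_log_or(Study(id="s", y=-0.8, se=0.3)) == (-0.8, 0.3)


def test_log_or_rejects_empty_margin():
    with pytest.raises(ValueError, match="empty margin"):
        compute_log_or(Study(id="s", events_trt=0, n_trt=0, events_ctl=5, n_ctl=20))


# ---------------------------------------------------------------------------
# Assessor pooling
# ---------------------------------------------------------------------------


def _elic(assessor, mean, variance, study="S1", bias="b1", nature="internal",
          action="additive"):
    return BiasElicitation(
        assessor_id=assessor, study_id=study, bias_id=bias, nature=nature,
        action=action, mean=mean, variance=variance,
    )


def test_pool_single_assessor_is_identity():
    [pooled] = pool_assessors([_elic("A1", 0.2, 0.01)], MetaConfig())
    assert pooled.mean == pytest.approx(0.2)
    assert pooled.variance == pytest.approx(0.01)
    assert pooled.n_assessors == 1


def test_pool_two_assessors_mixture_moments():
    # mixture of N(0.1, 0) and N(0.3, 0): second moment (0.01+0.09)/2 = 0.05
    [pooled] = pool_assessors(
        [_elic("A1", 0.1, 0.0), _elic("A2", 0.3, 0.0)], MetaConfig()
    )
    assert pooled.mean == pytest.approx(0.2)
    assert pooled.variance == pytest.approx(0.01)


@given(
    m=st.floats(-1, 1, allow_nan=False),
    v=st.floats(0, 0.5, allow_nan=False),
    k=st.integers(1, 5),
)
@settings(derandomize=True, max_examples=50)
def test_pool_identical_assessors_is_identity(m, v, k):
    elics = [_elic(f"A{i}", m, v) for i in range(k)]
    [pooled] = pool_assessors(elics, MetaConfig())
    assert pooled.mean == pytest.approx(m)
    assert pooled.variance == pytest.approx(v, abs=1e-12)
    assert pooled.n_assessors == k


def test_pool_filters_nature_and_action_independently():
    elics = [
        _elic("A1", 0.1, 0.01, bias="b_int_add", nature="internal", action="additive"),
        _elic("A1", 0.9, 0.01, bias="b_ext_prop", nature="external", action="proportional"),
    ]
    only_internal = pool_assessors(elics, MetaConfig(include_external=False))
    assert [b.bias_id for b in only_internal] == ["b_int_add"]
    only_prop = pool_assessors(elics, MetaConfig(include_additive=False))
    assert [b.bias_id for b in only_prop] == ["b_ext_prop"]


def test_pool_drops_bias_with_no_selected_assessor(caplog):
    elics = [_elic("A1", 0.1, 0.01), _elic("A2", 0.3, 0.01, bias="b2")]
    with caplog.at_level("WARNING"):
        pooled = pool_assessors(elics, MetaConfig(selected_assessor_ids={"A1"}))
    assert [b.bias_id for b in pooled] == ["b1"]
    assert "no selected assessor" in caplog.text


def test_pool_rejects_unknown_study_reference():
    with pytest.raises(ValueError, match="unknown"):
        pool_assessors([_elic("A1", 0.1, 0.01)], MetaConfig(), known_study_ids=["S9"])


# ---------------------------------------------------------------------------
# Bias adjustment (delta method) and its Monte-Carlo oracle
# ---------------------------------------------------------------------------


def _pb(mean, variance, action="additive", bias="b1"):
    return PooledBias(study_id="S1", bias_id=bias, action=action, mean=mean,
                      variance=variance, n_assessors=1)


def test_adjust_no_biases_is_identity():
    adj = adjust_study("S1", -0.8, 0.3)
    assert (adj.y_adj, adj.var_adj) == (-0.8, pytest.approx(0.09))


def test_adjust_degenerate_additive_shift():
    adj = adjust_study("S1", -0.8, 0.3, additive=[_pb(0.3, 0.0)])
    assert adj.y_adj == pytest.approx(-1.1)
    assert adj.var_adj == pytest.approx(0.09)


@given(v=st.floats(0.001, 0.5), y=st.floats(-2, 2), se=st.floats(0.05, 1))
@settings(derandomize=True, max_examples=50)
def test_zero_mean_additive_bias_only_inflates_variance(v, y, se):
    adj = adjust_study("S1", y, se, additive=[_pb(0.0, v)])
    assert adj.y_adj == pytest.approx(y)
    assert adj.var_adj == pytest.approx(se**2 + v)


def test_unit_proportional_bias_is_noop():
    adj = adjust_study("S1", -0.8, 0.3, proportional=[_pb(1.0, 0.0, "proportional")])
    assert (adj.y_adj, adj.var_adj) == (-0.8, pytest.approx(0.09))


def test_adjust_rejects_zero_proportional_mean():
    good = PooledBias("S1", "b", "proportional", mean=1.0, variance=0.0, n_assessors=1)
    bad = dataclasses.replace(good, mean=0.0)
    with pytest.raises(ValueError, match="divide by zero"):
        adjust_study("S1", -0.8, 0.3, proportional=[bad])


def mc_adjust_oracle(y, se, additive, proportional, n=10**6, seed=0):
    """Simulation oracle for the delta-method adjustment: empirical mean and
    variance of (y* - A) / P with all components drawn independently.

    Additive biases are normal.  Each proportional factor is drawn from a
    lognormal matched to its elicited mean and variance: a multiplicative
    bias factor has positive support, and a normal denominator would make
    the ratio's variance infinite (it crosses zero), leaving nothing finite
    to compare against.
    """
    rng = np.random.default_rng(seed)
    draws = rng.normal(y, se, n)
    for m, v in additive:
        draws = draws - rng.normal(m, math.sqrt(v), n)
    for m, v in proportional:
        s2 = math.log1p(v / m**2)
        draws = draws / rng.lognormal(math.log(m) - s2 / 2, math.sqrt(s2), n)
    return float(draws.mean()), float(draws.var())


def test_delta_method_matches_simulation():
    """First-order propagation tracks the simulated mean and variance to 10%
    for proportional factors of moderate spread (CV <= 0.15)."""
    y, se = -0.8, 0.3
    adj = adjust_study(
        "S1", y, se,
        additive=[_pb(0.1, 0.02)],
        proportional=[_pb(0.8, 0.0144, "proportional")],
    )
    mc_mean, mc_var = mc_adjust_oracle(y, se, [(0.1, 0.02)], [(0.8, 0.0144)], n=10**6)
    assert adj.y_adj == pytest.approx(mc_mean, rel=0.10)
    assert adj.var_adj == pytest.approx(mc_var, rel=0.10)


def test_delta_method_mean_holds_to_wider_spread():
    """The mean agreement extends to CV(P) = 0.25 even where the first-order
    variance starts to degrade."""
    y, se = -0.8, 0.3
    adj = adjust_study("S1", y, se, proportional=[_pb(0.8, 0.04, "proportional")])
    mc_mean, _ = mc_adjust_oracle(y, se, [], [(0.8, 0.04)], n=10**6)
    assert adj.y_adj == pytest.approx(mc_mean, rel=0.10)


# ---------------------------------------------------------------------------
# DerSimonian-Laird synthesis
# ---------------------------------------------------------------------------


def _adj(y, v, sid="S1"):
    return AdjustedStudy(study_id=sid, y_adj=y, var_adj=v)


def test_dl_single_study():
    r = dl_meta([_adj(0.5, 0.04)])
    assert r.mu_point == pytest.approx(0.5)
    assert r.tau_point == 0.0
    assert r.mu_interval == pytest.approx((0.5 - 1.96 * 0.2, 0.5 + 1.96 * 0.2))


def test_dl_identical_studies_have_zero_heterogeneity():
    r = dl_meta([_adj(0.5, 0.04, f"S{i}") for i in range(3)])
    assert r.mu_point == pytest.approx(0.5)
    assert r.tau_point == 0.0
    half = 1.96 * math.sqrt(0.04 / 3)
    assert r.mu_interval == pytest.approx((0.5 - half, 0.5 + half))


def test_dl_three_study_hand_oracle():
    """Frozen from independent spreadsheet-style arithmetic, confirmed by
    metafor's rma(method='DL') to 10 decimals."""
    r = dl_meta([_adj(0.2, 0.04, "a"), _adj(0.6, 0.09, "b"), _adj(-0.1, 0.01, "c")])
    assert r.mu_point == pytest.approx(0.1548604812, abs=1e-9)
    assert r.tau_point**2 == pytest.approx(0.0696428571, abs=1e-9)
    half = 1.96 * 0.1891831574
    assert r.mu_interval == pytest.approx((0.1548604812 - half, 0.1548604812 + half), abs=1e-8)


def test_dl_rejects_empty_input():
    with pytest.raises(ValueError):
        dl_meta([])


# ---------------------------------------------------------------------------
# Bayesian synthesis
# ---------------------------------------------------------------------------


def test_bayes_conjugate_fixed_effect_limit():
    """With tau pinned at 0 and a vague prior the posterior is the closed-form
    inverse-variance normal; the sampler must agree within 3 MC SEs."""
    ys = np.array([0.2, 0.6, -0.1])
    vs = np.array([0.04, 0.09, 0.01])
    cfg = MetaConfig(
        method="bayes",
        mcmc=MCMCOptions(iterations=5000, burn_in=500, seed=11),
        priors=Priors(mu_mean=0.0, mu_var=1e8, tau_upper=0.0),
    )
    r = bayes_meta([_adj(y, v, f"S{i}") for i, (y, v) in enumerate(zip(ys, vs))], cfg)
    post_mean = np.sum(ys / vs) / np.sum(1 / vs)
    post_sd = np.sum(1 / vs) ** -0.5
    draws = r.mu_samples
    mc_se_mean = draws.std() / math.sqrt(draws.size)
    assert draws.mean() == pytest.approx(post_mean, abs=3 * mc_se_mean)
    # SD of n normal draws: SE(sd) ~ sd / sqrt(2(n-1))
    mc_se_sd = post_sd / math.sqrt(2 * (draws.size - 1))
    assert draws.std(ddof=1) == pytest.approx(post_sd, abs=3 * mc_se_sd)


def test_bayes_matches_dl_on_well_separated_fixture():
    from tidi.synthetic import TrialSimSpec, gen_trials

    studies = gen_trials(TrialSimSpec(k=5, tau=0.1, seed=7))
    dl = run_meta(studies, (), MetaConfig(method="dl"))
    bayes = run_meta(
        studies, (), MetaConfig(method="bayes", mcmc=MCMCOptions(seed=7))
    )
    assert abs(bayes.mu_point - dl.mu_point) < 0.05


def test_bayes_is_deterministic_given_seed():
    adj = [_adj(0.2, 0.04, "a"), _adj(0.6, 0.09, "b"), _adj(-0.1, 0.01, "c")]
    cfg = MetaConfig(method="bayes", mcmc=MCMCOptions(iterations=500, burn_in=100, seed=5))
    r1, r2 = bayes_meta(adj, cfg), bayes_meta(adj, cfg)
    assert r1.mu_point == r2.mu_point
    assert np.array_equal(r1.mu_samples, r2.mu_samples)


def test_bayes_single_study_pins_tau(caplog):
    cfg = MetaConfig(method="bayes", mcmc=MCMCOptions(iterations=500, burn_in=100, seed=5))
    with caplog.at_level("WARNING"):
        r = bayes_meta([_adj(0.5, 0.04)], cfg)
    assert r.tau_point == 0.0


def test_bayes_interval_covers_truth_in_replications():
    """Parameter recovery: nominal 95% intervals cover the true effect in at
    least 90 of 100 seeded replications (mu=-0.7, tau=0.2, k=20)."""
    from tidi.synthetic import TrialSimSpec, gen_trials

    covered = 0
    reps = 100
    seeds = np.random.SeedSequence(123).generate_state(reps) % (2**31)
    cfg = MetaConfig(method="bayes", mcmc=MCMCOptions(iterations=1500, burn_in=300, seed=1))
    for s in seeds:
        studies = gen_trials(TrialSimSpec(k=20, true_mu=-0.7, tau=0.2, seed=int(s)))
        r = run_meta(studies, (), cfg)
        lo, hi = r.mu_interval
        covered += lo <= -0.7 <= hi
    assert covered >= 90


# ---------------------------------------------------------------------------
# Full pipeline and forest output
# ---------------------------------------------------------------------------


def test_run_meta_identity_when_all_toggles_off(trial_studies, elicitations):
    cfg_off = MetaConfig(include_internal=False, include_external=False)
    r = run_meta(trial_studies, elicitations, cfg_off)
    c = r.unadjusted_companion
    assert r.mu_point == c.mu_point
    assert r.mu_interval == c.mu_interval
    assert r.tau_point == c.tau_point
    assert r.per_study == c.per_study


def test_run_meta_subsetting_consistency(trial_studies):
    all_ids = {s.id for s in trial_studies[:3]}
    r_drop = run_meta(trial_studies[:3], (), MetaConfig(selected_study_ids=all_ids - {"S3"}))
    r_two = run_meta([s for s in trial_studies[:3] if s.id != "S3"], (), MetaConfig())
    assert r_drop.mu_point == r_two.mu_point


def test_run_meta_external_toggle_isolates_external_biases(trial_studies):
    """Only external biases elicited + external toggle off => no adjustment."""
    elics = [
        _elic("A1", 0.9, 0.01, study=s.id, bias="relevance", nature="external",
              action="proportional")
        for s in trial_studies[:2]
    ]
    r = run_meta(trial_studies[:2], elics, MetaConfig(include_external=False))
    c = r.unadjusted_companion
    assert r.mu_point == c.mu_point
    # sanity: with the toggle on the result must move
    r_on = run_meta(trial_studies[:2], elics, MetaConfig())
    assert r_on.mu_point != r_on.unadjusted_companion.mu_point


def test_run_meta_rejects_unknown_selected_study(trial_studies):
    with pytest.raises(ValueError, match="unknown study"):
        run_meta(trial_studies, (), MetaConfig(selected_study_ids={"nope"}))


def test_forest_single_study_weight_is_one():
    r = dl_meta([_adj(0.0, 0.04)])
    table = forest_data(r)
    study_rows = table[table["row"] != "pooled"]
    assert study_rows["weight"].tolist() == [1.0]
    assert study_rows["or"].tolist() == [1.0]  # symmetric y=0 study


def test_forest_weights_match_dl_hand_oracle():
    r = dl_meta([_adj(0.2, 0.04, "a"), _adj(0.6, 0.09, "b"), _adj(-0.1, 0.01, "c")])
    r.unadjusted_companion = None
    table = forest_data(r)
    shares = table[table["row"] != "pooled"]["weight"].to_numpy()
    v = np.array([0.04, 0.09, 0.01])
    w_star = 1 / (v + 0.0696428571)
    assert shares == pytest.approx(w_star / w_star.sum(), abs=1e-8)
    assert shares.sum() == pytest.approx(1.0)


def test_forest_includes_grayed_unadjusted_variant(trial_studies, elicitations):
    r = run_meta(trial_studies, elicitations, MetaConfig())
    table = forest_data(r)
    assert set(table["variant"]) == {"adjusted", "unadjusted"}
    for variant in ("adjusted", "unadjusted"):
        sub = table[(table["variant"] == variant) & (table["row"] != "pooled")]
        assert sub["weight"].sum() == pytest.approx(1.0)
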