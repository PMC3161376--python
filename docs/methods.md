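# Methods

This note records the models implemented in `tidi`, the defaults and the
numerical choices, and what the packaged synthetic data can and cannot
demonstrate.

## Evidence synthesis

### Effect measure

Studies enter as 2×2 tables `(events_trt, n_trt, events_ctl, n_ctl)` or
as precomputed `(y, se)` on the log odds ratio scale; supplying both is
an error (silent priority between inconsistent inputs would be worse).
From counts, `y = ln(ad/bc)` with the Woolf standard error
`√(1/a + 1/b + 1/c + 1/d)`. A Haldane–Anscombe continuity correction of
0.5 is added to **all four cells**, and only when at least one cell is
zero. An arm with zero size has no information and is rejected outright.

### Bias adjustment

Elicited biases are classified by *nature* (internal = rigor, external =
relevance) and *action* (additive on the log-OR, proportional on the
effect). Each (study, bias) pair may be elicited by several assessors;
the K selected assessors pool as an equal-weight mixture with moments

- mean `m̄ = Σ m_a / K`
- variance `v̄ = Σ (v_a + m_a²)/K − m̄²`.

Equal weights are the neutral choice: assessor weights are not elicited.
Biases combine under independence. With `α = Σ m̄_b` and
`σ²_A = Σ v̄_b` over additive biases, `π = Π m̄_b` and
`σ²_π = π² Σ (v̄_b / m̄_b²)` over proportional ones, the adjusted
study estimate is the first-order (delta-method) propagation of
`(y* − A)/P`:

```
y_adj = (y − α)/π
v_adj = (s² + σ²_A)/π² + (y − α)² σ²_π / π⁴
```

**Domain of validity.** First-order propagation of a ratio is accurate
only while the denominator's relative spread is small. Simulation against
an exact-moment oracle (proportional factors drawn lognormal with the
elicited mean and variance — a multiplicative bias factor is positive,
and an unbounded normal denominator would have no finite ratio moments
at all) shows both moments within ~7% of the simulated truth for
CV(π) ≤ 0.15, degrading to ~10–15% by CV(π) ≈ 0.2–0.25. The mean alone
stays within 10% to CV(π) ≈ 0.3. Elicitations with very diffuse
proportional biases should therefore be treated with care; the adjustment
is not rejected in that regime, but its variance is increasingly
optimistic.

### Pooling

Two interchangeable engines fit `y_i ~ N(θ_i, v_i)`, `θ_i ~ N(μ, τ²)`:

- **`dl`** — DerSimonian–Laird: `τ̂²` from Cochran's Q by the method of
  moments (truncated at 0), pooled mean by inverse-variance weights
  `1/(v_i + τ̂²)`, Wald 95% interval with z = 1.96. Deterministic and
  effectively instantaneous — the interactive workhorse.
- **`bayes`** — Gibbs sampler with conjugate normal updates for each
  `θ_i` and for `μ` (prior `N(0, 10⁴)`), and a slice-sampling update for
  `τ` under a `U(0, 5)` prior. Because τ's support is bounded, the slice
  interval starts as the whole support and shrinks toward the current
  point (no stepping-out phase is needed); a 1000-step shrink guard
  raises a diagnostic rather than looping. Defaults: 5000 retained
  iterations after 1000 burn-in, a run length at which the conjugate
  fixed-effect limit reproduces the closed-form posterior within Monte
  Carlo error. With a single study (or `tau_upper = 0`) the model
  collapses to the exact conjugate fixed-effect posterior, sampled
  i.i.d.; a warning notes that τ is pinned at zero.

Point estimates are posterior medians (`bayes`) or the DL point (`dl`);
these are also the values handed to the decision model in deterministic
mode. `run_meta` always computes an unadjusted companion on the same
study subset with the same method and seed, so adjusted and unadjusted
results can be overlaid; with every bias toggle off the two are
identical bit for bit.

### Calibration

The simulate-and-recover loop (`recovery_suite`) draws k trials from the
generating model, synthesises, and records coverage and error. On a
well-powered design (k = 20, τ = 0.2, arms of 500–2000, control risk
≈ 10%) DL coverage sits at 0.90–0.98 across master seeds with no
detectable bias. On small trials (arms of 100–1000) the
inverse-variance-weighted log odds ratio shows its known finite-sample
attenuation toward the null (≈ +0.02 at μ = −0.7): a property of the
estimator, not of the implementation, and the reason recovery claims are
stated for well-powered designs.

## Decision engine

A model definition is an ordered list of parameter specifications, a
strategy list, a treatment list, and a pure outcome function mapping one
complete parameter record to `{cost, qaly, ...clinical}` per
(strategy, treatment). Supported families: point, normal, lognormal,
beta, gamma (shape/rate), uniform, empirical.

- **Deterministic mode** evaluates at distribution **means** (not
  medians). For skewed families such as the lognormal these differ; mean
  was chosen so linear models are evaluated at their expected inputs.
- **Stochastic mode** draws each parameter from its own RNG substream
  keyed by (seed, parameter name). Consequences: runs are reproducible
  bit for bit; and replacing one parameter's distribution — the
  effectiveness hand-off — leaves every other parameter's draws
  untouched, which makes paired scenario comparisons exact rather than
  noisy.
- **Empirical blocks**: parameters sharing a `block` label are resampled
  row-wise with replacement from their stored sample vectors, preserving
  their joint structure (this is how posterior OR draws retain their
  correlation if several parameters come from one fit). Independence
  holds only across blocks.

The outcome function runs under a purity contract; missing keys or
non-finite values are rejected with the offending draw index.

## Anti-D fixture model

The packaged example models routine antenatal anti-D prophylaxis: an
RhD-negative cohort (default 100,000 women), sensitization risk `s0`
without prophylaxis, and a shared effectiveness odds ratio `or_eff`
applied on the logit scale for covered women. Coverage is 0 / `p_prim` /
1 for the three strategies. Sensitization leads, with lag `t_lag` and
probabilities `p_subseq · p_affected`, to an HDN-affected subsequent
pregnancy, possibly fetal loss (`p_loss`); QALY and life-year losses and
management costs follow, discounted at `d_eff` / `d_cost`. The four
products differ only in cost per dose.

It is an openly synthetic fixture: a single subsequent-pregnancy stage
stands in for the multi-pregnancy cascade, and the defaults
(s0 = 0.0095, or_eff = 0.4, p_prim = 0.4, …) are round plausible values
chosen for auditable arithmetic, not estimates from any appraisal. Every
PSA distribution's mean equals its documented default, so deterministic
runs of the packaged `antid.yaml` reproduce the documented arithmetic
exactly. QALYs and life-years are reported as negative losses so "more
is better" holds uniformly downstream.

## Economics

- **INMB** `= λ·ΔE − ΔC` per draw; intervals are empirical 2.5/97.5
  percentiles.
- **Frontier**: sort by ascending mean cost (ties: descending effect,
  then input order); remove dominated alternatives (another costs no
  more and yields at least as much effect; exact ties keep the
  first-listed); then iteratively remove extendedly dominated interior
  points until incremental ICERs strictly increase. Verified
  property-wise against an exhaustive convex-hull oracle.
- **CEAC** treats every strategy × treatment combination as a mutually
  exclusive alternative in one comparison; at each λ the probability is
  the fraction of draws in which the alternative's NMB is maximal, exact
  ties split equally — so the curve sums to 1 at every λ by
  construction. Default λ grid: 0–50,000 in steps of 500.
- **Cost per clinical unit** uses ratios of mean increments (not means
  of per-draw ratios, which are unstable when the denominator crosses
  zero); increments below 10⁻⁹ in absolute value are flagged undefined
  rather than divided by.

## Influence analysis

Deterministic tornado: each parameter in turn at its low/high value
(explicit bounds if given, otherwise 2.5/97.5 distribution quantiles;
point parameters without bounds cannot move and are skipped), all others
at central values; bars sorted by descending width, ties by name. ICER
outcomes whose effect increment changes sign across a bar are flagged
non-interpretable instead of plotted. Bars narrower than 10⁻¹² of the
outcome scale are dropped from plots but kept in tables.

The stochastic variant pins one parameter at its low/high quantile while
sampling all others, and uses the conditional mean outcomes as
endpoints; all conditional runs share one seed (common random numbers)
so widths are not inflated by between-run noise. Its reference bar is
the unconditional PSA mean with a 95% interval (interval for INMB only;
for ICERs the reference is the ratio of mean increments, since per-draw
ICERs have no stable distribution). For outcomes additive in independent
parameters the two variants agree within Monte Carlo error; for
nonlinear models the stochastic variant measures interaction-averaged
influence, which is the point of having it.

## Scenarios and reproducibility

A scenario bundles parameter overrides, the meta-analysis configuration
(study/bias/assessor selections, method, priors), and run options. One
master seed is split deterministically into component seeds (MCMC, PSA),
so a scenario is a complete, replayable description of an analysis: two
runs produce byte-identical output trees, and the manifest records the
seeds, the model fingerprint and a SHA-256 hash of every table for
after-the-fact verification. Run outputs contain no timestamps for this
reason; plots are written only on request since image metadata is not
byte-stable.

## Synthetic data

`gen_trials` draws per-study true effects `θ_i ~ N(μ, τ²)`, control-arm
risks on the logit scale, and binomial event counts — the standard
generating model of a binary-outcome evidence base, with defaults shaped
like an antenatal-prophylaxis literature (true OR 0.4, τ = 0.15, control
risk ≈ 10%, arms of 100–1000). `gen_elicitations` scatters assessor
means around known bias descriptors with fixed elicited variances, which
keeps the pooled-bias oracle exact. What passing tests show is therefore
internal validity: correct arithmetic, calibrated intervals under the
assumed generating model, exact frontier/CEAC logic. What they cannot
show is robustness to real-data features the generator omits —
non-normal effect distributions, correlated biases across studies or
assessors, publication selection, or model-structure error in the
decision tree.

## Problem sizes

Default run lengths — 5000 retained MCMC iterations, 5000 PSA draws, 100
recovery replications, 10⁶-draw adjustment oracles — keep a full
scenario run around a second on one CPU while leaving Monte Carlo error
well inside every tolerance used in the tests.

## Known limitations

- Bias variance from the delta method is optimistic for proportional
  biases with CV(π) ≳ 0.2 (see above).
- Parameters outside empirical blocks are independent by assumption.
- Tornado plots compare exactly two alternatives; with more strategies
  they remain pairwise snapshots.
- The Markov-trace cohort machinery needed for time-varying models
  (stopping rules, utility over time) is out of scope, as are value-of-
  information analysis, publication-bias diagnostics and network
  meta-analysis.
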