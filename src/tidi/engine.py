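"""Generic decision-model executor.

A decision model is a pure outcome function evaluated over a parameter
space.  The engine owns the parameter specifications (distribution family
plus hyperparameters per parameter), draws seeded parameter vectors for
probabilistic sensitivity analysis (PSA), and evaluates the outcome
function either once at central values (deterministic mode) or once per
draw (stochastic mode).

Correlated inputs — typically posterior draws of an effectiveness
parameter produced by the evidence-synthesis component — are registered as
*empirical blocks*: the stored samples of all parameters in a block are
resampled row-wise, so whatever joint structure the upstream analysis
produced survives into the decision model instead of being flattened into
independent marginals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

DISTRIBUTIONS = ("point", "normal", "lognormal", "beta", "gamma", "uniform", "empirical")

#: outcome keys every (strategy, treatment) record must provide
REQUIRED_OUTCOMES = ("cost", "qaly")

Record = dict[str, float]
#: outcome function contract: one complete parameter record ->
#: {(strategy_id, treatment_id): {"cost": ..., "qaly": ..., <clinical>: ...}}
OutcomeFn = Callable[[Record], dict[tuple[str, str], Record]]


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: a distribution family plus hyperparameters.

    ``low``/``high`` optionally fix the range used by one-way influence
    analysis; otherwise the 2.5/97.5 distribution quantiles are used.
    Empirical parameters carry their sample vector in ``params["samples"]``
    and may name a joint ``params["block"]``.
    """

    name: str
    distribution: str
    params: Mapping[str, object] = field(default_factory=dict)
    low: float | None = None
    high: float | None = None
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"parameter {self.name!r}: unknown distribution {self.distribution!r}"
            )
        p = self.params
        d = self.distribution
        try:
            if d == "point":
                float(p["value"])
            elif d == "normal":
                if float(p["sd"]) <= 0:
                    raise ValueError("sd must be > 0")
                float(p["mean"])
            elif d == "lognormal":
                if float(p["sigma"]) <= 0:
                    raise ValueError("sigma must be > 0")
                float(p["mu"])
            elif d == "beta":
                if float(p["alpha"]) <= 0 or float(p["beta"]) <= 0:
                    raise ValueError("alpha and beta must be > 0")
            elif d == "gamma":
                if float(p["shape"]) <= 0 or float(p["rate"]) <= 0:
                    raise ValueError("shape and rate must be > 0")
            elif d == "uniform":
                if not float(p["low"]) < float(p["high"]):
                    raise ValueError("uniform requires low < high")
            elif d == "empirical":
                samples = np.asarray(p["samples"], dtype=float)
                if samples.size == 0:
                    raise ValueError("empirical sample vector is empty")
                if not np.all(np.isfinite(samples)):
                    raise ValueError("empirical samples must be finite")
        except KeyError as exc:
            raise ValueError(
                f"parameter {self.name!r}: missing hyperparameter {exc}"
            ) from exc
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError(f"parameter {self.name!r}: low > high")

    @property
    def block(self) -> str | None:
        if self.distribution != "empirical":
            return None
        return self.params.get("block")

    @property
    def samples(self) -> np.ndarray:
        return np.asarray(self.params["samples"], dtype=float)


def central_value(spec: ParameterSpec) -> float:
    """Distribution mean, used as the deterministic-mode input.

    The mean (not the median) is used throughout; for skewed families such
    as the lognormal these differ, so the choice is deliberate and uniform.
    """
    p = spec.params
    d = spec.distribution
    if d == "point":
        return float(p["value"])
    if d == "normal":
        return float(p["mean"])
    if d == "lognormal":
        return float(np.exp(float(p["mu"]) + float(p["sigma"]) ** 2 / 2))
    if d == "beta":
        a, b = float(p["alpha"]), float(p["beta"])
        return a / (a + b)
    if d == "gamma":
        return float(p["shape"]) / float(p["rate"])
    if d == "uniform":
        return (float(p["low"]) + float(p["high"])) / 2
    return float(spec.samples.mean())


def quantile(spec: ParameterSpec, q: float) -> float:
    """Quantile of the parameter's distribution (point mass: the value)."""
    p = spec.params
    d = spec.distribution
    if d == "point":
        return float(p["value"])
    if d == "normal":
        return float(stats.norm.ppf(q, loc=float(p["mean"]), scale=float(p["sd"])))
    if d == "lognormal":
        return float(
            stats.lognorm.ppf(q, s=float(p["sigma"]), scale=np.exp(float(p["mu"])))
        )
    if d == "beta":
        return float(stats.beta.ppf(q, float(p["alpha"]), float(p["beta"])))
    if d == "gamma":
        return float(stats.gamma.ppf(q, float(p["shape"]), scale=1 / float(p["rate"])))
    if d == "uniform":
        lo, hi = float(p["low"]), float(p["high"])
        return lo + q * (hi - lo)
    return float(np.quantile(spec.samples, q))


@dataclass(frozen=True)
class ModelDefinition:
    """Parameters + strategies + treatments + the outcome function."""

    name: str
    parameters: tuple[ParameterSpec, ...]
    strategies: tuple[tuple[str, str], ...]
    treatments: tuple[tuple[str, str], ...]
    outcome_fn: OutcomeFn

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(names) != len(set(names)):
            raise ValueError("parameter names must be unique")
        if not self.strategies or not self.treatments:
            raise ValueError("strategies and treatments must be non-empty")

    def parameter(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"unknown parameter {name!r}")

    def replace_parameter(self, spec: ParameterSpec) -> "ModelDefinition":
        if spec.name not in {p.name for p in self.parameters}:
            raise KeyError(f"unknown parameter {spec.name!r}")
        new = tuple(spec if p.name == spec.name else p for p in self.parameters)
        return replace(self, parameters=new)

    @property
    def alternatives(self) -> list[tuple[str, str]]:
        return [(s, t) for s, _ in self.strategies for t, _ in self.treatments]

    def central_record(self) -> Record:
        return {p.name: central_value(p) for p in self.parameters}

    def fingerprint(self) -> str:
        """Content hash of the definition (outcome function by name only)."""
        payload = {
            "name": self.name,
            "strategies": list(self.strategies),
            "treatments": list(self.treatments),
            "parameters": [
                {
                    "name": p.name,
                    "distribution": p.distribution,
                    "params": {
                        k: (list(np.asarray(v, dtype=float)) if k == "samples" else v)
                        for k, v in p.params.items()
                    },
                    "low": p.low,
                    "high": p.high,
                }
                for p in self.parameters
            ],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunOptions:
    """Execution switches: deterministic vs stochastic, size, seed, WTP grid."""

    mode: str = "deterministic"
    n_sims: int = 1000
    seed: int = 0
    lambda_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 50001, 500))

    def __post_init__(self) -> None:
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")
        if self.n_sims <= 0:
            raise ValueError("n_sims must be positive")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be non-empty, non-negative, strictly ascending")


@dataclass
class PSAResult:
    """Per-draw parameter values and per-alternative outcome vectors."""

    draws: pd.DataFrame
    outcomes: dict[tuple[str, str], pd.DataFrame]
    options: RunOptions
    model_fingerprint: str

    @property
    def n_sims(self) -> int:
        return len(self.draws)

    @property
    def alternatives(self) -> list[tuple[str, str]]:
        return list(self.outcomes.keys())

    @property
    def outcome_names(self) -> list[str]:
        first = next(iter(self.outcomes.values()))
        return list(first.columns)

    def to_long(self) -> pd.DataFrame:
        """Outcomes in long format: sim, strategy, treatment, outcome, value."""
        frames = []
        for (s, t), df in self.outcomes.items():
            melted = df.reset_index(names="sim").melt(
                id_vars="sim", var_name="outcome", value_name="value"
            )
            melted.insert(1, "strategy", s)
            melted.insert(2, "treatment", t)
            frames.append(melted)
        return pd.concat(frames, ignore_index=True)


def draw_parameters(model: ModelDefinition, options: RunOptions) -> pd.DataFrame:
    """Seeded PSA draws, one column per parameter, one row per simulation.

    Each parameter (or empirical block) draws from its own substream keyed
    by (seed, name), so changing one parameter's distribution — e.g.
    swapping a fitted effectiveness OR in — leaves every other parameter's
    draws untouched.  All members of an empirical block share one vector
    of resampled row indices (sampling with replacement), which preserves
    their joint structure; an empirical parameter without a named block
    forms a block of its own.
    """
    import zlib

    def keyed_rng(key: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((options.seed, zlib.crc32(key.encode())))
        )

    n = options.n_sims

    block_lengths: dict[str, int] = {}
    for p in model.parameters:
        if p.block is not None:
            length = p.samples.size
            prev = block_lengths.setdefault(p.block, length)
            if prev != length:
                raise ValueError(
                    f"empirical block {p.block!r} has members with unequal "
                    f"sample lengths ({prev} vs {length})"
                )

    block_indices: dict[str, np.ndarray] = {}
    columns: dict[str, np.ndarray] = {}
    for p in model.parameters:
        d = p.distribution
        pp = p.params
        rng = keyed_rng(p.name)
        if d == "point":
            columns[p.name] = np.full(n, float(pp["value"]))
        elif d == "normal":
            columns[p.name] = rng.normal(float(pp["mean"]), float(pp["sd"]), n)
        elif d == "lognormal":
            columns[p.name] = rng.lognormal(float(pp["mu"]), float(pp["sigma"]), n)
        elif d == "beta":
            columns[p.name] = rng.beta(float(pp["alpha"]), float(pp["beta"]), n)
        elif d == "gamma":
            columns[p.name] = rng.gamma(float(pp["shape"]), 1 / float(pp["rate"]), n)
        elif d == "uniform":
            columns[p.name] = rng.uniform(float(pp["low"]), float(pp["high"]), n)
        else:  # empirical
            samples = p.samples
            if p.block is None:
                idx = rng.integers(0, samples.size, n)
            else:
                if p.block not in block_indices:
                    block_indices[p.block] = keyed_rng(f"block:{p.block}").integers(
                        0, samples.size, n
                    )
                idx = block_indices[p.block]
            columns[p.name] = samples[idx]
    return pd.DataFrame(columns)


def _validate_outcome(
    model: ModelDefinition,
    record: dict[tuple[str, str], Record],
    sim: int,
    expected_keys: set[str] | None,
) -> set[str]:
    for alt in model.alternatives:
        if alt not in record:
            raise ValueError(f"outcome function missing alternative {alt} at draw {sim}")
        out = record[alt]
        for key in REQUIRED_OUTCOMES:
            if key not in out:
                raise ValueError(
                    f"outcome for {alt} missing required key {key!r} at draw {sim}"
                )
        keys = set(out)
        if expected_keys is None:
            expected_keys = keys
        elif keys != expected_keys:
            raise ValueError(f"inconsistent outcome keys for {alt} at draw {sim}")
        for key, val in out.items():
            if not np.isfinite(val):
                raise ValueError(
                    f"non-finite outcome {key!r}={val!r} for {alt} at draw {sim}"
                )
    return expected_keys


def run_model(model: ModelDefinition, options: RunOptions) -> PSAResult:
    """Evaluate the model: once at central values, or once per PSA draw."""
    if options.mode == "deterministic":
        draws = pd.DataFrame([model.central_record()])
    else:
        draws = draw_parameters(model, options)

    records: dict[tuple[str, str], list[Record]] = {a: [] for a in model.alternatives}
    expected_keys: set[str] | None = None
    for sim, row in enumerate(draws.to_dict("records")):
        out = model.outcome_fn(row)
        expected_keys = _validate_outcome(model, out, sim, expected_keys)
        for alt in model.alternatives:
            records[alt].append(dict(out[alt]))

    outcomes = {alt: pd.DataFrame(rows) for alt, rows in records.items()}
    fp = model.fingerprint()
    logger.info(
        "run_model: model=%s fingerprint=%s mode=%s n_sims=%d seed=%d",
        model.name, fp, options.mode, len(draws), options.seed,
    )
    return PSAResult(draws=draws, outcomes=outcomes, options=options, model_fingerprint=fp)


# ---------------------------------------------------------------------------
# Model definition documents (YAML / JSON)
# ---------------------------------------------------------------------------

#: registry mapping a document's ``outcome`` name to an outcome function
OUTCOME_REGISTRY: dict[str, OutcomeFn] = {}


def register_outcome(name: str, fn: OutcomeFn) -> None:
    OUTCOME_REGISTRY[name] = fn


def load_model(path: str | Path) -> ModelDefinition:
    """Read a YAML/JSON model definition document.

    Layout::

        name: antid
        outcome: antid            # registry key for the outcome function
        strategies: [[id, label], ...]
        treatments: [[id, label], ...]
        parameters:
          - {name: s0, distribution: beta, params: {alpha: 9.5, beta: 990.5}}
          ...

    Empirical parameters may reference a CSV of samples via
    ``params: {samples_csv: file.csv, column: or_eff}`` (path relative to
    the document).
    """
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text)
    params = []
    for p in doc.get("parameters", []):
        hyper = dict(p.get("params", {}))
        if "samples_csv" in hyper:
            csv_path = path.parent / hyper.pop("samples_csv")
            col = hyper.pop("column")
            hyper["samples"] = pd.read_csv(csv_path)[col].to_list()
        params.append(
            ParameterSpec(
                name=p["name"],
                distribution=p["distribution"],
                params=hyper,
                low=p.get("low"),
                high=p.get("high"),
                description=p.get("description", ""),
                source=p.get("source", ""),
            )
        )
    outcome_name = doc["outcome"]
    if outcome_name not in OUTCOME_REGISTRY:
        raise KeyError(
            f"outcome function {outcome_name!r} is not registered; known: "
            f"{sorted(OUTCOME_REGISTRY)}"
        )
    return ModelDefinition(
        name=doc.get("name", path.stem),
        parameters=tuple(params),
        strategies=tuple((str(a), str(b)) for a, b in doc["strategies"]),
        treatments=tuple((str(a), str(b)) for a, b in doc["treatments"]),
        outcome_fn=OUTCOME_REGISTRY[outcome_name],
    )


def export_psa(psa: PSAResult, draws_path: str | Path, outcomes_path: str | Path) -> None:
    """Write parameter draws and long-format outcomes as CSV."""
    psa.draws.to_csv(draws_path, index=False)
    psa.to_long().to_csv(outcomes_path, index=False)
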