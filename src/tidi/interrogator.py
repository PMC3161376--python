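"""Scenario building, storage and orchestrated runs.

A *scenario* bundles everything a committee-style "what if" needs: which
studies and bias assessors feed the evidence synthesis, any parameter
overrides on the decision model, and the run options.  Running a scenario
chains the full pipeline — meta-analysis, effectiveness hand-off, model
execution, economic post-processing and (optionally) influence analysis —
and writes every table under a per-scenario directory with a manifest of
seeds, fingerprints and content hashes, so any result can be reproduced
and verified byte for byte.

All randomness flows from one scenario-level master seed, split
deterministically into per-component seeds.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .antid import attach_effectiveness
from .economics import EconSummary, summarize
from .engine import (
    ModelDefinition,
    ParameterSpec,
    PSAResult,
    RunOptions,
    export_psa,
    run_model,
)
from .evidence import (
    BiasElicitation,
    MCMCOptions,
    MetaConfig,
    MetaResult,
    Priors,
    Study,
    forest_data,
    run_meta,
)
from .influence import OutcomeSelector, TornadoResult, tornado

logger = logging.getLogger(__name__)


def split_seed(master: int, n: int) -> list[int]:
    """Derive ``n`` independent component seeds from one master seed."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


@dataclass
class Scenario:
    """Named bundle of overrides and selections defining one analysis."""

    name: str
    description: str = ""
    parameter_overrides: dict[str, ParameterSpec] = field(default_factory=dict)
    meta_config: MetaConfig | None = None
    run_options: RunOptions = field(default_factory=RunOptions)
    created: str = ""
    provenance: dict[str, str] = field(default_factory=dict)

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        def spec_dict(p: ParameterSpec) -> dict:
            return {
                "name": p.name,
                "distribution": p.distribution,
                "params": {k: v for k, v in p.params.items()},
                "low": p.low,
                "high": p.high,
                "description": p.description,
                "source": p.source,
            }

        meta = None
        if self.meta_config is not None:
            m = self.meta_config
            meta = {
                "selected_study_ids": sorted(m.selected_study_ids)
                if m.selected_study_ids is not None
                else None,
                "include_internal": m.include_internal,
                "include_external": m.include_external,
                "include_additive": m.include_additive,
                "include_proportional": m.include_proportional,
                "selected_assessor_ids": sorted(m.selected_assessor_ids)
                if m.selected_assessor_ids is not None
                else None,
                "method": m.method,
                "mcmc": dataclasses.asdict(m.mcmc),
                "priors": dataclasses.asdict(m.priors),
                "continuity": m.continuity,
            }
        return {
            "name": self.name,
            "description": self.description,
            "parameter_overrides": {k: spec_dict(v) for k, v in self.parameter_overrides.items()},
            "meta_config": meta,
            "run_options": {
                "mode": self.run_options.mode,
                "n_sims": self.run_options.n_sims,
                "seed": self.run_options.seed,
                "lambda_grid": list(self.run_options.lambda_grid),
            },
            "created": self.created,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Scenario":
        overrides = {
            k: ParameterSpec(
                name=v["name"],
                distribution=v["distribution"],
                params=v.get("params", {}),
                low=v.get("low"),
                high=v.get("high"),
                description=v.get("description", ""),
                source=v.get("source", ""),
            )
            for k, v in doc.get("parameter_overrides", {}).items()
        }
        meta = None
        m = doc.get("meta_config")
        if m is not None:
            meta = MetaConfig(
                selected_study_ids=set(m["selected_study_ids"])
                if m.get("selected_study_ids") is not None
                else None,
                include_internal=m.get("include_internal", True),
                include_external=m.get("include_external", True),
                include_additive=m.get("include_additive", True),
                include_proportional=m.get("include_proportional", True),
                selected_assessor_ids=set(m["selected_assessor_ids"])
                if m.get("selected_assessor_ids") is not None
                else None,
                method=m.get("method", "dl"),
                mcmc=MCMCOptions(**m.get("mcmc", {})),
                priors=Priors(**m.get("priors", {})),
                continuity=m.get("continuity", 0.5),
            )
        ro = doc.get("run_options", {})
        return cls(
            name=doc["name"],
            description=doc.get("description", ""),
            parameter_overrides=overrides,
            meta_config=meta,
            run_options=RunOptions(
                mode=ro.get("mode", "deterministic"),
                n_sims=ro.get("n_sims", 1000),
                seed=ro.get("seed", 0),
                lambda_grid=tuple(ro.get("lambda_grid", tuple(range(0, 50001, 500)))),
            ),
            created=doc.get("created", ""),
            provenance=doc.get("provenance", {}),
        )

    def validate_against(self, model: ModelDefinition) -> None:
        known = {p.name for p in model.parameters}
        for name in self.parameter_overrides:
            if name not in known:
                raise ValueError(
                    f"scenario {self.name!r} overrides unknown parameter {name!r}"
                )


# -- scenario store --------------------------------------------------------


def save_scenario(scenario: Scenario, store_path: str | Path, overwrite: bool = False) -> Path:
    store = Path(store_path)
    store.mkdir(parents=True, exist_ok=True)
    target = store / f"{scenario.name}.json"
    if target.exists() and not overwrite:
        raise FileExistsError(
            f"scenario {scenario.name!r} already exists (pass overwrite=True)"
        )
    if not scenario.created:
        scenario.created = datetime.datetime.now(datetime.timezone.utc).isoformat()
    target.write_text(json.dumps(scenario.to_dict(), indent=2, sort_keys=True))
    return target


def load_scenario(store_path: str | Path, name: str, model: ModelDefinition | None = None) -> Scenario:
    path = Path(store_path) / f"{name}.json"
    scenario = Scenario.from_dict(json.loads(path.read_text()))
    if model is not None:
        scenario.validate_against(model)
    return scenario


def list_scenarios(store_path: str | Path) -> list[str]:
    """Scenario names in creation order."""
    store = Path(store_path)
    if not store.exists():
        return []
    entries = []
    for path in store.glob("*.json"):
        doc = json.loads(path.read_text())
        entries.append((doc.get("created", ""), doc.get("name", path.stem)))
    return [name for _, name in sorted(entries)]


# -- orchestration ---------------------------------------------------------


@dataclass
class ScenarioResult:
    scenario: Scenario
    model: ModelDefinition
    meta: MetaResult | None
    psa: PSAResult
    econ: EconSummary
    tornado: TornadoResult | None
    out_dir: Path | None
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_scenario(
    base_model: ModelDefinition,
    scenario: Scenario,
    studies: Sequence[Study] | None = None,
    elicitations: Sequence[BiasElicitation] = (),
    out_dir: str | Path | None = None,
    tornado_selector: OutcomeSelector | None = None,
    comparator: str = "1",
    plots: bool = False,
) -> ScenarioResult:
    """Execute the full pipeline for one scenario.

    The scenario's ``run_options.seed`` is the master seed; component
    seeds (meta-analysis MCMC, PSA) are split from it deterministically,
    so two runs of the same scenario are byte-identical.  Output tree::

        <out_dir>/{meta,psa,econ,tornado}/*.csv + manifest.json
    """
    scenario.validate_against(base_model)
    meta_seed, psa_seed = split_seed(scenario.run_options.seed, 2)

    model = base_model
    for spec in scenario.parameter_overrides.values():
        model = model.replace_parameter(spec)

    meta_result: MetaResult | None = None
    if scenario.meta_config is not None:
        if studies is None:
            raise ValueError(
                f"scenario {scenario.name!r} has a meta_config but no studies "
                "were supplied"
            )
        cfg = dataclasses.replace(
            scenario.meta_config,
            mcmc=dataclasses.replace(scenario.meta_config.mcmc, seed=meta_seed),
        )
        try:
            meta_result = run_meta(studies, elicitations, cfg)
        except Exception as exc:
            raise RuntimeError(f"scenario {scenario.name!r}: meta-analysis failed") from exc
        model = attach_effectiveness(model, meta_result, mode=scenario.run_options.mode)

    options = dataclasses.replace(scenario.run_options, seed=psa_seed)
    psa = run_model(model, options)
    econ = summarize(psa, comparator=comparator)

    tornado_result: TornadoResult | None = None
    if tornado_selector is not None:
        tornado_result = tornado(model, tornado_selector)

    manifest: dict = {
        "scenario": scenario.name,
        "version": __version__,
        "master_seed": scenario.run_options.seed,
        "component_seeds": {"meta": meta_seed, "psa": psa_seed},
        "model_fingerprint": psa.model_fingerprint,
        "mode": options.mode,
        "n_sims": psa.n_sims,
        "files": {},
    }

    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        for sub in ("meta", "psa", "econ", "tornado"):
            (out_path / sub).mkdir(parents=True, exist_ok=True)

        written: list[Path] = []

        def write_df(df: pd.DataFrame, rel: str, **kwargs) -> None:
            p = out_path / rel
            df.to_csv(p, **kwargs)
            written.append(p)

        if meta_result is not None:
            write_df(forest_data(meta_result), "meta/forest.csv", index=False)
            summary = pd.DataFrame(
                [
                    {
                        "variant": variant,
                        "or": r.or_point,
                        "or_low": r.or_interval[0],
                        "or_high": r.or_interval[1],
                        "mu": r.mu_point,
                        "tau": r.tau_point,
                        "method": r.method,
                        "k": r.k,
                    }
                    for variant, r in (
                        ("adjusted", meta_result),
                        ("unadjusted", meta_result.unadjusted_companion),
                    )
                    if r is not None
                ]
            )
            write_df(summary, "meta/meta.csv", index=False)

        export_psa(psa, out_path / "psa/draws.csv", out_path / "psa/outcomes.csv")
        written += [out_path / "psa/draws.csv", out_path / "psa/outcomes.csv"]

        means = econ.means.reset_index()
        write_df(means, "econ/summary.csv", index=False)
        write_df(econ.icer_table, "econ/icer.csv", index=False)
        if not econ.incrementals.empty:
            write_df(econ.incrementals, "econ/incrementals.csv", index=False)
        write_df(econ.inmb_table, "econ/inmb.csv", index=False)
        if not econ.ceac_table.empty:
            from .economics import ceac_long

            write_df(ceac_long(econ.ceac_table), "econ/ceac.csv", index=False)
        if tornado_result is not None:
            write_df(tornado_result.to_frame(), "tornado/tornado.csv", index=False)

        if plots:
            from . import plots as _plots

            if meta_result is not None:
                _plots.forest_plot(meta_result, out_path / "meta/forest.png")
            if not econ.ceac_table.empty:
                _plots.ceac_plot(econ.ceac_table, out_path / "econ/ceac.png")
            if tornado_result is not None:
                _plots.tornado_plot(tornado_result, out_path / "tornado/tornado.png")

        manifest["files"] = {
            str(p.relative_to(out_path)): _sha256(p) for p in sorted(written)
        }
        (out_path / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )

    return ScenarioResult(
        scenario=scenario,
        model=model,
        meta=meta_result,
        psa=psa,
        econ=econ,
        tornado=tornado_result,
        out_dir=out_path,
        manifest=manifest,
    )


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every file listed in a run's manifest; True iff all match."""
    out_path = Path(out_dir)
    manifest = json.loads((out_path / "manifest.json").read_text())
    return all(
        _sha256(out_path / rel) == digest for rel, digest in manifest["files"].items()
    )


def compare_scenarios(
    results: Sequence[ScenarioResult],
    selector: OutcomeSelector,
) -> pd.DataFrame:
    """Side-by-side scenario table for one selected economic outcome.

    One row per scenario: the outcome computed from each scenario's PSA
    (mean over draws; exact value for deterministic runs) plus the
    difference against the first (reference) scenario.
    """
    if len(results) < 2:
        raise ValueError("compare_scenarios needs at least two result bundles")
    strategy_sets = {tuple(sorted(r.psa.alternatives)) for r in results}
    if len(strategy_sets) > 1:
        raise ValueError("scenarios cover different strategy/treatment sets")
    rows = []
    for r in results:
        value, interval = selector.psa_value(r.psa)
        rows.append(
            {
                "scenario": r.scenario.name,
                "outcome": selector.label(),
                "value": value,
                "low": interval[0] if interval else np.nan,
                "high": interval[1] if interval else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["diff_vs_reference"] = df["value"] - df.loc[0, "value"]
    return df
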