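"""Pipeline orchestration: simulate -> traits -> varcomp -> index -> impact.

A single YAML config with one section per stage drives the full replay;
every run writes a JSON manifest recording the config snapshot, the master
seed, per-stage output digests, editing-filter counts and REML convergence
flags, so a run can be reproduced bit-for-bit and audited.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .index import (
    GeneticParameterSet,
    Scenario,
    demonstration_parameters,
    expected_response,
    scenario_delta,
    scenario_suite,
    standard_scenarios,
)
from .impact import ImpactAssumptions, methane_impact
from .pedigree import Pedigree
from .reml import BivariateREML, RepeatabilityREML
from .simulate import (
    SimulationTruth,
    default_truth,
    simulate_pedigree,
    simulate_phenotypes,
)
from .traits import add_residual_traits, build_trait_table

STAGES = ("simulate", "traits", "varcomp", "index", "impact")

#: Residual traits fitted with the mean-only model by default.
MEAN_ONLY_TRAITS = {"rmep", "rmec", "rfi1", "rfi2"}


class ConfigError(ValueError):
    """Raised before any compute when a config fails validation."""


class StageError(RuntimeError):
    """Raised when a stage fails, naming the stage."""


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path], **info) -> None:
        entry = {"outputs": {}, **info}
        for name, path in outputs.items():
            entry["outputs"][name] = {
                "path": str(path),
                "sha256": _sha256(path),
            }
        self.stages[stage] = entry

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                default=_json_default,
            )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# config parsing / validation (all before any compute)


def _index_params_from_config(section: dict) -> GeneticParameterSet:
    p = section.get("parameters", "demonstration")
    methane = section.get("methane_trait", "mep")
    if p == "demonstration":
        base = demonstration_parameters(methane)
        rel = section.get("reliability")
        inten = section.get("intensity")
        if rel is not None:
            base.reliability = float(rel)
        if inten is not None:
            base.intensity = float(inten)
        return base
    corr = {
        frozenset(tuple(k.split(":"))): float(v)
        for k, v in p.get("correlations", {}).items()
    }
    return GeneticParameterSet(
        traits=tuple(p["traits"]),
        genetic_sd={k: float(v) for k, v in p["genetic_sd"].items()},
        correlations=corr,
        reliability=float(p.get("reliability", 0.81)),
        intensity=float(p.get("intensity", 1.0)),
    )


def _scenarios_from_config(section: dict) -> list[Scenario]:
    sc = section.get("scenarios", "standard")
    if sc == "standard":
        return standard_scenarios(section.get("methane_trait", "mep"))
    return [Scenario(s["name"], dict(s["economic_values"])) for s in sc]


def validate_config(config: dict) -> None:
    """Schema and pre-flight checks; raises :class:`ConfigError`.

    In particular, a scenario requiring a genetic correlation the parameter
    set does not supply is reported here, naming the missing pairs, before
    any simulation or fitting starts.
    """
    unknown = set(config) - set(STAGES) - {"seed", "name"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    sim = config.get("simulate", {})
    for key in ("n_founders", "n_generations", "offspring_per_mating", "n_cows"):
        if key in sim and int(sim[key]) < 1:
            raise ConfigError(f"simulate.{key} must be >= 1")
    vc = config.get("varcomp", {})
    for pair in vc.get("pairs", []):
        if len(pair) != 2:
            raise ConfigError(f"varcomp.pairs entries must be pairs, got {pair}")
    idx = config.get("index")
    if idx is not None:
        try:
            params = _index_params_from_config(idx)
            scenarios = _scenarios_from_config(idx)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"index section invalid: {exc}") from exc
        for sc in scenarios:
            weighted = [t for t, w in sc.economic_values.items() if w != 0.0]
            missing = sorted(
                {
                    tuple(sorted((t, u)))
                    for t in weighted
                    for u in params.traits
                    if t != u and frozenset((t, u)) not in params.correlations
                }
            )
            if missing:
                raise ConfigError(
                    f"scenario {sc.name!r} requires genetic correlations "
                    f"not supplied: {missing}"
                )
    imp = config.get("impact", {})
    if "assumptions" in imp:
        try:
            ImpactAssumptions(**imp["assumptions"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"impact.assumptions invalid: {exc}") from exc


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, seed, out_dir, manifest):
    sim = config.get("simulate", {})
    truth_cfg = sim.get("truth", "default")
    n_cows = int(sim.get("n_cows", 600))
    weeks = sim.get("weeks_per_cow", 30)
    if isinstance(weeks, list):
        weeks = tuple(weeks)
    if truth_cfg == "default":
        truth = default_truth(n_cows=n_cows, weeks_per_cow=weeks, seed=seed)
    else:
        truth = SimulationTruth.from_dict({**truth_cfg, "n_cows": n_cows,
                                           "weeks_per_cow": weeks, "seed": seed})
    ped = simulate_pedigree(
        int(sim.get("n_founders", 320)),
        int(sim.get("n_generations", 1)),
        int(sim.get("offspring_per_mating", 4)),
        seed=seed,
    )
    herd = simulate_phenotypes(ped, truth, seed=seed)
    ped_path = out_dir / "pedigree.csv"
    rec_path = out_dir / "records.csv"
    truth_path = out_dir / "truth.yaml"
    ped.to_csv(ped_path)
    herd.records.to_csv(rec_path, index=False)
    truth.to_yaml(truth_path)
    manifest.record(
        "simulate",
        {"pedigree": ped_path, "records": rec_path, "truth": truth_path},
        n_animals=len(ped),
        n_cows=truth.n_cows,
        n_records=len(herd.records),
        n_clipped=herd.n_clipped,
    )


def _stage_traits(config, seed, out_dir, manifest):
    rec_path = out_dir / "records.csv"
    if not rec_path.exists():
        raise StageError(f"traits: missing input {rec_path}")
    records = pd.read_csv(rec_path)
    cfg = config.get("traits", {})
    table, report = build_trait_table(
        records, apply_filters=bool(cfg.get("apply_filters", True))
    )
    table = add_residual_traits(table)
    out = out_dir / "traits.csv"
    table.to_csv(out, index=False)
    manifest.record("traits", {"traits": out}, filter_counts=report.as_dict())


def _stage_varcomp(config, seed, out_dir, manifest):
    traits_path = out_dir / "traits.csv"
    ped_path = out_dir / "pedigree.csv"
    for p in (traits_path, ped_path):
        if not p.exists():
            raise StageError(f"varcomp: missing input {p}")
    table = pd.read_csv(traits_path)
    ped = Pedigree.from_csv(ped_path)
    cfg = config.get("varcomp", {})
    rows = []
    flags = {}
    for trait in cfg.get("traits", ["mep"]):
        est = RepeatabilityREML(
            trait=trait, mean_only=trait in MEAN_ONLY_TRAITS
        ).fit(table, ped)
        frame = est.result_.summary_frame()
        frame.insert(0, "kind", "univariate")
        rows.append(frame)
        flags[trait] = {"converged": est.converged_, "n_iter": est.n_iter_}
    for pair in cfg.get("pairs", []):
        a, b = pair
        est = BivariateREML(
            trait_a=a,
            trait_b=b,
            mean_only_a=a in MEAN_ONLY_TRAITS,
            mean_only_b=b in MEAN_ONLY_TRAITS,
        ).fit(table, ped)
        frame = est.result_.summary_frame()
        frame.insert(0, "kind", f"bivariate:{a}-{b}")
        frame["genetic_correlation"] = est.genetic_correlation_
        frame["genetic_correlation_se"] = est.genetic_correlation_se_
        frame["phenotypic_correlation"] = est.phenotypic_correlation_
        rows.append(frame)
        flags[f"{a}-{b}"] = {"converged": est.converged_, "n_iter": est.n_iter_}
    out = out_dir / "varcomp.csv"
    pd.concat(rows, ignore_index=True).to_csv(out, index=False)
    manifest.record("varcomp", {"varcomp": out}, convergence=flags)


def _stage_index(config, seed, out_dir, manifest):
    cfg = config.get("index", {})
    params = _index_params_from_config(cfg)
    scenarios = _scenarios_from_config(cfg)
    table = scenario_suite(params, scenarios)
    out = out_dir / "index_responses.csv"
    table.to_csv(out, index=False)
    manifest.record("index", {"responses": out}, scenarios=[s.name for s in scenarios])


def _stage_impact(config, seed, out_dir, manifest):
    cfg = config.get("impact", {})
    assumptions = ImpactAssumptions(**cfg.get("assumptions", {}))
    delta = cfg.get("delta_g_per_day")
    methane = config.get("index", {}).get("methane_trait", "mep")
    if delta is None:
        resp_path = out_dir / "index_responses.csv"
        if not resp_path.exists():
            raise StageError(f"impact: missing input {resp_path}")
        resp = pd.read_csv(resp_path).set_index("scenario")
        pair = cfg.get("compare", ["SC0", "SC2B"])
        col = f"response_{methane}"
        delta = float(resp.loc[pair[0], col] - resp.loc[pair[1], col])
    report = methane_impact(float(delta), assumptions)
    out = out_dir / "impact.csv"
    report.as_frame().to_csv(out, index=False)
    manifest.record(
        "impact", {"impact": out}, delta_g_per_day=float(delta),
        price_mode=report.price_mode,
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "traits": _stage_traits,
    "varcomp": _stage_varcomp,
    "index": _stage_index,
    "impact": _stage_impact,
}


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    stages: tuple[str, ...] | None = None,
) -> RunManifest:
    """Run the pipeline (or a subset of stages) under one master seed.

    ``config`` is a dict or a YAML path; it is validated in full before any
    stage runs.  ``stages`` restricts execution (outputs of earlier stages
    must already exist in ``out_dir``).  Returns the manifest, also written
    to ``out_dir/manifest.json``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    validate_config(config)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run = tuple(stages) if stages is not None else STAGES
    for s in run:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    manifest = RunManifest(config=config, seed=seed)
    manifest_path = out_dir / "manifest.json"
    # resume: carry forward records of stages already run
    if stages is not None and manifest_path.exists():
        with open(manifest_path) as fh:
            manifest.stages = json.load(fh).get("stages", {})
    for s in STAGES:
        if s not in run:
            continue
        try:
            _STAGE_FUNCS[s](config, seed, out_dir, manifest)
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {s!r} failed: {exc}") from exc
        manifest.write(manifest_path)
    return manifest
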