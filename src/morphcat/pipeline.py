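"""Configuration, end-to-end runs and seed provenance.

A run is fully determined by one master seed: the design, the subject
population and the permutation tests each draw from a named child stream
(``design``, ``population``, ``tests``) spawned from it, so e.g. changing
the number of permutations never perturbs the simulated responses.

All tabular artifacts are comma-separated UTF-8 text with a header row and
``.`` as the decimal mark; summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .analysis import (
    CRITERIA_PRESETS,
    apply_exclusions,
    remap_subjects,
    robustness_sweep,
    score_responses,
    summarize_cohort,
)
from .cohort import (
    CONDITIONS,
    PopulationSpec,
    run_cohort,
    write_records,
)
from .design import DesignConfig, build_stimulus_lists, validate_design, write_lists

__all__ = [
    "ConfigError",
    "AnalysisConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "seed_streams",
    "run_end_to_end",
]

log = logging.getLogger("morphcat")


class ConfigError(ValueError):
    """A configuration file is invalid; the message names the offending key."""


@dataclass(frozen=True)
class AnalysisConfig:
    criteria: str = "default"  # preset name, or "all" for the robustness sweep
    from_block: int = 3
    to_block: int = 9
    n_permutations: int = 10000
    remap: str = "auto"  # auto (unsupervised only) | always | never

    def __post_init__(self) -> None:
        if self.criteria not in (*CRITERIA_PRESETS, "all"):
            raise ConfigError(f"unknown criteria preset {self.criteria!r}")
        if self.remap not in ("auto", "always", "never"):
            raise ConfigError(f"unknown remap mode {self.remap!r}")


@dataclass(frozen=True)
class RunConfig:
    master_seed: int
    condition: str = "semi_supervised"
    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationSpec = field(default_factory=lambda: PopulationSpec(n_subjects=50))
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS and self.condition != "semi":
            raise ConfigError(f"unknown condition {self.condition!r}")


# Fields settable from the YAML file. Distribution families of the
# population mixture are a Python-API concern and are not exposed here.
_DESIGN_KEYS = {
    "n_blocks",
    "trials_per_block",
    "n_groups",
    "n_appendages",
    "realisations_per_appendage",
    "indicative_per_block",
    "per_group_per_block",
    "salient_boundary",
    "triangular_peak_weight",
    "design_seed",
}
_POPULATION_KEYS = {"n_subjects", "fraction_fast", "fraction_nonlearner"}
_ANALYSIS_KEYS = {"criteria", "from_block", "to_block", "n_permutations", "remap"}
_TOP_KEYS = {"master_seed", "condition", "design", "population", "analysis"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in {where}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Only ``master_seed`` is mandatory; every other field falls back to its
    default. Unknown keys are rejected with an error naming the key. The
    resolved configuration is echoed to the ``morphcat`` logger.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    if "master_seed" not in raw:
        raise ConfigError("missing required key 'master_seed'")
    design_raw = raw.get("design", {}) or {}
    _check_keys(design_raw, _DESIGN_KEYS, "design")
    pop_raw = raw.get("population", {}) or {}
    _check_keys(pop_raw, _POPULATION_KEYS, "population")
    ana_raw = raw.get("analysis", {}) or {}
    _check_keys(ana_raw, _ANALYSIS_KEYS, "analysis")
    try:
        config = RunConfig(
            master_seed=int(raw["master_seed"]),
            condition=str(raw.get("condition", "semi_supervised")),
            design=DesignConfig(**design_raw),
            population=PopulationSpec(n_subjects=50, **pop_raw)
            if "n_subjects" not in pop_raw
            else PopulationSpec(**pop_raw),
            analysis=AnalysisConfig(**ana_raw),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    log.info("resolved configuration: %s", config)
    return config


def save_config(config: RunConfig, path) -> None:
    """Write a configuration back to YAML (YAML-exposed fields only)."""
    doc = {
        "master_seed": config.master_seed,
        "condition": config.condition,
        "design": {
            k: getattr(config.design, k) for k in sorted(_DESIGN_KEYS)
        },
        "population": {
            k: getattr(config.population, k) for k in sorted(_POPULATION_KEYS)
        },
        "analysis": {k: getattr(config.analysis, k) for k in sorted(_ANALYSIS_KEYS)},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def seed_streams(master_seed: int) -> dict[str, int]:
    """Named integer sub-seeds derived from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(3)
    names = ("design", "population", "tests")
    return {
        name: int(np.random.default_rng(ss).integers(2**31))
        for name, ss in zip(names, children)
    }


def run_end_to_end(config: RunConfig, out_dir) -> dict[str, str]:
    """Design -> simulate -> score -> exclude -> (remap) -> summarise.

    Writes the stimulus lists, the trial-record dataset, the design
    validation report, the exclusion report and the cohort summary to
    ``out_dir`` and returns the paths. Byte-identical across reruns with
    the same configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = seed_streams(config.master_seed)
    log.info("seed provenance: %s", seeds)
    paths: dict[str, str] = {}

    t0 = time.perf_counter()
    design = replace(config.design, design_seed=seeds["design"])
    lists = build_stimulus_lists(design)
    reports = [validate_design(sl, design) for sl in lists]
    if not all(r.passed for r in reports):
        raise RuntimeError("design stage: generated lists failed validation")
    paths["lists"] = str(out / "lists.csv")
    write_lists(lists, design, paths["lists"])
    paths["design_validation"] = str(out / "design_validation.json")
    with open(paths["design_validation"], "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
    log.info("design stage done in %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    population = replace(config.population, master_seed=seeds["population"])
    records = run_cohort(population, config.condition, design, lists=lists)
    paths["dataset"] = str(out / "dataset.csv")
    write_records(records, paths["dataset"])
    log.info(
        "simulation stage done in %.2fs (%d records)",
        time.perf_counter() - t0,
        len(records),
    )

    t0 = time.perf_counter()
    scored = score_responses(records)
    kept, exclusions = apply_exclusions(scored, config.condition)
    remap_mode = config.analysis.remap
    do_remap = remap_mode == "always" or (
        remap_mode == "auto" and config.condition == "unsupervised"
    )
    mappings: dict[str, str] = {}
    if do_remap and len(kept):
        kept, mappings = remap_subjects(kept)
        kept = score_responses(kept)
    tests_rng = np.random.default_rng(seeds["tests"])
    if config.analysis.criteria == "all":
        sweep = robustness_sweep(
            kept,
            from_block=config.analysis.from_block,
            to_block=config.analysis.to_block,
            n_permutations=config.analysis.n_permutations,
            rng=tests_rng,
        )
        summary_doc = [
            {
                "name": entry["name"],
                "indicative_divergence": entry["indicative_divergence"],
                "indicative_divergence_sign": entry["indicative_divergence_sign"],
                "summary": entry["summary"].to_dict(),
            }
            for entry in sweep
        ]
    else:
        conf, nonc = CRITERIA_PRESETS[config.analysis.criteria]
        summary_doc = summarize_cohort(
            kept,
            conf,
            nonc,
            from_block=config.analysis.from_block,
            to_block=config.analysis.to_block,
            n_permutations=config.analysis.n_permutations,
            rng=tests_rng,
        ).to_dict()
    paths["exclusions"] = str(out / "exclusions.json")
    with open(paths["exclusions"], "w", encoding="utf-8") as fh:
        json.dump(exclusions.to_dict() | {"remapped": mappings}, fh, indent=2, sort_keys=True)
    paths["summary"] = str(out / "summary.json")
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary_doc, fh, indent=2, sort_keys=True)
    log.info("analysis stage done in %.2fs", time.perf_counter() - t0)
    return paths
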