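"""Cohort simulation: heterogeneous learners under three feedback schedules.

This is the synthetic-data stage. A population mixes fast attention
switchers, slow switchers and non-learners; each simulated subject runs one
session (one stimulus list under one feedback schedule), producing
trial-level records including response times and occasional invalid trials
so the downstream exclusion filters are exercisable.

Response times are purely phenomenological (log-normal, independent of
model state): the analysis operates on accuracy, so RTs exist only to feed
the validity window. Each subject's salient-dimension prior has a random
sign, emulating the arbitrary key assignment subjects adopt before (or
without) feedback; corrective feedback resolves the sign quickly, while in
the unsupervised condition it persists and must be handled by response
remapping downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignConfig, StimulusList, build_stimulus_lists
from .learners import AttentionState, DeltaRuleLearner, PrototypeLearner, step_trial

__all__ = [
    "CONDITIONS",
    "FeedbackSchedule",
    "SubjectParams",
    "PopulationSpec",
    "make_schedule",
    "sample_subject_params",
    "run_subject",
    "run_cohort",
    "TRIAL_COLUMNS",
    "write_records",
    "read_records",
    "ParseError",
]

CONDITIONS = ("unsupervised", "supervised", "semi_supervised")
_ALIASES = {"semi": "semi_supervised"}

#: Validity window on response times, in milliseconds (exclusive bounds).
RT_WINDOW_MS = (300.0, 1500.0)

TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "list_id",
    "block",
    "block_type",
    "trial",
    "morph",
    "group",
    "category",
    "indicative",
    "feedback_given",
    "response",
    "rt",
    "valid",
]


class ParseError(ValueError):
    """A trial-record file failed schema validation."""


@dataclass(frozen=True)
class FeedbackSchedule:
    condition: str
    feedback_blocks: frozenset[int]


def make_schedule(condition: str, n_blocks: int = 10) -> FeedbackSchedule:
    """Feedback schedule for a condition: none, all blocks, or the first three."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    condition = _ALIASES.get(condition, condition)
    if condition == "unsupervised":
        blocks: frozenset[int] = frozenset()
    elif condition == "supervised":
        blocks = frozenset(range(1, n_blocks + 1))
    elif condition == "semi_supervised":
        blocks = frozenset(range(1, min(3, n_blocks) + 1))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return FeedbackSchedule(condition=condition, feedback_blocks=blocks)


@dataclass(frozen=True)
class SubjectParams:
    """One simulated learner's parameters.

    ``switch_rate`` controls how fast supervised errors move attention from
    the salient to the subtle channels; ``salient_prior`` is the magnitude
    of the initial salient-dimension association (its sign is drawn from
    the subject's own stream); ``rt_location``/``rt_scale`` parameterise
    the log-normal response-time generator in log-milliseconds.
    """

    subject_id: str
    model_kind: str  # "delta_rule" | "prototype"
    learning_rate: float
    switch_rate: float
    alpha_subtle_init: float
    salient_prior: float
    similarity_scale: float
    temperature: float
    lapse: float
    invalid_rate: float
    rt_location: float
    rt_scale: float
    seed: int
    component: str = "unspecified"  # fast | slow | nonlearner (diagnostic)

    def __post_init__(self) -> None:
        if self.model_kind not in ("delta_rule", "prototype"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        for name in ("lapse", "invalid_rate", "alpha_subtle_init"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("learning_rate", "switch_rate", "temperature", "similarity_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _sample_dist(dist, rng: np.random.Generator) -> float | str:
    """Draw from a named distribution family ``(name, *params)``."""
    name = dist[0]
    if name == "constant":
        return dist[1]
    if name == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if name == "loguniform":
        return float(np.exp(rng.uniform(np.log(dist[1]), np.log(dist[2]))))
    if name == "normal_clipped":
        _, mu, sd, lo, hi = dist
        return float(np.clip(rng.normal(mu, sd), lo, hi))
    if name == "choice":
        values, probs = dist[1], dist[2]
        return values[int(rng.choice(len(values), p=probs))]
    raise ValueError(f"unknown distribution family {name!r}")


def _default_field_dists() -> dict:
    # Population defaults; see docs/methods.md for the rationale behind the
    # ranges. switch_rate is drawn per mixture component, not here.
    return {
        "model_kind": ("choice", ("delta_rule", "prototype"), (0.5, 0.5)),
        "learning_rate": ("uniform", 0.15, 0.3),
        "alpha_subtle_init": ("uniform", 0.02, 0.08),
        "salient_prior": ("uniform", 0.5, 1.5),
        "similarity_scale": ("uniform", 4.0, 8.0),
        "temperature": ("uniform", 0.5, 0.8),
        "lapse": ("uniform", 0.01, 0.06),
        "invalid_rate": ("uniform", 0.0, 0.05),
        "rt_location": ("uniform", float(np.log(500.0)), float(np.log(800.0))),
        "rt_scale": ("uniform", 0.15, 0.3),
    }


def _default_nonlearner_overrides() -> dict:
    return {
        "learning_rate": ("uniform", 0.0, 0.05),
        "alpha_subtle_init": ("uniform", 0.02, 0.08),
        "temperature": ("uniform", 1.5, 3.0),
        "lapse": ("uniform", 0.1, 0.25),
        "salient_prior": ("uniform", 0.0, 0.3),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture population of simulated subjects.

    ``fraction_fast`` is the weight of the high-switch-rate component among
    the learner sub-population; ``fraction_nonlearner`` is the weight of a
    disengaged/non-learning component (its size in real cohorts is
    population-dependent, so it is configurable rather than calibrated).
    """

    n_subjects: int
    fraction_fast: float = 0.53
    fraction_nonlearner: float = 0.25
    master_seed: int = 0
    field_dists: dict = field(default_factory=_default_field_dists)
    fast_switch_rate: tuple = ("loguniform", 0.3, 1.0)
    slow_switch_rate: tuple = ("loguniform", 0.05, 0.15)
    nonlearner_switch_rate: tuple = ("uniform", 0.0, 0.02)
    nonlearner_overrides: dict = field(default_factory=_default_nonlearner_overrides)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in ("fraction_fast", "fraction_nonlearner"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def sample_subject_params(
    spec: PopulationSpec, rng: np.random.Generator, subject_id: str = "s0000"
) -> SubjectParams:
    """Draw one subject's parameters from the population mixture."""
    if rng.random() < spec.fraction_nonlearner:
        component = "nonlearner"
        switch_dist = spec.nonlearner_switch_rate
    elif rng.random() < spec.fraction_fast:
        component = "fast"
        switch_dist = spec.fast_switch_rate
    else:
        component = "slow"
        switch_dist = spec.slow_switch_rate
    fields = {k: _sample_dist(d, rng) for k, d in spec.field_dists.items()}
    if component == "nonlearner":
        for k, d in spec.nonlearner_overrides.items():
            fields[k] = _sample_dist(d, rng)
    return SubjectParams(
        subject_id=subject_id,
        switch_rate=float(_sample_dist(switch_dist, rng)),
        seed=int(rng.integers(2**31)),
        component=component,
        **fields,
    )


def _build_learner(params: SubjectParams, n_groups: int, sign: float):
    """Initialise the subject's model with a signed salient-dimension prior."""
    n_features = n_groups + 2
    attention = AttentionState(
        alpha_subtle=params.alpha_subtle_init, switch_rate=params.switch_rate
    )
    s = sign * params.salient_prior
    if params.model_kind == "delta_rule":
        weights = np.zeros((n_features, 2))
        weights[0, 0] = -s / 2.0
        weights[0, 1] = s / 2.0
        return DeltaRuleLearner(
            n_features, params.learning_rate, attention, weights=weights
        )
    prototypes = np.zeros((2, n_features))
    prototypes[0, 0] = -s / 2.0
    prototypes[1, 0] = s / 2.0
    prototypes[:, -1] = 1.0  # matches the constant bias channel
    return PrototypeLearner(
        n_features,
        params.similarity_scale,
        attention,
        learning_rate=params.learning_rate,
        prototypes=prototypes,
    )


def run_subject(
    params: SubjectParams,
    slist: StimulusList,
    schedule: FeedbackSchedule,
    n_groups: int = 4,
) -> pd.DataFrame:
    """Simulate one subject's full session; returns one row per trial.

    Invalid trials (probability ``invalid_rate``, i.i.d.) are emitted as a
    missing response, a too-fast RT or a too-slow RT with equal
    probability; the learner itself still runs those trials, only the
    record is spoiled. Valid-trial RTs are log-normal clipped into the
    validity window.
    """
    rng = np.random.default_rng(params.seed)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    learner = _build_learner(params, n_groups, sign)
    lo, hi = RT_WINDOW_MS
    rows = []
    t = 0
    for block in slist.blocks:
        feedback = block.index in schedule.feedback_blocks
        for stim in block.stimuli:
            t += 1
            label = stim.category if feedback else None
            response, _ = step_trial(
                learner,
                stim,
                label,
                rng,
                temperature=params.temperature,
                lapse=params.lapse,
                n_groups=n_groups,
            )
            if rng.random() < params.invalid_rate:
                mode = int(rng.integers(3))
                if mode == 0:  # no key press
                    resp_out, rt = np.nan, np.nan
                elif mode == 1:  # anticipatory press
                    resp_out, rt = float(response), float(rng.uniform(60.0, lo - 10.0))
                else:  # timeout
                    resp_out, rt = float(response), float(rng.uniform(hi + 10.0, 3000.0))
            else:
                rt = float(
                    np.clip(
                        rng.lognormal(params.rt_location, params.rt_scale),
                        lo + 5.0,
                        hi - 5.0,
                    )
                )
                resp_out = float(response)
            valid = bool(not np.isnan(resp_out) and lo < rt < hi)
            rows.append(
                {
                    "subject_id": params.subject_id,
                    "condition": schedule.condition,
                    "list_id": slist.list_id,
                    "block": block.index,
                    "block_type": block.block_type,
                    "trial": t,
                    "morph": stim.morph,
                    "group": stim.group,
                    "category": stim.category,
                    "indicative": stim.indicative,
                    "feedback_given": feedback,
                    "response": resp_out,
                    "rt": rt,
                    "valid": valid,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_cohort(
    spec: PopulationSpec,
    condition: str,
    config: DesignConfig | None = None,
    lists: Sequence[StimulusList] | None = None,
) -> pd.DataFrame:
    """Simulate a full cohort; fully reproducible from ``spec.master_seed``.

    Builds the four stimulus lists (unless given), assigns each subject one
    list uniformly at random, and concatenates the per-subject records. The
    design and population streams are independent children of the master
    seed, so the same subjects see the same lists across reruns.
    """
    if config is None:
        config = DesignConfig()
    design_ss, pop_ss = np.random.SeedSequence(spec.master_seed).spawn(2)
    if lists is None:
        design_seed = int(np.random.default_rng(design_ss).integers(2**31))
        lists = build_stimulus_lists(replace(config, design_seed=design_seed))
    schedule = make_schedule(condition, config.n_blocks)
    rng = np.random.default_rng(pop_ss)
    frames = []
    for i in range(spec.n_subjects):
        params = sample_subject_params(spec, rng, subject_id=f"s{i:04d}")
        slist = lists[int(rng.integers(len(lists)))]
        frames.append(run_subject(params, slist, schedule, config.n_groups))
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_records(records: pd.DataFrame, path) -> None:
    """Write trial records as comma-separated text with a header row."""
    records.to_csv(path, index=False, float_format="%.17g")


def read_records(path) -> pd.DataFrame:
    """Read and validate a trial-record file.

    Raises :class:`ParseError` naming the missing column or the first
    offending row if the schema is violated.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    bad = df.index[df["response"].notna() & ~df["response"].isin([1.0, 2.0])]
    if len(bad):
        raise ParseError(f"invalid response value at row {int(bad[0])}")
    bad = df.index[~df["block"].astype(float).between(1, 10**6)]
    if len(bad):
        raise ParseError(f"invalid block number at row {int(bad[0])}")
    for col in ("indicative", "feedback_given", "valid"):
        df[col] = df[col].astype(bool)
    return df
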