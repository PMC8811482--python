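"""Behavioral analysis: scoring, exclusions, remapping, classification,
change directions and permutation tests.

The pipeline consumes trial-level records (see
:data:`morphcat.cohort.TRIAL_COLUMNS`) and proceeds:

1. **Scoring** — every missing or invalid response counts as incorrect.
2. **Exclusions** — subjects with repeated performance warnings (more than
   6 fast/slow/invalid responses within the trailing 12 trials, more than
   twice) or with an uninterrupted same-key or strictly alternating key run
   (length 12 under supervised training, 18 otherwise) are dropped.
3. **Remapping** — in the unsupervised condition subjects choose their own
   key assignment, so responses are re-mapped per subject to whichever of
   the two possible response-to-category mappings maximises accuracy on
   the unindicative items (which are correct under either representation
   and therefore provide the neutral reference).
4. **Classification** — a subject whose windowed accuracy (mean over the
   last four blocks by default) exceeds 60% on both item types is a
   *conformant* learner; above 60% on unindicative but below 40% on
   indicative items is *non-conformant* (consistent with salient-dimension
   responding); everything else is *other*. Threshold comparisons are
   strict, so values exactly at a threshold fall to *other*.
5. **Change directions and tests** — the sign of the accuracy change from
   the last supervised block (3) to the structurally identical late block
   (9), and one-sample sign-flip permutation tests of accuracies against
   chance and of changes against zero.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CriterionSpec",
    "CRITERIA_PRESETS",
    "PermutationResult",
    "ExclusionReport",
    "CohortSummary",
    "UndefinedMappingError",
    "score_responses",
    "apply_exclusions",
    "best_label_mapping",
    "apply_label_mapping",
    "remap_subjects",
    "block_item_accuracy",
    "classify_learner",
    "classify_all",
    "change_direction",
    "one_sample_permutation_test",
    "summarize_cohort",
    "robustness_sweep",
]

ITEM_TYPES = ("indicative", "unindicative")
CLASSES = ("conformant", "non_conformant", "other")
CHANGE_VALUES = ("improved", "worsened", "no_change")


class UndefinedMappingError(ValueError):
    """A subject has no valid unindicative trial, so no reference mapping exists."""


@dataclass(frozen=True)
class CriterionSpec:
    """One performance criterion over a window of blocks.

    Exactly one of ``indicative_min`` (conformant-style) and
    ``indicative_max`` (non-conformant-style) must be set.
    """

    name: str
    window_blocks: frozenset = frozenset({7, 8, 9, 10})
    unindicative_min: float = 0.6
    indicative_min: float | None = None
    indicative_max: float | None = None

    def __post_init__(self) -> None:
        if (self.indicative_min is None) == (self.indicative_max is None):
            raise ValueError(
                "exactly one of indicative_min / indicative_max must be set"
            )


def _pair(name: str, unind: float, ind_min: float, ind_max: float):
    return (
        CriterionSpec(f"{name}_conformant", unindicative_min=unind, indicative_min=ind_min),
        CriterionSpec(f"{name}_non_conformant", unindicative_min=unind, indicative_max=ind_max),
    )


#: Named (conformant, non_conformant) criterion pairs. ``default`` is the
#: 60/60 and 60/40 pair; the stricter pairs tighten both thresholds so the
#: classes are nested.
CRITERIA_PRESETS: dict[str, tuple[CriterionSpec, CriterionSpec]] = {
    "default": _pair("default", 0.6, 0.6, 0.4),
    "strict1": _pair("strict1", 0.7, 0.7, 0.3),
    "strict2": _pair("strict2", 0.8, 0.8, 0.2),
}


# ---------------------------------------------------------------------------
# scoring and exclusions
# ---------------------------------------------------------------------------

def score_responses(records: pd.DataFrame) -> pd.DataFrame:
    """Add a boolean ``correct`` column; invalid or missing responses are incorrect."""
    out = records.copy()
    out["correct"] = (
        out["valid"].astype(bool)
        & out["response"].notna()
        & (out["response"] == out["category"])
    )
    return out


def _warning_count(valid_seq: Sequence[bool], window: int = 12, threshold: int = 6) -> int:
    """Performance warnings: > ``threshold`` invalid trials within the trailing
    ``window``; the window restarts after each warning (one on-screen warning
    per burst)."""
    buf: deque[bool] = deque(maxlen=window)
    warnings = 0
    for v in valid_seq:
        buf.append(not v)
        if sum(buf) > threshold:
            warnings += 1
            buf.clear()
    return warnings


def _max_runs(responses: Sequence[float]) -> tuple[int, int]:
    """Longest same-key run and longest strict-alternation (ABAB) run.

    Missing responses break both runs. An alternation run needs at least
    two distinct keys; its length counts trials, so ``A B A`` has length 3.
    """
    max_same = same = 0
    max_alt = alt = 0
    prev = prev2 = None
    for r in responses:
        if r is None or (isinstance(r, float) and np.isnan(r)):
            same = alt = 0
            prev = prev2 = None
            continue
        same = same + 1 if r == prev else 1
        if prev is None:
            alt = 1
        elif r == prev:
            alt = 1
        elif prev2 is None or r == prev2:
            alt = alt + 1 if alt >= 2 else 2
        else:
            alt = 2
        max_same = max(max_same, same)
        max_alt = max(max_alt, alt)
        prev2, prev = prev, r
    return max_same, max_alt


@dataclass(frozen=True)
class ExclusionReport:
    excluded: dict  # subject_id -> list of reasons
    details: dict  # subject_id -> {"warnings": int, "max_same_run": int, ...}
    run_threshold: int

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_dict(self) -> dict:
        return {
            "run_threshold": self.run_threshold,
            "n_excluded": self.n_excluded,
            "excluded": {k: list(v) for k, v in self.excluded.items()},
            "details": self.details,
        }


def apply_exclusions(
    records: pd.DataFrame, condition: str | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop inattentive subjects; returns the kept records and a report.

    The same-key / alternation run threshold is 12 trials when feedback
    regulates responding throughout (supervised training) and 18 otherwise.
    """
    if condition is None:
        conds = records["condition"].unique() if len(records) else []
        condition = str(conds[0]) if len(conds) else "supervised"
    run_threshold = 12 if condition == "supervised" else 18
    excluded: dict[str, list[str]] = {}
    details: dict[str, dict] = {}
    for sid, sdf in records.sort_values("trial").groupby("subject_id", sort=True):
        warnings = _warning_count(sdf["valid"].tolist())
        max_same, max_alt = _max_runs(sdf["response"].tolist())
        details[str(sid)] = {
            "warnings": warnings,
            "max_same_run": max_same,
            "max_alternation_run": max_alt,
        }
        reasons = []
        if warnings > 2:
            reasons.append("performance warnings")
        if max_same >= run_threshold or max_alt >= run_threshold:
            reasons.append("response run")
        if reasons:
            excluded[str(sid)] = reasons
    kept = records[~records["subject_id"].astype(str).isin(excluded)].copy()
    return kept, ExclusionReport(excluded=excluded, details=details, run_threshold=run_threshold)


# ---------------------------------------------------------------------------
# response remapping
# ---------------------------------------------------------------------------

def best_label_mapping(subject_records: pd.DataFrame) -> str:
    """``"identity"`` or ``"swap"``: whichever mapping maximises accuracy on
    the subject's valid unindicative trials; exact tie -> identity."""
    u = subject_records[
        ~subject_records["indicative"].astype(bool)
        & subject_records["valid"].astype(bool)
        & subject_records["response"].notna()
    ]
    if len(u) == 0:
        raise UndefinedMappingError(
            "subject has no valid unindicative trial; mapping undefined"
        )
    n_identity = int((u["response"] == u["category"]).sum())
    n_swap = len(u) - n_identity
    return "swap" if n_swap > n_identity else "identity"


def apply_label_mapping(records: pd.DataFrame, mapping: str) -> pd.DataFrame:
    """Apply a response-to-category mapping (``identity`` leaves records alone)."""
    if mapping == "identity":
        return records.copy()
    if mapping != "swap":
        raise ValueError(f"unknown mapping {mapping!r}")
    out = records.copy()
    out["response"] = 3.0 - out["response"]
    return out


def remap_subjects(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-subject remapping to the unindicative-maximising reference.

    Used for unsupervised-condition data, where the key assignment was the
    subject's free choice; supervised and semi-supervised data keep the
    instructed mapping.
    """
    frames = []
    mappings: dict[str, str] = {}
    for sid, sdf in records.groupby("subject_id", sort=True):
        mapping = best_label_mapping(sdf)
        mappings[str(sid)] = mapping
        frames.append(apply_label_mapping(sdf, mapping))
    if not frames:
        return records.copy(), {}
    return pd.concat(frames, ignore_index=True), mappings


# ---------------------------------------------------------------------------
# accuracies, classification, change directions
# ---------------------------------------------------------------------------

def block_item_accuracy(scored: pd.DataFrame) -> pd.DataFrame:
    """Accuracy per (subject, block, item type); invalid trials stay in the
    denominator as incorrect."""
    if "correct" not in scored.columns:
        raise ValueError("records must be scored first (missing 'correct' column)")
    df = scored.assign(
        item_type=np.where(scored["indicative"].astype(bool), "indicative", "unindicative")
    )
    return (
        df.groupby(["subject_id", "block", "item_type"], as_index=False)
        .agg(accuracy=("correct", "mean"), n_trials=("correct", "size"))
    )


def _windowed_mean(acc: pd.DataFrame, blocks: frozenset, item_type: str) -> float:
    rows = acc[(acc["item_type"] == item_type) & (acc["block"].isin(blocks))]
    present = set(rows["block"])
    if present != set(blocks):
        raise ValueError(
            f"window blocks {sorted(set(blocks) - present)} missing for {item_type}"
        )
    return float(rows["accuracy"].mean())


def classify_learner(
    subject_acc: pd.DataFrame,
    conformant: CriterionSpec,
    non_conformant: CriterionSpec,
) -> str:
    """Classify one subject's accuracy table as conformant / non_conformant / other."""
    unind_c = _windowed_mean(subject_acc, conformant.window_blocks, "unindicative")
    ind_c = _windowed_mean(subject_acc, conformant.window_blocks, "indicative")
    if unind_c > conformant.unindicative_min and ind_c > conformant.indicative_min:
        return "conformant"
    unind_n = _windowed_mean(subject_acc, non_conformant.window_blocks, "unindicative")
    ind_n = _windowed_mean(subject_acc, non_conformant.window_blocks, "indicative")
    if unind_n > non_conformant.unindicative_min and ind_n < non_conformant.indicative_max:
        return "non_conformant"
    return "other"


def classify_all(
    acc: pd.DataFrame, conformant: CriterionSpec, non_conformant: CriterionSpec
) -> pd.Series:
    """Classification per subject over a cohort accuracy table."""
    out = {}
    for sid, sdf in acc.groupby("subject_id", sort=True):
        out[sid] = classify_learner(sdf, conformant, non_conformant)
    return pd.Series(out, name="learner_class", dtype=object)


def change_direction(
    subject_acc: pd.DataFrame,
    from_block: int = 3,
    to_block: int = 9,
    item_type: str = "indicative",
) -> str:
    """Sign of the accuracy change between two structurally identical blocks."""
    rows = subject_acc[subject_acc["item_type"] == item_type].set_index("block")["accuracy"]
    if from_block not in rows.index or to_block not in rows.index:
        raise ValueError(f"blocks {from_block} and {to_block} must both be present")
    delta = float(rows[to_block]) - float(rows[from_block])
    if delta > 0:
        return "improved"
    if delta < 0:
        return "worsened"
    return "no_change"


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    statistic: float  # mean deviation from the null value
    p_value: float
    n_permutations: int
    alternative: str
    exact: bool

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "alternative": self.alternative,
            "exact": self.exact,
        }


_TIE_TOL = 1e-12


def one_sample_permutation_test(
    values: Sequence[float],
    null_value: float = 0.5,
    alternative: str = "greater",
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
    exact_threshold: int = 12,
) -> PermutationResult:
    """One-sample sign-flip permutation test of ``mean(values)`` against
    ``null_value``.

    The null distribution is generated by randomly flipping the signs of
    the centred values. For ``len(values) <= exact_threshold`` all sign
    patterns are enumerated exactly; otherwise a Monte-Carlo sample of
    ``n_permutations`` patterns is drawn and the add-one convention
    ``p = (count + 1) / (n + 1)`` keeps p strictly positive.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    centred = x - null_value
    observed = float(centred.mean())
    n = x.size
    if n <= exact_threshold:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        stats = signs @ centred / n
        exact = True
        n_perm = stats.size
        if alternative == "greater":
            count = int(np.sum(stats >= observed - _TIE_TOL))
        elif alternative == "less":
            count = int(np.sum(stats <= observed + _TIE_TOL))
        else:
            count = int(np.sum(np.abs(stats) >= abs(observed) - _TIE_TOL))
        p = count / n_perm
    else:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        signs = gen.choice((-1.0, 1.0), size=(n_permutations, n))
        stats = signs @ centred / n
        exact = False
        n_perm = n_permutations
        if alternative == "greater":
            count = int(np.sum(stats >= observed - _TIE_TOL))
        elif alternative == "less":
            count = int(np.sum(stats <= observed + _TIE_TOL))
        else:
            count = int(np.sum(np.abs(stats) >= abs(observed) - _TIE_TOL))
        p = (count + 1) / (n_perm + 1)
    return PermutationResult(
        statistic=observed,
        p_value=float(min(p, 1.0)),
        n_permutations=int(n_perm),
        alternative=alternative,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

#: Directional alternatives for the baseline (pre-withdrawal block) tests,
#: matching the expectation each class embodies: conformant learners above
#: chance on both item types, non-conformant above chance on unindicative
#: but below on indicative items, the remainder tested two-sided.
BASELINE_ALTERNATIVES: Mapping[tuple[str, str], str] = {
    ("conformant", "indicative"): "greater",
    ("conformant", "unindicative"): "greater",
    ("non_conformant", "indicative"): "less",
    ("non_conformant", "unindicative"): "greater",
    ("other", "indicative"): "two_sided",
    ("other", "unindicative"): "two_sided",
}

CHANGE_ALTERNATIVES: Mapping[tuple[str, str], str] = {
    ("conformant", "indicative"): "greater",
    ("conformant", "unindicative"): "greater",
    ("non_conformant", "indicative"): "less",
    ("non_conformant", "unindicative"): "greater",
    ("other", "indicative"): "two_sided",
    ("other", "unindicative"): "two_sided",
}


@dataclass(frozen=True)
class CohortSummary:
    """Machine-readable summary of one criterion pair applied to a cohort."""

    criteria: tuple[str, str]
    n_subjects: int
    class_counts: dict
    class_fractions: dict
    change_fractions: dict  # class -> item_type -> {improved, worsened, no_change, n}
    mean_change: dict  # class -> item_type -> mean accuracy change
    baseline_tests: dict  # class -> item_type -> PermutationResult dict (or None)
    change_tests: dict
    learning_curves: dict  # class -> item_type -> {block: mean accuracy}
    from_block: int
    to_block: int

    def to_dict(self) -> dict:
        return {
            "criteria": list(self.criteria),
            "n_subjects": self.n_subjects,
            "class_counts": self.class_counts,
            "class_fractions": self.class_fractions,
            "change_fractions": self.change_fractions,
            "mean_change": self.mean_change,
            "baseline_tests": self.baseline_tests,
            "change_tests": self.change_tests,
            "learning_curves": self.learning_curves,
            "from_block": self.from_block,
            "to_block": self.to_block,
        }


def summarize_cohort(
    scored: pd.DataFrame,
    conformant: CriterionSpec | None = None,
    non_conformant: CriterionSpec | None = None,
    from_block: int = 3,
    to_block: int = 9,
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> CohortSummary:
    """Classify subjects, tabulate change directions and run the tests.

    ``scored`` must already have exclusions applied (and remapping, where
    it applies). An empty dataset yields a summary with zero counts.
    """
    if conformant is None or non_conformant is None:
        conformant, non_conformant = CRITERIA_PRESETS["default"]
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    if len(scored) == 0:
        zero = {c: 0 for c in CLASSES}
        empty = {c: {it: None for it in ITEM_TYPES} for c in CLASSES}
        return CohortSummary(
            criteria=(conformant.name, non_conformant.name),
            n_subjects=0,
            class_counts=zero,
            class_fractions={c: 0.0 for c in CLASSES},
            change_fractions={
                c: {it: {k: 0.0 for k in CHANGE_VALUES} | {"n": 0} for it in ITEM_TYPES}
                for c in CLASSES
            },
            mean_change=empty,
            baseline_tests=empty,
            change_tests=empty,
            learning_curves={c: {it: {} for it in ITEM_TYPES} for c in CLASSES},
            from_block=from_block,
            to_block=to_block,
        )

    acc = block_item_accuracy(scored)
    classes = classify_all(acc, conformant, non_conformant)
    n_subjects = len(classes)
    class_counts = {c: int((classes == c).sum()) for c in CLASSES}
    class_fractions = {c: class_counts[c] / n_subjects for c in CLASSES}

    change_fractions: dict = {}
    mean_change: dict = {}
    baseline_tests: dict = {}
    change_tests: dict = {}
    learning_curves: dict = {}
    for cls in CLASSES:
        members = classes.index[classes == cls]
        change_fractions[cls] = {}
        mean_change[cls] = {}
        baseline_tests[cls] = {}
        change_tests[cls] = {}
        learning_curves[cls] = {}
        cls_acc = acc[acc["subject_id"].isin(members)]
        for item in ITEM_TYPES:
            sub = cls_acc[cls_acc["item_type"] == item]
            curve = sub.groupby("block")["accuracy"].mean()
            learning_curves[cls][item] = {int(b): float(v) for b, v in curve.items()}
            if len(members) == 0:
                change_fractions[cls][item] = {k: 0.0 for k in CHANGE_VALUES} | {"n": 0}
                mean_change[cls][item] = None
                baseline_tests[cls][item] = None
                change_tests[cls][item] = None
                continue
            pivot = sub.pivot(index="subject_id", columns="block", values="accuracy")
            deltas = pivot[to_block] - pivot[from_block]
            directions = np.where(deltas > 0, "improved", np.where(deltas < 0, "worsened", "no_change"))
            n = len(deltas)
            change_fractions[cls][item] = {
                k: float(np.mean(directions == k)) for k in CHANGE_VALUES
            } | {"n": n}
            mean_change[cls][item] = float(deltas.mean())
            baseline_tests[cls][item] = one_sample_permutation_test(
                pivot[from_block].to_numpy(),
                null_value=0.5,
                alternative=BASELINE_ALTERNATIVES[(cls, item)],
                n_permutations=n_permutations,
                rng=gen,
            ).to_dict()
            change_tests[cls][item] = one_sample_permutation_test(
                deltas.to_numpy(),
                null_value=0.0,
                alternative=CHANGE_ALTERNATIVES[(cls, item)],
                n_permutations=n_permutations,
                rng=gen,
            ).to_dict()

    return CohortSummary(
        criteria=(conformant.name, non_conformant.name),
        n_subjects=n_subjects,
        class_counts=class_counts,
        class_fractions=class_fractions,
        change_fractions=change_fractions,
        mean_change=mean_change,
        baseline_tests=baseline_tests,
        change_tests=change_tests,
        learning_curves=learning_curves,
        from_block=from_block,
        to_block=to_block,
    )


def robustness_sweep(
    scored: pd.DataFrame,
    criteria_pairs: Sequence[tuple[CriterionSpec, CriterionSpec]] | None = None,
    **kwargs,
) -> list[dict]:
    """Re-run the cohort summary under several criterion pairs.

    For each pair, reports the summary plus the sign of the indicative-item
    divergence: mean indicative change of conformant minus non-conformant
    subjects (positive when the two classes diverge in the expected
    directions).
    """
    if criteria_pairs is None:
        criteria_pairs = list(CRITERIA_PRESETS.values())
    if len(criteria_pairs) == 0:
        raise ValueError("need at least one criterion pair")
    out = []
    for conf, nonc in criteria_pairs:
        summary = summarize_cohort(scored, conf, nonc, **kwargs)
        mc = summary.mean_change
        conf_ind = mc["conformant"]["indicative"]
        nonc_ind = mc["non_conformant"]["indicative"]
        if conf_ind is None or nonc_ind is None:
            divergence = None
            sign = 0
        else:
            divergence = conf_ind - nonc_ind
            sign = int(np.sign(divergence))
        out.append(
            {
                "name": conf.name.rsplit("_conformant", 1)[0],
                "summary": summary,
                "indicative_divergence": divergence,
                "indicative_divergence_sign": sign,
            }
        )
    return out
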