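"""Constrained stimulus-list generation for the morph/appendage category task.

The task presents artificial objects that vary along one *salient*,
continuous body-morph dimension and four *subtle*, discrete appendage
features. The appendages deterministically identify four stimulus groups;
pairs of groups form the two categories the learner must acquire, so the
morph dimension is task-irrelevant even though it dominates perception.

Each block covers a fixed grid of equally spaced morph values exactly once,
contains the same number of exemplars from every group, and a fixed number
of *indicative* items — items whose morph-implied category differs from
their true category, so that responses to them reveal which representation
(salient or subtle) the responder is using. All remaining items are
*unindicative*: either representation categorises them correctly.

Morph values are assigned to group slots with triangular (extremeness)
weights: extreme morphs preferentially become unindicative items of
same-side groups, near-boundary morphs preferentially become indicative
items of cross-assigned groups. Pooled over groups the morph distribution
in every block is exactly uniform (each grid point once), which leaves only
a small morph-category correlation carried by the indicative/unindicative
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InfeasibleDesignError",
    "DesignConfig",
    "Stimulus",
    "Block",
    "StimulusList",
    "ValidationReport",
    "make_morph_grid",
    "salient_implied_category",
    "compute_indicativeness",
    "indicative_group_counts",
    "sample_block",
    "build_stimulus_lists",
    "reverse_list",
    "validate_design",
    "lists_to_frame",
    "frame_to_lists",
    "write_lists",
    "read_lists",
]

LEFT = "left"
RIGHT = "right"
#: Which category the salient dimension implies on each side of the boundary.
DEFAULT_SIDE_MAP = {LEFT: 1, RIGHT: 2}

BLOCK_TYPES = ("A", "B")


class InfeasibleDesignError(ValueError):
    """The block constraints cannot be satisfied for the given configuration."""


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the constrained stimulus design.

    Defaults reproduce the standard session: 10 blocks of 16 trials, four
    groups with four appendages of three realisations each, 6 indicative and
    10 unindicative items per block, and a category boundary implied at the
    midpoint of the morph continuum.
    """

    n_blocks: int = 10
    trials_per_block: int = 16
    n_groups: int = 4
    n_appendages: int = 4
    realisations_per_appendage: int = 3
    indicative_per_block: int = 6
    per_group_per_block: int = 4
    group_to_category: Mapping[int, int] = field(
        default_factory=lambda: {1: 1, 2: 1, 3: 2, 4: 2}
    )
    salient_boundary: float = 0.5
    #: Exponent on the normalised distance-to-boundary used as assignment
    #: weight; 1.0 gives linear (triangular) weighting, larger values bias
    #: unindicative items more strongly toward the extremes.
    triangular_peak_weight: float = 1.0
    design_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 2:
            raise ValueError("need at least 1 block and 2 trials per block")
        if self.per_group_per_block * self.n_groups != self.trials_per_block:
            raise ValueError(
                "per_group_per_block * n_groups must equal trials_per_block"
            )
        if not 0 <= self.indicative_per_block < self.trials_per_block:
            raise ValueError("indicative_per_block must be in [0, trials_per_block)")
        if set(self.group_to_category) != set(range(1, self.n_groups + 1)):
            raise ValueError("group_to_category must map exactly groups 1..n_groups")
        cats = set(self.group_to_category.values())
        if cats != {1, 2}:
            raise ValueError("group_to_category must use both categories 1 and 2")
        if not 0.0 < self.salient_boundary < 1.0:
            raise ValueError("salient_boundary must lie strictly inside (0, 1)")
        if self.triangular_peak_weight <= 0:
            raise ValueError("triangular_peak_weight must be positive")


@dataclass(frozen=True)
class Stimulus:
    """A single exemplar: morph position, group and appendage realisations."""

    morph: float
    group: int
    appendages: tuple[int, ...]
    category: int
    indicative: bool


@dataclass(frozen=True)
class Block:
    index: int
    block_type: str  # alternation parity, "A" or "B"
    stimuli: tuple[Stimulus, ...]


@dataclass(frozen=True)
class StimulusList:
    list_id: str
    blocks: tuple[Block, ...]
    provenance: str  # "sampled" or "reversed"

    @property
    def trials(self) -> tuple[Stimulus, ...]:
        return tuple(s for b in self.blocks for s in b.stimuli)


def make_morph_grid(n_points: int) -> np.ndarray:
    """Equally spaced morph values covering [0, 1] inclusive.

    Grid point i equals ``i / (n_points - 1)``, so the extremes of the
    continuum are always represented.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    return np.linspace(0.0, 1.0, n_points)


def salient_implied_category(
    morph: float,
    boundary: float = 0.5,
    side_map: Mapping[str, int] = DEFAULT_SIDE_MAP,
) -> int:
    """Category a pure salient-dimension responder would choose.

    A morph exactly on the boundary falls to the right half by convention
    (unreachable with the default 16-point grid and boundary 0.5).
    """
    if not 0.0 <= morph <= 1.0:
        raise ValueError("morph must lie in [0, 1]")
    return side_map[LEFT] if morph < boundary else side_map[RIGHT]


def compute_indicativeness(stimulus: Stimulus, config: DesignConfig) -> bool:
    """True iff the morph-implied category disagrees with the true category."""
    implied = salient_implied_category(stimulus.morph, config.salient_boundary)
    return implied != stimulus.category


def indicative_group_counts(config: DesignConfig, block_type: str) -> dict[int, int]:
    """Number of indicative items each group contributes in a block.

    The total is spread as evenly as possible over groups; the remainder is
    given to the odd-numbered groups on type-A blocks and to the
    even-numbered groups on type-B blocks, so consecutive blocks alternate
    the imbalance. With the defaults (6 indicative, 4 groups) a type-A block
    has 2 indicative items from groups 1 and 3 and 1 from groups 2 and 4.
    """
    if block_type not in BLOCK_TYPES:
        raise ValueError(f"unknown block type {block_type!r}")
    base, rem = divmod(config.indicative_per_block, config.n_groups)
    groups = list(range(1, config.n_groups + 1))
    odd, even = groups[0::2], groups[1::2]
    order = odd + even if block_type == "A" else even + odd
    counts = {g: base for g in groups}
    for g in order[:rem]:
        counts[g] += 1
    return counts


def _weighted_sample_without_replacement(
    rng: np.random.Generator, n_items: int, weights: np.ndarray, k: int
) -> list[int]:
    """Indices of k items drawn sequentially with probability ∝ weight."""
    avail = list(range(n_items))
    w = np.asarray(weights, dtype=float).copy()
    chosen: list[int] = []
    for _ in range(k):
        p = w / w.sum()
        j = rng.choice(len(avail), p=p)
        chosen.append(avail.pop(j))
        w = np.delete(w, j)
    return chosen


def sample_block(
    index: int,
    block_type: str,
    config: DesignConfig,
    rng: np.random.Generator,
) -> Block:
    """Sample one block satisfying all design constraints.

    Within each side of the boundary, the morph points that become
    unindicative items are drawn with weight proportional to their
    (normalised) distance from the boundary raised to
    ``triangular_peak_weight``; the remaining points of that side become
    indicative items of the cross-assigned groups.
    """
    grid = make_morph_grid(config.trials_per_block)
    b = config.salient_boundary
    kind = indicative_group_counts(config, block_type)

    side_points = {
        LEFT: [float(m) for m in grid if m < b],
        RIGHT: [float(m) for m in grid if m >= b],
    }
    # Build the slot lists ((group, indicative) pairs) each side must fill.
    need: dict[str, list[tuple[int, bool]]] = {LEFT: [], RIGHT: []}
    for g in range(1, config.n_groups + 1):
        cat = config.group_to_category[g]
        n_ind = kind[g]
        n_unind = config.per_group_per_block - n_ind
        if n_unind < 0:
            raise InfeasibleDesignError(
                f"group {g} would need {n_ind} indicative items but only "
                f"{config.per_group_per_block} slots exist"
            )
        same = LEFT if DEFAULT_SIDE_MAP[LEFT] == cat else RIGHT
        other = RIGHT if same == LEFT else LEFT
        need[same] += [(g, False)] * n_unind  # morph agrees -> unindicative
        need[other] += [(g, True)] * n_ind  # morph disagrees -> indicative
    for side in (LEFT, RIGHT):
        if len(need[side]) != len(side_points[side]):
            raise InfeasibleDesignError(
                f"{side} side requires {len(need[side])} grid points but the "
                f"grid provides {len(side_points[side])}"
            )

    stimuli: list[Stimulus] = []
    for side in (LEFT, RIGHT):
        pts = np.asarray(side_points[side])
        slots = need[side]
        unind_slots = [s for s in slots if not s[1]]
        ind_slots = [s for s in slots if s[1]]
        d = np.abs(pts - b)
        dmax = d.max() if d.size and d.max() > 0 else 1.0
        w = (d / dmax) ** config.triangular_peak_weight + 1e-9
        unind_idx = _weighted_sample_without_replacement(
            rng, len(pts), w, len(unind_slots)
        )
        ind_idx = [i for i in range(len(pts)) if i not in set(unind_idx)]
        for idx_pool, slot_pool in ((unind_idx, unind_slots), (ind_idx, ind_slots)):
            order = rng.permutation(len(idx_pool))
            for slot, j in zip(slot_pool, order):
                g, ind_flag = slot
                morph = float(pts[idx_pool[j]])
                appendages = tuple(
                    int(r)
                    for r in rng.integers(
                        1,
                        config.realisations_per_appendage + 1,
                        size=config.n_appendages,
                    )
                )
                stim = Stimulus(
                    morph=morph,
                    group=g,
                    appendages=appendages,
                    category=config.group_to_category[g],
                    indicative=ind_flag,
                )
                assert compute_indicativeness(stim, config) == ind_flag
                stimuli.append(stim)

    order = rng.permutation(len(stimuli))
    return Block(index=index, block_type=block_type, stimuli=tuple(stimuli[i] for i in order))


def reverse_list(source: StimulusList, list_id: str) -> StimulusList:
    """List whose trial sequence is the source's in exact reverse order.

    Equivalent to reversing the block order and the trial order within each
    block; block types travel with their source blocks, so alternation is
    preserved.
    """
    n = len(source.blocks)
    blocks = tuple(
        Block(
            index=i + 1,
            block_type=source.blocks[n - 1 - i].block_type,
            stimuli=tuple(reversed(source.blocks[n - 1 - i].stimuli)),
        )
        for i in range(n)
    )
    return StimulusList(list_id=list_id, blocks=blocks, provenance="reversed")


def build_stimulus_lists(
    config: DesignConfig, rng: np.random.Generator | None = None
) -> list[StimulusList]:
    """Build the four session lists: two sampled, two reversed copies.

    List L1 starts the block-type alternation with type A, list L2 with
    type B; L1R and L2R are their exact trial-order reversals.
    """
    if rng is None:
        rng = np.random.default_rng(config.design_seed)
    lists: list[StimulusList] = []
    for list_id, start in (("L1", "A"), ("L2", "B")):
        other = "B" if start == "A" else "A"
        blocks = tuple(
            sample_block(i, start if i % 2 == 1 else other, config, rng)
            for i in range(1, config.n_blocks + 1)
        )
        lists.append(StimulusList(list_id=list_id, blocks=blocks, provenance="sampled"))
    lists.append(reverse_list(lists[0], "L1R"))
    lists.append(reverse_list(lists[1], "L2R"))
    return lists


@dataclass(frozen=True)
class ValidationReport:
    """Machine-readable outcome of the design checks for one list."""

    list_id: str
    checks: tuple[dict, ...]

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "list_id": self.list_id,
            "passed": self.passed,
            "checks": [dict(c) for c in self.checks],
        }


def validate_design(slist: StimulusList, config: DesignConfig) -> ValidationReport:
    """Run every structural check on a list; failures are reported, not raised.

    Exact checks: per-block group counts, indicative counts, morph-grid
    coverage, block-type alternation, per-group indicative alternation
    pattern, category/indicativeness consistency, appendage ranges, and the
    whole-list per-group boundary-side counts implied by the alternation.
    Approximate check: per-group mean extremeness (|morph - boundary|)
    should be similar across groups.
    """
    checks: list[dict] = []
    grid = make_morph_grid(config.trials_per_block)
    b = config.salient_boundary

    def add(name: str, passed: bool, **details) -> None:
        checks.append({"name": name, "passed": bool(passed), **details})

    # --- per-block exact structure ---
    group_ok = ind_ok = grid_ok = pattern_ok = consist_ok = app_ok = True
    group_counts_seen = []
    for block in slist.blocks:
        counts = {g: 0 for g in range(1, config.n_groups + 1)}
        ind_counts = {g: 0 for g in range(1, config.n_groups + 1)}
        n_ind = 0
        morphs = sorted(s.morph for s in block.stimuli)
        for s in block.stimuli:
            counts[s.group] += 1
            if s.indicative:
                n_ind += 1
                ind_counts[s.group] += 1
            if s.category != config.group_to_category[s.group]:
                consist_ok = False
            if compute_indicativeness(s, config) != s.indicative:
                consist_ok = False
            if not all(
                1 <= r <= config.realisations_per_appendage for r in s.appendages
            ) or len(s.appendages) != config.n_appendages:
                app_ok = False
        if any(c != config.per_group_per_block for c in counts.values()):
            group_ok = False
        if n_ind != config.indicative_per_block:
            ind_ok = False
        if len(morphs) != len(grid) or not np.allclose(morphs, grid, atol=1e-12):
            grid_ok = False
        if ind_counts != indicative_group_counts(config, block.block_type):
            pattern_ok = False
        group_counts_seen.append(counts)
    add("block_group_counts", group_ok, expected=config.per_group_per_block)
    add("block_indicative_count", ind_ok, expected=config.indicative_per_block)
    add("block_morph_grid_coverage", grid_ok, n_points=config.trials_per_block)
    add("indicative_alternation_pattern", pattern_ok)
    add("category_consistency", consist_ok)
    add("appendage_realisation_range", app_ok)

    types = [blk.block_type for blk in slist.blocks]
    add(
        "block_type_alternation",
        all(a != bb for a, bb in zip(types, types[1:])),
        types="".join(types),
    )

    # --- whole-list per-group side counts (exact, implied by alternation) ---
    expected_side = {g: {LEFT: 0, RIGHT: 0} for g in range(1, config.n_groups + 1)}
    for block in slist.blocks:
        kind = indicative_group_counts(config, block.block_type)
        for g in range(1, config.n_groups + 1):
            cat = config.group_to_category[g]
            same = LEFT if DEFAULT_SIDE_MAP[LEFT] == cat else RIGHT
            other = RIGHT if same == LEFT else LEFT
            expected_side[g][same] += config.per_group_per_block - kind[g]
            expected_side[g][other] += kind[g]
    actual_side = {g: {LEFT: 0, RIGHT: 0} for g in range(1, config.n_groups + 1)}
    for s in slist.trials:
        actual_side[s.group][LEFT if s.morph < b else RIGHT] += 1
    add(
        "per_group_side_counts",
        actual_side == expected_side,
        expected=expected_side,
        actual=actual_side,
    )

    # --- approximate per-group morph balance ---
    ext = {}
    for g in range(1, config.n_groups + 1):
        vals = [abs(s.morph - b) for s in slist.trials if s.group == g]
        ext[g] = float(np.mean(vals)) if vals else float("nan")
    spread = max(ext.values()) - min(ext.values()) if ext else 0.0
    add(
        "per_group_extremeness_balance",
        spread <= 0.1,
        spread=spread,
        per_group_mean_extremeness=ext,
        tolerance=0.1,
    )
    per_group_mean = {
        g: float(np.mean([s.morph for s in slist.trials if s.group == g]))
        for g in range(1, config.n_groups + 1)
    }
    add("per_group_mean_morph_reported", True, per_group_mean_morph=per_group_mean)

    return ValidationReport(list_id=slist.list_id, checks=tuple(checks))


# ---------------------------------------------------------------------------
# delimited-text interface
# ---------------------------------------------------------------------------

def lists_to_frame(lists: Sequence[StimulusList], config: DesignConfig) -> pd.DataFrame:
    rows = []
    for sl in lists:
        for block in sl.blocks:
            for t, s in enumerate(block.stimuli, start=1):
                row = {
                    "list_id": sl.list_id,
                    "block": block.index,
                    "block_type": block.block_type,
                    "trial": t,
                    "morph": s.morph,
                    "group": s.group,
                }
                for a, r in enumerate(s.appendages, start=1):
                    row[f"appendage_{a}"] = r
                row["category"] = s.category
                row["indicative"] = s.indicative
                rows.append(row)
    return pd.DataFrame(rows)


def frame_to_lists(frame: pd.DataFrame, config: DesignConfig) -> list[StimulusList]:
    app_cols = [f"appendage_{a}" for a in range(1, config.n_appendages + 1)]
    lists = []
    for list_id, lf in frame.groupby("list_id", sort=False):
        blocks = []
        for block_idx, bf in lf.groupby("block", sort=True):
            bf = bf.sort_values("trial")
            stimuli = tuple(
                Stimulus(
                    morph=float(r.morph),
                    group=int(r.group),
                    appendages=tuple(int(getattr(r, c)) for c in app_cols),
                    category=int(r.category),
                    indicative=bool(r.indicative),
                )
                for r in bf.itertuples()
            )
            blocks.append(
                Block(
                    index=int(block_idx),
                    block_type=str(bf.block_type.iloc[0]),
                    stimuli=stimuli,
                )
            )
        provenance = "reversed" if str(list_id).endswith("R") else "sampled"
        lists.append(
            StimulusList(list_id=str(list_id), blocks=tuple(blocks), provenance=provenance)
        )
    return lists


def write_lists(lists: Sequence[StimulusList], config: DesignConfig, path) -> None:
    # %.17g keeps the morph grid values exact across a write/read cycle
    lists_to_frame(lists, config).to_csv(path, index=False, float_format="%.17g")


def read_lists(path, config: DesignConfig) -> list[StimulusList]:
    return frame_to_lists(pd.read_csv(path, float_precision="round_trip"), config)
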