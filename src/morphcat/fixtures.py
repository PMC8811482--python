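"""Hand-authored subject fixtures with documented expected outcomes.

Each fixture is a full 160-trial record for one synthetic responder built
on a deterministic stimulus list. They exercise the analysis pipeline at
its decision points: classification, response remapping, and both
exclusion rules.

====================  =========================================================
fixture               expected outcome
====================  =========================================================
perfect_conformant    kept; class ``conformant``; improved on both item types
                      from block 3 to block 9 (errors only in blocks 1-4)
salient_attender      kept; responds with the morph-implied category on every
                      trial; mapping ``identity``; class ``non_conformant``;
                      indicative accuracy 0 at blocks 3 and 9 (``no_change``)
label_swapped         kept; responds with the swapped true category; mapping
                      ``swap``; conformant after remapping
same_key_presser      excluded (``response run``): one key for all 160 trials
all_invalid           excluded (``performance warnings``): never a valid
                      response; accuracy 0 in every block; no reference
                      mapping exists (:class:`UndefinedMappingError`)
====================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import TRIAL_COLUMNS, make_schedule
from .design import DesignConfig, StimulusList, build_stimulus_lists, salient_implied_category

__all__ = ["Fixture", "make_fixtures", "FIXTURE_DESIGN_SEED"]

FIXTURE_DESIGN_SEED = 20210404


@dataclass(frozen=True)
class Fixture:
    name: str
    records: pd.DataFrame
    expected: dict


def _records(
    subject_id: str,
    condition: str,
    slist: StimulusList,
    responses: list[float],
    rts: list[float],
) -> pd.DataFrame:
    schedule = make_schedule(condition)
    rows = []
    t = 0
    for block in slist.blocks:
        feedback = block.index in schedule.feedback_blocks
        for stim in block.stimuli:
            resp, rt = responses[t], rts[t]
            t += 1
            valid = bool(not np.isnan(resp) and 300.0 < rt < 1500.0)
            rows.append(
                {
                    "subject_id": subject_id,
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
                    "response": resp,
                    "rt": rt,
                    "valid": valid,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def make_fixtures(config: DesignConfig | None = None) -> dict[str, Fixture]:
    """Build the five documented fixtures on a fixed design seed."""
    if config is None:
        config = DesignConfig(design_seed=FIXTURE_DESIGN_SEED)
    slist = build_stimulus_lists(config)[0]
    trials = slist.trials
    n = len(trials)
    rts_ok = [700.0 + (i % 7) * 50.0 for i in range(n)]  # varied, all valid

    fixtures: dict[str, Fixture] = {}

    # --- perfect conformant: errors only early, perfect from block 5 on ---
    responses: list[float] = []
    for block in slist.blocks:
        ind_err = unind_err = 0
        for stim in block.stimuli:
            wrong = float(3 - stim.category)
            if block.index <= 4 and stim.indicative and ind_err < 2:
                ind_err += 1
                responses.append(wrong)
            elif block.index <= 4 and not stim.indicative and unind_err < 3:
                unind_err += 1
                responses.append(wrong)
            else:
                responses.append(float(stim.category))
    fixtures["perfect_conformant"] = Fixture(
        name="perfect_conformant",
        records=_records("fx_conformant", "semi_supervised", slist, responses, rts_ok),
        expected={
            "excluded": False,
            "class": "conformant",
            "mapping": "identity",
            "change_indicative": "improved",
            "change_unindicative": "improved",
            "block3_indicative_accuracy": 4 / 6,
            "block3_unindicative_accuracy": 7 / 10,
        },
    )

    # --- pure salient attender ---
    responses = [
        float(salient_implied_category(s.morph, config.salient_boundary)) for s in trials
    ]
    fixtures["salient_attender"] = Fixture(
        name="salient_attender",
        records=_records("fx_salient", "unsupervised", slist, responses, rts_ok),
        expected={
            "excluded": False,
            "class": "non_conformant",
            "mapping": "identity",
            "change_indicative": "no_change",
            "unindicative_accuracy": 1.0,
            "indicative_accuracy": 0.0,
        },
    )

    # --- label-swapped responder ---
    responses = [float(3 - s.category) for s in trials]
    fixtures["label_swapped"] = Fixture(
        name="label_swapped",
        records=_records("fx_swapped", "unsupervised", slist, responses, rts_ok),
        expected={
            "excluded": False,
            "mapping": "swap",
            "class_after_remap": "conformant",
        },
    )

    # --- disengaged same-key presser ---
    responses = [1.0] * n
    fixtures["same_key_presser"] = Fixture(
        name="same_key_presser",
        records=_records("fx_samekey", "semi_supervised", slist, responses, rts_ok),
        expected={"excluded": True, "reasons": ["response run"]},
    )

    # --- all-invalid responder ---
    responses = [float("nan")] * n
    rts_nan = [float("nan")] * n
    fixtures["all_invalid"] = Fixture(
        name="all_invalid",
        records=_records("fx_invalid", "semi_supervised", slist, responses, rts_nan),
        expected={
            "excluded": True,
            "reasons": ["performance warnings"],
            "accuracy_everywhere": 0.0,
            "mapping": "undefined",
        },
    )
    return fixtures
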