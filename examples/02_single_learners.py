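"""Simulate one fast and one slow attention switcher under full supervision.

The fast switcher reallocates attention to the subtle group features within
the first blocks and climbs on both item types; the slow switcher keeps
responding by the salient morph dimension for a while, producing the
characteristic U-shaped curve on indicative items.
"""

import numpy as np

import morphcat as mc
from morphcat.cohort import make_schedule, run_subject

config = mc.DesignConfig(design_seed=7)
slist = mc.build_stimulus_lists(config)[0]
schedule = make_schedule("supervised")


def simulate(switch_rate, seed):
    params = mc.SubjectParams(
        subject_id=f"sw{switch_rate}", model_kind="delta_rule",
        learning_rate=0.25, switch_rate=switch_rate, alpha_subtle_init=0.05,
        salient_prior=1.0, similarity_scale=6.0, temperature=0.6, lapse=0.02,
        invalid_rate=0.0, rt_location=float(np.log(650)), rt_scale=0.2, seed=seed,
    )
    records = run_subject(params, slist, schedule)
    acc = mc.block_item_accuracy(mc.score_responses(records))
    return acc.pivot(index="block", columns="item_type", values="accuracy")


for name, rate in (("fast switcher (rate 0.6)", 0.6), ("slow switcher (rate 0.08)", 0.08)):
    curves = simulate(rate, seed=12)
    print(f"\n{name}, supervised, accuracy per block:")
    print("  block:        " + " ".join(f"{b:5d}" for b in curves.index))
    print("  indicative:   " + " ".join(f"{v:5.2f}" for v in curves["indicative"]))
    print("  unindicative: " + " ".join(f"{v:5.2f}" for v in curves["unindicative"]))

print(
    "\nThe indicative rows tell the story: the fast switcher is above 0.6 by "
    "block 3, while the slow switcher dips below 0.5 (salient-dimension "
    "responding) before supervised errors accumulate enough to switch "
    "attention and recover."
)
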