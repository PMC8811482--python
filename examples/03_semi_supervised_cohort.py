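"""Simulate a semi-supervised cohort and run the full analysis pipeline.

Feedback is withdrawn after block 3. Subjects classified conformant at the
end of the session mostly improve on indicative items over the unsupervised
phase, while non-conformant subjects mostly worsen — self-training amplifies
whatever representation each learner held at withdrawal.
"""

import morphcat as mc

spec = mc.PopulationSpec(n_subjects=100, master_seed=11)
records = mc.run_cohort(spec, "semi_supervised")
print(f"simulated {spec.n_subjects} subjects -> {len(records)} trial records")

scored = mc.score_responses(records)
kept, exclusions = mc.apply_exclusions(scored, "semi_supervised")
print(f"excluded {exclusions.n_excluded} subjects "
      f"(inattentive response patterns), kept "
      f"{kept['subject_id'].nunique()}")

summary = mc.summarize_cohort(kept, n_permutations=2000, rng=0)
print(f"\nlearner classes (60/60 and 60/40 criteria over blocks 7-10):")
for cls, n in summary.class_counts.items():
    print(f"  {cls:15s} {n:3d}  ({100 * summary.class_fractions[cls]:.0f}%)")

print("\nchange direction from block 3 to block 9 (percent of class):")
for cls in ("conformant", "non_conformant"):
    for item in ("indicative", "unindicative"):
        cell = summary.change_fractions[cls][item]
        test = summary.change_tests[cls][item]
        print(f"  {cls:15s} {item:13s} improved {100*cell['improved']:4.0f}%  "
              f"worsened {100*cell['worsened']:4.0f}%  no change "
              f"{100*cell['no_change']:4.0f}%  (p = {test['p_value']:.3g}, "
              f"{test['alternative']})")

print(
    "\nReading: both classes improve on unindicative items (correct under "
    "either representation), but the classes diverge on indicative items — "
    "the signature of unsupervised trials helping aligned learners and "
    "hurting misaligned ones."
)
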