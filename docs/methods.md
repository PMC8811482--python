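# Methods

`morphcat` simulates and analyses a semi-supervised category-learning task
in which unsupervised trials can either help or hurt a learner depending on
whether their internal representation is aligned with the task at the
moment feedback is withdrawn. This note documents the task model, the
learner models, the simulated population, the analysis pipeline, and the
numerical and design choices that were genuinely open.

## Task structure

Stimuli are abstract feature vectors, not images. Each stimulus has

* a **morph** value on a continuous body-shape dimension in [0, 1] —
  perceptually salient but task-irrelevant;
* a **group** in {1..4}, identified deterministically by four discrete
  appendage features (each with three interchangeable realisations, drawn
  uniformly i.i.d.; the realisation ids are opaque and carry no category
  information beyond group identity);
* a **category** in {1, 2}, determined by the group (default: groups 1–2 →
  category 1, groups 3–4 → category 2; configurable).

A morph value *implies* a category through the salient dimension: values
left of the boundary (default 0.5) imply category 1, the rest category 2; a
morph exactly on the boundary falls to the right half by convention (with
the default 16-point grid and boundary 0.5 no grid point hits the
boundary, so the convention is unreachable by default). A stimulus is
**indicative** when the implied category disagrees with the true one —
responses to such items reveal which representation the responder uses —
and **unindicative** otherwise.

### Block sampling

Each block covers the `trials_per_block` (16) equally spaced morph values,
endpoints inclusive (`i/(n-1)`, so the extremes of the continuum always
appear), each exactly once; contains `per_group_per_block` (4) exemplars of
every group; and exactly `indicative_per_block` (6) indicative items. The
indicative quota is spread over groups as evenly as possible, with the
remainder alternating between odd- and even-numbered groups on consecutive
blocks (type A: 2 indicative from groups 1 and 3, 1 from groups 2 and 4;
type B swapped), so blocks 3 and 9 always share the same item structure —
the precondition of the change-direction analysis.

Within each side of the boundary, the grid points that become unindicative
items are drawn without replacement with weight proportional to their
normalised distance from the boundary raised to `triangular_peak_weight`
(default 1.0, i.e. linear/triangular weighting); the remaining points of
the side become indicative items of the cross-assigned groups. Extreme
morphs are therefore mostly unindicative and near-boundary morphs mostly
indicative, while the pooled per-block morph distribution stays exactly
uniform. Because the indicative/unindicative totals per group are
unbalanced by design (15 vs 25 over ten blocks), each group's marginal
morph distribution is deliberately *not* uniform — that is the small
morph–category correlation that makes salient-dimension responding
correct on the majority of trials. The validator checks the per-group
boundary-side counts exactly (they follow from the alternation pattern)
and the per-group mean extremeness approximately (spread ≤ 0.1).

Four lists are built per design seed: two sampled (starting the block-type
alternation with A and B respectively) and two exact trial-order
reversals. Reversal is an involution; block types travel with their source
blocks.

### Infeasibility

The per-side demand implied by the group/indicative quotas must match the
number of grid points on each side of the boundary; if not (e.g. boundary
0.2 with the default quotas), an `InfeasibleDesignError` is raised.

## Learner models

Both learners share a feature encoding, an attention mechanism and the
self-training rule; they differ only in how categories are represented.
The exact functional forms used in the original modelling work are not
published in the main text, so the package commits to the simplest
concretisations that satisfy every stated mechanism; they are isolated
behind `morphcat.learners` and parameterised.

**Encoding.** A stimulus becomes
`[α_sal · (2·morph − 1),  α_sub · onehot(group),  1]` —
a signed morph coordinate, group channels standing in for the
(deterministically group-diagnostic) appendages, and a constant bias
channel. `α_sal + α_sub = 1` is a single complementary attention pair: a
learner attending the salient dimension cannot see the group structure and
vice versa.

**Delta-rule learner.** A multinomial logistic unit: `p = softmax(Wᵀf)`,
updated by the gradient step `W += η · f ⊗ (onehot(target) − p)`. With
bounded features and η ≤ 1 the weights stay finite; a single self-training
step can never decrease the probability of its own target (gradient
ascent on a concave per-trial objective).

**Prototype learner.** One attention-weighted running average per
category; `p = softmax(−c · ‖f − prototype_k‖)` with similarity scale `c`.
Updates move the target prototype toward the observation by a fixed step
(`learning_rate`, used in simulation) or by `1/count` (exact running-mean
mode, used for oracle tests).

**Attention switching.** Supervised prediction errors (`1 − p(true)`)
accumulate in `E`; attention is placed at
`α_sub = σ(logit(α_sub,0) + switch_rate · E)`, a logistic in the
accumulated error anchored at the initial value. It is monotone
non-decreasing, saturates at 1, and — crucially — moves **only under
feedback**: representational correction requires supervision. The switch
is gradual; there are no discrete switch events, so the accumulator never
resets.

**Self-training.** Without feedback the update target is the
pseudo-label: the currently most probable category (exact ties go to
category 1, a deterministic convention that also fixes the behaviour of a
freshly initialised learner). The overt response is sampled separately
from the belief sharpened by a softmax temperature, with a lapse
probability of a uniform key press; learning never uses the sampled
response.

**Salient prior.** Each simulated subject starts with a salient-dimension
association of magnitude `salient_prior` and random sign (delta rule:
±prior/2 on the morph weights; prototype: prototypes offset by ±prior/2
along the morph coordinate). The random sign emulates the arbitrary
category-to-key assignment a learner adopts before any feedback: feedback
resolves it within the first blocks, while in the unsupervised condition
it persists and is handled by response remapping downstream.

## Simulated population

`PopulationSpec` mixes three components: **fast** switchers (switch rate
log-uniform 0.3–1.0), **slow** switchers (log-uniform 0.05–0.15) and
**non-learners** (near-zero switch and learning rates, high temperature
and lapse). `fraction_fast` defaults to 0.53 — the observed share of fast
learners among those who learned the task under full supervision — and
`fraction_nonlearner` to 0.25; the real share of non-learning participants
is population-dependent (it differed strongly between testing waves), so
this weight is configurable rather than calibrated.

Shared parameter ranges (uniform unless noted): learning rate 0.15–0.3,
softmax temperature 0.5–0.8, lapse 0.01–0.06, initial subtle attention
0.02–0.08, salient prior 0.5–1.5, prototype similarity scale 4–8, invalid
rate 0–0.05, log-normal RT location ln 500–ln 800 (ms) and shape
0.15–0.3. These values were fixed once, by simulation during development,
to the regime the task was engineered to produce: gradual learning with
fast switchers above 60 % on both item types by block 3, slow switchers
showing a below-chance dip on indicative items with late recovery, and
appreciable distance from ceiling at block 3 (the brief stimulus
presentation in the real task served exactly this purpose). They are
population parameters, not fitted quantities; no model is ever fit to
human data.

Response times are purely phenomenological — log-normal, independent of
model state, clipped into the 300–1500 ms validity window on valid trials
— because the analysis operates on accuracy only; RTs exist to exercise
the validity and exclusion logic. Invalid trials are i.i.d. per trial
(missing key, anticipatory or timeout RT, equal probability); the learner
still runs those trials, only the record is spoiled.

What the generator deliberately does **not** emulate: perceptual
similarity between appendage realisations, motivational drift or
disengagement dynamics within a session (the disengaged same-key fixture
covers the exclusion rule instead), population drift between testing
waves, and the appended supervised blocks some semi-supervised
participants received (those data were not analysed).

## Analysis pipeline

1. **Scoring.** `correct = valid ∧ (response = category)`; every missing
   or invalid response counts as incorrect, including in accuracy
   denominators.
2. **Exclusions.** A performance warning fires when more than 6
   fast/slow/invalid responses fall within the trailing 12 trials; the
   window restarts after each warning (one on-screen warning per burst —
   pure rising-edge counting would let a subject who is always invalid
   collect a single warning and evade the rule). Subjects with more than
   two warnings are excluded, as are subjects with an uninterrupted
   same-key or strict-alternation (ABAB; any repeat, break or missing
   response resets the counter) run of ≥ 12 trials under supervised
   training or ≥ 18 otherwise.
3. **Remapping** (unsupervised condition only, where the key assignment
   was the subject's free choice; configurable). Each subject's responses
   are mapped by whichever of the two response-to-category mappings
   maximises session-wide accuracy on their valid unindicative trials;
   exact ties keep the identity. The maximisation guarantees ≥ 50 %
   post-remap accuracy **on valid unindicative trials** — not on the
   all-trials accuracy that counts invalid responses as errors, which a
   sufficiently invalid subject can never bring to 0.5 under any mapping.
   A subject with no valid unindicative trial has no defined mapping and
   raises an error.
4. **Classification.** Windowed means over the last four blocks (7–10) by
   default; conformant = above 60 % on both item types, non-conformant =
   above 60 % unindicative and below 40 % indicative, everything else
   other. Comparisons are strict, so values exactly at a threshold fall to
   *other*. Stricter preset pairs (70/70–30, 80/80–20) tighten both
   thresholds so the classes are nested; the exact stricter thresholds
   used in the original robustness analysis are not published, so these
   are labelled placeholders, exposed as parameters.
5. **Change directions.** The sign of the accuracy change from the last
   supervised block (3) to the structurally identical late block (9), per
   item type.
6. **Permutation tests.** One-sample sign-flip tests of accuracies
   against chance (0.5) or of changes against 0. For n ≤ 12 all 2ⁿ sign
   patterns are enumerated exactly; otherwise a seeded Monte-Carlo null
   with the add-one convention `p = (count + 1)/(n_perm + 1)` (p can never
   be 0; the p-value floor is 1/(n_perm + 1)). Ties are counted as "as
   extreme" with a 1e-12 tolerance so that exactly-null data yield p = 1.
   Directional alternatives follow the expectation each learner class
   embodies (conformant: greater on both; non-conformant: less on
   indicative, greater on unindicative; other: two-sided).

One reported block-1 result in the unsupervised reference data (above
chance on indicative and below chance on unindicative items for
non-conformant subjects, the reverse of the end state) cannot be
disambiguated from the published text — it may follow from the
whole-session remapping or be a typographical swap — and the pipeline
makes no attempt to reproduce that specific direction.

## Seeds and determinism

Every random procedure descends from explicit integer seeds. An
end-to-end run derives named child streams (`design`, `population`,
`tests`) from one master seed via `numpy` seed sequences, so changing the
number of permutations never perturbs the simulated responses, and reruns
are byte-identical. The permutation-test Monte-Carlo stream is passed
explicitly.

## Problem sizes

The shipped checks use the sizes the analysis is designed around: design
validation over the full 4 × 10 × 16 structure (plus 100 single-block
seeds and 1000 blocks for the extremeness bias), a 200-subject
semi-supervised cohort for the divergence analysis, 100 runs per
component for the supervised curve shapes, 2000 null datasets for the
type-I calibration of the permutation test, and 500 random datasets for
the remapping guarantee. A full 200-subject cohort simulates in a few
seconds on one core.

## Known limitations

* The learner concretisations are sufficient, not unique: other
  functional forms (e.g. a density-estimation learner) satisfy the same
  qualitative constraints.
* Attention is one complementary pair, not per-feature weights; the task
  only dissociates salient vs subtle channels, so richer attention is not
  identifiable here.
* Human percentages from the reference cohorts (class splits, exact
  improved/worsened percentages) depend on an unobservable participant
  population and are not reproduction targets; the package's claims are
  the structural counts and the directions of the effects.
* The exclusion warning rule is a concretisation of an on-screen warning
  procedure whose exact re-arming behaviour is not published.
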