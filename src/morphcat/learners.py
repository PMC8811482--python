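"""Self-training category learners: delta-rule and prototype models.

Both learners share three mechanisms:

* **Attention weighting.** Stimuli are encoded through a complementary
  attention pair (salient morph channel vs subtle group channels); a
  learner attending the salient dimension effectively cannot see the group
  structure, and vice versa.
* **Error-driven attention switching.** Supervised prediction errors
  accumulate and gradually shift attention toward the subtle channels
  through a logistic function of the accumulated error scaled by a
  subject-specific switch rate. Without feedback attention stays put —
  representational correction requires supervision.
* **Self-training (pseudo-labelling).** On trials without feedback the
  model's current best guess — the category with the highest predicted
  probability — is treated exactly like an observed label. Self-training
  therefore amplifies whatever representation the learner currently holds:
  it improves an already task-aligned learner and entrenches the salient
  (wrong) boundary of a misaligned one.

The delta-rule learner is a multinomial logistic unit updated by gradient
steps on the prediction error; the prototype learner keeps one
attention-weighted average per category and classifies by softmax over
negative scaled Euclidean distances. These concretisations satisfy every
mechanism above while remaining as simple as possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, softmax

from .design import Stimulus

__all__ = [
    "AttentionState",
    "DeltaRuleLearner",
    "PrototypeLearner",
    "encode_stimulus",
    "pseudo_label",
    "step_trial",
    "learner_to_snapshot",
    "learner_from_snapshot",
]

N_CATEGORIES = 2
_ALPHA_CLIP = 1e-6


@dataclass
class AttentionState:
    """Complementary attention weights over the salient and subtle channels.

    ``alpha_subtle`` follows a logistic function of the accumulated
    supervised prediction error scaled by ``switch_rate``; the intercept is
    fixed at the logit of the initial value, so attention rises
    monotonically from its starting point toward 1 as errors accumulate.
    Trials without feedback leave attention (and the accumulator) unchanged.
    """

    alpha_subtle: float
    switch_rate: float
    error_accumulator: float = 0.0
    baseline_logit: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_subtle <= 1.0:
            raise ValueError("alpha_subtle must lie in [0, 1]")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be non-negative")
        if self.baseline_logit is None:
            a = float(np.clip(self.alpha_subtle, _ALPHA_CLIP, 1 - _ALPHA_CLIP))
            self.baseline_logit = float(logit(a))

    @property
    def alpha_salient(self) -> float:
        return 1.0 - self.alpha_subtle

    def update(self, error_magnitude: float, feedback_available: bool) -> None:
        """Accumulate supervised error and re-place attention; no-op without feedback."""
        if not feedback_available:
            return
        if error_magnitude < 0 or not np.isfinite(error_magnitude):
            raise ValueError("error_magnitude must be finite and non-negative")
        self.error_accumulator += float(error_magnitude)
        drive = self.baseline_logit + self.switch_rate * self.error_accumulator
        self.alpha_subtle = float(np.clip(expit(drive), 0.0, 1.0))


def encode_stimulus(
    stimulus: Stimulus, attention: AttentionState, n_groups: int = 4
) -> np.ndarray:
    """Attention-weighted feature vector for one stimulus.

    Layout: ``[alpha_salient * (2*morph - 1), alpha_subtle * one-hot(group),
    1.0]``. The signed morph coordinate is 0 at the continuum midpoint; the
    group one-hot channels stand in for the appendage features, which
    identify the group deterministically. The trailing constant is a bias
    channel.
    """
    f = np.zeros(n_groups + 2)
    f[0] = attention.alpha_salient * (2.0 * stimulus.morph - 1.0)
    f[1 + (stimulus.group - 1)] = attention.alpha_subtle
    f[-1] = 1.0
    return f


def pseudo_label(belief: np.ndarray) -> int:
    """Current best guess: the most probable category; exact tie -> category 1."""
    return int(np.argmax(belief)) + 1


class DeltaRuleLearner:
    """Multinomial logistic category unit trained by the delta rule.

    ``weights`` has one row per feature channel and one column per
    category. ``predict`` is a softmax over the per-category net inputs;
    ``update`` takes one gradient step of size ``learning_rate`` on the
    cross-entropy between the prediction and the (true or pseudo) label.
    """

    kind = "delta_rule"

    def __init__(
        self,
        n_features: int,
        learning_rate: float,
        attention: AttentionState,
        weights: np.ndarray | None = None,
    ) -> None:
        if learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        self.learning_rate = float(learning_rate)
        self.attention = attention
        if weights is None:
            self.weights = np.zeros((n_features, N_CATEGORIES))
        else:
            self.weights = np.array(weights, dtype=float)
            if self.weights.shape != (n_features, N_CATEGORIES):
                raise ValueError("weights must have shape (n_features, 2)")

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape != (self.weights.shape[0],):
            raise ValueError(
                f"feature vector of length {features.shape} does not match "
                f"{self.weights.shape[0]} input channels"
            )
        return softmax(features @ self.weights)

    def update(self, features: np.ndarray, target: int) -> None:
        if target not in (1, 2):
            raise ValueError("target must be category 1 or 2")
        p = self.predict(features)
        t = np.zeros(N_CATEGORIES)
        t[target - 1] = 1.0
        self.weights += self.learning_rate * np.outer(features, t - p)


class PrototypeLearner:
    """Prototype model: attention-weighted stimulus averages per category.

    ``predict`` is a softmax over negative Euclidean distances to the two
    prototypes scaled by ``similarity_scale``. ``update`` moves the target
    category's prototype toward the observed feature vector, either by a
    fixed step ``learning_rate`` or — when ``learning_rate`` is None — by
    ``1/count`` so the prototype is the exact running mean of everything
    assigned to that category.
    """

    kind = "prototype"

    def __init__(
        self,
        n_features: int,
        similarity_scale: float,
        attention: AttentionState,
        learning_rate: float | None = None,
        prototypes: np.ndarray | None = None,
    ) -> None:
        if similarity_scale <= 0:
            raise ValueError("similarity_scale must be positive")
        self.similarity_scale = float(similarity_scale)
        self.learning_rate = None if learning_rate is None else float(learning_rate)
        self.attention = attention
        if prototypes is None:
            self.prototypes = np.zeros((N_CATEGORIES, n_features))
        else:
            self.prototypes = np.array(prototypes, dtype=float)
            if self.prototypes.shape != (N_CATEGORIES, n_features):
                raise ValueError("prototypes must have shape (2, n_features)")
        self.counts = np.zeros(N_CATEGORIES, dtype=int)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape != (self.prototypes.shape[1],):
            raise ValueError(
                f"feature vector of length {features.shape} does not match "
                f"{self.prototypes.shape[1]} input channels"
            )
        d = np.linalg.norm(self.prototypes - features, axis=1)
        return softmax(-self.similarity_scale * d)

    def update(self, features: np.ndarray, target: int) -> None:
        if target not in (1, 2):
            raise ValueError("target must be category 1 or 2")
        features = np.asarray(features, dtype=float)
        k = target - 1
        self.counts[k] += 1
        step = (
            1.0 / self.counts[k] if self.learning_rate is None else self.learning_rate
        )
        self.prototypes[k] += step * (features - self.prototypes[k])


def _sample_response(
    belief: np.ndarray, temperature: float, rng: np.random.Generator
) -> int:
    if temperature < 1e-8:
        return int(np.argmax(belief)) + 1
    logp = np.log(np.clip(belief, 1e-300, None)) / temperature
    p = softmax(logp)
    return 1 if rng.random() < p[0] else 2


def step_trial(
    learner,
    stimulus: Stimulus,
    feedback_label: int | None,
    rng: np.random.Generator,
    temperature: float = 0.5,
    lapse: float = 0.0,
    n_groups: int = 4,
) -> tuple[int, np.ndarray]:
    """Run one trial: encode, predict, respond, learn.

    The overt response is sampled from the belief sharpened (or flattened)
    by ``temperature``, with probability ``lapse`` of a uniformly random
    key press. Learning uses the true label when feedback is available
    (also driving the attention switch with the pre-update error
    ``1 - p(true)``), and otherwise the pseudo-label — never the sampled,
    possibly lapsed, response.

    Returns the response (1 or 2) and the pre-update belief.
    """
    features = encode_stimulus(stimulus, learner.attention, n_groups)
    belief = learner.predict(features)
    if lapse > 0.0 and rng.random() < lapse:
        response = int(rng.integers(1, 3))
    else:
        response = _sample_response(belief, temperature, rng)
    if feedback_label is not None:
        error = 1.0 - float(belief[feedback_label - 1])
        learner.update(features, feedback_label)
        learner.attention.update(error, True)
    else:
        learner.update(features, pseudo_label(belief))
    return response, belief


# ---------------------------------------------------------------------------
# flat key-value snapshots
# ---------------------------------------------------------------------------

def _fmt_matrix(m: np.ndarray) -> str:
    return ";".join(",".join(repr(float(x)) for x in row) for row in np.atleast_2d(m))


def _parse_matrix(s: str) -> np.ndarray:
    return np.array([[float(x) for x in row.split(",")] for row in s.split(";")])


def learner_to_snapshot(learner) -> str:
    """Serialise a learner to a flat ``key=value`` text snapshot."""
    att = learner.attention
    lines = [
        f"kind={learner.kind}",
        f"alpha_subtle={att.alpha_subtle!r}",
        f"switch_rate={att.switch_rate!r}",
        f"error_accumulator={att.error_accumulator!r}",
        f"baseline_logit={att.baseline_logit!r}",
    ]
    if learner.kind == "delta_rule":
        lines += [
            f"learning_rate={learner.learning_rate!r}",
            f"weights={_fmt_matrix(learner.weights)}",
        ]
    else:
        lines += [
            f"learning_rate={'' if learner.learning_rate is None else repr(learner.learning_rate)}",
            f"similarity_scale={learner.similarity_scale!r}",
            f"prototypes={_fmt_matrix(learner.prototypes)}",
            f"counts={','.join(str(int(c)) for c in learner.counts)}",
        ]
    return "\n".join(lines) + "\n"


def learner_from_snapshot(text: str):
    """Rebuild a learner from :func:`learner_to_snapshot` output."""
    kv = dict(
        line.split("=", 1) for line in text.strip().splitlines() if line.strip()
    )
    att = AttentionState(
        alpha_subtle=float(kv["alpha_subtle"]),
        switch_rate=float(kv["switch_rate"]),
        error_accumulator=float(kv["error_accumulator"]),
        baseline_logit=float(kv["baseline_logit"]),
    )
    if kv["kind"] == "delta_rule":
        weights = _parse_matrix(kv["weights"])
        return DeltaRuleLearner(
            n_features=weights.shape[0],
            learning_rate=float(kv["learning_rate"]),
            attention=att,
            weights=weights,
        )
    prototypes = _parse_matrix(kv["prototypes"])
    learner = PrototypeLearner(
        n_features=prototypes.shape[1],
        similarity_scale=float(kv["similarity_scale"]),
        attention=att,
        learning_rate=float(kv["learning_rate"]) if kv["learning_rate"] else None,
        prototypes=prototypes,
    )
    learner.counts = np.array([int(c) for c in kv["counts"].split(",")])
    return learner
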