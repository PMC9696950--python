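"""Confidence-routed hierarchical ensemble decision logic.

The framework combines seven probabilistic classifiers ("players"):

* ``s3`` — a single 3-class classifier over benign keratosis (B),
  melanoma (M) and nevus (N);
* ``sB``, ``sM``, ``sN`` — one-vs-all (ova) classifiers, each specialised
  in one class and used *only* to score the confidence of ``s3``;
* ``sBM``, ``sBN``, ``sMN`` — one-vs-one (ovo) classifiers used to refine
  difficult predictions.

For an input ``x`` the 3-class player produces probabilities
``(pB, pM, pN)``; the confidence of its top prediction ``p_i`` is

    u = |p_i - p_i'|

where ``p_i'`` is the "belongs to class i" probability of the ova player
specialised in the same class.  The prediction is then grouped:

* ``u <= alpha1``            → *high* confidence: keep the 3-class decision;
* ``alpha1 < u <= alpha2``   → *medium*: defer to the single ovo player of
  the two most probable classes;
* ``u > alpha2``             → *uncertain*: defer to Max-Win voting over all
  three ovo players.

Final probabilities are renormalised so they sum to one.  Ties are broken
by a fixed class priority, melanoma first (``M > B > N``), because the
clinical cost of a missed melanoma dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CLASSES",
    "TIE_PRIORITY",
    "ProbabilityVector",
    "BinaryPrediction",
    "ConfidenceThresholds",
    "RoutingTrace",
    "ClassifierBundle",
    "argmax_decision",
    "confidence_score",
    "assign_group",
    "select_pairwise",
    "max_win",
    "normalize_probs",
    "predict",
]

#: Canonical class order used everywhere in the package.
CLASSES: tuple[str, str, str] = ("B", "M", "N")

#: Fixed tie-break priority: melanoma wins ties, then keratosis, then nevus.
TIE_PRIORITY: tuple[str, str, str] = ("M", "B", "N")

_PROB_TOL = 1e-6


class ContractViolation(ValueError):
    """A classifier emitted probabilities violating the probability contract."""


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if math.isnan(value) or not (-_PROB_TOL <= value <= 1.0 + _PROB_TOL):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")
    return min(max(value, 0.0), 1.0)


@dataclass(frozen=True)
class ProbabilityVector:
    """Per-class predicted probabilities for one image, ordered (B, M, N)."""

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.probs) != set(CLASSES):
            raise ValueError(
                f"expected probabilities for classes {CLASSES}, got {sorted(self.probs)}"
            )
        clean = {c: _check_prob(self.probs[c], f"p{c}") for c in CLASSES}
        total = sum(clean.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total:.8f})")
        object.__setattr__(self, "probs", clean)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ProbabilityVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (3,):
            raise ValueError(f"expected 3 probabilities, got shape {arr.shape}")
        return cls(dict(zip(CLASSES, arr.tolist())))

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[c] for c in CLASSES], dtype=float)

    def __getitem__(self, cls_label: str) -> float:
        return self.probs[cls_label]


@dataclass(frozen=True)
class BinaryPrediction:
    """Output of a two-class player: probabilities for its two classes."""

    class_a: str
    class_b: str
    p_a: float
    p_b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_a", _check_prob(self.p_a, "p_a"))
        object.__setattr__(self, "p_b", _check_prob(self.p_b, "p_b"))
        if abs(self.p_a + self.p_b - 1.0) > _PROB_TOL:
            raise ValueError(
                f"binary probabilities must sum to 1 (got {self.p_a + self.p_b:.8f})"
            )
        if self.class_a == self.class_b:
            raise ValueError("binary prediction needs two distinct classes")

    def prob_of(self, cls_label: str) -> float:
        if cls_label == self.class_a:
            return self.p_a
        if cls_label == self.class_b:
            return self.p_b
        raise KeyError(cls_label)

    def winner(self, priority: Sequence[str] = TIE_PRIORITY) -> str:
        if self.p_a > self.p_b:
            return self.class_a
        if self.p_b > self.p_a:
            return self.class_b
        # exact tie: class priority decides
        for c in priority:
            if c in (self.class_a, self.class_b):
                return c
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Grouping thresholds (alpha1, alpha2), 0 <= alpha1 <= alpha2 <= 1."""

    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        a1 = _check_prob(self.alpha1, "alpha1")
        a2 = _check_prob(self.alpha2, "alpha2")
        if a1 > a2:
            raise ValueError(f"alpha1 ({a1}) must not exceed alpha2 ({a2})")
        object.__setattr__(self, "alpha1", a1)
        object.__setattr__(self, "alpha2", a2)


@dataclass(frozen=True)
class RoutingTrace:
    """Audit record of one framework prediction, for explainability."""

    stage1: ProbabilityVector
    top_class: str
    confidence: float
    group: str  # "high" | "medium" | "uncertain"
    stage2_route: str  # classifier name(s) used, or "none"
    stage2_probs: Optional[Mapping[str, float]]
    final_class: str
    final_probs: ProbabilityVector
    image_id: Optional[str] = None


def _rank_key(priority: Sequence[str]):
    order = {c: i for i, c in enumerate(priority)}

    def key(item: tuple[str, float]):
        cls_label, p = item
        return (-p, order[cls_label])

    return key


def argmax_decision(
    p: ProbabilityVector, priority: Sequence[str] = TIE_PRIORITY
) -> str:
    """Class attaining the maximum probability; ties broken by ``priority``."""
    ranked = sorted(p.probs.items(), key=_rank_key(priority))
    return ranked[0][0]


def confidence_score(p_top: float, p_ova: float) -> float:
    """Confidence u = |p_top - p_ova|.

    ``p_top`` is the top-class probability of the 3-class player and
    ``p_ova`` the "belongs to that class" probability of the matching
    one-vs-all player.  Small u means the two players agree.
    """
    return abs(_check_prob(p_top, "p_top") - _check_prob(p_ova, "p_ova"))


def assign_group(u: float, t: ConfidenceThresholds) -> str:
    """Group a confidence score: high [0, a1], medium (a1, a2], uncertain (a2, 1]."""
    u = _check_prob(u, "u")
    if u <= t.alpha1:
        return "high"
    if u <= t.alpha2:
        return "medium"
    return "uncertain"


def select_pairwise(
    p: ProbabilityVector, priority: Sequence[str] = TIE_PRIORITY
) -> tuple[str, str]:
    """The two most probable classes, ranked; ties broken by ``priority``."""
    ranked = sorted(p.probs.items(), key=_rank_key(priority))
    return ranked[0][0], ranked[1][0]


def max_win(
    preds: Sequence[BinaryPrediction], priority: Sequence[str] = TIE_PRIORITY
) -> str:
    """Max-Win rule over the three pairwise duels.

    Each duel votes for its more probable class; most votes wins.  A 1-1-1
    circular tie falls back to the largest probability mass a class
    received over its two duels, then to the fixed class priority.
    """
    pairs = {frozenset((bp.class_a, bp.class_b)) for bp in preds}
    expected = {frozenset(p) for p in (("B", "M"), ("B", "N"), ("M", "N"))}
    if len(preds) != 3 or pairs != expected:
        raise ValueError(
            "max_win needs exactly the three duels {B,M}, {B,N}, {M,N}"
        )
    votes = {c: 0 for c in CLASSES}
    mass = {c: 0.0 for c in CLASSES}
    for bp in preds:
        votes[bp.winner(priority)] += 1
        mass[bp.class_a] += bp.p_a
        mass[bp.class_b] += bp.p_b
    order = {c: i for i, c in enumerate(priority)}
    return min(CLASSES, key=lambda c: (-votes[c], -mass[c], order[c]))


def normalize_probs(pi: float, pj: float, pk: float) -> np.ndarray:
    """Normalise three non-negative scores to a probability vector."""
    arr = np.asarray([pi, pj, pk], dtype=float)
    if np.any(arr < -_PROB_TOL) or np.any(np.isnan(arr)):
        raise ValueError(f"scores must be non-negative, got {arr.tolist()}")
    arr = np.clip(arr, 0.0, None)
    total = arr.sum()
    if total <= 0.0:
        raise ValueError("cannot normalise all-zero scores")
    return arr / total


# ---------------------------------------------------------------------------
# The classifier bundle and the full routing algorithm
# ---------------------------------------------------------------------------

OVA_NAMES = {"B": "sB", "M": "sM", "N": "sN"}
OVO_NAMES = {
    frozenset(("B", "M")): "sBM",
    frozenset(("B", "N")): "sBN",
    frozenset(("M", "N")): "sMN",
}
ROSTER = ("s3", "sB", "sM", "sN", "sBM", "sBN", "sMN")


@dataclass
class ClassifierBundle:
    """The seven players behind a uniform prediction contract.

    Each member must expose ``predict_proba(x) -> array`` over its own
    classes and a ``classes`` attribute giving their order: ``s3`` over
    (B, M, N); each ova player over (positive class, rest); each ovo
    player over its two classes.
    """

    members: Mapping[str, object]

    def __post_init__(self) -> None:
        missing = [n for n in ROSTER if n not in self.members]
        if missing:
            raise ValueError(f"bundle is missing players: {missing}")

    def __getitem__(self, name: str):
        return self.members[name]

    def stage1(self, x) -> ProbabilityVector:
        raw = np.asarray(self.members["s3"].predict_proba(x), dtype=float)
        try:
            return ProbabilityVector.from_array(raw)
        except ValueError as exc:
            raise ContractViolation(f"player s3: {exc}") from exc

    def ova(self, cls_label: str, x) -> float:
        """Probability that x belongs to ``cls_label`` per its ova player."""
        name = OVA_NAMES[cls_label]
        raw = np.asarray(self.members[name].predict_proba(x), dtype=float)
        if raw.shape != (2,) or abs(raw.sum() - 1.0) > _PROB_TOL:
            raise ContractViolation(
                f"player {name}: binary probabilities invalid ({raw!r})"
            )
        return float(raw[0])  # positive class first by contract

    def ovo(self, a: str, b: str, x) -> BinaryPrediction:
        name = OVO_NAMES[frozenset((a, b))]
        clf = self.members[name]
        raw = np.asarray(clf.predict_proba(x), dtype=float)
        if raw.shape != (2,) or abs(raw.sum() - 1.0) > _PROB_TOL:
            raise ContractViolation(
                f"player {name}: binary probabilities invalid ({raw!r})"
            )
        ca, cb = clf.classes
        try:
            return BinaryPrediction(ca, cb, float(raw[0]), float(raw[1]))
        except ValueError as exc:
            raise ContractViolation(f"player {name}: {exc}") from exc


def predict(
    x,
    bundle: ClassifierBundle,
    t: ConfidenceThresholds,
    priority: Sequence[str] = TIE_PRIORITY,
    image_id: Optional[str] = None,
) -> RoutingTrace:
    """Run the full confidence-routed prediction for one input.

    Stage 1: the 3-class player predicts ``(pB, pM, pN)`` and the ova
    player of the top class scores confidence ``u``.  High-confidence
    predictions are kept; medium ones are refined by the ovo player of the
    top-2 classes; uncertain ones go to Max-Win voting over all three ovo
    players.  The returned trace records every intermediate quantity.
    """
    stage1 = bundle.stage1(x)
    top = argmax_decision(stage1, priority)
    u = confidence_score(stage1[top], bundle.ova(top, x))
    group = assign_group(u, t)

    if group == "high":
        final_class = top
        final = ProbabilityVector.from_array(normalize_probs(*stage1.as_array()))
        return RoutingTrace(stage1, top, u, group, "none", None, final_class, final, image_id)

    if group == "medium":
        i, j = select_pairwise(stage1, priority)
        k = next(c for c in CLASSES if c not in (i, j))
        bp = bundle.ovo(i, j, x)
        final_class = bp.winner(priority)
        # pi, pj from the duel; pk carried over from stage 1
        scores = {i: bp.prob_of(i), j: bp.prob_of(j), k: stage1[k]}
        arr = normalize_probs(*(scores[c] for c in CLASSES))
        final = ProbabilityVector.from_array(arr)
        route = OVO_NAMES[frozenset((i, j))]
        return RoutingTrace(
            stage1, top, u, group, route,
            {bp.class_a: bp.p_a, bp.class_b: bp.p_b},
            final_class, final, image_id,
        )

    # uncertain: Max-Win over the three duels; each class scored by the
    # probability mass it received across its two duels
    duels = [
        bundle.ovo("B", "M", x),
        bundle.ovo("B", "N", x),
        bundle.ovo("M", "N", x),
    ]
    final_class = max_win(duels, priority)
    mass = {c: 0.0 for c in CLASSES}
    for bp in duels:
        mass[bp.class_a] += bp.p_a
        mass[bp.class_b] += bp.p_b
    arr = normalize_probs(*(mass[c] for c in CLASSES))
    final = ProbabilityVector.from_array(arr)
    stage2 = {f"{bp.class_a}{bp.class_b}": (bp.p_a, bp.p_b) for bp in duels}
    return RoutingTrace(
        stage1, top, u, group, "sBM+sBN+sMN", stage2, final_class, final, image_id
    )


def traces_to_frame(traces: Sequence[RoutingTrace]):
    """Flatten routing traces into the prediction CSV layout."""
    import pandas as pd

    rows = []
    for tr in traces:
        rows.append(
            {
                "image_id": tr.image_id,
                "pB": tr.stage1["B"],
                "pM": tr.stage1["M"],
                "pN": tr.stage1["N"],
                "confidence_u": tr.confidence,
                "group": tr.group,
                "route": tr.stage2_route,
                "final_class": tr.final_class,
                "final_pB": tr.final_probs["B"],
                "final_pM": tr.final_probs["M"],
                "final_pN": tr.final_probs["N"],
            }
        )
    return pd.DataFrame(rows)
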