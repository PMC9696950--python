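"""Core routing: decision rule, confidence grouping, Max-Win voting and
the full hierarchical prediction, checked against a straight-line
transcription of the routing procedure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermroute.routing import (
    CLASSES,
    BinaryPrediction,
    ClassifierBundle,
    ConfidenceThresholds,
    ProbabilityVector,
    argmax_decision,
    assign_group,
    confidence_score,
    max_win,
    normalize_probs,
    predict,
    select_pairwise,
)
from dermroute.synthetic import TaggedSample, identity_bundle

from conftest import random_mock_bundle


def pv(b, m, n):
    return ProbabilityVector({"B": b, "M": m, "N": n})


# ---------------------------------------------------------------------------
# Independent oracle: a literal, line-by-line transcription of the
# routing procedure, kept free of any package helper.
# ---------------------------------------------------------------------------

_PRIO = {"M": 0, "B": 1, "N": 2}


def _rank(probs: dict) -> list:
    return sorted(probs, key=lambda c: (-probs[c], _PRIO[c]))


def algorithm_transcription(x, bundle, a1, a2):
    """Stage 1 -> confidence -> group -> (keep | single duel | Max-Win)."""
    p3 = bundle.members["s3"].predict_proba(x)
    probs = dict(zip(CLASSES, p3))
    ranked = _rank(probs)
    i = ranked[0]
    ova_name = {"B": "sB", "M": "sM", "N": "sN"}[i]
    p_ova = bundle.members[ova_name].predict_proba(x)[0]
    u = abs(probs[i] - p_ova)
    if u <= a1:
        return i, "high"
    if u <= a2:
        j = ranked[1]
        duel_name = "s" + "".join(sorted((i, j)))
        duel = bundle.members[duel_name]
        dp = duel.predict_proba(x)
        dd = dict(zip(duel.classes, dp))
        if dd[i] > dd[j]:
            return i, "medium"
        if dd[j] > dd[i]:
            return j, "medium"
        return min((i, j), key=lambda c: _PRIO[c]), "medium"
    votes = {c: 0 for c in CLASSES}
    mass = {c: 0.0 for c in CLASSES}
    for name in ("sBM", "sBN", "sMN"):
        duel = bundle.members[name]
        dp = duel.predict_proba(x)
        a, b = duel.classes
        if dp[0] > dp[1]:
            votes[a] += 1
        elif dp[1] > dp[0]:
            votes[b] += 1
        else:
            votes[min((a, b), key=lambda c: _PRIO[c])] += 1
        mass[a] += dp[0]
        mass[b] += dp[1]
    win = sorted(CLASSES, key=lambda c: (-votes[c], -mass[c], _PRIO[c]))[0]
    return win, "uncertain"


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "probs,expected",
    [
        ((0.0, 1.0, 0.0), "M"),  # textbook confident melanoma
        ((0.2, 0.5, 0.3), "M"),
        ((0.5, 0.5, 0.0), "M"),  # tie broken by melanoma-first priority
        ((0.4, 0.2, 0.4), "B"),  # B beats N on ties
    ],
)
def test_argmax_decision(probs, expected):
    assert argmax_decision(pv(*probs)) == expected


def test_argmax_rejects_invalid_probabilities():
    with pytest.raises(ValueError):
        pv(0.5, 0.6, 0.2)
    with pytest.raises(ValueError):
        pv(float("nan"), 0.5, 0.5)


@pytest.mark.parametrize(
    "p_top,p_ova,expected",
    [(0.9, 0.9, 0.0), (1.0, 0.0, 1.0), (0.9, 0.7, 0.2), (0.3, 0.8, 0.5)],
)
def test_confidence_score(p_top, p_ova, expected):
    assert confidence_score(p_top, p_ova) == pytest.approx(expected)


def test_confidence_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        confidence_score(1.2, 0.5)


@pytest.mark.parametrize(
    "u,expected",
    [(0.05, "high"), (0.1, "high"), (0.3, "medium"), (0.5, "medium"), (0.7, "uncertain")],
)
def test_assign_group_boundaries(u, expected):
    t = ConfidenceThresholds(0.1, 0.5)
    assert assign_group(u, t) == expected


def test_thresholds_must_be_ordered():
    with pytest.raises(ValueError):
        ConfidenceThresholds(0.6, 0.5)


@given(u=st.floats(0, 1), a1=st.floats(0, 1), a2=st.floats(0, 1))
@settings(max_examples=200, derandomize=True)
def test_grouping_partitions_unit_interval(u, a1, a2):
    """Every confidence value lands in exactly one group."""
    if a1 > a2:
        a1, a2 = a2, a1
    assert assign_group(u, ConfidenceThresholds(a1, a2)) in {
        "high", "medium", "uncertain",
    }


@pytest.mark.parametrize(
    "probs,expected",
    [
        ((0.46, 0.53, 0.01), ("M", "B")),  # the borderline keratosis/melanoma case
        ((0.1, 0.1, 0.8), ("N", "M")),
        ((1 / 3, 1 / 3, 1 / 3), ("M", "B")),
    ],
)
def test_select_pairwise(probs, expected):
    assert select_pairwise(pv(*probs)) == expected


def test_max_win_majority():
    preds = [
        BinaryPrediction("B", "M", 0.3, 0.7),  # votes M
        BinaryPrediction("B", "N", 0.6, 0.4),  # votes B
        BinaryPrediction("M", "N", 0.8, 0.2),  # votes M
    ]
    assert max_win(preds) == "M"


def test_max_win_circular_tie_by_probability_mass():
    # B beats M, N beats B, M beats N: one vote each; summed masses
    # B: 0.6+0.4=1.0, M: 0.4+0.7=1.1, N: 0.6+0.3=0.9 -> M wins
    preds = [
        BinaryPrediction("B", "M", 0.6, 0.4),
        BinaryPrediction("B", "N", 0.4, 0.6),
        BinaryPrediction("M", "N", 0.7, 0.3),
    ]
    assert max_win(preds) == "M"


def test_max_win_full_tie_falls_back_to_priority():
    preds = [
        BinaryPrediction("B", "M", 0.5, 0.5),
        BinaryPrediction("B", "N", 0.5, 0.5),
        BinaryPrediction("M", "N", 0.5, 0.5),
    ]
    assert max_win(preds) == "M"


def test_max_win_rejects_bad_roster():
    with pytest.raises(ValueError):
        max_win([BinaryPrediction("B", "M", 0.5, 0.5)] * 3)


@pytest.mark.parametrize(
    "scores,expected",
    [
        ((0.6, 0.3, 0.1), (0.6, 0.3, 0.1)),
        ((0.9, 0.9, 0.2), (0.45, 0.45, 0.10)),
        ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ],
)
def test_normalize_probs(scores, expected):
    assert normalize_probs(*scores) == pytest.approx(expected)


def test_normalize_probs_rejects_all_zero():
    with pytest.raises(ValueError):
        normalize_probs(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Full prediction
# ---------------------------------------------------------------------------

def test_identity_bundle_gives_high_confidence_truth():
    bundle = identity_bundle()
    tr = predict(TaggedSample("x0", "M"), bundle, ConfidenceThresholds(0.1, 0.5))
    assert tr.group == "high"
    assert tr.stage2_route == "none"
    assert tr.final_class == "M"
    assert tr.final_probs.as_array() == pytest.approx([0.0, 1.0, 0.0])


def test_medium_route_uses_top2_duel():
    """A borderline B/M stage-1 prediction is refined by the B/M duel."""
    from dermroute.synthetic import MockProfile, mock_bundle

    profiles = {
        "s3": MockProfile({"M": [0.46, 0.53, 0.01]}, deterministic=True),
        "sM": MockProfile({"M": [0.95, 0.05]}, deterministic=True),  # u = 0.42
        "sB": MockProfile({"M": [0.05, 0.95]}, deterministic=True),
        "sN": MockProfile({"M": [0.05, 0.95]}, deterministic=True),
        "sBM": MockProfile({"M": [0.10, 0.90]}, deterministic=True),
        "sBN": MockProfile({"M": [0.5, 0.5]}, deterministic=True),
        "sMN": MockProfile({"M": [0.5, 0.5]}, deterministic=True),
    }
    bundle = mock_bundle(profiles)
    tr = predict(TaggedSample("x0", "M"), bundle, ConfidenceThresholds(0.1, 0.5))
    assert tr.group == "medium"
    assert tr.stage2_route == "sBM"
    assert tr.final_class == "M"
    # final probs: duel (pB=0.10, pM=0.90) with stage-1 pN=0.01 carried over
    assert tr.final_probs.as_array() == pytest.approx(
        np.array([0.10, 0.90, 0.01]) / 1.01
    )


def test_trace_final_probs_normalized(rng):
    bundle = random_mock_bundle(rng, seed=5)
    t = ConfidenceThresholds(0.1, 0.5)
    for k in range(50):
        tr = predict(TaggedSample(f"s{k}", CLASSES[k % 3]), bundle, t)
        assert tr.final_probs.as_array().sum() == pytest.approx(1.0, abs=1e-6)
        if tr.group == "high":
            assert tr.stage2_route == "none"
            assert tr.final_class == tr.top_class


def test_predict_matches_transcription_on_random_bundles(rng):
    """The framework agrees classwise with the straight-line oracle."""
    t = ConfidenceThresholds(0.15, 0.45)
    mismatches = 0
    for b in range(20):
        bundle = random_mock_bundle(rng, seed=1000 + b)
        for k in range(50):
            x = TaggedSample(f"s{k}", CLASSES[k % 3])
            tr = predict(x, bundle, t)
            cls, group = algorithm_transcription(x, bundle, 0.15, 0.45)
            assert (tr.final_class, tr.group) == (cls, group)
    assert mismatches == 0


def test_reduction_alpha1_one_equals_multiclass(rng):
    """With alpha1 = 1 every sample is high-confidence: the framework
    degenerates to the plain 3-class player."""
    bundle = random_mock_bundle(rng, seed=77)
    t = ConfidenceThresholds(1.0, 1.0)
    for k in range(100):
        x = TaggedSample(f"r{k}", CLASSES[k % 3])
        tr = predict(x, bundle, t)
        assert tr.group == "high"
        assert tr.final_class == argmax_decision(tr.stage1)


def test_reduction_alpha_zero_routes_all_to_max_win(rng):
    """With alpha1 = alpha2 = 0 and u > 0 every sample goes to voting."""
    bundle = random_mock_bundle(rng, seed=78)
    t = ConfidenceThresholds(0.0, 0.0)
    for k in range(100):
        x = TaggedSample(f"z{k}", CLASSES[k % 3])
        tr = predict(x, bundle, t)
        if tr.confidence > 0:
            assert tr.group == "uncertain"
            assert tr.stage2_route == "sBM+sBN+sMN"


def test_monotone_workload(rng):
    """Raising alpha1 never demotes a sample out of 'high'; raising
    alpha2 never pushes a 'medium' sample to 'uncertain'."""
    bundle = random_mock_bundle(rng, seed=79)
    rank = {"high": 0, "medium": 1, "uncertain": 2}
    xs = [TaggedSample(f"m{k}", CLASSES[k % 3]) for k in range(60)]
    for a1_lo, a1_hi in [(0.05, 0.2), (0.1, 0.4)]:
        for x in xs:
            g_lo = predict(x, bundle, ConfidenceThresholds(a1_lo, 0.5)).group
            g_hi = predict(x, bundle, ConfidenceThresholds(a1_hi, 0.5)).group
            assert rank[g_hi] <= rank[g_lo]
    for a2_lo, a2_hi in [(0.3, 0.6), (0.4, 0.9)]:
        for x in xs:
            g_lo = predict(x, bundle, ConfidenceThresholds(0.1, a2_lo)).group
            g_hi = predict(x, bundle, ConfidenceThresholds(0.1, a2_hi)).group
            assert rank[g_hi] <= rank[g_lo]


def test_contract_violation_names_offending_player():
    from dermroute.synthetic import MockProfile, mock_bundle

    profiles = {
        name: MockProfile({c: [0.5, 0.5] for c in CLASSES}, deterministic=True)
        for name in ("sB", "sM", "sN", "sBM", "sBN", "sMN")
    }
    profiles["s3"] = MockProfile({c: [1 / 3] * 3 for c in CLASSES}, deterministic=True)
    bundle = mock_bundle(profiles)
    bundle.members["sM"].predict_proba = lambda x: np.array([0.9, 0.9])
    with pytest.raises(ValueError, match="sM"):
        predict(TaggedSample("x", "M"), bundle, ConfidenceThresholds(0.0, 0.0))


def test_bundle_requires_all_seven_players():
    with pytest.raises(ValueError, match="missing"):
        ClassifierBundle({"s3": object()})
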