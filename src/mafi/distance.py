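"""Phonologically weighted feature edit distance and companion metrics.

The core scoring primitive: the minimum-cost alignment of two segment
sequences under insertions, deletions, and substitutions, where the cost
of substituting one segment for another is the weighted sum of their
articulatory feature differences,

    cost(a, b) = sum_f  w_f * |v_f(a) - v_f(b)|,

with feature values in {+1, 0, -1}. A full +1 <-> -1 flip on one feature
therefore costs two weight units: /b/ -> /p/ flips only voicing
(weight 0.125) and costs 0.25, while /b/ -> /k/ additionally flips the
anterior, labial, high, and back features (weight 0.25 each) and costs
2.25. Dividing the total cost by the segment count of the longer word
gives the normalized phonological distance whose negated per-word mean is
the MaFI score.

Companion metrics computed alongside: segment-level Levenshtein distance,
proportion of target phonemes correctly identified, and whole-word
accuracy (exact transcription match).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phonfeatures import FeatureTable, Segment, Transcription

__all__ = [
    "DistanceResult",
    "substitution_cost",
    "indel_cost",
    "weighted_feature_edit_distance",
    "normalized_distance",
    "levenshtein_distance",
    "pct_phonemes_correct",
    "exact_match",
    "score_pair",
]


@dataclass(frozen=True)
class DistanceResult:
    """All per-response metrics for one (target, response) pair."""

    raw_cost: float
    normalized: float
    levenshtein: int
    pct_phonemes: float
    exact: bool


def substitution_cost(a: Segment, b: Segment, table: FeatureTable) -> float:
    """Weighted feature difference between two segments."""
    w = np.asarray(table.weights)
    va = np.asarray(a.vector)
    vb = np.asarray(b.vector)
    return float(np.dot(w, np.abs(va - vb)))


def indel_cost(
    a: Segment, table: FeatureTable, constant: float | None = None
) -> float:
    """Cost of inserting or deleting one segment.

    Defaults to the segment's weighted feature mass, i.e. the substitution
    cost against an all-zero null segment. Pass ``constant`` for a flat
    per-segment penalty instead.
    """
    if constant is not None:
        return float(constant)
    w = np.asarray(table.weights)
    return float(np.dot(w, np.abs(np.asarray(a.vector))))


def weighted_feature_edit_distance(
    t1: Transcription,
    t2: Transcription,
    table: FeatureTable,
    indel_constant: float | None = None,
) -> float:
    """Minimum-cost alignment of two transcriptions (dynamic programming).

    Symmetric in its arguments; 0 for identical transcriptions and for
    empty-vs-empty.
    """
    n, m = len(t1), len(t2)
    a, b = t1.segments, t2.segments
    dels = [indel_cost(s, table, indel_constant) for s in a]
    inss = [indel_cost(s, table, indel_constant) for s in b]
    prev = np.concatenate([[0.0], np.cumsum(inss)])
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = prev[0] + dels[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + dels[i - 1],
                cur[j - 1] + inss[j - 1],
                prev[j - 1] + substitution_cost(a[i - 1], b[j - 1], table),
            )
        prev = cur
    return float(prev[m])


def normalized_distance(
    t1: Transcription,
    t2: Transcription,
    table: FeatureTable,
    indel_constant: float | None = None,
) -> float:
    """Edit cost divided by the phoneme count of the longer word."""
    denom = max(len(t1), len(t2))
    if denom == 0:
        raise ValueError("normalized distance undefined for two empty words")
    return weighted_feature_edit_distance(t1, t2, table, indel_constant) / denom


def levenshtein_distance(t1: Transcription, t2: Transcription) -> int:
    """Unit-cost segment-level edit distance."""
    a = [s.symbol for s in t1.segments]
    b = [s.symbol for s in t2.segments]
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def _max_matches_min_cost(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Identical-pair count, maximized over minimum unit-cost alignments.

    Lexicographic DP on (edit cost, -matches): among all alignments
    achieving the Levenshtein distance, returns the largest number of
    positions where the aligned segments are identical.
    """
    n, m = len(a), len(b)
    prev = [(j, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i, 0)] + [(0, 0)] * m
        for j in range(1, m + 1):
            same = a[i - 1] == b[j - 1]
            cands = [
                (prev[j][0] + 1, prev[j][1]),
                (cur[j - 1][0] + 1, cur[j - 1][1]),
                (prev[j - 1][0] + (not same), prev[j - 1][1] + same),
            ]
            cur[j] = min(cands, key=lambda t: (t[0], -t[1]))
        prev = cur
    return prev[m][1]


def pct_phonemes_correct(target: Transcription, response: Transcription) -> float:
    """Proportion of target phonemes identified correctly.

    Counts aligned identical segments in a minimum-cost unit alignment
    (choosing, among ties, the alignment with the most identical pairs)
    and divides by the target's segment count. Always in [0, 1].
    """
    if len(target) == 0:
        raise ValueError("pct_phonemes_correct undefined for empty target")
    matches = _max_matches_min_cost(
        tuple(s.symbol for s in target.segments),
        tuple(s.symbol for s in response.segments),
    )
    return min(1.0, matches / len(target))


def exact_match(target: Transcription, response: Transcription) -> bool:
    """Whole-word speechreading accuracy: exact segment-sequence identity."""
    return [s.symbol for s in target.segments] == [
        s.symbol for s in response.segments
    ]


def score_pair(
    target: Transcription,
    response: Transcription,
    table: FeatureTable,
    indel_constant: float | None = None,
) -> DistanceResult:
    """Compute all metrics for one (target, response) pair."""
    raw = weighted_feature_edit_distance(target, response, table, indel_constant)
    return DistanceResult(
        raw_cost=raw,
        normalized=raw / max(len(target), len(response)),
        levenshtein=levenshtein_distance(target, response),
        pct_phonemes=pct_phonemes_correct(target, response),
        exact=exact_match(target, response),
    )
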