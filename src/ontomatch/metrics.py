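"""String similarity ensemble used for candidate filtering and features.

Edit-based (Levenshtein), gram-based (Q-gram Dice), token-based
(word Jaccard, Monge-Elkan, block distance) measures plus ISub, a measure
designed for ontology labels that rewards long common substrings and
penalises unmatched remainders.  The weighted lexical similarity Sim_lex
combines ISub, Q-gram and Levenshtein:

    Sim_lex(e1, e2) = alpha * ISub + beta * QGram + gamma * Lev,
    alpha + beta + gamma = 1,

each component evaluated as the maximum over the label pairs of the two
entities (synonym-list semantics: one agreeing synonym pair suffices).
All similarities are symmetric and lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "LexWeights",
    "levenshtein_distance",
    "levenshtein_sim",
    "qgram_sim",
    "isub_sim",
    "jaccard_words",
    "monge_elkan",
    "block_distance_sim",
    "lexical_similarity",
]


@dataclass(frozen=True)
class LexWeights:
    """Weights of the ISub / Q-gram / Levenshtein mixture; must sum to 1."""

    alpha: float = 0.4
    beta: float = 0.3
    gamma: float = 0.3

    def __post_init__(self) -> None:
        for w in (self.alpha, self.beta, self.gamma):
            if not 0.0 <= w <= 1.0:
                raise ValueError("weights must lie in [0, 1]")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ValueError("alpha + beta + gamma must equal 1")


# ------------------------------------------------------------- Levenshtein


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character edits turning a into b."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    if len(a) * len(b) > 4096:
        return _levenshtein_distance_vec(a, b)
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        current = [i]
        for j, cb in enumerate(b, 1):
            current.append(
                min(previous[j] + 1, current[j - 1] + 1, previous[j - 1] + (ca != cb))
            )
        previous = current
    return previous[-1]


def _levenshtein_distance_vec(a: str, b: str) -> int:
    """Row-vectorised Wagner-Fischer for long inputs (same recurrence)."""
    a_codes = np.frombuffer(a.encode("utf-32-le"), dtype=np.uint32)
    b_codes = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32)
    idx = np.arange(len(b_codes) + 1)
    prev = idx.copy()
    cur = np.empty_like(prev)
    for i, ca in enumerate(a_codes, 1):
        cur[0] = i
        np.minimum(prev[1:] + 1, prev[:-1] + (b_codes != ca), out=cur[1:])
        # propagate insertions: running min of cur[j] - j, plus j back
        t = cur - idx
        np.minimum.accumulate(t, out=t)
        cur = t + idx
        prev, cur = cur, prev
    return int(prev[-1])


def levenshtein_sim(a: str, b: str) -> float:
    """1 - dist/max(|a|, |b|); two empty strings are identical (1)."""
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / longest


# ------------------------------------------------------------- Q-gram


def _qgrams(s: str, q: int, pad: bool) -> list[str]:
    if pad:
        s = "#" * (q - 1) + s + "#" * (q - 1)
    return [s[i : i + q] for i in range(max(len(s) - q + 1, 0))]


def qgram_sim(a: str, b: str, q: int = 3, *, pad: bool = True) -> float:
    """Dice coefficient over (padded) q-gram multisets."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if not a and not b:
        return 1.0
    ga, gb = _qgrams(a, q, pad), _qgrams(b, q, pad)
    if not ga and not gb:
        # both shorter than one gram even padded
        return 1.0 if a == b else 0.0
    counts: dict[str, int] = {}
    for g in ga:
        counts[g] = counts.get(g, 0) + 1
    common = 0
    for g in gb:
        if counts.get(g, 0) > 0:
            counts[g] -= 1
            common += 1
    return 2.0 * common / (len(ga) + len(gb))


# ------------------------------------------------------------- ISub


def _isub_common_length(a: str, b: str) -> int:
    """Total length of greedily removed longest common substrings
    (substrings shorter than 2 characters are not counted)."""
    common = 0
    while a and b:
        best_len, best_i, best_j = 0, 0, 0
        # longest common substring by dynamic programming
        row = [0] * (len(b) + 1)
        for i in range(1, len(a) + 1):
            new_row = [0] * (len(b) + 1)
            for j in range(1, len(b) + 1):
                if a[i - 1] == b[j - 1]:
                    new_row[j] = row[j - 1] + 1
                    if new_row[j] > best_len:
                        best_len, best_i, best_j = new_row[j], i, j
            row = new_row
        if best_len < 2:
            break
        common += best_len
        a = a[: best_i - best_len] + a[best_i:]
        b = b[: best_j - best_len] + b[best_j:]
    return common


def _isub_winkler(a: str, b: str, common: float) -> float:
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == 4:
            break
        prefix += 1
    return prefix * 0.1 * (1.0 - common)


def isub_sim(a: str, b: str) -> float:
    """ISub similarity, clamped from its native [-1, 1] to [0, 1].

    native = commonality - difference + winkler-improvement, where the
    difference term uses Hamacher parametrised product (p = 0.6) of the
    unmatched fractions of the two strings.
    """
    a, b = a.lower(), b.lower()
    if a == b:
        return 1.0
    if not a or not b:
        return 0.5  # native 0: no commonality, no difference
    if a > b:
        a, b = b, a  # greedy substring removal tie-breaks: fix an order
    matched = _isub_common_length(a, b)
    comm = 2.0 * matched / (len(a) + len(b))
    ula = (len(a) - matched) / len(a)
    ulb = (len(b) - matched) / len(b)
    p = 0.6  # Hamacher parameter of the published measure
    denom = p + (1.0 - p) * (ula + ulb - ula * ulb)
    diff = 0.0 if denom == 0 else (ula * ulb) / denom
    native = comm - diff + _isub_winkler(a, b, comm)
    native = max(-1.0, min(1.0, native))
    return (native + 1.0) / 2.0


# ------------------------------------------------------------- token based


def _tokens(s: str) -> list[str]:
    return s.split()


def jaccard_words(a: str, b: str) -> float:
    """Shared words over unique words of the two strings."""
    ta, tb = set(_tokens(a)), set(_tokens(b))
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def monge_elkan(a: str, b: str) -> float:
    """Symmetrised Monge-Elkan: mean over tokens of a of the best
    Levenshtein similarity against tokens of b, averaged both ways."""
    ta, tb = _tokens(a), _tokens(b)
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0

    def directed(xs: list[str], ys: list[str]) -> float:
        return sum(max(_lev_sim_cached(x, y) for y in ys) for x in xs) / len(xs)

    return (directed(ta, tb) + directed(tb, ta)) / 2.0


@lru_cache(maxsize=1 << 18)
def _lev_sim_cached(a: str, b: str) -> float:
    # token vocabularies repeat heavily across neighbourhood texts
    if a > b:
        a, b = b, a
    return levenshtein_sim(a, b)


def block_distance_sim(a: str, b: str) -> float:
    """1 - L1/(|a| + |b|) over token-count vectors (city-block distance)."""
    ta, tb = _tokens(a), _tokens(b)
    if not ta and not tb:
        return 1.0
    counts: dict[str, list[int]] = {}
    for t in ta:
        counts.setdefault(t, [0, 0])[0] += 1
    for t in tb:
        counts.setdefault(t, [0, 0])[1] += 1
    l1 = sum(abs(ca - cb) for ca, cb in counts.values())
    return 1.0 - l1 / (len(ta) + len(tb))


# ------------------------------------------------------------- Sim_lex


def lexical_similarity(
    labels1, labels2, weights: LexWeights = LexWeights(), q: int = 3
) -> float:
    """Weighted ISub/Q-gram/Levenshtein similarity between two label sets.

    Each component is the maximum over the cross product of label strings,
    so multi-synonym entities match as soon as one synonym pair agrees.
    Empty label sets score 0.
    """
    labels1, labels2 = list(labels1), list(labels2)
    if not labels1 or not labels2:
        return 0.0
    best_isub = best_qgram = best_lev = 0.0
    for s1 in labels1:
        for s2 in labels2:
            if s1 == s2:
                best_isub = best_qgram = best_lev = 1.0
                break
            best_isub = max(best_isub, isub_sim(s1, s2))
            best_qgram = max(best_qgram, qgram_sim(s1, s2, q))
            best_lev = max(best_lev, levenshtein_sim(s1, s2))
        if best_lev == 1.0 and best_isub == 1.0 and best_qgram == 1.0:
            break
    return (
        weights.alpha * best_isub
        + weights.beta * best_qgram
        + weights.gamma * best_lev
    )
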