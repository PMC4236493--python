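"""String-similarity ensemble vs independent brute-force oracles."""

import difflib
from collections import Counter
from functools import lru_cache

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontomatch.metrics import (
    LexWeights,
    block_distance_sim,
    isub_sim,
    jaccard_words,
    levenshtein_distance,
    levenshtein_sim,
    lexical_similarity,
    monge_elkan,
    qgram_sim,
)

strings = st.text(alphabet="abcdef g", max_size=15)


# ---------------------------------------------------------------- oracles


@lru_cache(maxsize=None)
def _lev_oracle(a: str, b: str) -> int:
    """Memoised textbook recursion, independent of the DP implementation."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _lev_oracle(a[1:], b) + 1,
        _lev_oracle(a, b[1:]) + 1,
        _lev_oracle(a[1:], b[1:]) + (a[0] != b[0]),
    )


def _qgram_oracle(a: str, b: str, q: int = 3) -> float:
    pad = "#" * (q - 1)
    a, b = pad + a + pad, pad + b + pad
    ga = Counter(a[i : i + q] for i in range(len(a) - q + 1))
    gb = Counter(b[i : i + q] for i in range(len(b) - q + 1))
    total = sum(ga.values()) + sum(gb.values())
    if total == 0:
        return 1.0
    return 2 * sum((ga & gb).values()) / total


def _jaccard_oracle(a: str, b: str) -> float:
    sa, sb = set(a.split()), set(b.split())
    if not sa and not sb:
        return 1.0
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def _block_oracle(a: str, b: str) -> float:
    ta, tb = a.split(), b.split()
    if not ta and not tb:
        return 1.0
    ca, cb = Counter(ta), Counter(tb)
    l1 = sum(abs(ca[t] - cb[t]) for t in set(ca) | set(cb))
    return 1.0 - l1 / (len(ta) + len(tb))


def _monge_elkan_oracle(a: str, b: str) -> float:
    ta, tb = a.split(), b.split()
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0

    def lev_sim(x, y):
        longest = max(len(x), len(y))
        return 1.0 if longest == 0 else 1 - edlib.align(x, y)["editDistance"] / longest

    d_ab = np.mean([max(lev_sim(x, y) for y in tb) for x in ta])
    d_ba = np.mean([max(lev_sim(y, x) for x in ta) for y in tb])
    return (d_ab + d_ba) / 2


def _isub_oracle(a: str, b: str) -> float:
    """Independent ISub transcription using difflib's longest-match search."""
    a, b = a.lower(), b.lower()
    if a == b:
        return 1.0
    if not a or not b:
        return 0.5
    if a > b:
        a, b = b, a  # mirror the fixed tie-break order
    la, lb = len(a), len(b)
    s1, s2, matched = a, b, 0
    while s1 and s2:
        m = difflib.SequenceMatcher(None, s1, s2, autojunk=False).find_longest_match(
            0, len(s1), 0, len(s2)
        )
        if m.size < 2:
            break
        matched += m.size
        s1 = s1[: m.a] + s1[m.a + m.size :]
        s2 = s2[: m.b] + s2[m.b + m.size :]
    comm = 2 * matched / (la + lb)
    ua, ub = (la - matched) / la, (lb - matched) / lb
    p = 0.6
    denom = p + (1 - p) * (ua + ub - ua * ub)
    diff = 0.0 if denom == 0 else ua * ub / denom
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == 4:
            break
        prefix += 1
    native = max(-1.0, min(1.0, comm - diff + prefix * 0.1 * (1 - comm)))
    return (native + 1) / 2


# ---------------------------------------------------------------- examples


def test_levenshtein_examples():
    assert levenshtein_distance("abc", "abc") == 0
    assert levenshtein_sim("abc", "abc") == 1.0
    assert levenshtein_distance("", "abc") == 3
    assert levenshtein_distance("kitten", "sitting") == 3
    assert levenshtein_sim("", "") == 1.0


def test_qgram_examples():
    assert qgram_sim("heart", "heart") == 1.0
    assert qgram_sim("aaa", "zzz") == 0.0
    # unpadded bigrams: night={ni,ig,gh,ht}, nacht={na,ac,ch,ht} -> 1 common
    assert qgram_sim("night", "nacht", q=2, pad=False) == pytest.approx(2 * 1 / 8)


def test_isub_examples():
    assert isub_sim("heart", "heart") == 1.0
    assert isub_sim("xyzvw", "qabcdefgh") <= 0.5  # non-positive native score
    assert isub_sim("Trademark", "Trade mark") == pytest.approx(
        _isub_oracle("Trademark", "Trade mark")
    )


def test_jaccard_examples():
    assert jaccard_words("heart attack", "attack heart") == 1.0
    assert jaccard_words("lung", "liver") == 0.0
    assert jaccard_words("left lung", "left lung lobe") == pytest.approx(2 / 3)


def test_monge_elkan_examples():
    assert monge_elkan("left lung", "left lung") == 1.0
    assert monge_elkan("heart", "haert") == levenshtein_sim("heart", "haert")
    a, b = "myocardial infarction", "infarction myocardium"
    assert monge_elkan(a, b) == pytest.approx(_monge_elkan_oracle(a, b))


def test_block_distance_examples():
    assert block_distance_sim("a b", "a b") == 1.0
    assert block_distance_sim("x", "y") == 0.0
    assert block_distance_sim("a b b", "a b c") == pytest.approx(2 / 3)


# ------------------------------------------------------------- oracle suite


def _random_pairs(n=500, max_len=15, seed=0):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("abcdefgh "))
    out = []
    for _ in range(n):
        la, lb = rng.integers(0, max_len + 1, size=2)
        a = "".join(rng.choice(alphabet, size=la)).strip()
        b = "".join(rng.choice(alphabet, size=lb)).strip()
        out.append((a, b))
    return out


def test_metric_oracle_suite():
    """All six metrics agree with their independent oracles on 500 random
    string pairs (edit distance additionally cross-checked against edlib)."""
    for a, b in _random_pairs():
        d = levenshtein_distance(a, b)
        assert d == _lev_oracle(a[:9], b[:9]) if (len(a) <= 9 and len(b) <= 9) else True
        if a and b:
            assert d == edlib.align(a, b)["editDistance"], (a, b)
        assert qgram_sim(a, b) == pytest.approx(_qgram_oracle(a, b)), (a, b)
        assert jaccard_words(a, b) == pytest.approx(_jaccard_oracle(a, b))
        assert block_distance_sim(a, b) == pytest.approx(_block_oracle(a, b))
        assert monge_elkan(a, b) == pytest.approx(_monge_elkan_oracle(a, b))
        assert isub_sim(a, b) == pytest.approx(_isub_oracle(a, b)), (a, b)


# ------------------------------------------------------------- properties


@settings(max_examples=300, deadline=None, derandomize=True)
@given(strings, strings)
def test_symmetry_identity_and_range(a, b):
    for metric in (
        levenshtein_sim,
        qgram_sim,
        isub_sim,
        jaccard_words,
        monge_elkan,
        block_distance_sim,
    ):
        s_ab, s_ba = metric(a, b), metric(b, a)
        assert s_ab == pytest.approx(s_ba)
        assert 0.0 <= s_ab <= 1.0
        assert metric(a, a) == 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(strings, strings, strings)
def test_levenshtein_triangle_inequality(a, b, c):
    assert levenshtein_distance(a, c) <= levenshtein_distance(
        a, b
    ) + levenshtein_distance(b, c)


# ------------------------------------------------------------- Sim_lex


def test_lexical_similarity_basics():
    assert lexical_similarity({"heart"}, {"heart"}) == 1.0
    w = LexWeights(alpha=1.0, beta=0.0, gamma=0.0)
    a, b = {"trademark"}, {"trade mark"}
    assert lexical_similarity(a, b, w) == pytest.approx(isub_sim("trademark", "trade mark"))
    # max over cross pairs: one identical synonym pair suffices
    assert lexical_similarity({"cor", "heart"}, {"heart", "pump"}) == 1.0
    assert lexical_similarity(set(), {"x"}) == 0.0


def test_lexical_similarity_monotone_in_weights():
    a, b = {"myocardial infarction"}, {"heart attack"}
    # isub component is the largest here; growing alpha grows Sim_lex
    vals = [
        lexical_similarity(a, b, LexWeights(alpha, (1 - alpha) / 2, (1 - alpha) / 2))
        for alpha in (0.2, 0.5, 0.8)
    ]
    comp_isub = isub_sim("myocardial infarction", "heart attack")
    comp_other = max(
        qgram_sim("myocardial infarction", "heart attack"),
        levenshtein_sim("myocardial infarction", "heart attack"),
    )
    if comp_isub > comp_other:
        assert vals[0] < vals[1] < vals[2]


def test_weights_validation():
    with pytest.raises(ValueError):
        LexWeights(0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        LexWeights(-0.1, 0.6, 0.5)
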