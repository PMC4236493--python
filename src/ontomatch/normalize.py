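"""Label normalization: the filter chain applied to every label at indexing
and query time, plus permutation enrichment and exact-mode concatenation.

The pipeline mirrors classic IR pre-processing for terminological matching:
camelCase/underscore splitting, lowercasing, non-alphanumeric removal,
stopword removal, spelling out of integer tokens (so that e.g. a "T9"
vertebra and a "Ninth" vertebra share a stemmable token) and Porter
stemming.  Permutation enrichment generates all orderings of the first few
words of a label, which makes whole-label matching robust to the
word-order variation typical of UMLS-derived synonym lists
("myocardial infarction" / "infarctions myocardial").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import permutations

from ._porter import porter_stem

__all__ = [
    "NormalizerConfig",
    "normalize",
    "permute",
    "concatenate",
    "exact_forms",
    "number_to_words",
    "load_stopwords",
]

_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")
_ALPHA_DIGIT_RE = re.compile(r"(?<=[a-z])(?=[0-9])|(?<=[0-9])(?=[a-z])")

_ONES = [
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen",
]
_TENS = [
    "", "", "twenty", "thirty", "forty", "fifty", "sixty", "seventy",
    "eighty", "ninety",
]


def number_to_words(n: int) -> list[str]:
    """Spell out an integer in 0..999 as English word tokens."""
    if not 0 <= n <= 999:
        raise ValueError(f"number out of supported range 0..999: {n}")
    if n < 20:
        return [_ONES[n]]
    if n < 100:
        tens, ones = divmod(n, 10)
        return [_TENS[tens]] + ([_ONES[ones]] if ones else [])
    hundreds, rest = divmod(n, 100)
    words = [_ONES[hundreds], "hundred"]
    return words + (number_to_words(rest) if rest else [])


@lru_cache(maxsize=None)
def load_stopwords(language: str = "en") -> frozenset[str]:
    """Load the bundled one-word-per-line stopword list for a language."""
    name = f"stopwords_{language}.txt"
    try:
        text = resources.files("ontomatch.data").joinpath(name).read_text("utf-8")
    except FileNotFoundError:
        return frozenset()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class NormalizerConfig:
    """Configuration of the label filter chain.

    Parameters
    ----------
    language:
        IETF language tag; selects the stopword list.
    stopwords:
        Explicit stopword set; defaults to the bundled list for ``language``.
    stem:
        Apply Porter stemming as the final filter.
    number_to_words:
        Spell out standalone integer tokens (0-999) as words.
    max_permuted_words:
        Orderings are generated for the first this-many tokens of a label.
    """

    language: str = "en"
    stopwords: frozenset[str] = field(default=None)  # type: ignore[assignment]
    stem: bool = True
    number_to_words: bool = True
    max_permuted_words: int = 4

    def __post_init__(self) -> None:
        if self.max_permuted_words < 1:
            raise ValueError("max_permuted_words must be >= 1")
        if self.stopwords is None:
            object.__setattr__(self, "stopwords", load_stopwords(self.language))


def _pre_tokens(label: str) -> list[str]:
    """Split, lowercase and strip a raw label down to alphanumeric tokens."""
    s = label.replace("_", " ")
    s = _CAMEL_RE.sub(" ", s)
    s = s.lower()
    s = _NON_ALNUM_RE.sub(" ", s)
    s = _ALPHA_DIGIT_RE.sub(" ", s)
    return s.split()


def normalize(label: str, cfg: NormalizerConfig, *, stem: bool | None = None) -> list[str]:
    """Run a label through the full filter chain; may return [] if every
    token is a stopword."""
    tokens = [t for t in _pre_tokens(label) if t not in cfg.stopwords]
    if cfg.number_to_words:
        expanded: list[str] = []
        for t in tokens:
            if t.isdigit() and len(t) <= 3:
                expanded.extend(number_to_words(int(t)))
            else:
                expanded.append(t)
        tokens = expanded
    do_stem = cfg.stem if stem is None else stem
    if do_stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def permute(tokens: list[str], max_words: int = 4) -> set[tuple[str, ...]]:
    """All orderings of the first ``min(len, max_words)`` tokens, each
    followed by the unchanged tail; includes the original ordering."""
    if not tokens:
        return set()
    head = tokens[:max_words]
    tail = tuple(tokens[max_words:])
    return {tuple(p) + tail for p in permutations(head)}


def concatenate(tokens: list[str] | tuple[str, ...]) -> str:
    """Join tokens with no separator (exact-mode whole-label term)."""
    return "".join(tokens)


def exact_forms(label: str, cfg: NormalizerConfig) -> set[str]:
    """Exact-mode vocabulary of one label: stemmed concatenations of every
    permutation of its first ``max_permuted_words`` normalized tokens.

    Permutation happens after stopword/symbol removal and before stemming,
    so two labels that are word permutations of each other yield identical
    form sets.
    """
    tokens = normalize(label, cfg, stem=False)
    if not tokens:
        return set()
    forms = set()
    for perm in permute(tokens, cfg.max_permuted_words):
        stemmed = [porter_stem(t) for t in perm] if cfg.stem else list(perm)
        forms.add(concatenate(stemmed))
    return forms
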