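"""Key-phrase discovery from tokenized posts.

An adjacent word pair is scored by pointwise mutual information plus its
left and right branch entropies (the pair treated as a single unit when
tallying its boundary contexts): high PMI means the two words co-occur far
more than chance, and high boundary entropies mean the pair combines freely
with its surroundings — both signatures of a genuine phrase.  Probabilities
are empirical: p(x) over all tokens, p(x, y) over all ordered adjacency
slots; bigrams never span a post boundary.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CorpusCounts",
    "PhraseCandidate",
    "count_corpus",
    "pmi",
    "branch_entropy",
    "extract_key_phrases",
    "phrases_to_frame",
]


@dataclass
class CorpusCounts:
    unigrams: Counter
    bigrams: Counter  # ordered adjacent pairs
    total_tokens: int
    total_bigrams: int
    word_left: dict  # word -> Counter of words immediately to its left
    word_right: dict
    pair_left: dict  # (x, y) -> Counter of words immediately left of the pair
    pair_right: dict


def _token_lists(posts) -> list[list[str]]:
    out = []
    for p in posts:
        toks = p.tokens if hasattr(p, "tokens") else p
        out.append([str(t) for t in toks])
    return out


def count_corpus(posts, stopwords=(), synonyms=None) -> CorpusCounts:
    """Exact unigram/bigram/context counts over tokenized posts.

    ``stopwords`` are removed and ``synonyms`` (a token -> canonical-token
    mapping) are merged before counting; both default to no-ops.
    """
    stop = set(stopwords)
    syn = dict(synonyms or {})
    unigrams: Counter = Counter()
    bigrams: Counter = Counter()
    word_left: dict = {}
    word_right: dict = {}
    pair_left: dict = {}
    pair_right: dict = {}
    total_tokens = 0
    total_bigrams = 0
    for toks in _token_lists(posts):
        toks = [syn.get(t, t) for t in toks if t not in stop]
        total_tokens += len(toks)
        unigrams.update(toks)
        for i in range(len(toks) - 1):
            x, y = toks[i], toks[i + 1]
            bigrams[(x, y)] += 1
            total_bigrams += 1
            word_right.setdefault(x, Counter())[y] += 1
            word_left.setdefault(y, Counter())[x] += 1
            if i > 0:
                pair_left.setdefault((x, y), Counter())[toks[i - 1]] += 1
            if i + 2 < len(toks):
                pair_right.setdefault((x, y), Counter())[toks[i + 2]] += 1
    return CorpusCounts(
        unigrams=unigrams,
        bigrams=bigrams,
        total_tokens=total_tokens,
        total_bigrams=total_bigrams,
        word_left=word_left,
        word_right=word_right,
        pair_left=pair_left,
        pair_right=pair_right,
    )


def pmi(pair: tuple[str, str], counts: CorpusCounts, log_base: float = 2.0) -> float:
    """log( p(x,y) / (p(x) p(y)) ) for an ordered adjacent pair.

    p(x, y) is the pair's share of adjacency slots; p(x), p(y) are token
    shares.  A pair that never occurs adjacently has no PMI: KeyError.
    """
    x, y = pair
    n_xy = counts.bigrams.get((x, y), 0)
    if n_xy == 0:
        raise KeyError(f"pair never adjacent in corpus: {pair!r}")
    p_xy = n_xy / counts.total_bigrams
    p_x = counts.unigrams[x] / counts.total_tokens
    p_y = counts.unigrams[y] / counts.total_tokens
    return math.log(p_xy / (p_x * p_y), log_base)


def branch_entropy(
    unit,
    side: str,
    counts: CorpusCounts,
    log_base: float = 2.0,
) -> float:
    """Shannon entropy of the empirical context distribution beside ``unit``.

    ``unit`` is a single word or an ordered (x, y) pair treated as one unit;
    ``side`` selects the words immediately to its left or right.  A unit with
    no context on that side (only corpus-edge occurrences) has entropy 0 by
    convention.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if isinstance(unit, tuple):
        table = counts.pair_left if side == "left" else counts.pair_right
    else:
        table = counts.word_left if side == "left" else counts.word_right
    ctx = table.get(unit)
    if not ctx:
        return 0.0
    total = sum(ctx.values())
    ent = 0.0
    for c in ctx.values():
        p = c / total
        ent -= p * math.log(p, log_base)
    return ent


@dataclass(frozen=True)
class PhraseCandidate:
    pair: tuple[str, str]
    pmi: float
    e_left: float
    e_right: float
    score: float  # pmi + e_left + e_right (or pmi alone in pmi_only scoring)
    frequency: int


def extract_key_phrases(
    posts,
    top_k: int = 200,
    min_frequency: int = 2,
    stopwords=(),
    synonyms=None,
    log_base: float = 2.0,
    scoring: str = "pmi_plus_entropy",
) -> list[PhraseCandidate]:
    """Ranked phrase candidates: adjacent pairs scored by PMI + E_L + E_R.

    Pairs below ``min_frequency`` adjacent occurrences are dropped (singleton
    adjacencies have degenerate entropies).  Ordering is by descending score,
    then descending frequency, then lexicographic pair; at most ``top_k``
    candidates are returned.
    """
    if scoring not in ("pmi_plus_entropy", "pmi_only"):
        raise ValueError(f"unknown scoring: {scoring!r}")
    if top_k <= 0:
        return []
    counts = count_corpus(posts, stopwords=stopwords, synonyms=synonyms)
    if counts.total_bigrams == 0:
        return []
    out: list[PhraseCandidate] = []
    for pair, freq in counts.bigrams.items():
        if freq < min_frequency:
            continue
        v_pmi = pmi(pair, counts, log_base=log_base)
        e_l = branch_entropy(pair, "left", counts, log_base=log_base)
        e_r = branch_entropy(pair, "right", counts, log_base=log_base)
        score = v_pmi if scoring == "pmi_only" else v_pmi + e_l + e_r
        out.append(
            PhraseCandidate(
                pair=pair,
                pmi=v_pmi,
                e_left=e_l,
                e_right=e_r,
                score=score,
                frequency=freq,
            )
        )
    out.sort(key=lambda c: (-c.score, -c.frequency, c.pair))
    return out[:top_k]


def phrases_to_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [c.pair[0] for c in candidates],
            "y": [c.pair[1] for c in candidates],
            "pmi": [c.pmi for c in candidates],
            "e_left": [c.e_left for c in candidates],
            "e_right": [c.e_right for c in candidates],
            "score": [c.score for c in candidates],
            "frequency": [c.frequency for c in candidates],
        }
    )
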