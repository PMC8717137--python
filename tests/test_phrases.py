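"""Corpus counting, PMI, branch entropy and key-phrase ranking."""

import math
from collections import Counter

import numpy as np
import pytest

from ohcnet.phrases import (
    branch_entropy,
    count_corpus,
    extract_key_phrases,
    pmi,
)
from ohcnet.synth import generate_token_stream


def _random_posts(n_posts, vocab, rng, length=20):
    return [
        [str(rng.choice(vocab)) for _ in range(length)] for _ in range(n_posts)
    ]


class TestCountCorpus:
    def test_single_two_token_post(self):
        c = count_corpus([["x", "y"]])
        assert c.unigrams == Counter({"x": 1, "y": 1})
        assert c.bigrams == Counter({("x", "y"): 1})
        assert c.total_tokens == 2 and c.total_bigrams == 1

    def test_empty_corpus(self):
        c = count_corpus([])
        assert c.total_tokens == 0 and c.total_bigrams == 0

    def test_bigrams_do_not_span_posts(self):
        c = count_corpus([["a", "b"], ["c", "d"]])
        assert ("b", "c") not in c.bigrams
        assert c.total_bigrams == 2

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(4)
        posts = _random_posts(50, [f"w{i}" for i in range(12)], rng)
        c = count_corpus(posts)
        uni, bi = Counter(), Counter()
        for toks in posts:
            uni.update(toks)
            for i in range(len(toks) - 1):
                bi[(toks[i], toks[i + 1])] += 1
        assert c.unigrams == uni
        assert c.bigrams == bi
        assert c.total_tokens == sum(uni.values())
        assert c.total_bigrams == sum(len(t) - 1 for t in posts)

    def test_stopwords_and_synonyms_applied_before_counting(self):
        posts = [["the", "tumour", "treatment"], ["tumor", "treatment"]]
        c = count_corpus(posts, stopwords={"the"}, synonyms={"tumour": "tumor"})
        assert c.unigrams["tumor"] == 2
        assert "the" not in c.unigrams
        assert c.bigrams[("tumor", "treatment")] == 2


class TestPmi:
    def test_independent_pair_zero(self):
        # p(x)=p(y)=1/2 and (x,y) fills 1 of 4 adjacency slots: p(xy)=p(x)p(y)
        c = count_corpus([["x", "y"], ["y", "x"], ["x", "x"], ["y", "y"]])
        assert pmi(("x", "y"), c) == pytest.approx(
            math.log2((1 / 4) / ((1 / 2) * (1 / 2)))
        )
        assert pmi(("x", "y"), c) == pytest.approx(0.0)

    def test_hand_counted_example(self):
        c = count_corpus([["x", "y", "x", "y", "x", "y", "x", "z"]])
        assert c.unigrams["x"] == 4 and c.unigrams["y"] == 3
        assert c.bigrams[("x", "y")] == 3 and c.total_bigrams == 7
        expected = math.log2((3 / 7) / ((4 / 8) * (3 / 8)))
        assert pmi(("x", "y"), c) == pytest.approx(expected)
        assert expected == pytest.approx(1.1926, abs=5e-4)

    def test_never_adjacent_pair_excluded(self):
        c = count_corpus([["x", "y"]])
        with pytest.raises(KeyError):
            pmi(("y", "x"), c)

    def test_alternating_corpus_pair_is_maximal(self):
        toks = ["p", "q"] * 30
        c = count_corpus([toks])
        scores = {pair: pmi(pair, c) for pair in c.bigrams}
        assert max(scores, key=scores.get) in {("p", "q"), ("q", "p")}

    def test_invariant_under_corpus_duplication(self):
        rng = np.random.default_rng(6)
        posts = _random_posts(10, ["a", "b", "c", "d"], rng, length=12)
        c1 = count_corpus(posts)
        c2 = count_corpus(posts + posts)
        for pair in c1.bigrams:
            assert pmi(pair, c1) == pytest.approx(pmi(pair, c2), abs=1e-12)


class TestBranchEntropy:
    def test_deterministic_context_zero(self):
        c = count_corpus([["w", "only"], ["w", "only"], ["w", "only"]])
        assert branch_entropy("w", "right", c) == 0.0

    def test_uniform_four_contexts_two_bits(self):
        posts = [["w", x] for x in ["a", "b", "c", "d"]]
        c = count_corpus(posts)
        assert branch_entropy("w", "right", c) == pytest.approx(2.0)

    def test_no_context_side_zero_by_convention(self):
        c = count_corpus([["w", "a"]])
        assert branch_entropy("w", "left", c) == 0.0

    def test_pair_as_unit_contexts(self):
        posts = [["l1", "x", "y", "r1"], ["l2", "x", "y", "r1"]]
        c = count_corpus(posts)
        assert branch_entropy(("x", "y"), "left", c) == pytest.approx(1.0)
        assert branch_entropy(("x", "y"), "right", c) == 0.0

    def test_matches_tally_oracle_and_uniform_bound(self):
        rng = np.random.default_rng(7)
        posts = _random_posts(40, ["a", "b", "c", "d", "e"], rng, length=15)
        c = count_corpus(posts)
        for w in ["a", "b", "c"]:
            tally = Counter()
            for toks in posts:
                for i, t in enumerate(toks[:-1]):
                    if t == w:
                        tally[toks[i + 1]] += 1
            total = sum(tally.values())
            expected = -sum(
                (v / total) * math.log2(v / total) for v in tally.values()
            )
            got = branch_entropy(w, "right", c)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got <= math.log2(len(tally)) + 1e-12


class TestExtractKeyPhrases:
    def test_planted_collocation_ranks_first(self):
        stream = generate_token_stream(40, [(("alpha", "beta"), 50)], 4000, seed=3)
        ranked = extract_key_phrases([stream], top_k=20)
        assert ranked[0].pair == ("alpha", "beta")

    def test_top_k_zero(self):
        assert extract_key_phrases([["a", "b"]], top_k=0) == []

    def test_keyword_budget(self):
        rng = np.random.default_rng(11)
        posts = _random_posts(400, [f"w{i}" for i in range(50)], rng)
        ranked = extract_key_phrases(posts, top_k=200)
        assert len(ranked) <= 200
        assert len({w for c in ranked for w in c.pair}) <= 400

    def test_min_frequency_drops_singletons(self):
        posts = [["a", "b"], ["c", "d"], ["c", "d"]]
        ranked = extract_key_phrases(posts, min_frequency=2)
        assert [c.pair for c in ranked] == [("c", "d")]

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        posts = _random_posts(100, [f"w{i}" for i in range(20)], rng)
        a = extract_key_phrases(posts, top_k=50)
        b = extract_key_phrases(posts, top_k=50)
        assert a == b

    def test_score_components_sum(self):
        stream = generate_token_stream(30, [(("u", "v"), 20)], 1500, seed=9)
        ranked = extract_key_phrases([stream], top_k=500, min_frequency=2)
        for c in ranked:
            assert c.score == pytest.approx(c.pmi + c.e_left + c.e_right)
        pmi_only = extract_key_phrases(
            [stream], top_k=500, min_frequency=2, scoring="pmi_only"
        )
        for c in pmi_only:
            assert c.score == pytest.approx(c.pmi)
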