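"""Katz back-off model against an independent brute-force implementation,
cache-model algebra, interpolation, scoring and the ARPA round trip."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gazepred as gp
from gazepred import ngram as ng
from gazepred.exceptions import (DegenerateCacheError, ParameterError)


# ---------------------------------------------------------------------------
# Straight-line textbook reference implementation (kept deliberately naive
# and independent of gazepred.ngram internals)
# ---------------------------------------------------------------------------

class BruteKatz:
    """Enumerative Katz/Good-Turing reference for tiny corpora.

    Orders >= 2 use Good-Turing discounted counts r* = (r+1) N_{r+1} / N_r
    for r <= gt_max_r (skipped when undefined or not strictly below r);
    order 1 is the maximum-likelihood unigram.  Back-off weights are
    computed from first principles per context.
    """

    def __init__(self, sentences, n_order, gt_max_r=5):
        self.n = n_order
        self.gt_max_r = gt_max_r
        self.vocab = sorted({w for s in sentences for w in s})
        pad = ["<s>"] * (n_order - 1)
        self.grams = {k: Counter() for k in range(1, n_order + 1)}
        for s in sentences:
            seq = pad + list(s)
            for i in range(len(pad), len(seq)):
                for k in range(1, n_order + 1):
                    if i - k + 1 >= 0:
                        self.grams[k][tuple(seq[i - k + 1:i + 1])] += 1
        self.disc = {}
        for k in range(2, n_order + 1):
            n_r = Counter(self.grams[k].values())
            d = {}
            for r in range(1, gt_max_r + 1):
                if n_r[r] > 0 and n_r[r + 1] > 0:
                    r_star = (r + 1) * n_r[r + 1] / n_r[r]
                    if 0 < r_star < r:
                        d[r] = r_star
            self.disc[k] = d

    def _dc(self, k, r):
        return self.disc[k].get(r, float(r)) if k >= 2 else float(r)

    def p(self, word, context):
        context = tuple(context)[-(self.n - 1):] if self.n > 1 else ()
        return self._p(word, context)

    def _p(self, word, context):
        if not context:
            total = sum(self.grams[1].values())
            return self.grams[1][(word,)] / total
        k = len(context) + 1
        ctx_total = sum(c for g, c in self.grams[k].items()
                        if g[:-1] == context)
        if ctx_total == 0:
            return self._p(word, context[1:])
        c = self.grams[k][context + (word,)]
        seen = [(g[-1], c) for g, c in self.grams[k].items()
                if g[:-1] == context]
        seen_mass = sum(self._dc(k, c) / ctx_total for _, c in seen)
        denom = 1.0 - sum(self._p(w, context[1:]) for w, _ in seen)
        if c > 0:
            if denom <= 1e-12:
                # every vocabulary word seen under this context: the
                # discount has no unseen continuation to go to; renormalize
                return (self._dc(k, c) / ctx_total) / seen_mass
            return self._dc(k, c) / ctx_total
        left = 1.0 - seen_mass
        alpha = left / denom if left > 0 and denom > 1e-12 else 0.0
        return alpha * self._p(word, context[1:])


TINY_SENTENCES = [  # 20 tokens, 3-word vocabulary, repeated bigrams
    ["a", "b", "a", "c", "a", "b"],
    ["b", "a", "a", "c", "b", "a", "b"],
    ["c", "a", "b", "a", "c", "a", "a"],
]


class TestKatzOracle:
    @pytest.mark.parametrize("n_order", [2, 3])
    def test_matches_brute_force_everywhere(self, n_order):
        model = ng.KatzNgramModel(n_order=n_order, min_count=1).fit(
            TINY_SENTENCES)
        brute = BruteKatz(TINY_SENTENCES, n_order)
        vocab = ["a", "b", "c"]
        contexts = [()]
        for k in range(1, n_order):
            contexts += list(itertools.product(vocab + ["<s>"], repeat=k))
        for ctx in contexts:
            total = 0.0
            for w in vocab:
                p_model = model.p(w, ctx)
                p_brute = brute.p(w, ctx)
                assert p_model == pytest.approx(p_brute, abs=1e-12), (ctx, w)
                total += p_model
            assert total == pytest.approx(1.0, abs=1e-8), ctx

    def test_unigram_is_mle(self):
        model = ng.KatzNgramModel(n_order=1, min_count=1).fit([["a", "a", "b"]])
        assert model.p("a") == pytest.approx(2 / 3)
        assert model.p("b") == pytest.approx(1 / 3)

    def test_good_turing_discount_formula(self):
        # bigram counts-of-counts N_1 = 3, N_2 = 1 -> r*(1) = 2 * 1/3
        model = ng.KatzNgramModel(n_order=2, min_count=1).fit(
            [["x", "y"], ["x", "z"], ["w", "v"], ["x", "y"]])
        n_r = Counter(model.counts[2].values())
        assert n_r[1] == 3 and n_r[2] == 1
        assert model.discounted_count(2, 1) == pytest.approx(2 / 3)

    def test_unseen_context_backs_off_to_unigram(self):
        model = ng.KatzNgramModel(n_order=3, min_count=1).fit(TINY_SENTENCES)
        # a context that never occurs in training backs off transparently
        assert model.p("a", ("c", "c")) == pytest.approx(
            model.p("a", ("c",)), abs=1e-12)

    def test_high_count_ngram_is_count_ratio(self):
        sents = [["p", "q"]] * 10 + [["p", "r"]] * 2
        model = ng.KatzNgramModel(n_order=2, min_count=1, gt_max_r=5).fit(sents)
        # count 10 > gt_max_r: undiscounted ratio 10/12
        assert model.p("q", ("p",)) == pytest.approx(10 / 12)

    def test_normalization_on_sampled_language(self, lang, train_corpus):
        model = ng.KatzNgramModel(n_order=3).fit(train_corpus)
        rng = np.random.default_rng(0)
        vocab = sorted(model.vocab)
        contexts = [(), (vocab[0],), tuple(rng.choice(vocab, 2))]
        for ctx in contexts:
            total = sum(model.p(w, ctx) for w in vocab)
            assert total == pytest.approx(1.0, abs=1e-8)


class TestCache:
    def test_mle_when_delta_zero(self):
        cache = ng.CacheModel(vocab=5, delta=0.0)
        for w in ["a"] * 2 + ["b"] * 8:
            cache.update(w)
        assert cache.p("a") == pytest.approx(0.2)

    def test_additive_formula(self):
        cache = ng.CacheModel(vocab=4, delta=0.5)
        for w in ["a", "a", "a", "b", "b", "c", "d", "b", "c", "d"]:
            cache.update(w)
        assert cache.p("a") == pytest.approx(3.5 / 12, abs=1e-12)

    def test_empty_cache_is_uniform(self):
        cache = ng.CacheModel(vocab=1000, delta=0.00015)
        assert cache.p("anything") == pytest.approx(1 / 1000, abs=1e-15)

    def test_degenerate_cache_raises(self):
        cache = ng.CacheModel(vocab=10, delta=0.0)
        with pytest.raises(DegenerateCacheError):
            cache.p("a")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_normalizes_over_vocabulary(self, seed):
        rng = np.random.default_rng(seed)
        v = int(rng.integers(2, 40))
        vocab = [f"w{i}" for i in range(v)]
        cache = ng.CacheModel(vocab=set(vocab),
                              delta=float(rng.uniform(1e-5, 1.0)))
        for w in rng.choice(vocab, size=rng.integers(1, 60)):
            cache.update(str(w))
        total = sum(cache.p(w) for w in vocab)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestInterpolation:
    @pytest.mark.parametrize("lam,pc,pn,expected", [
        (0.0, 0.9, 0.1, 0.1),
        (1.0, 0.9, 0.1, 0.9),
        (0.15, 0.2, 0.1, 0.115),
    ])
    def test_linear_interpolation(self, lam, pc, pn, expected):
        assert ng.p_combined(pc, pn, lam) == pytest.approx(expected, abs=1e-12)

    def test_lambda_out_of_range(self):
        with pytest.raises(ParameterError):
            ng.p_combined(0.5, 0.5, 1.5)


class TestScoreText:
    @pytest.fixture
    def model(self, train_corpus):
        return ng.KatzNgramModel(n_order=3).fit(train_corpus)

    def test_first_token_cache_is_uniform(self, model, reading_corpus):
        scores = ng.score_text(model, reading_corpus, delta=0.001, lam=0.2)
        first = scores.groupby("text_id").first()
        v0 = len(model.train_vocab | set())
        # first token of each text: empty cache -> 1/V (training vocab only)
        assert np.allclose(first["p_cache"], 1 / v0)

    def test_lambda_zero_equals_pure_ngram(self, model, reading_corpus):
        scores = ng.score_text(model, reading_corpus, delta=0.001, lam=0.0)
        assert np.allclose(scores["p_combined"], scores["p_ngram"])

    def test_repetition_boosts_combined_score(self, model):
        rep = gp.build_corpus(["kiko zupa mira. kiko zupa mira. kiko zupa mira."])
        with_cache = ng.score_text(model, rep, delta=1e-4, lam=0.3)
        without = ng.score_text(model, rep, delta=1e-4, lam=0.0)
        later = rep.tokens["idx_in_text"] >= 3  # every word already read once
        assert (with_cache["p_combined"][later]
                > without["p_combined"][later]).all()

    def test_cache_sees_only_previous_text(self, model, reading_corpus):
        """Score-then-update: a token's own occurrence is not in its cache."""
        scores = ng.score_text(model, reading_corpus, delta=1e-4, lam=1.0)
        comp = ng.score_components(model, reading_corpus)
        tok = reading_corpus.tokens
        first_occurrence = ~tok.duplicated(subset=["text_id", "norm"])
        assert (comp["cache_count"][first_occurrence.to_numpy()] == 0).all()
        assert len(scores) == len(tok)


class TestGridSearch:
    def test_single_cell(self, train_corpus, reading_corpus):
        model = ng.KatzNgramModel(n_order=2).fit(train_corpus)
        table, best = ng.grid_search(model, reading_corpus,
                                     lambda p: float(np.mean(np.log(p))),
                                     [0.1], [0.5])
        assert len(table) == 1
        assert best["delta"] == 0.1 and best["lambda"] == 0.5

    def test_default_grids_contain_operating_point(self):
        assert any(np.isclose(d, 0.00015) for d in ng.DEFAULT_DELTA_GRID)
        assert any(np.isclose(l, 0.15) for l in ng.DEFAULT_LAMBDA_GRID)
        assert min(ng.DEFAULT_DELTA_GRID) <= 0.00015 <= max(ng.DEFAULT_DELTA_GRID)
        assert min(ng.DEFAULT_LAMBDA_GRID) <= 0.15 <= max(ng.DEFAULT_LAMBDA_GRID)

    def test_cache_helps_on_repetitive_text(self, lang, train_corpus):
        """On text with heavy word repetition the best lambda is > 0 when the
        criterion rewards in-text recurrence."""
        model = ng.KatzNgramModel(n_order=2).fit(train_corpus)
        # build a test text that reuses rare words often
        rare = [w for w in lang.vocabulary[-5:]]
        text = ". ".join(" ".join(rare) for _ in range(20)) + "."
        rep = gp.build_corpus([text])
        # geometric-mean probability: positive criterion, higher is better
        table, best = ng.grid_search(
            model, rep, lambda p: float(np.exp(np.mean(np.log(p)))),
            [1e-4], [0.0, 0.2, 0.4, 0.6])
        assert best["lambda"] > 0

    def test_empty_grid_rejected(self, train_corpus, reading_corpus):
        model = ng.KatzNgramModel(n_order=2).fit(train_corpus)
        with pytest.raises(ParameterError):
            ng.grid_search(model, reading_corpus, np.mean, [], [0.1])


class TestArpa:
    def test_round_trip_probabilities(self, train_corpus, reading_corpus,
                                      tmp_path):
        model = ng.KatzNgramModel(n_order=3).fit(train_corpus)
        path = ng.write_arpa(model, tmp_path / "m.arpa")
        back = ng.read_arpa(path)
        words = reading_corpus.tokens["norm"].tolist()[:120]
        for i in range(len(words)):
            for ctx_len in (0, 1, 2):
                ctx = words[max(0, i - ctx_len):i]
                assert back.p(words[i], ctx) == pytest.approx(
                    model.p(words[i], ctx), rel=1e-9)

    def test_header_counts_match_sections(self, train_corpus, tmp_path):
        model = ng.KatzNgramModel(n_order=2).fit(train_corpus)
        path = ng.write_arpa(model, tmp_path / "m.arpa")
        text = path.read_text().splitlines()
        declared = {int(l.split("=")[0].split()[1]): int(l.split("=")[1])
                    for l in text if l.startswith("ngram ")}
        for k, n in declared.items():
            start = text.index(f"\\{k}-grams:") + 1
            count = 0
            for line in text[start:]:
                if not line.strip() or line.startswith("\\"):
                    break
                count += 1
            assert count == n
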