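"""Katz back-off N-gram LM, additive-smoothed cache, and their interpolation.

The corpus model is a Katz back-off N-gram with Good-Turing discounting:
counts ``r <= gt_max_r`` are replaced by ``r* = (r + 1) N_{r+1} / N_r``
(counts-of-counts), the freed mass of each context is redistributed to
unseen continuations through back-off weights ``alpha(context)``, and the
order-1 distribution is the maximum-likelihood unigram over the closed
vocabulary (singleton training words are mapped to ``<unk>`` so held-out
text never receives zero probability).

The cache model is an additively smoothed unigram over the text read so
far::

    p_additive(w) = (c(w) + delta) / (delta * V + N)

with ``c(w)`` the running count, ``N`` the tokens read so far and ``V`` the
number of unique words (training vocabulary plus words seen so far in the
test text).  The two are combined by linear interpolation::

    p = lambda * p_cache + (1 - lambda) * p_ngram

The cache is reset at each text start and updated with each token only
*after* the token is scored, so a word never predicts itself.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import TokenizedCorpus
from .exceptions import DegenerateCacheError, ParameterError

logger = logging.getLogger(__name__)

BOS = "<s>"
UNK = "<unk>"

#: Grid bounds used in the delta/lambda search (cache constant and
#: interpolation weight); the selected operating point delta=0.00015,
#: lambda=0.15 lies inside.
DEFAULT_DELTA_GRID = (5e-5, 1e-4, 1.5e-4, 2e-4, 3e-4, 4e-4, 5e-4)
DEFAULT_LAMBDA_GRID = tuple(np.linspace(0.05, 0.6, 12))
DEFAULT_DELTA = 0.00015
DEFAULT_LAMBDA = 0.15


class KatzNgramModel:
    """Katz back-off model of order ``n_order`` (the reference order is 4).

    ``gt_max_r`` bounds Good-Turing discounting: k-gram counts above it are
    trusted as-is.  Degenerate counts-of-counts (``N_{r+1} = 0`` for a
    needed ``r``, or a discount that fails ``r* < r``) fall back to no
    discount at that count, logged once per order.
    """

    def __init__(self, n_order: int = 4, gt_max_r: int = 5,
                 min_count: int = 2) -> None:
        if n_order < 1:
            raise ParameterError(f"n_order must be >= 1, got {n_order}")
        self.n_order = n_order
        self.gt_max_r = gt_max_r
        self.min_count = min_count  # words below this train as <unk>
        self.counts: list[Counter] = [Counter() for _ in range(n_order + 1)]
        self.context_totals: list[dict] = [{} for _ in range(n_order + 1)]
        # context -> list of (word, count) continuations, per order
        self.continuations: list[dict[tuple, list]] = [{} for _ in range(n_order + 1)]
        self.discount: list[dict[int, float]] = [{} for _ in range(n_order + 1)]
        self.vocab: set[str] = set()        # LM event vocabulary (incl. <unk>)
        self.train_vocab: set[str] = set()  # surface types incl. singletons
        self.unigram_total = 0
        self._alpha_cache: dict[tuple, float] = {}

    # -- training -----------------------------------------------------------

    def fit(self, corpus_or_sentences: TokenizedCorpus | Iterable[Sequence[str]]
            ) -> "KatzNgramModel":
        if isinstance(corpus_or_sentences, TokenizedCorpus):
            sentences = list(corpus_or_sentences.sentences())
        else:
            sentences = [list(s) for s in corpus_or_sentences]
        if not any(sentences):
            raise ParameterError("training corpus is empty")
        raw_uni = Counter(w for s in sentences for w in s)
        self.train_vocab = set(raw_uni)
        keep = {w for w, c in raw_uni.items() if c >= self.min_count}
        if not keep:  # tiny corpora: keep everything rather than all-<unk>
            keep = set(raw_uni)
        mapped = [[w if w in keep else UNK for w in s] for s in sentences]
        self.vocab = keep | {UNK}
        pad = [BOS] * (self.n_order - 1)
        for sent in mapped:
            padded = pad + sent
            for i in range(len(pad), len(padded)):
                for k in range(1, self.n_order + 1):
                    if i - k + 1 < 0:
                        continue
                    self.counts[k][tuple(padded[i - k + 1: i + 1])] += 1
        for k in range(2, self.n_order + 1):
            totals: dict = {}
            conts: dict[tuple, list] = {}
            for gram, c in self.counts[k].items():
                ctx = gram[:-1]
                totals[ctx] = totals.get(ctx, 0) + c
                conts.setdefault(ctx, []).append((gram[-1], c))
            self.context_totals[k] = totals
            self.continuations[k] = conts
            self.discount[k] = self._gt_discounts(k)
        self.unigram_total = sum(self.counts[1].values())
        self._alpha_cache.clear()
        return self

    def _gt_discounts(self, k: int) -> dict[int, float]:
        n_r = Counter(self.counts[k].values())
        disc: dict[int, float] = {}
        for r in range(1, self.gt_max_r + 1):
            if n_r.get(r, 0) == 0 or n_r.get(r + 1, 0) == 0:
                logger.debug("order %d: no N_%d/N_%d; count %d undiscounted",
                             k, r, r + 1, r)
                continue
            r_star = (r + 1) * n_r[r + 1] / n_r[r]
            if not 0.0 < r_star < r + 1e-12 or r_star >= r:
                logger.debug("order %d: r*=%.4f invalid for r=%d; undiscounted",
                             k, r_star, r)
                continue
            disc[r] = r_star
        return disc

    def discounted_count(self, k: int, r: int) -> float:
        return self.discount[k].get(r, float(r)) if k >= 2 else float(r)

    # -- probabilities ------------------------------------------------------

    def _map(self, word: str) -> str:
        return word if word in self.vocab else UNK

    def p_unigram(self, word: str) -> float:
        return self.counts[1][(self._map(word),)] / self.unigram_total

    def _ctx_norm(self, context: tuple) -> tuple[float, float]:
        """(back-off weight alpha, seen-probability scale) for a context.

        Normally the scale is 1 and alpha redistributes the discounted mass
        over unseen continuations.  When every vocabulary word has been
        seen under the context there are no unseen continuations to absorb
        the discount, so the seen probabilities are rescaled to sum to 1
        (alpha is then irrelevant).
        """
        if context in self._alpha_cache:
            return self._alpha_cache[context]
        k = len(context) + 1
        total = self.context_totals[k][context]
        seen_mass = 0.0
        backoff_mass = 0.0
        for word, c in self.continuations[k][context]:
            seen_mass += self.discounted_count(k, c) / total
            backoff_mass += self._p(word, context[1:])
        left = 1.0 - seen_mass
        denom = 1.0 - backoff_mass
        if denom <= 1e-12:  # full vocabulary coverage under this context
            out = (0.0, 1.0 / seen_mass if seen_mass > 0 else 1.0)
        elif left <= 0:
            out = (0.0, 1.0)
        else:
            out = (left / denom, 1.0)
        self._alpha_cache[context] = out
        return out

    def _p(self, word: str, context: tuple) -> float:
        if not context:
            return self.p_unigram(word)
        k = len(context) + 1
        total = self.context_totals[k].get(context)
        if total is None:
            return self._p(word, context[1:])
        alpha, scale = self._ctx_norm(context)
        c = self.counts[k].get(context + (word,), 0)
        if c > 0:
            return scale * self.discounted_count(k, c) / total
        return alpha * self._p(word, context[1:])

    def p(self, word: str, context: Sequence[str] = ()) -> float:
        """Katz probability of ``word`` given the preceding tokens.

        The context is trimmed to the last ``n_order - 1`` tokens; words
        outside the LM vocabulary (in the context or as target) are mapped
        to ``<unk>``.  ``<s>`` markers in the context are kept as-is, so a
        sentence-initial context of ``<s>`` padding matches training.
        """
        ctx = tuple(context)[-(self.n_order - 1):] if self.n_order > 1 else ()
        ctx = tuple(w if w == BOS else self._map(w) for w in ctx)
        return self._p(self._map(word), ctx)

    def conditional_distribution(self, context: Sequence[str]) -> dict[str, float]:
        """P(. | context) enumerated over the vocabulary (diagnostics/tests)."""
        return {w: self.p(w, context) for w in sorted(self.vocab)}


# ---------------------------------------------------------------------------
# Cache model (additive smoothing over the text read so far)
# ---------------------------------------------------------------------------

@dataclass
class CacheModel:
    """Running unigram over previously read text with additive smoothing.

    ``vocab`` may be a set (grows as novel test words arrive) or a fixed
    integer vocabulary size.
    """

    vocab: set[str] | int
    delta: float = DEFAULT_DELTA
    counts: Counter = field(default_factory=Counter)
    n_cache: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ParameterError(f"delta must be >= 0, got {self.delta}")
        if isinstance(self.vocab, set):
            self.vocab = set(self.vocab)

    @property
    def vocab_size(self) -> int:
        return self.vocab if isinstance(self.vocab, int) else len(self.vocab)

    def p(self, word: str) -> float:
        """Eq-style additive estimate ``(c(w) + delta) / (delta V + N)``."""
        denom = self.delta * self.vocab_size + self.n_cache
        if denom == 0:
            raise DegenerateCacheError(
                "cache probability undefined: delta = 0 and empty cache")
        return (self.counts[word] + self.delta) / denom

    def update(self, word: str) -> None:
        if isinstance(self.vocab, set):
            self.vocab.add(word)
        self.counts[word] += 1
        self.n_cache += 1


def p_combined(p_cache: float, p_ngram: float,
               lam: float = DEFAULT_LAMBDA) -> float:
    """Linear interpolation ``lambda * p_cache + (1 - lambda) * p_ngram``."""
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    return lam * p_cache + (1.0 - lam) * p_ngram


# ---------------------------------------------------------------------------
# Per-token scoring over running text
# ---------------------------------------------------------------------------

def score_components(model: KatzNgramModel, corpus: TokenizedCorpus
                     ) -> pd.DataFrame:
    """Per-token N-gram probabilities and cache state, delta/lambda-free.

    The cache state recorded for token *i* is the state *before* the token
    is read (score-then-update), so any (delta, lambda) combination can be
    evaluated afterwards without re-scoring.  The N-gram context is the
    preceding words of the same sentence, <s>-padded; the cache spans the
    whole text read so far.
    """
    rows = []
    for text_id, grp in corpus.tokens.groupby("text_id", sort=True):
        grp = grp.sort_values("idx_in_text")
        cache_counts: Counter = Counter()
        seen: set[str] = set(model.train_vocab)
        n_cache = 0
        pad = [BOS] * (model.n_order - 1)
        sent_ctx: list[str] = list(pad)
        cur_sent = None
        for sent_id, idx, word in zip(grp["sent_id"], grp["idx_in_text"],
                                      grp["norm"]):
            if sent_id != cur_sent:
                cur_sent = sent_id
                sent_ctx = list(pad)
            p_ng = model.p(word, sent_ctx)
            seen.add(word)  # novel test words join the cache vocabulary
            rows.append((text_id, idx, word, p_ng,
                         cache_counts[word], n_cache, len(seen)))
            cache_counts[word] += 1
            n_cache += 1
            sent_ctx.append(word)
    return pd.DataFrame(rows, columns=[
        "text_id", "idx_in_text", "norm", "p_ngram",
        "cache_count", "n_cache", "v_cache"])


def combine_scores(components: pd.DataFrame, delta: float = DEFAULT_DELTA,
                   lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Interpolated N-gram+cache probabilities from precomputed components."""
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    if delta < 0:
        raise ParameterError(f"delta must be >= 0, got {delta}")
    denom = delta * components["v_cache"].to_numpy() + components["n_cache"].to_numpy()
    if np.any(denom == 0):
        raise DegenerateCacheError(
            "cache probability undefined: delta = 0 and empty cache")
    p_cache = (components["cache_count"].to_numpy() + delta) / denom
    return lam * p_cache + (1.0 - lam) * components["p_ngram"].to_numpy()


def score_text(model: KatzNgramModel, corpus: TokenizedCorpus,
               delta: float = DEFAULT_DELTA, lam: float = DEFAULT_LAMBDA
               ) -> pd.DataFrame:
    """N-gram+cache probability for every token of held-out text.

    Returns a table aligned to the corpus tokens with columns ``p_ngram``,
    ``p_cache`` and ``p_combined``.
    """
    comp = score_components(model, corpus)
    combined = combine_scores(comp, delta, lam)
    denom = delta * comp["v_cache"].to_numpy() + comp["n_cache"].to_numpy()
    out = comp[["text_id", "idx_in_text", "p_ngram"]].copy()
    out["p_cache"] = (comp["cache_count"].to_numpy() + delta) / denom
    out["p_combined"] = combined
    return out


def grid_search(model: KatzNgramModel, corpus: TokenizedCorpus, eval_fn,
                delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
                lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
                ) -> tuple[pd.DataFrame, dict]:
    """Evaluate ``eval_fn(p_combined) -> criterion`` over the full grid.

    Returns the full (delta, lambda, criterion) table and the argmax cell
    (maximum absolute criterion, matching optimization on |t| or |r|).
    """
    if not len(delta_grid) or not len(lambda_grid):
        raise ParameterError("delta and lambda grids must be non-empty")
    comp = score_components(model, corpus)
    rows = []
    for d in delta_grid:
        for lam in lambda_grid:
            crit = float(eval_fn(combine_scores(comp, d, lam)))
            rows.append({"delta": float(d), "lambda": float(lam),
                         "criterion": crit})
    table = pd.DataFrame(rows)
    best = table.iloc[int(table["criterion"].abs().idxmax())].to_dict()
    return table, best


# ---------------------------------------------------------------------------
# ARPA back-off format
# ---------------------------------------------------------------------------

def _arpa_entries(model: KatzNgramModel):
    """(order -> {gram: (log10 p, log10 alpha | None)}) for ARPA export."""
    n = model.n_order
    entries: list[dict] = [dict() for _ in range(n + 1)]
    contexts: set[tuple] = set()
    for k in range(2, n + 1):
        contexts.update(model.context_totals[k].keys())
    for k in range(1, n + 1):
        grams = set(model.counts[k])
        grams.update(c for c in contexts if len(c) == k)
        for gram in grams:
            if gram in model.counts[k] and gram[-1] != BOS:
                logp = math.log10(model._p(gram[-1], gram[:-1]))
            else:
                logp = -99.0  # context-only entry (e.g. <s> padding)
            if k < n and gram in model.context_totals[k + 1]:
                alpha = model._ctx_norm(gram)[0]
                logb = math.log10(alpha) if alpha > 0 else -99.0
            else:
                logb = None
            entries[k][gram] = (logp, logb)
    return entries


def write_arpa(model: KatzNgramModel, path: str | Path) -> Path:
    path = Path(path)
    entries = _arpa_entries(model)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for k in range(1, model.n_order + 1):
            fh.write(f"ngram {k}={len(entries[k])}\n")
        for k in range(1, model.n_order + 1):
            fh.write(f"\n\\{k}-grams:\n")
            for gram in sorted(entries[k]):
                logp, logb = entries[k][gram]
                line = f"{logp:.12g}\t{' '.join(gram)}"
                if logb is not None:
                    line += f"\t{logb:.12g}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")
    return path


class ArpaModel:
    """Back-off model reconstructed from an ARPA file (cross-check path)."""

    def __init__(self, logp: list[dict], logb: list[dict], n_order: int,
                 vocab: set[str]):
        self.logp = logp
        self.logb = logb
        self.n_order = n_order
        self.vocab = vocab

    def p(self, word: str, context: Sequence[str] = ()) -> float:
        word = word if word in self.vocab else UNK
        ctx = tuple(w if (w in self.vocab or w == BOS) else UNK
                    for w in tuple(context)[-(self.n_order - 1):])
        return 10.0 ** self._logp(word, ctx)

    def _logp(self, word: str, ctx: tuple) -> float:
        k = len(ctx) + 1
        gram = ctx + (word,)
        lp = self.logp[k].get(gram)
        if lp is not None and lp > -99.0:
            return lp
        if not ctx:
            return lp if lp is not None else -99.0
        back = self.logb[k - 1].get(ctx, 0.0)
        return back + self._logp(word, ctx[1:])


def read_arpa(path: str | Path) -> ArpaModel:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    n_order = 0
    logp: list[dict] = [dict()]
    logb: list[dict] = [dict()]
    section = 0
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("ngram "):
            n_order = max(n_order, int(ln.split("=")[0].split()[1]))
            while len(logp) <= n_order:
                logp.append(dict())
                logb.append(dict())
        elif ln.endswith("-grams:"):
            section = int(ln[1:].split("-")[0])
        elif ln == "\\end\\":
            break
        elif section and not ln.startswith("\\"):
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if "\t" in ln:
                words = tuple(parts[1].split())
                rest = [parts[0]] + parts[2:]
            else:
                words = tuple(parts[1:1 + section])
                rest = [parts[0]] + parts[1 + section:]
            logp[section][words] = float(rest[0])
            if len(rest) > 1:
                logb[section][words] = float(rest[1])
    vocab = {g[0] for g in logp[1] if g[0] not in (BOS,)}
    return ArpaModel(logp, logb, n_order, vocab)
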