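"""Word-embedding spaces and cosine-similarity context predictability.

Two sources of vectors are supported: LSA trained in-package (tf-idf
word-by-document matrix, rank-d truncated SVD, word vectors = left singular
vectors scaled by singular values) and externally trained vectors loaded
from the word2vec text format (skipgram/FastText training itself is out of
scope — any file in that format is accepted).

The context predictability of the token at position *i* is the cosine
similarity between its vector and its previous-``w``-word context, either
as the mean of pairwise cosines (``mean`` variant) or as the cosine with
the summed context vector (``resultant`` variant).  With the
``without``-stopwords policy the window gathers the ``w`` previous content
words.  Out-of-vocabulary context words are skipped (they neither dilute
nor inflate the score); a token whose usable context is empty, or which is
itself out of vocabulary, gets a missing score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .corpus import TokenizedCorpus
from .exceptions import FormatError, ParameterError

DEFAULT_DIMENSIONS = 300
#: Default context-window sweep; the reference operating points (9 for the
#: LSA score, 50 for the FastText score) are members.
DEFAULT_WINDOWS = (1, 2, 3, 5, 7, 9, 13, 20, 30, 50, 75, 100, 150)


@dataclass
class EmbeddingSpace:
    """Vocabulary plus a |V| x d real matrix of word vectors."""

    vocabulary: list[str]
    vectors: np.ndarray
    provenance: str = "loaded"  # "lsa" | "loaded"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise ParameterError("vector matrix must be |V| x d")
        if self.vectors.shape[1] < 1:
            raise ParameterError("embedding dimension must be >= 1")
        self.index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index[word]]

    def cosine(self, a: str, b: str) -> float:
        return _cos(self.vector(a), self.vector(b))


def _cos(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


# ---------------------------------------------------------------------------
# LSA training
# ---------------------------------------------------------------------------

def train_lsa(corpus: TokenizedCorpus, d: int = DEFAULT_DIMENSIONS,
              tfidf: bool = True, idf: str = "smooth") -> EmbeddingSpace:
    """LSA embedding from the word-by-document matrix of a corpus.

    tf is the raw count of word *w* in document *j*; idf is
    ``log(1 + n_docs / doc_frequency)`` by default (``idf="smooth"``),
    which stays strictly positive for words present in every document — the
    textbook ``log(n_docs / doc_frequency)`` (``idf="classic"``) zeroes
    such words out entirely, which on small document collections leaves
    much of the vocabulary without a vector.  The weighted matrix is
    decomposed by SVD and word vectors are the rows of ``U_d * S_d``;
    ``d`` beyond the matrix rank is clamped with a warning.  Deterministic
    up to the sign of each singular vector (cosines are sign-invariant).
    """
    if idf not in ("smooth", "classic"):
        raise ParameterError(f"unknown idf variant {idf!r}")
    tok = corpus.tokens
    n_docs = corpus.n_texts
    if n_docs < 2:
        raise ParameterError("LSA needs at least 2 documents")
    vocab = sorted(tok["norm"].unique())
    windex = {w: i for i, w in enumerate(vocab)}
    rows = tok["norm"].map(windex).to_numpy()
    cols = tok["text_id"].to_numpy()
    counts = sp.coo_matrix(
        (np.ones(len(tok)), (rows, cols)),
        shape=(len(vocab), n_docs)).tocsr()
    counts.sum_duplicates()
    mat = counts.astype(float)
    if tfidf:
        df_count = np.asarray((counts > 0).sum(axis=1)).ravel()
        if idf == "smooth":
            weights = np.log1p(n_docs / df_count)
        else:
            weights = np.log(n_docs / df_count)
        mat = sp.diags(weights) @ mat
    max_rank = min(mat.shape)
    k = min(d, max_rank)
    if k < d:
        import warnings
        warnings.warn(f"LSA dimension clamped from {d} to matrix rank bound {k}")
    if k == max_rank:
        u, s, _ = np.linalg.svd(mat.toarray(), full_matrices=False)
        u, s = u[:, :k], s[:k]
    else:
        # deterministic start vector; svds returns ascending singular values
        u, s, _ = svds(mat, k=k, v0=np.ones(min(mat.shape)))
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]
    return EmbeddingSpace(vocab, u * s, provenance="lsa")


# ---------------------------------------------------------------------------
# word2vec text format
# ---------------------------------------------------------------------------

def load_vectors(path: str | Path) -> EmbeddingSpace:
    """Read a word2vec-text vector file (``count dim`` header line).

    Duplicate words keep their first occurrence (logged); a row whose float
    count disagrees with the header dimension raises a format error naming
    the line.
    """
    path = Path(path)
    words: list[str] = []
    vecs: list[np.ndarray] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: line 1: expected 'count dim' header")
        try:
            n_words, dim = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}: line 1: non-integer header") from None
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, floats = parts[0], parts[1:]
            if floats and floats[-1] == "":
                floats = floats[:-1]
            if len(floats) != dim:
                raise FormatError(
                    f"{path}: line {lineno}: expected {dim} floats for "
                    f"{word!r}, got {len(floats)}")
            if word in seen:
                import logging
                logging.getLogger(__name__).warning(
                    "%s: line %d: duplicate word %r ignored", path, lineno, word)
                continue
            seen.add(word)
            words.append(word)
            vecs.append(np.asarray(floats, dtype=float))
    if len(words) != n_words:
        import logging
        logging.getLogger(__name__).warning(
            "%s: header declares %d words, found %d", path, n_words, len(words))
    return EmbeddingSpace(words, np.vstack(vecs) if vecs else np.empty((0, dim)))


def save_vectors(space: EmbeddingSpace, path: str | Path,
                 fmt: str = "%.8g") -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(space.vocabulary)} {space.d}\n")
        for w, v in zip(space.vocabulary, space.vectors):
            fh.write(w + " " + " ".join(fmt % x for x in v) + "\n")
    return path


# ---------------------------------------------------------------------------
# Cosine-similarity context scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsConfig:
    """Window and variant options for the cosine-similarity score."""

    window: int = 9
    variant: str = "mean"           # "mean" | "resultant"
    stopword_policy: str = "with"   # "with" | "without"
    oov_policy: str = "skip"        # "skip" | "fail"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ParameterError(f"window must be >= 1, got {self.window}")
        if self.variant not in ("mean", "resultant"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        if self.stopword_policy not in ("with", "without"):
            raise ParameterError(f"unknown stopword_policy {self.stopword_policy!r}")
        if self.oov_policy not in ("skip", "fail"):
            raise ParameterError(f"unknown oov_policy {self.oov_policy!r}")


def cs_score(space: EmbeddingSpace, corpus: TokenizedCorpus,
             cfg: CsConfig = CsConfig(),
             stopwords: frozenset[str] | set[str] = frozenset()) -> np.ndarray:
    """Cosine-similarity predictability per token (NaN where undefined).

    The context of token *i* is its previous ``window`` words within the
    same text (``without`` policy: the previous ``window`` content words,
    i.e. stopwords are passed over without consuming window slots); the
    window is truncated at the text start.
    """
    tok = corpus.tokens
    out = np.full(len(tok), np.nan)
    norms_v = np.linalg.norm(space.vectors, axis=1)
    pos = 0
    for _, grp in tok.groupby("text_id", sort=True):
        words = grp.sort_values("idx_in_text")["norm"].tolist()
        ctx_rows: list[int] = []  # embedding row of each usable context word
        for i, w in enumerate(words):
            if i > 0:
                prev = words[i - 1]
                usable = not (cfg.stopword_policy == "without"
                              and prev in stopwords)
                if usable:
                    if prev in space:
                        ctx_rows.append(space.index[prev])
                    elif cfg.oov_policy == "fail":
                        raise KeyError(f"context word {prev!r} not in embedding")
                    else:
                        ctx_rows.append(-1)  # placeholder keeps window arithmetic
            window = [r for r in ctx_rows[-cfg.window:] if r >= 0]
            if w in space and window:
                tv = space.vectors[space.index[w]]
                tn = norms_v[space.index[w]]
                ctx = space.vectors[window]
                if cfg.variant == "mean":
                    cn = norms_v[window]
                    ok = (cn > 0) & (tn > 0)
                    if ok.any():
                        sims = (ctx[ok] @ tv) / (cn[ok] * tn)
                        out[pos + i] = float(np.clip(sims, -1, 1).mean())
                else:
                    res = ctx.sum(axis=0)
                    out[pos + i] = _cos(tv, res)
            elif w not in space and cfg.oov_policy == "fail":
                raise KeyError(f"target word {w!r} not in embedding")
        pos += len(words)
    return out


def window_sweep(space: EmbeddingSpace, corpus: TokenizedCorpus, eval_fn,
                 windows: Sequence[int] = DEFAULT_WINDOWS,
                 variants: Iterable[str] = ("mean", "resultant"),
                 stopword_policies: Iterable[str] = ("with", "without"),
                 stopwords: frozenset[str] = frozenset()
                 ) -> tuple[pd.DataFrame, dict]:
    """Criterion per (window, variant, stopword policy) combination.

    ``eval_fn(scores) -> float`` is any scalar criterion (correlation with
    cloze-predictability, or a mixed-model t-value).  Selection rule is the
    maximum absolute criterion.
    """
    if not len(list(windows)):
        raise ParameterError("windows must be non-empty")
    rows = []
    for w in windows:
        for variant in variants:
            for pol in stopword_policies:
                cfg = CsConfig(window=int(w), variant=variant,
                               stopword_policy=pol)
                crit = float(eval_fn(cs_score(space, corpus, cfg, stopwords)))
                rows.append({"window": int(w), "variant": variant,
                             "stopword_policy": pol, "criterion": crit})
    table = pd.DataFrame(rows)
    best = table.iloc[int(table["criterion"].abs().idxmax())].to_dict()
    return table, best
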