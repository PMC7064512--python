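"""Synthetic language, cloze responses and gaze durations with known truth.

The generator stands in for human reading data so that every downstream
stage can be checked against a ground truth:

* a **generative language**: an order-``m`` Markov chain over an invented
  vocabulary whose conditional next-word distributions are drawn from a
  Dirichlet centered on a Zipf-like unigram base measure.  The Dirichlet
  ``concentration`` controls how peaked the conditionals are, i.e. how
  predictable the language is; centering on the base measure makes frequent
  words more predictable on average, mirroring the frequency covariation
  seen in cloze norms;
* **cloze responders** who sample their answer from the true next-word
  distribution, optionally mixed with uniform guessing noise, so the cloze
  proportion-correct estimator has a known target;
* **gaze durations** drawn from the same crossed-random-intercepts linear
  model the analysis fits: log duration = centered covariates times known
  coefficients, plus Gaussian subject/text/word intercepts and residual
  noise, exponentiated to milliseconds.  Word skipping is an independent
  Bernoulli per token (more skipping for predictable and short words),
  present only to create realistic missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import TOKEN_COLUMNS, TokenizedCorpus, TokenizerConfig
from .exceptions import AlignmentError, ParameterError

_CONSONANTS = list("bcdfglmnprstvz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class SentenceLengthDist:
    """Sentence length in words: Poisson(mean) clipped to [min, max]."""

    mean: float = 12.0
    min: int = 3
    max: int = 30

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.clip(rng.poisson(self.mean, size=size), self.min, self.max)


@dataclass
class GenerativeLanguage:
    """An order-``order`` Markov language with explicit conditional tables.

    ``tables[k]`` has shape ``(V,) * k + (V,)`` and holds
    ``P(w | context of length k)``; contexts shorter than ``order`` are used
    at text starts.  ``cond_probs`` exposes the order-``order`` table as the
    context-tuple mapping.
    """

    vocabulary: list[str]
    order: int
    tables: list[np.ndarray]
    base_probs: np.ndarray
    stopwords: frozenset[str]
    sentence_length_dist: SentenceLengthDist
    seed: int
    word_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.word_index = {w: i for i, w in enumerate(self.vocabulary)}
        for k, tab in enumerate(self.tables):
            flat = tab.reshape(-1, len(self.vocabulary))
            if (flat < 0).any():
                raise ParameterError("negative conditional probability")
            if np.max(np.abs(flat.sum(axis=1) - 1.0)) > 1e-12:
                raise ParameterError(f"order-{k} conditionals do not sum to 1")

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    def cond_prob_vector(self, context: Sequence[str]) -> np.ndarray:
        """P(. | context); context is truncated to the last ``order`` words."""
        ctx = tuple(context)[-self.order:] if self.order else ()
        idx = tuple(self.word_index[w] for w in ctx)
        return self.tables[len(idx)][idx]

    @property
    def cond_probs(self) -> dict[tuple[str, ...], np.ndarray]:
        """Full-order context mapping (materialized; use on small vocabularies)."""
        k = self.order
        out: dict[tuple[str, ...], np.ndarray] = {}
        for flat_idx in range(self.vocab_size ** k):
            idx, rest = [], flat_idx
            for _ in range(k):
                idx.append(rest % self.vocab_size)
                rest //= self.vocab_size
            ctx = tuple(self.vocabulary[i] for i in reversed(idx))
            out[ctx] = self.tables[k][tuple(reversed(idx))]
        return out

    def true_entropy(self, context: Sequence[str]) -> float:
        p = self.cond_prob_vector(context)
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())


def _make_words(vocab_size: int, rng: np.random.Generator) -> list[str]:
    """CV-syllable word forms, 1-12 letters, frequent ranks shorter."""
    words: list[str] = []
    seen = set()
    for rank in range(vocab_size):
        frac = rank / max(vocab_size - 1, 1)
        lo = 1 + int(4 * frac)          # syllable count grows with rank
        n_syll = int(rng.integers(lo, min(lo + 2, 7)))
        while True:
            if n_syll == 1 and rng.random() < 0.3:
                w = rng.choice(_VOWELS)  # single-letter word
            else:
                w = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                            for _ in range(n_syll))
            if w not in seen:
                break
            n_syll = min(n_syll + 1, 6)
        seen.add(w)
        words.append(str(w))
    return words


def make_language(vocab_size: int, order: int = 2, concentration: float = 0.1,
                  seed: int = 0,
                  sentence_length_dist: SentenceLengthDist | None = None,
                  stopword_fraction: float = 0.1) -> GenerativeLanguage:
    """Draw a generative Markov language.

    ``concentration`` is the Dirichlet scale: the conditional distribution
    for every context is Dirichlet(concentration * V * base) where ``base``
    is a Zipf-like unigram measure.  Small values give near-one-hot
    (highly predictable) conditionals; large values give conditionals close
    to the base measure.  The ~``stopword_fraction`` most frequent words are
    designated the closed-class (stopword) subset.
    """
    if vocab_size < 10:
        raise ParameterError(f"vocab_size must be >= 10, got {vocab_size}")
    if concentration <= 0:
        raise ParameterError(f"concentration must be > 0, got {concentration}")
    if order < 0:
        raise ParameterError(f"order must be >= 0, got {order}")
    rng = np.random.default_rng(seed)
    words = _make_words(vocab_size, rng)
    base = 1.0 / np.arange(1, vocab_size + 1) ** 1.1
    base /= base.sum()
    alpha = concentration * vocab_size * base
    tables = []
    for k in range(order + 1):
        n_ctx = vocab_size ** k
        # Dirichlet via log-space gamma (Gamma(a) = Gamma(a+1) * U^(1/a)),
        # stable for the tiny shapes that arise at small concentration
        g1 = rng.gamma(shape=alpha + 1.0, scale=1.0, size=(n_ctx, vocab_size))
        u = rng.random((n_ctx, vocab_size))
        log_g = np.log(g1) + np.log(u) / alpha
        log_g -= log_g.max(axis=1, keepdims=True)
        tab = np.exp(log_g)
        tab /= tab.sum(axis=1, keepdims=True)
        tables.append(tab.reshape((vocab_size,) * k + (vocab_size,)))
    n_stop = max(1, int(round(stopword_fraction * vocab_size)))
    return GenerativeLanguage(
        vocabulary=words, order=order, tables=tables, base_probs=base,
        stopwords=frozenset(words[:n_stop]),
        sentence_length_dist=sentence_length_dist or SentenceLengthDist(),
        seed=seed)


def sample_corpus(lang: GenerativeLanguage, n_texts: int, words_per_text: int,
                  seed: int = 0,
                  tokenizer: TokenizerConfig | None = None) -> TokenizedCorpus:
    """Sample texts from the language; every token carries its true
    next-word probability ``true_pred`` under the generative model.

    The word chain runs across sentence boundaries within a text (context
    resets only at text starts); sentence lengths are drawn independently
    from the language's sentence-length distribution.
    """
    if n_texts < 1:
        raise ParameterError(f"n_texts must be >= 1, got {n_texts}")
    rng = np.random.default_rng(seed)
    V = lang.vocab_size
    order = lang.order
    full_cum = np.cumsum(lang.tables[order].reshape(-1, V), axis=1)
    rows: list[tuple] = []
    true_preds: list[float] = []
    cfg = tokenizer or TokenizerConfig()
    for text_id in range(n_texts):
        if words_per_text == 0:
            continue
        n_sent_guess = max(1, int(2 * words_per_text / lang.sentence_length_dist.mean) + 2)
        sent_lens = list(lang.sentence_length_dist.sample(rng, n_sent_guess))
        ctx: list[int] = []
        idx_in_text, sent_id, idx_in_sent = 0, 0, 0
        line_id, idx_in_line, line_len = 0, 0, 0
        remaining = sent_lens.pop(0)
        while idx_in_text < words_per_text:
            k = len(ctx)
            if k == order:
                flat = 0
                for c in ctx:
                    flat = flat * V + c
                cum = full_cum[flat]
            else:
                cum = np.cumsum(lang.tables[k][tuple(ctx)])
            w = int(np.searchsorted(cum, rng.random(), side="right"))
            w = min(w, V - 1)
            p = float(lang.tables[k][tuple(ctx)][w])
            surface = lang.vocabulary[w]
            width = len(surface) if line_len == 0 else line_len + 1 + len(surface)
            if line_len > 0 and width > cfg.wrap_width:
                line_id += 1
                idx_in_line, line_len = 0, len(surface)
            else:
                line_len = width
            rows.append((text_id, sent_id, idx_in_sent, idx_in_text,
                         line_id, idx_in_line, surface, surface))
            true_preds.append(p)
            idx_in_line += 1
            idx_in_text += 1
            idx_in_sent += 1
            ctx = (ctx + [w])[-order:] if order else []
            remaining -= 1
            if remaining == 0 and idx_in_text < words_per_text:
                sent_id += 1
                idx_in_sent = 0
                if not sent_lens:
                    sent_lens = list(lang.sentence_length_dist.sample(rng, 8))
                remaining = sent_lens.pop(0)
    frame = pd.DataFrame(rows, columns=TOKEN_COLUMNS)
    frame["true_pred"] = np.asarray(true_preds, dtype=float)
    return TokenizedCorpus(frame, cfg)


def sample_cloze_responses(lang: GenerativeLanguage, corpus: TokenizedCorpus,
                           responses_per_word: int, guess_noise: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Simulated cloze survey: each responder samples from
    ``(1 - guess_noise) * P(w | context) + guess_noise * uniform``.

    Returns a response table (text_id, idx_in_text, response) with
    ``responses_per_word`` rows per corpus token.
    """
    if responses_per_word < 1:
        raise ParameterError("responses_per_word must be >= 1")
    if not 0.0 <= guess_noise <= 1.0:
        raise ParameterError("guess_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    V = lang.vocab_size
    order = lang.order
    text_ids, idxs, resp = [], [], []
    tok = corpus.tokens
    for text_id, grp in tok.groupby("text_id", sort=True):
        norms = grp.sort_values("idx_in_text")["norm"].tolist()
        ctx_ids: list[int] = []
        for i, w in enumerate(norms):
            p = lang.tables[len(ctx_ids)][tuple(ctx_ids)]
            mixed = (1.0 - guess_noise) * p + guess_noise / V
            cum = np.cumsum(mixed)
            u = rng.random(responses_per_word)
            picks = np.minimum(np.searchsorted(cum, u, side="right"), V - 1)
            text_ids.extend([text_id] * responses_per_word)
            idxs.extend([i] * responses_per_word)
            resp.extend(lang.vocabulary[j] for j in picks)
            wid = lang.word_index[w]
            ctx_ids = (ctx_ids + [wid])[-order:] if order else []
    return pd.DataFrame({"text_id": text_ids, "idx_in_text": idxs,
                         "response": resp})


# ---------------------------------------------------------------------------
# Gaze generation
# ---------------------------------------------------------------------------

#: Covariate order used to assemble the generative design matrix.
GAZE_COVARIATES = ["launch_site", "inv_length", "log10_freq",
                   "inv_length:log10_freq", "rpl", "rpt", "rps",
                   "pred_n", "pred_n1"]


def default_skip_prob(true_pred: np.ndarray, length: np.ndarray) -> np.ndarray:
    """Skip probability rises with predictability, falls with length."""
    p = 0.08 + 0.35 * true_pred - 0.025 * (length - 4)
    return np.clip(p, 0.02, 0.85)


@dataclass
class GazeGenConfig:
    """Coefficients and variance components of the generative gaze model.

    ``beta`` maps covariate names (``intercept`` plus any of
    :data:`GAZE_COVARIATES`) to coefficients on the *centered* covariates;
    the sigmas are the SDs of the subject/text/word random intercepts and
    the residual, on the log-duration scale.
    """

    beta: Mapping[str, float]
    sigma_subj: float = 0.1
    sigma_text: float = 0.05
    sigma_word: float = 0.08
    sigma_resid: float = 0.25
    n_subjects: int = 30
    skip_prob_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = default_skip_prob
    launch_jitter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_subj", "sigma_text", "sigma_word", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        unknown = set(self.beta) - set(GAZE_COVARIATES) - {"intercept"}
        if unknown:
            raise ParameterError(f"unknown beta terms: {sorted(unknown)}")


def sample_gaze(corpus: TokenizedCorpus, features: pd.DataFrame,
                pred_n: np.ndarray, pred_n1: np.ndarray,
                cfg: GazeGenConfig) -> pd.DataFrame:
    """Simulate per-subject gaze durations from the known linear model.

    For every subject x non-skipped token, the log gaze duration is the
    linear predictor over covariates centered across all

    emitted rows, plus the three random intercepts and residual noise;
    durations are returned in ms.  Launch site is the length of the
    previous fixated word plus Gaussian jitter (0 at text start).  Rows
    whose required covariates are undefined (e.g. ``pred_n1`` on a text's
    last token when the model uses it) are dropped.

    Returns a fixation table with columns
    (subject_id, text_id, idx_in_text, gaze_ms, launch_site).
    """
    tok = corpus.tokens
    n_tok = len(tok)
    pred_n = np.asarray(pred_n, dtype=float)
    pred_n1 = np.asarray(pred_n1, dtype=float)
    if len(pred_n) != n_tok or len(pred_n1) != n_tok:
        raise AlignmentError(
            f"pred vectors (len {len(pred_n)}, {len(pred_n1)}) must align with "
            f"the {n_tok} corpus tokens")
    if len(features) != n_tok:
        raise AlignmentError("feature table must align with corpus tokens")
    rng = np.random.default_rng(cfg.seed)
    if "true_pred" in tok.columns:
        tp = tok["true_pred"].to_numpy()
    else:
        tp = np.full(n_tok, 0.1)
    lengths = features["length"].to_numpy(dtype=float)
    p_skip = cfg.skip_prob_fn(tp, lengths)

    u_subj = rng.normal(0.0, cfg.sigma_subj, size=cfg.n_subjects)
    n_text = corpus.n_texts
    u_text = rng.normal(0.0, cfg.sigma_text, size=n_text)
    u_word = rng.normal(0.0, cfg.sigma_word, size=n_tok)

    text_ids = tok["text_id"].to_numpy()
    idx_in_text = tok["idx_in_text"].to_numpy()

    rows_subj, rows_text, rows_idx, rows_row = [], [], [], []
    launch = []
    for s in range(cfg.n_subjects):
        fixated = rng.random(n_tok) >= p_skip
        for t in range(n_text):
            mask = (text_ids == t) & fixated
            rows = np.flatnonzero(mask)
            if not len(rows):
                continue
            prev = np.concatenate([[0.0], lengths[rows[:-1]]])
            ls = prev + rng.normal(0.0, cfg.launch_jitter_sd, size=len(rows))
            rows_subj.extend([s] * len(rows))
            rows_text.extend([t] * len(rows))
            rows_idx.extend(idx_in_text[rows])
            rows_row.extend(rows)
            launch.append(ls)
    launch_site = np.concatenate(launch) if launch else np.empty(0)
    row_idx = np.asarray(rows_row, dtype=int)
    subj = np.asarray(rows_subj, dtype=int)
    text = np.asarray(rows_text, dtype=int)

    cov = {
        "launch_site": launch_site,
        "inv_length": features["inv_length"].to_numpy()[row_idx],
        "log10_freq": features["log10_freq"].to_numpy()[row_idx],
        "rpl": features["rpl"].to_numpy()[row_idx],
        "rpt": features["rpt"].to_numpy()[row_idx],
        "rps": features["rps"].to_numpy()[row_idx],
        "pred_n": pred_n[row_idx],
        "pred_n1": pred_n1[row_idx],
    }
    used = [c for c in GAZE_COVARIATES
            if cfg.beta.get(c, 0.0) != 0.0 and c != "inv_length:log10_freq"]
    if cfg.beta.get("inv_length:log10_freq", 0.0) != 0.0:
        used = sorted(set(used) | {"inv_length", "log10_freq"})
    keep = np.ones(len(row_idx), dtype=bool)
    for c in used:
        keep &= np.isfinite(cov[c])
    for k in cov:
        cov[k] = cov[k][keep]
    row_idx, subj, text = row_idx[keep], subj[keep], text[keep]

    centered = {k: v - np.nanmean(v) if np.isfinite(v).any() else v
                for k, v in cov.items()}
    inter = centered["inv_length"] * centered["log10_freq"]
    centered["inv_length:log10_freq"] = inter - np.nanmean(inter)

    eta = np.full(len(row_idx), float(cfg.beta.get("intercept", 0.0)))
    for name in GAZE_COVARIATES:
        b = float(cfg.beta.get(name, 0.0))
        if b != 0.0:
            eta += b * centered[name]
    eta += u_subj[subj] + u_text[text] + u_word[row_idx]
    if cfg.sigma_resid > 0:
        eta += rng.normal(0.0, cfg.sigma_resid, size=len(eta))
    return pd.DataFrame({
        "subject_id": subj,
        "text_id": text,
        "idx_in_text": np.asarray(rows_idx, dtype=int)[keep],
        "gaze_ms": np.exp(eta),
        "launch_site": cov["launch_site"],
    })
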