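"""Tokenization, corpus containers, per-token covariates, and table I/O.

The token table produced here is the single source of truth for word
identity and position: every downstream stage (cloze aggregation, language
model scoring, embedding scores, the mixed-model frame) aligns to it via
``(text_id, idx_in_text)``.

Positional covariates follow the eye-movement literature: relative position
in the sentence (``rps``), in the line (``rpl``) and in the text (``rpt``),
each rescaled to [0, 1] as ``i / (L - 1)`` with a single-element scope
mapped to 0.  Lines are reconstructed by greedy wrapping at a configurable
character width, emulating an on-screen presentation.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError

_SENT_END = re.compile(r"(?<=[.!?…])\s+")
_WORD_CHARS = re.compile(r"[^\W\d_]+(?:['’-][^\W\d_]+)*", re.UNICODE)

#: Columns of the token table, in storage order.
TOKEN_COLUMNS = [
    "text_id", "sent_id", "idx_in_sent", "idx_in_text",
    "line_id", "idx_in_line", "surface", "norm",
]


@dataclass(frozen=True)
class TokenizerConfig:
    """Normalization and layout rules applied when building a corpus.

    Accent stripping is off by default: in Spanish orthography accents are
    contrastive, so folding them changes word identity.
    """

    lowercase: bool = True
    strip_accents: bool = False
    wrap_width: int = 80

    def normalize(self, word: str) -> str:
        w = word.lower() if self.lowercase else word
        if self.strip_accents:
            w = "".join(
                c for c in unicodedata.normalize("NFD", w)
                if unicodedata.category(c) != "Mn"
            )
        return w


@dataclass
class TokenizedCorpus:
    """Ordered texts -> sentences -> word tokens with positional indices.

    ``tokens`` has one row per word token with the columns in
    :data:`TOKEN_COLUMNS` (all indices 0-based and consecutive within their
    scope) plus, for synthetic corpora, a ``true_pred`` column holding the
    generative next-word probability of each token.
    """

    tokens: pd.DataFrame
    config: TokenizerConfig = field(default_factory=TokenizerConfig)

    @property
    def n_texts(self) -> int:
        return 0 if self.tokens.empty else int(self.tokens["text_id"].max()) + 1

    def __len__(self) -> int:
        return len(self.tokens)

    def text_norms(self, text_id: int) -> list[str]:
        sub = self.tokens[self.tokens["text_id"] == text_id]
        return sub.sort_values("idx_in_text")["norm"].tolist()

    def token_key(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.tokens[["text_id", "idx_in_text"]])

    def sentences(self) -> Iterable[list[str]]:
        """Yield each sentence as a list of normalized tokens, corpus order."""
        for (_, _), grp in self.tokens.groupby(["text_id", "sent_id"], sort=True):
            yield grp.sort_values("idx_in_sent")["norm"].tolist()


def split_sentences(raw_text: str) -> list[str]:
    parts = [p.strip() for p in _SENT_END.split(raw_text.strip())]
    return [p for p in parts if p]


def _words(sentence: str) -> list[str]:
    return _WORD_CHARS.findall(sentence)


def tokenize(raw_text: str, config: TokenizerConfig | None = None,
             text_id: int = 0) -> TokenizedCorpus:
    """Tokenize one document into a single-text corpus fragment.

    Sentences split on terminal punctuation; punctuation is stripped from
    word tokens; empty input yields an empty fragment.
    """
    return build_corpus([raw_text], config=config, first_text_id=text_id)


def build_corpus(texts: Iterable[str], config: TokenizerConfig | None = None,
                 first_text_id: int = 0) -> TokenizedCorpus:
    """Tokenize documents into a corpus; deterministic for a fixed config."""
    cfg = config or TokenizerConfig()
    if cfg.wrap_width < 1:
        raise ParameterError(f"wrap_width must be >= 1, got {cfg.wrap_width}")
    rows: list[tuple] = []
    for t_off, raw in enumerate(texts):
        text_id = first_text_id + t_off
        idx_in_text = 0
        line_id, idx_in_line, line_len = 0, 0, 0
        for sent_id, sentence in enumerate(split_sentences(raw)):
            for idx_in_sent, surface in enumerate(_words(sentence)):
                width = len(surface) if line_len == 0 else line_len + 1 + len(surface)
                if line_len > 0 and width > cfg.wrap_width:
                    line_id += 1
                    idx_in_line, line_len = 0, len(surface)
                else:
                    line_len = width
                rows.append((text_id, sent_id, idx_in_sent, idx_in_text,
                             line_id, idx_in_line, surface, cfg.normalize(surface)))
                idx_in_line += 1
                idx_in_text += 1
    frame = pd.DataFrame(rows, columns=TOKEN_COLUMNS)
    return TokenizedCorpus(frame, cfg)


# ---------------------------------------------------------------------------
# Frequency table
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Mapping normalized word -> corpus count, with the corpus total."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ParameterError("frequency counts must be >= 1")
        if self.total != sum(self.counts.values()):
            raise ParameterError("total must equal the sum of counts")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "FrequencyTable":
        counts = dict(counts)
        return cls(counts, sum(counts.values()))

    @classmethod
    def from_corpus(cls, corpus: TokenizedCorpus) -> "FrequencyTable":
        vc = corpus.tokens["norm"].value_counts()
        return cls.from_counts({str(w): int(c) for w, c in vc.items()})

    def log10_freq_per_million(self, word: str, floor_count: int = 1) -> float:
        """log10 frequency per million tokens; OOV words get ``floor_count``."""
        c = self.counts.get(word, floor_count)
        return float(np.log10(1e6 * c / self.total))


# ---------------------------------------------------------------------------
# Per-token covariates
# ---------------------------------------------------------------------------

def _rescale(idx: pd.Series, scope_len: pd.Series) -> pd.Series:
    # i/(L-1); degenerate single-element scope maps to 0
    denom = (scope_len - 1).where(scope_len > 1, 1)
    return (idx / denom).where(scope_len > 1, 0.0)


def compute_features(corpus: TokenizedCorpus, freq: FrequencyTable,
                     wrap_width: int | None = None,
                     oov_floor_count: int = 1) -> pd.DataFrame:
    """Per-token covariate table aligned row-for-row with ``corpus.tokens``.

    Columns: ``length`` (letters), ``inv_length``, ``log10_freq`` (per
    million tokens, OOV floored), ``repetition`` (prior occurrences of the
    word within the same text), and the rescaled positions ``rps``, ``rpl``,
    ``rpt``.  A pure function of its inputs.

    ``wrap_width`` overrides the line layout stored in the corpus: lines are
    re-wrapped at that width before ``rpl`` is computed.
    """
    if wrap_width is not None and wrap_width < 1:
        raise ParameterError(f"wrap_width must be >= 1, got {wrap_width}")
    tok = corpus.tokens.copy()
    if wrap_width is not None and len(tok):
        tok = _rewrap(tok, wrap_width)
    feats = pd.DataFrame(index=tok.index)
    if not len(tok):
        for c in ["length", "inv_length", "log10_freq", "repetition",
                  "rps", "rpl", "rpt"]:
            feats[c] = pd.Series(dtype=float)
        return feats
    feats["length"] = tok["surface"].str.len().astype(int)
    feats["inv_length"] = 1.0 / feats["length"]
    feats["log10_freq"] = tok["norm"].map(
        lambda w: freq.log10_freq_per_million(w, oov_floor_count))
    feats["repetition"] = tok.groupby(["text_id", "norm"]).cumcount()

    sent_len = tok.groupby(["text_id", "sent_id"])["idx_in_sent"].transform("size")
    feats["rps"] = _rescale(tok["idx_in_sent"], sent_len)
    line_len = tok.groupby(["text_id", "line_id"])["idx_in_line"].transform("size")
    feats["rpl"] = _rescale(tok["idx_in_line"], line_len)
    text_len = tok.groupby("text_id")["idx_in_text"].transform("size")
    feats["rpt"] = _rescale(tok["idx_in_text"], text_len)
    for key in ("text_id", "idx_in_text", "sent_id", "idx_in_sent",
                "line_id", "idx_in_line"):
        feats[key] = tok[key]
    return feats


def _rewrap(tok: pd.DataFrame, wrap_width: int) -> pd.DataFrame:
    tok = tok.sort_values(["text_id", "idx_in_text"]).copy()
    line_ids, idxs = [], []
    cur_text, line_id, idx_in_line, line_len = None, 0, 0, 0
    for text_id, surface in zip(tok["text_id"], tok["surface"]):
        if text_id != cur_text:
            cur_text, line_id, idx_in_line, line_len = text_id, 0, 0, 0
        width = len(surface) if line_len == 0 else line_len + 1 + len(surface)
        if line_len > 0 and width > wrap_width:
            line_id += 1
            idx_in_line, line_len = 0, len(surface)
        else:
            line_len = width
        line_ids.append(line_id)
        idxs.append(idx_in_line)
        idx_in_line += 1
    tok["line_id"] = line_ids
    tok["idx_in_line"] = idxs
    return tok


# ---------------------------------------------------------------------------
# Readers / writers (plain text corpus; TSV tables with header rows)
# ---------------------------------------------------------------------------

CLOZE_COLUMNS = ["text_id", "idx_in_text", "response"]
FIXATION_COLUMNS = ["subject_id", "text_id", "idx_in_text", "gaze_ms", "launch_site"]


def write_corpus(corpus: TokenizedCorpus, out_dir: str | Path) -> list[Path]:
    """One UTF-8 text file per document; sentences end with a period."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for text_id in range(corpus.n_texts):
        sub = corpus.tokens[corpus.tokens["text_id"] == text_id]
        sents = [
            " ".join(g.sort_values("idx_in_sent")["surface"]) + "."
            for _, g in sub.groupby("sent_id", sort=True)
        ]
        path = out_dir / f"text_{text_id:03d}.txt"
        path.write_text("\n".join(sents) + "\n", encoding="utf-8")
        paths.append(path)
    return paths


def read_corpus(paths: Iterable[str | Path],
                config: TokenizerConfig | None = None) -> TokenizedCorpus:
    texts = [Path(p).read_text(encoding="utf-8") for p in sorted(map(Path, paths))]
    return build_corpus(texts, config=config)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _to_number(df: pd.DataFrame, col: str, path, kind=float) -> pd.Series:
    try:
        return df[col].astype(kind)
    except (TypeError, ValueError):
        for i, v in enumerate(df[col]):
            try:
                kind(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {i + 1}: non-numeric value {v!r} in column {col!r}"
                ) from None
        raise


def read_cloze_responses(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CLOZE_COLUMNS)
    out = pd.DataFrame({
        "text_id": _to_number(df, "text_id", path, int),
        "idx_in_text": _to_number(df, "idx_in_text", path, int),
        "response": df["response"].astype(str),
    })
    return out


def write_cloze_responses(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[CLOZE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_fixations(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, FIXATION_COLUMNS)
    out = pd.DataFrame({
        "subject_id": _to_number(df, "subject_id", path, int),
        "text_id": _to_number(df, "text_id", path, int),
        "idx_in_text": _to_number(df, "idx_in_text", path, int),
        "gaze_ms": _to_number(df, "gaze_ms", path, float),
        "launch_site": _to_number(df, "launch_site", path, float),
    })
    bad = np.flatnonzero(~(out["gaze_ms"] > 0))
    if len(bad):
        raise FormatError(
            f"{path}: row {bad[0] + 1}: gaze duration must be > 0 ms "
            f"(got {out['gaze_ms'].iloc[bad[0]]})")
    return out


def write_fixations(table: pd.DataFrame, path: str | Path,
                    float_fmt: str = "%.6f") -> Path:
    if (table["gaze_ms"] <= 0).any():
        row = int(np.flatnonzero(table["gaze_ms"] <= 0)[0])
        raise FormatError(f"row {row + 1}: gaze duration must be > 0 ms")
    path = Path(path)
    table[FIXATION_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format=float_fmt)
    return path


def read_frequency(path: str | Path) -> FrequencyTable:
    df = _read_tsv(path, ["word", "count"])
    counts = dict(zip(df["word"], _to_number(df, "count", path, int)))
    return FrequencyTable.from_counts(counts)


def write_frequency(freq: FrequencyTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"word": list(freq.counts), "count": list(freq.counts.values())}
    ).to_csv(path, sep="\t", index=False)
    return path
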