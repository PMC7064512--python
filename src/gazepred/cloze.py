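"""Cloze-predictability: response aggregation, logit transform, covariation.

Cloze-predictability of a word is the proportion of survey responses that
guessed it correctly from the preceding context.  Words with fewer answers
than a threshold (default 8) are flagged as excluded from analysis.  The
logit transform uses the empirical-logit correction
``logit((k + 0.5) / (n + 1))`` so proportions of 0 and 1 map to finite
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import TokenizedCorpus, TokenizerConfig
from .exceptions import AlignmentError, ParameterError

DEFAULT_MIN_ANSWERS = 8

CLOZE_PRED_COLUMNS = ["text_id", "idx_in_text", "n_answers", "n_correct",
                      "pred", "logit_pred", "included"]


@dataclass(frozen=True)
class MatchConfig:
    """How a response string is compared with the target word.

    Exact match after tokenizer normalization is the default; the
    normalization (case, accents) is delegated to the tokenizer config so
    survey responses and corpus tokens share one word-identity rule.
    """

    tokenizer: TokenizerConfig = TokenizerConfig()

    def is_correct(self, response: str, target_norm: str) -> bool:
        return self.tokenizer.normalize(response.strip()) == target_norm


def aggregate(responses: pd.DataFrame, corpus: TokenizedCorpus,
              match: MatchConfig | None = None,
              min_answers: int = DEFAULT_MIN_ANSWERS) -> pd.DataFrame:
    """Aggregate a response table into per-token cloze-predictability.

    Returns one row per corpus token: ``n_answers``, ``n_correct``,
    ``pred = n_correct / n_answers`` (NaN when a token has no answers, with
    ``included`` False), the empirical-logit transform, and the
    ``included`` flag (``n_answers >= min_answers``).  Permutation-invariant
    over response rows.
    """
    match = match or MatchConfig()
    tok = corpus.tokens[["text_id", "idx_in_text", "norm"]]
    merged = responses.merge(tok, on=["text_id", "idx_in_text"], how="left",
                             validate="many_to_one")
    if merged["norm"].isna().any():
        bad = merged[merged["norm"].isna()].iloc[0]
        raise AlignmentError(
            f"response references unknown token (text {bad['text_id']}, "
            f"index {bad['idx_in_text']})")
    correct = np.fromiter(
        (match.is_correct(r, t) for r, t in zip(merged["response"], merged["norm"])),
        dtype=bool, count=len(merged))
    merged["correct"] = correct
    grp = merged.groupby(["text_id", "idx_in_text"])["correct"].agg(
        n_answers="size", n_correct="sum")
    out = tok[["text_id", "idx_in_text"]].merge(
        grp.reset_index(), on=["text_id", "idx_in_text"], how="left")
    out[["n_answers", "n_correct"]] = (
        out[["n_answers", "n_correct"]].fillna(0).astype(int))
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pred"] = np.where(out["n_answers"] > 0,
                               out["n_correct"] / out["n_answers"], np.nan)
    out["logit_pred"] = empirical_logit(out["n_correct"], out["n_answers"])
    out["included"] = out["n_answers"] >= min_answers
    return out[CLOZE_PRED_COLUMNS]


def empirical_logit(n_correct, n_answers) -> np.ndarray:
    """logit((k + 0.5) / (n + 1)); finite for k = 0 and k = n, NaN for n = 0."""
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_answers, dtype=float)
    p = (k + 0.5) / (n + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log(p / (1.0 - p))
    return np.where(n > 0, out, np.nan)


def logit_transform(pred_table: pd.DataFrame) -> np.ndarray:
    """Empirical-logit cloze-predictability for every token row."""
    return empirical_logit(pred_table["n_correct"], pred_table["n_answers"])


def covariation_summary(pred_table: pd.DataFrame, features: pd.DataFrame,
                        n_bins: int = 8,
                        covariates: tuple[str, ...] = (
                            "repetition", "log10_freq", "inv_length", "rps"),
                        ) -> pd.DataFrame:
    """Mean logit cloze-predictability binned by word covariates.

    For each covariate, included tokens are cut into bins (integer levels
    for ``repetition``, quantile bins otherwise); the summary holds the bin
    definition, the mean logit-predictability and its standard error
    (SD / sqrt(n)) per bin.  Empty bins are omitted.
    """
    if len(pred_table) != len(features):
        raise AlignmentError("pred table and feature table must align")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    mask = pred_table["included"].to_numpy()
    y = pred_table["logit_pred"].to_numpy()[mask]
    rows = []
    for cov in covariates:
        x = features[cov].to_numpy()[mask]
        if cov == "repetition":
            levels = pd.Series(x.astype(int))
            labels = levels.astype(str)
            centers = levels.astype(float)
        else:
            uniq = min(n_bins, max(1, len(np.unique(x))))
            cats = pd.qcut(pd.Series(x), q=uniq, duplicates="drop")
            labels = cats.astype(str)
            centers = pd.Series([iv.mid for iv in cats], dtype=float)
        df = pd.DataFrame({"bin": labels, "center": centers, "y": y})
        for (label, ), grp in df.groupby(["bin"], sort=False):
            n = len(grp)
            sd = float(grp["y"].std(ddof=1)) if n > 1 else 0.0
            rows.append({
                "covariate": cov, "bin": label,
                "bin_center": float(grp["center"].iloc[0]),
                "n": n, "mean_logit_pred": float(grp["y"].mean()),
                "sem": sd / np.sqrt(n) if n else np.nan,
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["covariate", "bin_center"]).reset_index(drop=True)


def read_cloze_pred(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[CLOZE_PRED_COLUMNS]


def write_cloze_pred(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[CLOZE_PRED_COLUMNS].to_csv(path, sep="\t", index=False,
                                     float_format="%.10g")
    return path
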