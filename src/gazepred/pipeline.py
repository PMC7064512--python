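"""Configuration-driven orchestration of the full synthetic pipeline.

Stages, in dependency order::

    simulate -> features -> cloze -> ngram -> embed -> lmm -> report

``simulate`` draws the generative language, a held-out reading corpus (with
per-token true predictability), an independent training corpus for the
language model and LSA, cloze responses, and gaze durations from the known
mixed model.  Later stages consume only the written artifacts, so the same
pipeline runs on real data by pointing the config at existing files.

Every run writes a manifest (config hash, seeds, artifact list); re-running
with an identical config and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import cloze as cloze_mod
from . import corpus as corpus_mod
from . import embed as embed_mod
from . import lmm as lmm_mod
from . import ngram as ngram_mod
from . import synth
from .exceptions import DependencyError, ParameterError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "cloze", "ngram", "embed", "lmm", "report")

PIPELINE_VERSION = "0.1.0"

FLOAT_FMT = "%.10g"

#: Default coefficients of the generative gaze model (centered covariates,
#: log-ms scale).  Chosen as plausible reading-study magnitudes: predictable,
#: frequent and short words are read faster; the next-word predictability
#: effect is negative, matching long-text reading.
DEFAULT_BETA = {
    "intercept": 5.5,
    "launch_site": 0.012,
    "inv_length": -0.25,
    "log10_freq": -0.035,
    "inv_length:log10_freq": 0.02,
    "rpl": 0.02,
    "rpt": -0.05,
    "rps": 0.03,
    "pred_n": -0.04,
    "pred_n1": -0.012,
}


@dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML."""

    output_dir: str = "gazepred_run"
    seed: int = 1
    # synthetic study conditions
    vocab_size: int = 150
    language_order: int = 2
    concentration: float = 0.2
    n_texts: int = 8
    words_per_text: int = 400
    train_texts: int = 40
    train_words_per_text: int = 2500
    responses_per_word: int = 20
    guess_noise: float = 0.1
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_subj: float = 0.12
    sigma_text: float = 0.03
    sigma_word: float = 0.08
    sigma_resid: float = 0.3
    n_subjects: int = 30
    # tokenizer
    lowercase: bool = True
    strip_accents: bool = False
    wrap_width: int = 80
    # cloze
    min_answers: int = 8
    # n-gram + cache
    n_order: int = 4
    gt_max_r: int = 5
    delta: float = ngram_mod.DEFAULT_DELTA
    lam: float = ngram_mod.DEFAULT_LAMBDA
    delta_grid: list = field(default_factory=lambda: list(ngram_mod.DEFAULT_DELTA_GRID))
    lambda_grid: list = field(default_factory=lambda: list(ngram_mod.DEFAULT_LAMBDA_GRID))
    run_grid_search: bool = False
    # embeddings
    dimensions: int = 40
    lsa_window: int = 9
    lsa_variant: str = "mean"
    ft_window: int = 50
    ft_variant: str = "resultant"
    stopword_policy: str = "with"
    vectors_path: str | None = None  # external word2vec-text file for the ft role
    run_window_sweep: bool = False
    sweep_windows: list = field(default_factory=lambda: [1, 3, 9, 25, 50])
    # mixed models
    include_n1: bool = True
    length_term: str = "inv_length"
    min_word_length: int = 3
    drop_sentence_edges: bool = True
    drop_line_edges: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def tokenizer(self) -> corpus_mod.TokenizerConfig:
        return corpus_mod.TokenizerConfig(
            lowercase=self.lowercase, strip_accents=self.strip_accents,
            wrap_width=self.wrap_width)


def validate(config: RunConfig) -> list[tuple[str, str]]:
    """Schema and cross-field checks; returns (level, message) findings."""
    findings: list[tuple[str, str]] = []
    err = lambda m: findings.append(("error", m))
    warn = lambda m: findings.append(("warning", m))
    if any(not 0.0 <= l <= 1.0 for l in config.lambda_grid):
        err("lambda grid values must lie in [0, 1]")
    if not 0.0 <= config.lam <= 1.0:
        err("lambda must lie in [0, 1]")
    if any(d < 0 for d in config.delta_grid) or config.delta < 0:
        err("delta values must be >= 0")
    if any(w < 1 for w in config.sweep_windows):
        err("context windows must be >= 1")
    if min(config.lsa_window, config.ft_window) < 1:
        err("context windows must be >= 1")
    if config.n_subjects < 2:
        err("n_subjects must be >= 2")
    if config.n_order < 1:
        err("n_order must be >= 1")
    if not 0.0 <= config.guess_noise <= 1.0:
        err("guess_noise must lie in [0, 1]")
    if config.vectors_path and not Path(config.vectors_path).exists():
        err(f"vectors_path does not exist: {config.vectors_path}")
    if config.min_answers > config.responses_per_word:
        warn("min_answers exceeds responses_per_word: every word will be excluded")
    if config.dimensions > config.train_texts:
        warn("LSA dimensions exceed the training document count; "
             "the rank will be clamped")
    return findings


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


class Runner:
    """Executes pipeline stages against one output directory."""

    def __init__(self, config: RunConfig):
        problems = [m for lvl, m in validate(config) if lvl == "error"]
        if problems:
            raise ParameterError("invalid config: " + "; ".join(problems))
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[str] = []

    # -- artifact helpers ---------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.out / name

    def _record(self, path: Path) -> Path:
        rel = str(path.relative_to(self.out))
        if rel not in self.artifacts:
            self.artifacts.append(rel)
        return path

    def _require(self, name: str, stage: str, needed_by: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise DependencyError(
                f"stage {needed_by!r} requires {name} produced by stage "
                f"{stage!r}; run it first")
        return p

    def _language(self) -> synth.GenerativeLanguage:
        cfg = self.config
        return synth.make_language(
            cfg.vocab_size, cfg.language_order, cfg.concentration,
            seed=_stage_seed(cfg.seed, "language"))

    def _read_corpus(self, name: str, stage: str, needed_by: str
                     ) -> corpus_mod.TokenizedCorpus:
        d = self._require(name, stage, needed_by)
        paths = sorted(Path(d).glob("*.txt"))
        corp = corpus_mod.read_corpus(paths, self.config.tokenizer())
        truth = self._path(f"{name}_true_pred.tsv")
        if truth.exists():
            tp = pd.read_csv(truth, sep="\t")
            corp.tokens["true_pred"] = tp["true_pred"].to_numpy()
        return corp

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        lang = self._language()
        tok = cfg.tokenizer()
        reading = synth.sample_corpus(lang, cfg.n_texts, cfg.words_per_text,
                                      seed=_stage_seed(cfg.seed, "reading"),
                                      tokenizer=tok)
        training = synth.sample_corpus(lang, cfg.train_texts,
                                       cfg.train_words_per_text,
                                       seed=_stage_seed(cfg.seed, "training"),
                                       tokenizer=tok)
        for name, corp in (("corpus", reading), ("train_corpus", training)):
            for p in corpus_mod.write_corpus(corp, self._path(name)):
                self._record(p)
        for name, corp in (("corpus", reading), ("train_corpus", training)):
            self._record(_write(
                corp.tokens[["text_id", "idx_in_text"]].assign(
                    true_pred=corp.tokens["true_pred"]),
                self._path(f"{name}_true_pred.tsv")))
        responses = synth.sample_cloze_responses(
            lang, reading, cfg.responses_per_word, cfg.guess_noise,
            seed=_stage_seed(cfg.seed, "cloze"))
        self._record(corpus_mod.write_cloze_responses(
            responses, self._path("responses.tsv")))

        freq = corpus_mod.FrequencyTable.from_corpus(training)
        self._record(corpus_mod.write_frequency(freq, self._path("frequency.tsv")))
        feats = corpus_mod.compute_features(reading, freq)
        true_pred = reading.tokens["true_pred"].to_numpy()
        pred_n = _safe_logit(true_pred)
        nxt = np.full(len(true_pred), np.nan)
        same = (reading.tokens["text_id"].to_numpy()[:-1]
                == reading.tokens["text_id"].to_numpy()[1:])
        nxt[:-1][same] = pred_n[1:][same]
        gaze_cfg = synth.GazeGenConfig(
            beta=cfg.beta, sigma_subj=cfg.sigma_subj, sigma_text=cfg.sigma_text,
            sigma_word=cfg.sigma_word, sigma_resid=cfg.sigma_resid,
            n_subjects=cfg.n_subjects, seed=_stage_seed(cfg.seed, "gaze"))
        fix = synth.sample_gaze(reading, feats, pred_n, nxt, gaze_cfg)
        self._record(corpus_mod.write_fixations(fix, self._path("fixations.tsv"),
                                                float_fmt=FLOAT_FMT))
        stops = pd.DataFrame({"word": sorted(lang.stopwords)})
        self._record(_write(stops, self._path("stopwords.tsv")))

    def features(self) -> None:
        corp = self._read_corpus("corpus", "simulate", "features")
        freq = corpus_mod.read_frequency(
            self._require("frequency.tsv", "simulate", "features"))
        feats = corpus_mod.compute_features(corp, freq)
        self._record(_write(feats, self._path("features.tsv")))

    def cloze(self) -> None:
        corp = self._read_corpus("corpus", "simulate", "cloze")
        responses = corpus_mod.read_cloze_responses(
            self._require("responses.tsv", "simulate", "cloze"))
        match = cloze_mod.MatchConfig(self.config.tokenizer())
        table = cloze_mod.aggregate(responses, corp, match,
                                    self.config.min_answers)
        self._record(cloze_mod.write_cloze_pred(table, self._path("cloze_pred.tsv")))

    def ngram(self) -> None:
        cfg = self.config
        train = self._read_corpus("train_corpus", "simulate", "ngram")
        test = self._read_corpus("corpus", "simulate", "ngram")
        model = ngram_mod.KatzNgramModel(cfg.n_order, cfg.gt_max_r).fit(train)
        self._record(ngram_mod.write_arpa(model, self._path("model.arpa")))
        delta, lam = cfg.delta, cfg.lam
        if cfg.run_grid_search:
            truth = test.tokens.get("true_pred")
            target = (_safe_logit(truth.to_numpy()) if truth is not None
                      else None)
            comp = ngram_mod.score_components(model, test)

            def crit(p: np.ndarray) -> float:
                if target is None:
                    return float(np.mean(np.log(p)))  # held-out log-score
                return float(np.corrcoef(_safe_logit(p), target)[0, 1])

            table, best = ngram_mod.grid_search(
                model, test, crit, cfg.delta_grid, cfg.lambda_grid)
            self._record(_write(table, self._path("ngram_grid.tsv")))
            delta, lam = float(best["delta"]), float(best["lambda"])
        scores = ngram_mod.score_text(model, test, delta, lam)
        scores["delta"], scores["lambda"] = delta, lam
        self._record(_write(scores, self._path("ngram_scores.tsv")))

    def embed(self) -> None:
        cfg = self.config
        train = self._read_corpus("train_corpus", "simulate", "embed")
        test = self._read_corpus("corpus", "simulate", "embed")
        stop_path = self._path("stopwords.tsv")
        stopwords = frozenset(
            pd.read_csv(stop_path, sep="\t")["word"]) if stop_path.exists() \
            else frozenset()
        space = embed_mod.train_lsa(train, cfg.dimensions)
        self._record(embed_mod.save_vectors(space, self._path("lsa_vectors.txt")))
        if cfg.vectors_path:
            ft_space = embed_mod.load_vectors(cfg.vectors_path)
        else:
            # no external vector file: the second embedding score reuses the
            # LSA space at the long-window/resultant operating point
            ft_space = space
        out = test.tokens[["text_id", "idx_in_text"]].copy()
        out["cs_lsa"] = embed_mod.cs_score(
            space, test,
            embed_mod.CsConfig(cfg.lsa_window, cfg.lsa_variant,
                               cfg.stopword_policy), stopwords)
        out["cs_ft"] = embed_mod.cs_score(
            ft_space, test,
            embed_mod.CsConfig(cfg.ft_window, cfg.ft_variant,
                               cfg.stopword_policy), stopwords)
        self._record(_write(out, self._path("cs_scores.tsv")))
        if cfg.run_window_sweep:
            truth = test.tokens.get("true_pred")
            target = _safe_logit(truth.to_numpy()) if truth is not None else None

            def crit(s: np.ndarray) -> float:
                if target is None:
                    return float(np.nanmean(s))
                ok = np.isfinite(s) & np.isfinite(target)
                return float(np.corrcoef(s[ok], target[ok])[0, 1])

            table, _ = embed_mod.window_sweep(
                space, test, crit, cfg.sweep_windows, stopwords=stopwords)
            self._record(_write(table, self._path("cs_window_sweep.tsv")))

    def _build_frame(self) -> lmm_mod.ModelFrame:
        cfg = self.config
        corp = self._read_corpus("corpus", "simulate", "lmm")
        feats = pd.read_csv(self._require("features.tsv", "features", "lmm"),
                            sep="\t")
        fix = corpus_mod.read_fixations(
            self._require("fixations.tsv", "simulate", "lmm"))
        cl = cloze_mod.read_cloze_pred(
            self._require("cloze_pred.tsv", "cloze", "lmm"))
        ng = pd.read_csv(self._require("ngram_scores.tsv", "ngram", "lmm"),
                         sep="\t")
        cs = pd.read_csv(self._require("cs_scores.tsv", "embed", "lmm"),
                         sep="\t")
        cloze_logit = np.where(cl["included"], cl["logit_pred"], np.nan)
        preds = {
            "cloze": cloze_logit,
            "ngram_cache": _safe_logit(ng["p_combined"].to_numpy()),
            "cs_lsa": cs["cs_lsa"].to_numpy(),
            "cs_ft": cs["cs_ft"].to_numpy(),
        }
        frame_cfg = lmm_mod.FrameConfig(
            min_word_length=cfg.min_word_length,
            drop_sentence_edges=cfg.drop_sentence_edges,
            drop_line_edges=cfg.drop_line_edges,
            length_term=cfg.length_term)
        return lmm_mod.build_frame(fix, corp, feats, preds, frame_cfg)

    def lmm(self) -> None:
        cfg = self.config
        frame = self._build_frame()
        specs = lmm_mod.roster(include_n1=cfg.include_n1,
                               length_term=cfg.length_term)
        fits = [lmm_mod.fit_lmm(frame, s) for s in specs]
        rows = []
        for f in fits:
            for term in f.beta.index:
                rows.append({
                    "model": f.name, "term": term,
                    "estimate": f.beta[term], "se": f.se[term], "t": f.t[term],
                    "loglik": f.loglik, "nparam": f.nparam, "aic": f.aic,
                    "n_obs": f.n_obs, "converged": f.converged,
                    "sigma_subj": f.sigma["subj"], "sigma_text": f.sigma["text"],
                    "sigma_word": f.sigma["word"], "sigma_resid": f.sigma["resid"],
                })
        self._record(_write(pd.DataFrame(rows), self._path("lmm_fits.tsv")))
        suffix = ".N+1" if cfg.include_n1 else ".N"
        tables = lmm_mod.report(fits, frame, baseline="M0" + suffix,
                                cloze_model="M1" + suffix)
        self._record(_write(tables["refit_t"], self._path("refit_t.tsv")))
        self._record(_write(
            tables["fixed_t"].reset_index(names="term"),
            self._path("fixed_t.tsv")))
        self._record(_write(tables["delta_aic"], self._path("delta_aic.tsv")))
        self._record(_write(tables["lrt"], self._path("lrt.tsv")))

    def report(self) -> None:
        fits = pd.read_csv(self._require("lmm_fits.tsv", "lmm", "report"),
                           sep="\t")
        self._require("refit_t.tsv", "lmm", "report")
        summary = (fits.drop_duplicates("model")
                   [["model", "loglik", "nparam", "aic", "n_obs"]]
                   .reset_index(drop=True))
        base_aic = summary["aic"].iloc[0]
        summary["delta_aic"] = summary["aic"] - base_aic
        self._record(_write(summary, self._path("report_summary.tsv")))

    # -- driver -------------------------------------------------------------

    def run(self, stages: Iterable[str] | None = None) -> dict[str, Any]:
        requested = list(stages) if stages else list(STAGES)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in requested:
                logger.info("running stage %s", stage)
                getattr(self, stage)()
        manifest = {
            "config_hash": _config_hash(self.config),
            "seed": self.config.seed,
            "stage_seeds": {s: _stage_seed(self.config.seed, s)
                            for s in ("language", "reading", "training",
                                      "cloze", "gaze")},
            "pipeline_version": PIPELINE_VERSION,
            "stages_run": [s for s in STAGES if s in requested],
            "artifacts": sorted(self.artifacts),
            "config": self.config.to_dict(),
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8")
        return manifest


def _safe_logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    q = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(q / (1.0 - q))


def run(config: RunConfig, stages: Iterable[str] | None = None) -> dict:
    """Execute the requested stages (all by default); returns the manifest."""
    return Runner(config).run(stages)
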