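"""Seeded simulation studies: parameter recovery, LRT power, remef logic.

These drive the package end to end under known ground truth and summarize
how well the mixed-model machinery recovers it.  They are used both by the
test suite and by the acceptance script, so the study conditions live here
in one place:

* recovery/power: 30 subjects reading 8 texts of ~375 words (about 3000
  tokens), generative coefficients from the pipeline defaults with the
  next-word effect switched off, and the frame built *without* the
  short-word/edge filters so that the generator's covariate centering and
  the analysis centering coincide exactly (the filters only shift the
  intercept by the dropped rows' covariate means; they are exercised in
  unit tests);
* remef: a model generated with a language-model-style predictor, a noisy
  cloze measurement of the same quantity, and the question whether removing
  the predictor's fixed effects absorbs the cloze-shaped variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cloze as cloze_mod
from . import lmm, synth
from .corpus import FrequencyTable, TokenizedCorpus, compute_features
from .pipeline import DEFAULT_BETA, _safe_logit
from .synth import GazeGenConfig, make_language, sample_corpus

NO_FILTER = lmm.FrameConfig(min_word_length=1, drop_sentence_edges=False,
                            drop_line_edges=False)


def _rep_seed(seed: int, rep: int) -> int:
    return (seed + 7919 * (rep + 1)) % (2 ** 31)


@dataclass
class StudyData:
    corpus: TokenizedCorpus
    features: "object"
    logit_pred: np.ndarray
    logit_pred_n1: np.ndarray


def make_study_data(seed: int, vocab_size: int = 150, n_texts: int = 8,
                    words_per_text: int = 375,
                    concentration: float = 0.2) -> StudyData:
    """One reading corpus with per-token logit true predictability."""
    lang = make_language(vocab_size, 2, concentration, seed=_rep_seed(seed, 0))
    corp = sample_corpus(lang, n_texts, words_per_text,
                         seed=_rep_seed(seed, 1))
    train = sample_corpus(lang, 15, 2000, seed=_rep_seed(seed, 2))
    feats = compute_features(corp, FrequencyTable.from_corpus(train))
    logit = _safe_logit(corp.tokens["true_pred"].to_numpy())
    nxt = np.full(len(logit), np.nan)
    same = (corp.tokens["text_id"].to_numpy()[:-1]
            == corp.tokens["text_id"].to_numpy()[1:])
    nxt[:-1][same] = logit[1:][same]
    return StudyData(corp, feats, logit, nxt)


def parameter_recovery_study(seed: int, n_reps: int = 20,
                             n_subjects: int = 30) -> dict:
    """Coverage of 95% intervals and LRT power under known coefficients.

    For each replication, gaze durations are redrawn from the generative
    mixed model on a fixed corpus; the baseline model and the model with
    the true predictability term are fitted by ML, each fixed effect is
    checked against its 95% interval, and the likelihood-ratio test of the
    predictability term is recorded.
    """
    data = make_study_data(seed)
    beta = dict(DEFAULT_BETA)
    beta["pred_n1"] = 0.0
    true_by_term = {
        "intercept": beta["intercept"], "launch_site": beta["launch_site"],
        "inv_length": beta["inv_length"], "log10_freq": beta["log10_freq"],
        "inv_length:log10_freq": beta["inv_length:log10_freq"],
        "rpl": beta["rpl"], "rpt": beta["rpt"], "rps": beta["rps"],
        "cloze_n": beta["pred_n"],
    }
    spec0 = lmm.ModelSpec("M0")
    spec1 = lmm.ModelSpec("M1", ("cloze_n",))
    cover = {t: 0 for t in true_by_term}
    power = 0
    n_obs = 0
    for rep in range(n_reps):
        cfg = GazeGenConfig(beta=beta, n_subjects=n_subjects,
                            seed=_rep_seed(seed, 100 + rep))
        fix = synth.sample_gaze(data.corpus, data.features, data.logit_pred,
                                np.zeros_like(data.logit_pred), cfg)
        frame = lmm.build_frame(fix, data.corpus, data.features,
                                {"cloze": data.logit_pred}, NO_FILTER)
        n_obs = frame.n_obs
        f0 = lmm.fit_lmm(frame, spec0)
        f1 = lmm.fit_lmm(frame, spec1)
        for term, truth in true_by_term.items():
            half = 1.96 * f1.se[term]
            if abs(f1.beta[term] - truth) <= half:
                cover[term] += 1
        if lmm.compare(f1, f0).p < 0.05:
            power += 1
    return {
        "coverage": {t: c / n_reps for t, c in cover.items()},
        "min_coverage": min(c / n_reps for c in cover.values()),
        "power": power / n_reps,
        "n_reps": n_reps,
        "n_obs": n_obs,
    }


def remef_study(seed: int, n_reps: int = 20, n_subjects: int = 15,
                n_texts: int = 4, words_per_text: int = 300) -> dict:
    """Does removing a predictor's fixed effects absorb cloze variance?

    Gaze is generated with an LM-style predictability effect; the cloze
    measurement is the proportion-correct estimate from simulated
    responses, a noisy correlate of the same quantity.  Per replication the
    cloze-only re-fit t-value is compared between residuals of the
    baseline model and residuals of the predictor-including model; a
    separate white-noise arm (no predictability effect at all) counts
    false-positive refits at |t| > 2.
    """
    lang = make_language(100, 2, 0.2, seed=_rep_seed(seed, 3))
    corp = sample_corpus(lang, n_texts, words_per_text, seed=_rep_seed(seed, 4))
    train = sample_corpus(lang, 10, 1500, seed=_rep_seed(seed, 5))
    feats = compute_features(corp, FrequencyTable.from_corpus(train))
    lm_pred = _safe_logit(corp.tokens["true_pred"].to_numpy())
    responses = synth.sample_cloze_responses(lang, corp, 20, 0.1,
                                             seed=_rep_seed(seed, 6))
    cl = cloze_mod.aggregate(responses, corp)
    cloze_logit = np.where(cl["included"], cl["logit_pred"], np.nan)
    beta = dict(DEFAULT_BETA)
    beta["pred_n1"] = 0.0
    noise_beta = {k: (v if k == "intercept" else 0.0) for k, v in beta.items()}
    spec0 = lmm.ModelSpec("M0")
    spec2 = lmm.ModelSpec("M2", ("lm_n",))
    preds = {"cloze": cloze_logit, "lm": lm_pred}
    drop, white_fp = 0, 0
    t_base, t_incl = [], []
    for rep in range(n_reps):
        cfg = GazeGenConfig(beta=beta, n_subjects=n_subjects,
                            seed=_rep_seed(seed, 200 + rep))
        fix = synth.sample_gaze(corp, feats, lm_pred, np.zeros_like(lm_pred),
                                cfg)
        frame = lmm.build_frame(fix, corp, feats, preds, NO_FILTER)
        f0 = lmm.fit_lmm(frame, spec0)
        f2 = lmm.fit_lmm(frame, spec2)
        tb = float(lmm.refit_cloze(
            lmm.remef_residuals(f0, frame), frame).t["cloze_n"])
        ti = float(lmm.refit_cloze(
            lmm.remef_residuals(f2, frame), frame).t["cloze_n"])
        t_base.append(tb)
        t_incl.append(ti)
        if abs(ti) < abs(tb):
            drop += 1
        # white-noise arm: no predictability signal anywhere
        ncfg = GazeGenConfig(beta=noise_beta, sigma_subj=0.0, sigma_text=0.0,
                             sigma_word=0.0, sigma_resid=0.3,
                             n_subjects=n_subjects,
                             seed=_rep_seed(seed, 300 + rep))
        nfix = synth.sample_gaze(corp, feats, lm_pred,
                                 np.zeros_like(lm_pred), ncfg)
        nframe = lmm.build_frame(nfix, corp, feats, preds, NO_FILTER)
        nf0 = lmm.fit_lmm(nframe, spec0)
        tw = float(lmm.refit_cloze(
            lmm.remef_residuals(nf0, nframe), nframe).t["cloze_n"])
        if abs(tw) > lmm.SIGNIFICANCE_T:
            white_fp += 1
    return {
        "drop_fraction": drop / n_reps,
        "mean_abs_t_baseline": float(np.mean(np.abs(t_base))),
        "mean_abs_t_including": float(np.mean(np.abs(t_incl))),
        "white_noise_fp_fraction": white_fp / n_reps,
        "n_reps": n_reps,
    }
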