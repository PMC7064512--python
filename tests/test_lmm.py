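import numpy as np
import pandas as pd
import pytest

import gazepred as gp
from gazepred import lmm, pipeline, synth
from gazepred.exceptions import AlignmentError, ParameterError, SpecError


@pytest.fixture(scope="module")
def study(lang):
    """Small simulated reading study with known coefficients."""
    corp = gp.sample_corpus(lang, n_texts=4, words_per_text=300, seed=50)
    freq = gp.FrequencyTable.from_corpus(
        gp.sample_corpus(lang, 10, 800, seed=51))
    feats = gp.compute_features(corp, freq)
    p = np.clip(corp.tokens["true_pred"].to_numpy(), 1e-6, 1 - 1e-6)
    logit = np.log(p / (1 - p))
    nxt = np.full(len(logit), np.nan)
    same = (corp.tokens["text_id"].to_numpy()[:-1]
            == corp.tokens["text_id"].to_numpy()[1:])
    nxt[:-1][same] = logit[1:][same]
    cfg = synth.GazeGenConfig(beta=pipeline.DEFAULT_BETA, n_subjects=12,
                              seed=52)
    fix = gp.sample_gaze(corp, feats, logit, nxt, cfg)
    return dict(corp=corp, feats=feats, fix=fix, logit=logit, cfg=cfg)


@pytest.fixture(scope="module")
def frame(study):
    return lmm.build_frame(study["fix"], study["corp"], study["feats"],
                           {"cloze": study["logit"]})


class TestBuildFrame:
    def test_short_words_excluded(self, study, frame):
        merged = frame.data.merge(
            study["feats"][["text_id", "idx_in_text", "length"]],
            on=["text_id", "idx_in_text"])
        assert (merged["length"] >= 3).all()

    def test_sentence_and_line_edges_excluded(self, study, frame):
        feats = study["feats"]
        kept = frame.data[["text_id", "idx_in_text"]].drop_duplicates()
        merged = kept.merge(feats, on=["text_id", "idx_in_text"])
        assert (merged["rps"] > 0).all() and (merged["rps"] < 1).all()
        assert (merged["rpl"] > 0).all() and (merged["rpl"] < 1).all()

    def test_covariates_centered(self, frame):
        for c in frame.covariates:
            assert abs(frame.data[c].mean()) < 1e-10, c

    def test_response_is_log_duration(self, study, frame):
        assert frame.data["log_gd"].between(3, 9).all()

    def test_n1_missing_drops_row(self, study):
        """The last token of a text has no next word: rows on it are absent
        once any model uses N+1 columns (shared complete-case rule)."""
        fr = lmm.build_frame(study["fix"], study["corp"], study["feats"],
                             {"cloze": study["logit"]},
                             lmm.FrameConfig(drop_sentence_edges=False,
                                             drop_line_edges=False,
                                             min_word_length=1))
        last = (study["corp"].tokens.groupby("text_id")["idx_in_text"]
                .max().reset_index())
        joined = fr.data.merge(last.rename(columns={"idx_in_text": "last"}),
                               on="text_id")
        assert (joined["idx_in_text"] < joined["last"]).all()

    def test_misaligned_pred_raises(self, study):
        with pytest.raises(AlignmentError):
            lmm.build_frame(study["fix"], study["corp"], study["feats"],
                            {"cloze": np.zeros(7)})


class TestFitLmm:
    def test_zero_variance_matches_ols(self, study):
        """All random SDs zero in the generator: the ML fit collapses to
        ordinary least squares."""
        cfg = synth.GazeGenConfig(
            beta=pipeline.DEFAULT_BETA, sigma_subj=0, sigma_text=0,
            sigma_word=0, sigma_resid=0.2, n_subjects=6, seed=53)
        fix = gp.sample_gaze(study["corp"], study["feats"], study["logit"],
                             np.zeros(len(study["logit"])), cfg)
        fr = lmm.build_frame(fix, study["corp"], study["feats"],
                             {"cloze": study["logit"]})
        spec = lmm.ModelSpec("M1", ("cloze_n",))
        fit = lmm.fit_lmm(fr, spec)
        X = fr.design(spec.fixed_terms)
        y = fr.column("log_gd")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, rtol=1e-4)

    def test_matches_statsmodels_mixedlm(self, frame):
        sm = pytest.importorskip("statsmodels.api")
        spec = lmm.ModelSpec("M1", ("cloze_n",))
        fit = lmm.fit_lmm(frame, spec)
        df = frame.data.rename(columns={"inv_length:log10_freq": "ixf"})
        df["g"] = 1
        terms = [t if ":" not in t else "ixf" for t in spec.fixed_terms]
        md = sm.MixedLM.from_formula(
            "log_gd ~ " + " + ".join(terms), groups="g",
            vc_formula={"s": "0 + C(sujid)", "t": "0 + C(textid)",
                        "w": "0 + C(wordid)"},
            re_formula="0", data=df)
        oracle = md.fit(reml=False, method="lbfgs")
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        np.testing.assert_allclose(fit.beta.to_numpy(),
                                   oracle.fe_params.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se.to_numpy(),
                                   oracle.bse_fe.to_numpy(), rtol=2e-2)

    def test_intercept_estimates_mean_log_duration(self, frame):
        fit = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        mean_log = float(frame.data["log_gd"].mean())
        assert fit.beta["intercept"] == pytest.approx(mean_log, abs=0.05)

    def test_aic_identity_and_nparam(self, frame):
        fit = lmm.fit_lmm(frame, lmm.ModelSpec("M1", ("cloze_n",)))
        assert fit.nparam == len(fit.beta) + 4
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.nparam,
                                        abs=1e-12)

    def test_variance_components_nonnegative(self, frame):
        fit = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        assert all(v >= 0 for v in fit.sigma.values())

    def test_deterministic(self, frame):
        a = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        b = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        assert a.loglik == b.loglik
        pd.testing.assert_series_equal(a.beta, b.beta)

    def test_unknown_term_rejected(self, frame):
        with pytest.raises(SpecError):
            lmm.fit_lmm(frame, lmm.ModelSpec("bad", ("nonexistent",)))


class TestCompare:
    def test_identical_specs_give_null_result(self, frame):
        f = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        res = lmm.compare(f, f)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_nested_chi2_nonnegative_and_significant_effect(self, frame):
        f0 = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        f1 = lmm.fit_lmm(frame, lmm.ModelSpec("M1", ("cloze_n",)))
        res = lmm.compare(f1, f0)
        assert res.chi2 >= 0 and res.df == 1
        assert res.p < 0.05  # generator includes a true pred_n effect

    def test_ml_loglik_never_decreases_with_terms(self, frame):
        """Nesting property across the roster."""
        lls = {}
        for extra in [(), ("cloze_n",), ("cloze_n", "cloze_n1")]:
            lls[extra] = lmm.fit_lmm(frame,
                                     lmm.ModelSpec(str(extra), extra)).loglik
        assert lls[("cloze_n",)] >= lls[()] - 1e-6
        assert lls[("cloze_n", "cloze_n1")] >= lls[("cloze_n",)] - 1e-6

    def test_different_frames_refused(self, study, frame):
        sub = study["fix"].iloc[: len(study["fix"]) // 2]
        fr2 = lmm.build_frame(sub, study["corp"], study["feats"],
                              {"cloze": study["logit"]})
        f1 = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        f2 = lmm.fit_lmm(fr2, lmm.ModelSpec("M0"))
        with pytest.raises(ParameterError):
            lmm.compare(f1, f2)


class TestRemef:
    def test_residuals_definition(self, frame):
        fit = lmm.fit_lmm(frame, lmm.ModelSpec("M1", ("cloze_n",)))
        resid = lmm.remef_residuals(fit, frame)
        X = frame.design(fit.terms)
        np.testing.assert_allclose(resid,
                                   frame.column("log_gd") - X @ fit.beta.to_numpy())
        # intercept removed: mean of the output is (near) zero
        assert abs(resid.mean()) < 0.02

    def test_ols_limit_orthogonality(self, study):
        cfg = synth.GazeGenConfig(
            beta=pipeline.DEFAULT_BETA, sigma_subj=0, sigma_text=0,
            sigma_word=0, sigma_resid=0.2, n_subjects=6, seed=54)
        fix = gp.sample_gaze(study["corp"], study["feats"], study["logit"],
                             np.zeros(len(study["logit"])), cfg)
        fr = lmm.build_frame(fix, study["corp"], study["feats"],
                             {"cloze": study["logit"]})
        fit = lmm.fit_lmm(fr, lmm.ModelSpec("M1", ("cloze_n",)))
        resid = lmm.remef_residuals(fit, fr)
        for term in fit.terms:
            r = np.corrcoef(resid, fr.column(term))[0, 1]
            assert abs(r) < 1e-4, term

    def test_variance_absorption(self, frame):
        """Removing the fixed effects of a model that contains the
        generating predictor leaves less cloze-shaped variance than
        removing only the baseline effects."""
        f0 = lmm.fit_lmm(frame, lmm.ModelSpec("M0"))
        f1 = lmm.fit_lmm(frame, lmm.ModelSpec("M1", ("cloze_n",)))
        t_base = lmm.refit_cloze(lmm.remef_residuals(f0, frame), frame)
        t_incl = lmm.refit_cloze(lmm.remef_residuals(f1, frame), frame)
        assert abs(t_incl.t["cloze_n"]) < abs(t_base.t["cloze_n"])
        assert abs(t_incl.t["cloze_n"]) < lmm.SIGNIFICANCE_T


class TestRoster:
    def test_baseline_terms(self):
        specs = {s.name: s for s in lmm.roster()}
        assert specs["M0.N"].fixed_terms == lmm.BASELINE_TERMS

    def test_combination_count(self):
        names = [s.name for s in lmm.roster()]
        assert names == [f"M{i}.N" for i in range(9)]
        # M5-M8: three pairs plus the triple
        specs = {s.name: s for s in lmm.roster()}
        assert len(specs["M5.N"].extra_terms) == 2
        assert len(specs["M8.N"].extra_terms) == 3

    def test_n1_roster_and_m9(self):
        specs = {s.name: s for s in lmm.roster(include_n1=True)}
        assert specs["M9.N+1"].extra_terms == ("ngram_cache_n", "cs_ft_n1")
        assert "cloze_n1" in specs["M1.N+1"].extra_terms


class TestReport:
    def test_tables_consistent(self, frame):
        fits = [lmm.fit_lmm(frame, lmm.ModelSpec("M0.N")),
                lmm.fit_lmm(frame, lmm.ModelSpec("M1.N", ("cloze_n",)))]
        tables = lmm.report(fits, frame)
        delta = tables["delta_aic"]
        assert delta.loc[delta["model"] == "M0.N", "delta_aic"].iloc[0] == 0.0
        # delta AIC recomputable from loglik and nparam exactly
        recomputed = (-2 * delta["loglik"] + 2 * delta["nparam"])
        np.testing.assert_allclose(delta["aic"], recomputed, atol=1e-10)
        # a true cloze effect: the cloze model improves the AIC
        assert delta.loc[delta["model"] == "M1.N", "delta_aic"].iloc[0] < 0
        assert tables["lrt"].set_index("model").loc["M1.N", "p_vs_baseline"] < 0.05
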