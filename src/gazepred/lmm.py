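"""Gaze-duration analysis with crossed-random-intercepts linear mixed models.

The response is the natural log of gaze duration (first-pass reading time).
Every model in the roster shares the baseline fixed effects::

    log(GD) ~ LaunchSite + length * frequency + rpl + rpt + rps
              + (1 | subject) + (1 | text) + (1 | word)

with word length entering as its inverse by default, covariates centered
(so the intercept estimates the mean log duration), and predictability
scores for the fixated word N and/or the next word N+1 added on top.
Candidate models are compared on one shared complete-case frame by AIC and
likelihood-ratio tests; an effect is called significant at |t| = |b/SE| > 2.

Fitting is maximum likelihood (not REML: the models differ in their fixed
effects, so REML likelihoods would not be comparable).  The profiled ML
deviance is optimized over the three relative random-intercept SDs using
the penalized-least-squares representation; the largest factor's block of
the penalized normal equations is diagonal and is eliminated analytically,
so each deviance evaluation costs O(n).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats

from .corpus import TokenizedCorpus
from .exceptions import AlignmentError, ParameterError, SpecError

#: Fixed-effect terms of the baseline model, in reporting order.
BASELINE_TERMS = ("launch_site", "inv_length", "log10_freq",
                  "inv_length:log10_freq", "rpl", "rpt", "rps")

RANDOM_FACTORS = ("sujid", "textid", "wordid")

SIGNIFICANCE_T = 2.0


@dataclass(frozen=True)
class FrameConfig:
    """Dataset-construction rules for the analysis frame."""

    min_word_length: int = 3        # words shorter than this are dropped
    drop_sentence_edges: bool = True
    drop_line_edges: bool = True
    length_term: str = "inv_length"  # "inv_length" | "length"


@dataclass
class ModelFrame:
    """Complete-case fixation dataset with centered covariates.

    ``data`` holds the response ``log_gd``, the centered covariate columns,
    and integer grouping codes ``sujid``/``textid``/``wordid``.  The means
    subtracted during centering are kept in ``center_means``.
    """

    data: pd.DataFrame
    covariates: list[str]
    center_means: dict[str, float]
    config: FrameConfig = field(default_factory=FrameConfig)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def design(self, terms: Sequence[str]) -> np.ndarray:
        unknown = [t for t in terms if t not in self.data.columns]
        if unknown:
            raise SpecError(f"unknown model terms: {unknown}")
        X = np.column_stack(
            [np.ones(self.n_obs)] + [self.column(t) for t in terms])
        return X

    def group_codes(self) -> list[np.ndarray]:
        return [self.column(f).astype(int) for f in RANDOM_FACTORS]


def build_frame(fixations: pd.DataFrame, corpus: TokenizedCorpus,
                features: pd.DataFrame,
                pred_tables: Mapping[str, np.ndarray] | None = None,
                config: FrameConfig = FrameConfig()) -> ModelFrame:
    """Assemble the shared analysis frame from fixations and covariates.

    ``pred_tables`` maps a score name (e.g. ``"cloze"``, ``"ngram_cache"``)
    to a per-token vector aligned with ``corpus.tokens``; the frame gains
    columns ``<name>_n`` (score of the fixated word) and ``<name>_n1``
    (score of the next token in reading order, NaN at text ends).

    Filters follow the eye-movement conventions: short words (fewer than
    ``min_word_length`` letters) and the first and last word of each
    sentence and line are excluded.  Rows with any missing covariate are
    dropped (one shared complete-case set for every roster model), and all
    covariates are centered afterwards.
    """
    tok = corpus.tokens
    n_tok = len(tok)
    if len(features) != n_tok:
        raise AlignmentError("features must align with corpus tokens")
    pred_tables = dict(pred_tables or {})
    token_tab = features[["text_id", "idx_in_text", "length", "inv_length",
                          "log10_freq", "rpl", "rpt", "rps"]].copy()
    token_tab["word_uid"] = np.arange(n_tok)
    # token-level exclusion flags
    drop = features["length"].to_numpy() < config.min_word_length
    if config.drop_sentence_edges:
        drop |= (features["rps"].to_numpy() == 0.0)
        drop |= (features["rps"].to_numpy() == 1.0)
    if config.drop_line_edges:
        drop |= (features["rpl"].to_numpy() == 0.0)
        drop |= (features["rpl"].to_numpy() == 1.0)
    token_tab["excluded"] = drop
    pred_cols = []
    for name, vec in pred_tables.items():
        vec = np.asarray(vec, dtype=float)
        if len(vec) != n_tok:
            raise AlignmentError(
                f"pred table {name!r} (len {len(vec)}) must align with "
                f"the {n_tok} corpus tokens")
        token_tab[f"{name}_n"] = vec
        # next token in reading order within the same text
        nxt = np.full(n_tok, np.nan)
        same_text = tok["text_id"].to_numpy()[:-1] == tok["text_id"].to_numpy()[1:]
        nxt[:-1][same_text] = vec[1:][same_text]
        token_tab[f"{name}_n1"] = nxt
        pred_cols += [f"{name}_n", f"{name}_n1"]

    df = fixations.merge(token_tab, on=["text_id", "idx_in_text"],
                         how="left", validate="many_to_one")
    if df["word_uid"].isna().any():
        bad = df[df["word_uid"].isna()].iloc[0]
        raise AlignmentError(
            f"fixation references unknown token (text {bad['text_id']}, "
            f"index {bad['idx_in_text']})")
    df = df[~df["excluded"].astype(bool)].copy()
    df["log_gd"] = np.log(df["gaze_ms"].to_numpy())

    length_col = config.length_term
    covariates = ["launch_site", length_col, "log10_freq",
                  f"{length_col}:log10_freq", "rpl", "rpt", "rps"] + pred_cols
    needed = [c for c in covariates if ":" not in c]
    df = df.dropna(subset=needed + ["log_gd"]).copy()
    if not len(df):
        raise ParameterError("analysis frame is empty after filtering")

    means: dict[str, float] = {}
    for c in needed:
        means[c] = float(df[c].mean())
        df[c] = df[c] - means[c]
    inter = df[length_col].to_numpy() * df["log10_freq"].to_numpy()
    means[f"{length_col}:log10_freq"] = float(inter.mean())
    df[f"{length_col}:log10_freq"] = inter - inter.mean()

    df["sujid"] = pd.factorize(df["subject_id"])[0]
    df["textid"] = pd.factorize(df["text_id"])[0]
    df["wordid"] = pd.factorize(df["word_uid"])[0]
    keep = (["log_gd"] + covariates + ["sujid", "textid", "wordid",
                                       "subject_id", "text_id", "idx_in_text"])
    return ModelFrame(df[keep].reset_index(drop=True), covariates, means,
                      config)


# ---------------------------------------------------------------------------
# Model specification and roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect roster entry; random intercepts are always the three
    crossed factors."""

    name: str
    extra_terms: tuple[str, ...] = ()
    length_term: str = "inv_length"

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        base = tuple(t.replace("inv_length", self.length_term)
                     for t in BASELINE_TERMS)
        return base + self.extra_terms


def roster(pred_names: Mapping[str, str] | None = None,
           include_n1: bool = False,
           length_term: str = "inv_length") -> list[ModelSpec]:
    """The standard model roster.

    ``pred_names`` maps the roles ``cloze``, ``ngram``, ``lsa``, ``ft`` to
    frame column stems (defaults to those names).  The N roster is M0
    (baseline), M1 (+cloze), M2-M4 (each computer score), M5-M8 (the three
    pairs and the triple).  With ``include_n1`` each model also carries the
    matching next-word column, and M9 (ngram for the fixated word, the
    FastText-style score for the next word) is appended.
    """
    names = {"cloze": "cloze", "ngram": "ngram_cache", "lsa": "cs_lsa",
             "ft": "cs_ft"}
    names.update(pred_names or {})
    cz, ng, ls, ft = (names[k] for k in ("cloze", "ngram", "lsa", "ft"))
    combos: list[tuple[str, tuple[str, ...]]] = [("M0", ()), ("M1", (cz,))]
    singles = [ng, ls, ft]
    for i, s in enumerate(singles, start=2):
        combos.append((f"M{i}", (s,)))
    k = 5
    for r in (2, 3):
        for combo in itertools.combinations(singles, r):
            combos.append((f"M{k}", combo))
            k += 1
    suffix = ".N+1" if include_n1 else ".N"
    out = []
    for name, stems in combos:
        terms: tuple[str, ...] = ()
        for s in stems:
            terms += (f"{s}_n",)
            if include_n1:
                terms += (f"{s}_n1",)
        out.append(ModelSpec(name + suffix, terms, length_term))
    if include_n1:
        out.append(ModelSpec("M9.N+1", (f"{ng}_n", f"{ft}_n1"), length_term))
    return out


# ---------------------------------------------------------------------------
# Profiled-ML fitting
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """Fitted mixed model: estimates, variance components, fit statistics."""

    name: str
    terms: tuple[str, ...]
    beta: pd.Series          # fixed-effect estimates, index = term names
    se: pd.Series
    t: pd.Series
    sigma: dict[str, float]  # SDs: subj, text, word, resid
    loglik: float
    nparam: int
    aic: float
    n_obs: int
    converged: bool
    theta: np.ndarray        # relative SDs (sigma_f / sigma_resid)

    def significant(self, term: str) -> bool:
        return abs(float(self.t[term])) > SIGNIFICANCE_T


class _CrossedSolver:
    """Penalized normal equations for crossed random intercepts.

    The factor with the most levels has a diagonal block in
    ``Lam Z'Z Lam + I`` and is eliminated analytically; the remaining
    factors' block is small and dense.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 codes: list[np.ndarray], n_levels: list[int]):
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.n_fac = len(codes)
        self.codes = codes
        self.n_levels = n_levels
        self.big = int(np.argmax(n_levels))
        rest = [i for i in range(self.n_fac) if i != self.big]
        self.rest = rest
        offs = np.cumsum([0] + [n_levels[i] for i in rest])
        self.r = int(offs[-1])
        self.b = n_levels[self.big]
        rest_code = np.concatenate(
            [codes[i] + offs[j] for j, i in enumerate(rest)]) if rest else np.empty(0, int)
        rows = np.tile(np.arange(self.n), len(rest))
        Zr = sp.csr_matrix((np.ones(len(rest_code)), (rows, rest_code)),
                           shape=(self.n, self.r))
        Zb = sp.csr_matrix(
            (np.ones(self.n), (np.arange(self.n), codes[self.big])),
            shape=(self.n, self.b))
        self.Zr, self.Zb = Zr, Zb
        self.G_rr = (Zr.T @ Zr).toarray()
        self.G_rb = (Zr.T @ Zb).toarray()
        self.d_b = np.asarray(Zb.sum(axis=0)).ravel()
        self.ZrtX, self.ZbtX = Zr.T @ X, Zb.T @ X
        self.Zrty, self.Zbty = Zr.T @ y, Zb.T @ y
        self.XtX, self.Xty, self.yty = X.T @ X, X.T @ y, y @ y
        # factor label per rest-column
        self.rest_factor = np.concatenate(
            [np.full(n_levels[i], i) for i in rest]) if rest else np.empty(0, int)

    def deviance(self, theta: np.ndarray):
        """Profiled -2 logLik at relative SDs ``theta``; returns the
        deviance plus the quantities needed to finish the fit."""
        lam_r = theta[self.rest_factor] if self.r else np.empty(0)
        lam_b = theta[self.big]
        # C = Lam Z'Z Lam + I, partitioned [rest, big]
        A = lam_r[:, None] * self.G_rr * lam_r[None, :] + np.eye(self.r)
        B = lam_r[:, None] * self.G_rb * lam_b
        D = lam_b ** 2 * self.d_b + 1.0
        BD = B / D[None, :]
        S_rr = A - BD @ B.T
        L = np.linalg.cholesky(S_rr)
        logdet = float(np.sum(np.log(D)) + 2.0 * np.sum(np.log(np.diag(L))))

        def solve(rhs_r, rhs_b):
            w = rhs_r - BD @ rhs_b
            u_r = np.linalg.solve(L.T, np.linalg.solve(L, w))
            u_b = (rhs_b - B.T @ u_r) / (D[:, None] if rhs_b.ndim == 2 else D)
            return u_r, u_b

        LZtX_r = lam_r[:, None] * self.ZrtX
        LZtX_b = lam_b * self.ZbtX
        LZty_r = lam_r * self.Zrty
        LZty_b = lam_b * self.Zbty
        CiX_r, CiX_b = solve(LZtX_r, LZtX_b)
        Ciy_r, Ciy_b = solve(LZty_r, LZty_b)
        S_beta = self.XtX - (LZtX_r.T @ CiX_r + LZtX_b.T @ CiX_b)
        rhs = self.Xty - (LZtX_r.T @ Ciy_r + LZtX_b.T @ Ciy_b)
        beta = np.linalg.solve(S_beta, rhs)
        u_r, u_b = solve(LZty_r - LZtX_r @ beta, LZty_b - LZtX_b @ beta)
        resid = (self.y - self.X @ beta
                 - self.Zr @ (lam_r * u_r) - self.Zb @ (lam_b * u_b))
        pwrss = float(resid @ resid + u_r @ u_r + u_b @ u_b)
        dev = logdet + self.n * (1.0 + np.log(2.0 * np.pi * pwrss / self.n))
        return dev, beta, S_beta, pwrss


def fit_lmm(frame: ModelFrame, spec: ModelSpec,
            theta_start: float = 1.0) -> LmmFit:
    """Fit one roster model by profiled maximum likelihood.

    Deterministic: fixed starting values (all relative SDs at
    ``theta_start``) and a bounded quasi-Newton optimizer with fixed
    tolerances.  Non-convergence is flagged on the returned fit;
    comparisons refuse flagged fits.
    """
    terms = spec.fixed_terms
    X = frame.design(terms)
    y = frame.column("log_gd")
    solver = _CrossedSolver(y, X, frame.group_codes(),
                            [int(frame.column(f).max()) + 1
                             for f in RANDOM_FACTORS])
    objective = lambda th: solver.deviance(np.abs(th))[0]
    res = optimize.minimize(
        objective, np.full(len(RANDOM_FACTORS), theta_start),
        method="L-BFGS-B", bounds=[(0.0, 50.0)] * len(RANDOM_FACTORS),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    if not res.success:
        # finite-difference line searches occasionally stall near the
        # optimum; polish with a derivative-free pass (still deterministic)
        polish = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 2000})
        if polish.fun <= res.fun:
            res = polish
    theta = np.abs(res.x)
    dev, beta, S_beta, pwrss = solver.deviance(theta)
    sigma2 = pwrss / solver.n
    cov_beta = np.linalg.inv(S_beta) * sigma2
    names = ["intercept"] + list(terms)
    beta_s = pd.Series(beta, index=names)
    se_s = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    sig = {
        "subj": float(np.sqrt(sigma2) * theta[0]),
        "text": float(np.sqrt(sigma2) * theta[1]),
        "word": float(np.sqrt(sigma2) * theta[2]),
        "resid": float(np.sqrt(sigma2)),
    }
    loglik = -dev / 2.0
    nparam = len(names) + len(RANDOM_FACTORS) + 1
    return LmmFit(
        name=spec.name, terms=tuple(terms), beta=beta_s, se=se_s,
        t=beta_s / se_s, sigma=sig, loglik=float(loglik), nparam=nparam,
        aic=float(-2.0 * loglik + 2.0 * nparam), n_obs=solver.n,
        converged=bool(res.success), theta=theta)


def fit_response(frame: ModelFrame, response: np.ndarray,
                 extra_terms: Sequence[str], name: str) -> LmmFit:
    """Fit an arbitrary response on the frame's random-effect structure:
    ``response ~ extra_terms + (1|sujid) + (1|textid) + (1|wordid)``."""
    if len(response) != frame.n_obs:
        raise AlignmentError("response vector must align with the frame")
    tmp = frame.data.copy()
    tmp["log_gd"] = np.asarray(response, dtype=float)
    sub = ModelFrame(tmp, frame.covariates, frame.center_means, frame.config)

    class _BareSpec(ModelSpec):
        @property
        def fixed_terms(self) -> tuple[str, ...]:  # type: ignore[override]
            return tuple(self.extra_terms)

    spec = _BareSpec(name, tuple(extra_terms))
    return fit_lmm(sub, spec)


# ---------------------------------------------------------------------------
# Comparison, fixed-effect removal, reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


def compare(fit_full: LmmFit, fit_reduced: LmmFit) -> LrtResult:
    """Likelihood-ratio test of nested ML fits on the identical dataset."""
    if not (fit_full.converged and fit_reduced.converged):
        raise ParameterError("refusing comparison involving non-converged fits")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ParameterError(
            f"fits use different datasets ({fit_full.n_obs} vs "
            f"{fit_reduced.n_obs} rows); rebuild one shared complete-case frame")
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise SpecError("reduced model terms are not nested in the full model")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    df = fit_full.nparam - fit_reduced.nparam
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LrtResult(float(chi2), int(df), p)


def remef_residuals(fit: LmmFit, frame: ModelFrame) -> np.ndarray:
    """Response with every fixed-effect prediction removed: ``y - X beta``.

    Random-effect predictions stay in the residual, which is re-fitted with
    the same random-factor structure afterwards.
    """
    X = frame.design(fit.terms)
    return frame.column("log_gd") - X @ fit.beta.to_numpy()


def refit_cloze(residuals: np.ndarray, frame: ModelFrame,
                pred_col: str = "cloze_n", name: str = "refit") -> LmmFit:
    """Fit ``residuals ~ pred_col + (1|sujid) + (1|textid) + (1|wordid)``.

    The t-value of ``pred_col`` measures how much cloze-shaped variance the
    removed fixed effects left behind.
    """
    return fit_response(frame, residuals, [pred_col], name)


def report(fits: Sequence[LmmFit], frame: ModelFrame,
           baseline: str = "M0.N", cloze_model: str = "M1.N",
           refit_pred: str = "cloze_n") -> dict[str, pd.DataFrame]:
    """Summary tables across a fitted roster.

    Returns ``fixed_t`` (terms x models t-value matrix), ``delta_aic``
    (AIC relative to the baseline model), ``lrt`` (likelihood-ratio
    p-values against the baseline and the cloze model), and ``refit_t``
    (cloze t-value after all fixed effects of each model are removed).
    """
    by_name = {f.name: f for f in fits}
    if len({f.n_obs for f in fits}) != 1:
        raise ParameterError("fits were not produced on one shared frame")
    base = by_name[baseline]
    all_terms = ["intercept"]
    for f in fits:
        all_terms += [t for t in f.terms if t not in all_terms]
    t_mat = pd.DataFrame(index=all_terms,
                         columns=[f.name for f in fits], dtype=float)
    for f in fits:
        for term in ["intercept"] + list(f.terms):
            t_mat.loc[term, f.name] = float(f.t[term])
    delta = pd.DataFrame({
        "model": [f.name for f in fits],
        "aic": [f.aic for f in fits],
        "delta_aic": [f.aic - base.aic for f in fits],
        "loglik": [f.loglik for f in fits],
        "nparam": [f.nparam for f in fits],
    })
    rows = []
    for f in fits:
        row = {"model": f.name, "p_vs_baseline": np.nan, "p_vs_cloze": np.nan}
        if f.name != baseline and set(base.terms) <= set(f.terms):
            row["p_vs_baseline"] = compare(f, base).p
        cz = by_name.get(cloze_model)
        if cz is not None and f.name not in (baseline, cloze_model):
            if set(cz.terms) <= set(f.terms):
                row["p_vs_cloze"] = compare(f, cz).p
            elif set(f.terms) <= set(cz.terms):
                row["p_vs_cloze"] = compare(cz, f).p
        rows.append(row)
    lrt = pd.DataFrame(rows)
    refit_rows = []
    for f in fits:
        if refit_pred in frame.data.columns and refit_pred not in f.terms:
            resid = remef_residuals(f, frame)
            rf = refit_cloze(resid, frame, refit_pred, name=f"refit[{f.name}]")
            refit_rows.append({"model": f.name,
                               "refit_t": float(rf.t[refit_pred]),
                               "refit_b": float(rf.beta[refit_pred])})
    return {"fixed_t": t_mat, "delta_aic": delta, "lrt": lrt,
            "refit_t": pd.DataFrame(refit_rows)}
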