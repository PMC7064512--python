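# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the places where the design was genuinely open.

## Predictability sources

**Cloze.** Cloze-Predictability of a token is the proportion of survey
responses whose normalized form equals the token's normalized form
(case-insensitive by default; accent stripping is off because Spanish-style
orthography is contrastive, and configurable). Tokens with fewer than 8
answers are flagged `included = False` and drop out of analyses. For logit
scales the empirical-logit correction `logit((k + 0.5)/(n + 1))` is used so
that proportions of exactly 0 or 1 stay finite; the uncorrected proportion
is also reported. Matching is exact-after-normalization; morphological
near-misses count as wrong (the rule is pluggable via `MatchConfig`).

**N-gram + cache.** The corpus model is a Katz back-off N-gram (reference
order 4). Good-Turing discounting replaces counts `r ≤ gt_max_r` (default
5) by `r* = (r+1)·N_{r+1}/N_r`; higher counts are trusted. Degenerate
counts-of-counts (`N_{r+1} = 0`, or `r* ≥ r`) leave the count undiscounted,
logged. The freed mass of each context goes to unseen continuations through
the back-off weight `α(context)`; when every vocabulary word has been seen
under a context there is no unseen continuation to absorb the discount and
the seen probabilities are renormalized instead (this arises only on tiny
vocabularies). The order-1 model is the ML unigram over the closed
vocabulary: training words below `min_count = 2` occurrences are mapped to
`<unk>`, so every vocabulary item has positive probability and held-out
text never scores zero. Sentences are `<s>`-padded; `<s>` is never a
predicted event. Every context's distribution sums to 1 by construction
(enumerated in tests, and against an independent brute-force implementation
on a tiny corpus).

The cache is an additively smoothed unigram over the text read so far,
`p = (c(w) + δ)/(δV + N)`, with `V` = training vocabulary plus words seen
so far in the test text, so novel in-text words carry cache mass. The cache
resets at each text start and is updated only *after* a token is scored: a
word never predicts itself. Whether punctuation or cross-text persistence
should enter the cache is undefined in the literature this follows;
reset-per-text and word-tokens-only are the implemented conventions. The
interpolation is `λ·p_cache + (1−λ)·p_ngram`; the default operating point
is δ = 0.00015, λ = 0.15, and `grid_search` evaluates any scalar criterion
over δ ∈ [5·10⁻⁵, 5·10⁻⁴], λ ∈ [0.05, 0.6] (argmax on |criterion|, which
presumes a correlation- or t-like criterion — use a positive transform for
likelihood-type criteria). The trained model round-trips through the ARPA
back-off format (log10 probabilities, `-99` for context-only entries) to
~1e-12, enabling cross-checks with external LM toolkits.

**Embedding CS scores.** LSA vectors come from the word-by-document count
matrix with tf-idf weighting (tf = raw count; idf = `log(1 + n_docs/df)` —
the unsmoothed `log(n_docs/df)` is available but zeroes out words present
in every document, which on small collections is much of the vocabulary),
followed by a rank-`d` SVD; word vectors are `U_d·S_d` rows (scaling by the
singular values is the default and configurable, since unscaled `U` changes
cosines). The decomposition is deterministic up to singular-vector sign,
to which cosines are invariant. Externally trained skipgram/FastText-style
vectors are ingested from the word2vec text format; training such networks
is out of scope. The CS score of token *i* is the cosine between its vector
and its previous-`w`-word context: `mean` averages pairwise cosines,
`resultant` takes the cosine with the summed context vector (the two
coincide at w = 1). "Without stopwords" gathers the `w` previous *content*
words (stopwords do not consume window slots). OOV context words are
skipped rather than zero-padded so they neither dilute nor inflate the
score, but they do consume their window slot; a token that is itself OOV or
has no usable context gets a missing score and becomes an incomplete case
downstream. A word may appear inside its own context window (repetition);
it is not excluded.

## The mixed-model evaluation

The response is the natural log of gaze duration in ms (any log base only
rescales coefficients). Dataset construction follows eye-movement
conventions: words under 3 letters and the first and last word of every
sentence and line are excluded; "lines" are reconstructed by greedy
wrapping at a configurable character width (80 by default) because the
original screen layout of a reading experiment is generally unavailable —
the synthetic generator uses the same wrapper, so `rpl` is well defined end
to end. Relative positions use `i/(L−1)` with single-element scopes mapped
to 0. Word length enters as its inverse by default (configurable to raw).
Word frequency is log10 per million tokens with OOV words floored at count
1 (keeps the covariate finite without a missing-data path). One shared
complete-case frame serves every model in a comparison; all covariates are
centered after the drops, so the intercept estimates the mean log duration.
The length × frequency interaction is the product of the centered main
effects, itself centered.

Models have the baseline fixed effects (launch site, inverse length, log
frequency, their interaction, rpl, rpt, rps), optional predictability terms
for the fixated word N and/or the next word N+1 (N+1 = next token in
reading order; its value for a text's last token is missing), and crossed
random intercepts for subject, text and word token. The roster is M0
(baseline), M1 (+cloze), M2–M4 (each computer score), M5–M8 (pairs and
triple), and in the N+1 roster each model carries both the N and N+1
columns plus M9 = n-gram+cache(N) + CS-FT(N+1). The next-word cloze term
lives in the N+1 roster rather than the N baseline (both are expressible
via custom rosters).

**Fitting.** Maximum likelihood, not REML: the models differ in fixed
effects, so REML objectives would not be comparable. The profiled ML
deviance is optimized over the three relative random-intercept SDs
(`σ_f/σ_resid`, bounded [0, 50], started at 1) with L-BFGS-B at tight
tolerances and a deterministic Nelder–Mead polish if the line search
stalls; everything downstream (β, SEs, variance components, logLik) is
closed-form given those ratios. The penalized normal equations exploit the
structure of crossed intercepts: the block of the factor with the most
levels (usually word) is diagonal and is eliminated analytically, leaving a
small dense system over the remaining factors, so one deviance evaluation
is O(n). Fits agree with an independent general-purpose mixed-model
implementation to ~1e-6 in log-likelihood on test fixtures. Fixed-effect
covariance is `σ̂²(XᵀV⁻¹X)⁻¹` via the same elimination. `nparam` = fixed
effects + 3 variance components + residual; `AIC = −2·logLik + 2·nparam`
exactly. Significance labeling uses |t| = |b/SE| > 2; no per-coefficient
degrees-of-freedom p-values are attempted. Likelihood-ratio tests require
nested term sets and identical row counts and refuse non-converged fits.

**Fixed-effect removal (remef).** Residuals are `y − Xβ̂` — every fixed
effect removed, random-effect predictions left in the response — then
re-fitted with the same three random intercepts and cloze-Predictability as
the only fixed effect. The drop in the cloze t-value relative to the
baseline-residual re-fit measures how much cloze-shaped variance the
removed model had absorbed.

## Synthetic study conditions

The generative language is an order-2 Markov chain over an invented
CV-syllable vocabulary (150 words by default, lengths 1–12 letters,
frequent words shorter). Conditional next-word distributions are
Dirichlet-draws centered on a Zipf-like base measure, sampled in log space
(`Γ(a) = Γ(a+1)·U^{1/a}`) because direct gamma sampling underflows at small
concentrations. The concentration default is 0.2, which gives a
token-weighted true-predictability distribution with mean ≈ 0.10 and median
≈ 0.07 — strongly right-skewed, as empirical cloze norms are (most words
are hard to guess). Centering the Dirichlet on the unigram base measure
makes frequent words more predictable on average, reproducing the
frequency–predictability covariation. Sentence lengths are clipped Poisson
(mean 12, range 3–30) overlaid on the word chain; the chain resets per
text.

Cloze responders sample from `(1−g)·P(w|context) + g·uniform` with guess
noise g = 0.1 by default (0 in consistency checks). At 500 noise-free
responses per word the estimator's mean absolute error has a binomial floor
`E|p̂−p| = √(2p(1−p)/(π·500))` per word — about 0.009 under the default
language; no estimator can beat this, which is why the consistency checks
are run under the realistic right-skewed predictability distribution.

Gaze durations follow the analysis model exactly: log duration = centered
covariates × known coefficients + subject/text/word intercepts + residual,
exponentiated to ms. Default coefficients (log-ms scale) are plausible
reading-study magnitudes — intercept 5.5 (≈245 ms), negative effects of
inverse length (−0.25), log frequency (−0.035) and predictability (−0.04 on
the logit scale; next-word effect −0.012, negative as in long-text
reading), small positional effects; SDs 0.12/0.03/0.08 (subject/text/word)
and 0.3 residual; 30 subjects. Skipping is an independent Bernoulli per
token, increasing with predictability and decreasing with length, purely to
create realistic missingness — there is no sequential eye-movement model,
no refixations or regressions. Launch site is the previous fixated word's
length plus N(0,1) jitter (its empirical definition varies across labs; the
analysis treats it as an opaque covariate). What passing tests therefore
show is that the estimation machinery is correct under the stated model —
not that real reading data satisfies that model: the generator has no
saccade dynamics, no parafoveal preview mechanism beyond the optional N+1
coefficient, and Gaussian random effects by construction.

In the default pipeline no externally trained vector file is supplied, so
the second embedding score (the FastText role, window 50 / resultant) is
computed from the same LSA space at a different operating point; pointing
`vectors_path` at any word2vec-text file replaces it.

## Simulation studies and problem sizes

`parameter_recovery_study`: 20 replications of 30 subjects × 8 texts ×
~375 words (≈77 000 fixations after skipping), gaze redrawn per
replication on a fixed corpus. Each fixed effect is checked against its
±1.96·SE interval and the predictability term against the baseline by LRT.
These runs build the frame *without* the short-word/edge filters so that
the generator's covariate centering and the analysis centering are computed
over identical rows — with filtering they differ by the dropped rows'
covariate means, which shifts only the intercept (slopes are unaffected);
the filters themselves are exercised in unit tests. `remef_study`: 20
replications at 15 subjects × 4 texts × 300 words, with a cloze measure
aggregated from 20 simulated responses per word, plus a white-noise arm for
the false-positive rate of the residual re-fit. The LM-consistency check
trains an order-3 model on 10⁶ sampled tokens of a 20-word-vocabulary
language and compares conditionals on contexts seen ≥ 1000 times (mean
absolute error). These sizes were chosen so the whole verification cycle
runs in about a minute on one CPU while keeping Monte-Carlo noise well
below the tested margins.

## Numerical and degenerate-input conventions

- Probabilities: conditional tables validated to sum to 1 within 1e-12
  (generator) / 1e-8 (LM enumeration); cache distributions sum to 1 within
  1e-12 for any state with `δV + N > 0`; δ = 0 with an empty cache raises a
  degenerate-cache error.
- Cosines are clipped to [−1, 1] against floating-point drift; zero vectors
  yield cosine 0 (they cannot arise from the default tf-idf).
- Empty corpora tokenize to empty fragments, not errors; an analysis frame
  that filters to zero rows raises.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); per-stage seeds are derived from the master
  seed by hashing, and identical configs + seeds reproduce byte-identical
  output tables (fixed float formatting `%.10g`).
- Tie-breaks: grid and window sweeps report the first argmax in scan order;
  duplicate words in vector files keep the first occurrence.

## Known limitations

- Skipping in the generator depends only on covariates (predictability,
  length), so the missingness is ignorable by construction; informative
  missingness is untested.
- The Katz implementation targets desk-scale corpora (10⁶–10⁷ tokens);
  counting is pure-Python dictionaries, not a compiled trie.
- LRT p-values against the cloze model are only defined for nested rosters;
  non-nested pairs are reported as missing rather than via information
  criteria alone.
- The `mean` CS variant weights each context word equally; no distance
  decay within the window is implemented.
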