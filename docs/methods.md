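# Methods

This note documents the models and procedures implemented in
`tweetscreen`, the parameter choices that matter, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Units of observation

All analyses operate on *user-days* (or ISO-8601 *user-weeks*): every
tweet a user posts within one UTC calendar day is aggregated into one
feature vector. Days with no posts yield no observation — activity enters
through the `n_tweets` feature on posting days rather than zero-padded
series, because the unit of analysis is posted content. A "word" is a
maximal run of non-whitespace characters; raw word counts use that
definition, while lexicon lookups use a normalized token (lowercased,
leading/trailing punctuation stripped, no stemming). Lexicon matching is
case-insensitive and unigram-only.

The observation feature roster is fixed and data-driven: `n_tweets`,
`mean_word_count`, `retweet_fraction`, `reply_fraction`, one
`<lexicon>_happy` column per happiness instrument (mean over tweets with
at least one matched token; missing if none), and one `cat_<label>`
token-weighted frequency per category in the supplied category lexicon.
Coverage columns (`<lexicon>_coverage`) are audit data, not predictors.

## Filters

Applied in a fixed order mirroring the collection protocol: per-user
3,200-tweet history cap (most recent kept, stable tie-break on input
order) → minimum five posts → clinical survey cutoff on the affected arm
only (CES-D ≥ 22 for depression, TSQ ≥ 6 for PTSD; healthy participants
are screened by a no-history questionnaire, not a scale, and pass
through) → in screening mode, removal of affected users' tweets on or
after the calendar day of first diagnosis. "Before diagnosis" is read as
a strict calendar-day inequality — the diagnosis day itself is excluded —
because the screening claim of interest is detection *before* the first
diagnosis exists. Every stage is audited in a `FilterReport` whose counts
are checked to be non-increasing.

## Screening model

A 1200-tree random forest with "affected" as the positive class.
Protocol per run: stratified 70/30 split at the observation level; median
imputation of missing features using training-split statistics only;
grid search over a small standard grid (depth ∈ {∞, 10, 20},
features-per-split ∈ {√p, log₂p}, min-leaf ∈ {1, 5}) by stratified 5-fold
CV maximizing F1 (the search uses a 200-tree forest for speed; the final
model refits with 1200 trees and the winning parameters); evaluation via
the five-metric battery (recall, specificity, precision, NPV, F1) at a
0.5 probability threshold plus ROC/AUC over all thresholds. Results are
averaged over five independently seeded runs. Class imbalance is left
unweighted.

Observation-level splitting means one user's days can appear in both
train and test; this leaks user identity whenever features are
user-identifiable (here, via the per-user posting rate behind
`n_tweets`). It is retained as the default for fidelity with the protocol
this package mirrors, the caveat is documented rather than silently
"fixed", and `by_user=True` provides a leakage-free user-level split for
sensitivity analysis. Impurity-based importances rank predictor
*relevance* only; they carry no directionality.

## Trajectory model

A single two-state hidden Markov model with diagonal Gaussian emissions
is fit by EM to all users pooled — each user is one period-ordered
sequence — on z-scored features with labels stripped before fitting.
Numerical choices: convergence tolerance 1e-4, at most 500 iterations,
means initialized k-means-style with a fixed seed, start and transition
probabilities initialized uniform. The uniform transition initialization
matters: randomly drawn transition matrices occasionally place EM in a
basin where the two states collapse onto one emission distribution, and a
neutral start removes that failure mode without informing the fit. Fitted
means/covariances are reported back in raw feature units. A fit whose
state means separate by less than 0.2 pooled SD on every feature is
flagged degenerate.

Because HMM states are exchangeable, state identity is established by the
**alignment-agreement** procedure: for each feature, compare the sign of
(affected − healthy) class means in the raw data with the sign of the
between-state difference in fitted means, under the state-to-class
mapping that maximizes agreement; features with an exactly zero raw
difference are excluded from the denominator. A high agreement fraction
licenses reading the matched state as "affected".

The **time course** uses the posterior probability of the affected state
(not the Viterbi indicator, which is also computed and exported):
posteriors produce the smooth aggregate trajectories of interest.
Affected users' observations are indexed by signed days from their anchor
(diagnosis for depression, trauma for PTSD; day 0 = anchor); healthy
users have no anchor and are centered on the midpoint of their own
observed span, giving a consecutive comparison span of equivalent length.
Observations are binned into half-open windows [k·w, (k+1)·w) with w = 14
days (diagnosis-anchored) or 30 days (trauma-anchored); each bin reports
the mean posterior with a normal-approximation 95% CI, and a cubic
least-squares trend with a 95% band is fit per group over bin midpoints.
Swapping HMM state labels leaves the time course invariant because the
alignment step re-fixes the mapping.

## Word shifts

Class happiness pools normalized tokens per class, drops words in the
neutral stop band and promotional retweets, and takes the
frequency-weighted mean score. The stop band is *strict*: 4 < h < 6, so
words scoring exactly 4.0 or 6.0 are retained — the conservative reading
of "between 4 and 6", matching common usage of the instrument. The band
is applied for word-shift analysis and off by default for
classifier/HMM happiness features; both are configurable. "Promotional
retweet" is operationalized as a retweet matching any of a configurable
case-insensitive whole-word pattern list (default: win, free, giveaway,
promo), logged per run.

The decomposition is the standard first-order word shift
δ_w = (h_w − h_ref)(p_comp,w − p_ref,w) with reference = healthy and
comparison = affected; Σ_w δ_w = h_comp − h_ref holds to 1e-10 on every
input and is the module's defining test. Removing band words can move
class happiness in either direction; no monotonicity is assumed.

## Synthetic cohort generator

The generator exists because participant-level data of this kind cannot
be shared; it produces cohorts with the statistical structure the
analyses assume, so that every downstream stage is testable and
calibratable.

Structure per user: a log-normal posting rate (σ = 0.4 in log units)
around `post_rate` = 5 tweets/day; per-day tweet counts Poisson; spans of
`days_span` calendar days from a common start date. Affected users carry
a latent daily affected probability: zero until onset, a linear ramp of
length `onset_lead_days` (default 90) reaching `plateau` (default 0.9) at
diagnosis, a plateau until `recovery_start_days` (default 90) after
diagnosis, then a linear decline over 120 days — the onset-ahead-of-
diagnosis and post-treatment-improvement shape the trajectory analysis is
designed to detect. In PTSD mode the ramp is anchored at the trauma date
(geometric-ish gap ahead of diagnosis, mean 586 days) rather than at
diagnosis. Survey scores are drawn above the clinical cutoff with 20%
leakage below, so the inclusion filters have work to do.

Each tweet draws its state from that day's latent probability, then its
tokens from a state-specific unigram distribution: an exponential tilt
p_w ∝ exp(θ·h_w) of the bundled lexicon, with θ solved so the healthy
state's mean happiness is 6.2 and the affected state's is 6.2 −
`effect_size`. Tilting keeps every word in play and shifts every
category's frequency monotonically, which is what makes the
alignment-agreement check meaningful across the whole feature roster.
All other class-linked behaviours scale with the same effect size —
affected-state tweets are longer (+0.75·effect words), less often
retweets (−0.04·effect), more often replies (+0.04·effect), and
slightly sparser (posting rate × (1 − 0.08·effect)) — so that
`effect_size = 0` is an exact null with no class signal anywhere. 30% of
tokens are out-of-lexicon filler, exercising coverage handling, and 5% of
retweets are "win/free/gift" promotional spam, exercising the word-shift
filter.

What the generator does **not** emulate: natural language (tokens are
i.i.d. draws, so there is no syntax, negation, or topical burstiness),
user-specific vocabulary, social-graph structure, circadian/weekday
rhythms, or drift in instrument coverage. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes when that
structure is present — a necessary calibration, not evidence about
performance on real populations.

## Calibration experiments and problem sizes

`tweetscreen.experiments` defines the standard self-checks, shared by the
test-suite and `scripts/acceptance.py`. Two stock cohort shapes are used:
the *episode* cohort (50 users/class, 120-day spans, affected users fully
in the affected state) isolates the emission-level effect size and is the
condition for classifier-power measurements — under a trajectory-shaped
cohort, most affected observations are genuinely emitted from the healthy
state, which caps attainable discrimination and would conflate latent
mixing with classifier power; the *trajectory* cohort (50 users/class,
one-year spans, onset 90 days pre-diagnosis) exercises the latent arc.
Power measurements use a 300-tree forest without grid search across
effect sizes {0, 0.5, 1, 2} × 5 seeds; HMM recovery uses 200 sequences ×
50 steps from a known two-state chain (means 0/3, unit variance,
self-transition 0.95). These sizes keep each experiment to minutes on one
core while holding Monte-Carlo error well below the margins being
checked. Typical results: AUC ≈ 0.52 at effect 0 (the residual above 0.5
is the observation-level-split leakage noted above), ≈ 0.99 at effect 2;
state means recovered within ~0.02 and self-transitions within ~0.01;
alignment agreement 100% on strong-effect cohorts; binned posterior
trajectories correlate ≈ 0.99 with the generator's latent ramp.

## Limitations

- Happiness measurement is unigram and lexicon-bound; sarcasm, negation
  and context are invisible.
- The HMM assumes conditionally independent Gaussian emissions and shared
  dynamics across users; per-individual trajectory modeling and richer
  time-series methods are out of scope.
- The alignment procedure validates state *identity*, not model adequacy.
- Benchmark constants shipped for report tables (general-practitioner
  accuracy and prior computational screens) are literature values for
  context only and are never recomputed.
- Published headline classifier metrics for this protocol came from a
  private population and are not reproducible from shippable inputs; the
  package's quantitative claims are therefore calibration results on the
  synthetic generator plus exact in-table arithmetic.
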