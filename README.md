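# tweetscreen

Lexicon-based mental-health screening and latent-trajectory analysis for
social-media text streams.

Clinical depression and PTSD often go undiagnosed for months. Because both
conditions change how people write — more negatively valenced words, longer
tweets, fewer retweets — a user's posting history carries signal that
precedes the first clinical diagnosis. `tweetscreen` is a reusable,
tested pipeline for this kind of analysis, aimed at computational social
scientists and digital-epidemiology researchers. It provides:

- **Feature extraction** — tweets are aggregated into *user-day* (or ISO
  user-week) observations: activity (tweets/day), mean word count,
  retweet/reply fractions, happiness under one or more word–valence
  lexicons (labMT/ANEW-style, 1–9 scale), and LIWC-style semantic category
  frequencies. Tweet happiness is the frequency-weighted mean
  *h* = Σ_w f_w·h_w / Σ_w f_w over lexicon-matched tokens.
- **Cohort filters** — the study-protocol inclusion rules: 3,200-tweet
  history cap, ≥5 posts, clinical survey cutoffs (CES-D ≥ 22,
  TSQ ≥ 6), and, in screening mode, restriction to tweets strictly before
  first diagnosis.
- **Screening** — a 1200-tree random forest on labeled observations:
  stratified 70/30 split, median imputation, stratified 5-fold
  cross-validated grid search maximizing F1, and recall / specificity /
  precision / NPV / F1 (+ ROC/AUC) averaged over five seeded runs, with
  impurity-based predictor importances.
- **Trajectories** — a two-state Gaussian HMM (diagonal covariance, EM +
  Viterbi) fit to unlabeled observation sequences; state identity is
  established post hoc by sign-agreement between state-mean differences
  and raw class-mean differences; the posterior probability of the
  affected state is binned by days from diagnosis (or trauma, for PTSD)
  with cubic polynomial trends and 95% CI bands.
- **Word shifts** — the between-class happiness difference decomposed into
  per-word contributions δ_w = (h_w − h_ref)(p_comp,w − p_ref,w), which
  sum exactly to h_comp − h_ref, after removing neutral-band words
  (4 < h < 6) and promotional retweets.
- **Synthetic cohorts** — since participant-level Twitter data of this
  kind are private, a seeded generator produces cohorts with the assumed
  structure: two user classes, log-normal per-user posting rates, and a
  latent onset → plateau → recovery arc anchored to diagnosis/trauma
  dates, with a configurable happiness effect size.

## Worked example

Run the full pipeline on a small synthetic depression cohort:

```bash
cat > config.yaml <<'EOF'
seed: 11
output_dir: runs/demo
simulation: {n_affected: 6, n_healthy: 6, days_span: 40, diagnosis_day: 30,
             onset_lead_days: 20, effect_size: 2.0}
screening: {n_trees: 30, hyperparameter_grid: null, n_runs: 2}
EOF
tweetscreen run --config config.yaml
```

which prints

```
run complete; report at runs/demo/report.json
screening mean metrics: recall=0.442, specificity=0.965, precision=0.818, npv=0.825, f1=0.573, auc=0.730
```

Reading the numbers: this cohort's affected users spend half their span in
the pre-onset (healthy) latent state, so recall is modest — many affected
user-days genuinely look healthy — while specificity and precision are
high: days the model flags are nearly always from affected users. The
output directory contains the filter audit (`filter_report.json`),
observation tables, per-run metrics and ROC points, the predictor ranking
(`importances.csv` — the happiness measure ranks first, e.g.
`toy_labmt_happy` at 0.164), the diagnosis-anchored time course
(`time_course.csv`, with `agreement_fraction: 1.0` in the run report
confirming the HMM states track the classes), and the word shift
(`wordshift.txt`), whose top lines show the affected class's happiness
pulled down by increased use of low-valence words:

```
h_ref = 6.3644   h_comp = 5.2043   shift = -1.1601

████████████████████| murder (-↑) -0.08570
   █████████████████| death (-↑) -0.07359
```

The same stages are available individually (`tweetscreen simulate`,
`filter`, `extract`, `screen`, `trajectory`, `wordshift`, `report`), and
everything is importable as a library (`tweetscreen.screening`,
`tweetscreen.trajectory`, ...).

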