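"""Calibration experiments run against the synthetic generator.

These are the package's standard self-checks: because the real study
population is private, correctness is demonstrated by recovering known
quantities from synthetic cohorts — classifier power that grows with the
configured happiness gap, HMM parameter recovery from data with known
dynamics, perfect state/label alignment under a strong effect, and
anchor-aligned trajectories that match the generator's latent ramp.

Two stock cohort shapes are used:

* the *episode* cohort — affected users observed during a fully developed
  illness episode (latent probability ~1 throughout) — isolates the
  emission-level effect size, making it the right condition for measuring
  classifier power as a function of that effect;
* the *trajectory* cohort — one year of history with onset 90 days before
  diagnosis and recovery beginning 90 days after — exercises the latent
  ramp that the HMM time course should reconstruct.

Problem sizes (50 users per class, 120- or 365-day spans, a few hundred
trees without grid search) are chosen to make each experiment run in
minutes on one core while leaving Monte-Carlo error well below the margins
being tested.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .features import extract_observations, feature_columns
from .filters import apply_filters
from .lexicon import toy_category_lexicon, toy_happiness_lexicon
from .screening import ScreeningConfig, evaluate, split_observations, train_classifier
from .synthetic import SimulationConfig, generate_cohort, ground_truth_states, latent_series
from .trajectory import align_states, fit_gaussian_hmm, fit_hmm, time_course


def episode_config(effect_size: float, seed: int, n_per_class: int = 50) -> SimulationConfig:
    """Affected users in a fully developed episode for the whole span."""
    return SimulationConfig(
        n_affected=n_per_class, n_healthy=n_per_class,
        days_span=120, effect_size=effect_size,
        diagnosis_day=0, diagnosis_jitter_days=0,
        onset_lead_days=0, recovery_start_days=100_000,
        plateau=1.0, seed=seed,
    )


def trajectory_config(effect_size: float, seed: int, n_per_class: int = 50,
                      days_span: int = 365) -> SimulationConfig:
    """One year of history with a diagnosis-anchored onset/recovery arc."""
    return SimulationConfig(
        n_affected=n_per_class, n_healthy=n_per_class,
        days_span=days_span, effect_size=effect_size, seed=seed,
    )


def quick_screening_config() -> ScreeningConfig:
    """Single-run forest without grid search, for power measurements."""
    return ScreeningConfig(n_trees=300, hyperparameter_grid=None, n_runs=1)


def _observations(cfg: SimulationConfig) -> pd.DataFrame:
    users, tweets = generate_cohort(cfg)
    users, tweets, _ = apply_filters(
        users, tweets, condition=cfg.condition, prediagnosis_only=False)
    return extract_observations(
        tweets, users,
        happiness_lexicons=[toy_happiness_lexicon("toy_labmt"),
                            toy_happiness_lexicon("toy_anew")],
        category_lexicon=toy_category_lexicon(),
    )


def held_out_auc(effect_size: float, seed: int,
                 config: ScreeningConfig | None = None) -> float:
    """AUC of one split/fit/evaluate cycle on an episode cohort."""
    obs = _observations(episode_config(effect_size, seed))
    cfg = config or quick_screening_config()
    train, test = split_observations(obs, cfg.train_fraction, seed, cfg.by_user)
    model = train_classifier(train, cfg, seed)
    return float(evaluate(model, test)["auc"])


def power_curve(effect_sizes=(0.0, 0.5, 1.0, 2.0), seeds=(0, 1, 2, 3, 4),
                config: ScreeningConfig | None = None) -> pd.DataFrame:
    """Held-out AUC per (effect size, seed) on episode cohorts."""
    rows = [
        {"effect_size": e, "seed": s, "auc": held_out_auc(e, s, config)}
        for e in effect_sizes for s in seeds
    ]
    return pd.DataFrame(rows)


def alignment_experiment(seed: int, effect_size: float = 2.0,
                         n_per_class: int = 50):
    """Fit the pooled 2-state HMM to a strong-effect cohort and run the
    state/label sign-agreement check."""
    cfg = trajectory_config(effect_size, seed, n_per_class, days_span=180)
    cfg = replace(cfg, diagnosis_day=120)
    obs = _observations(cfg)
    fit = fit_hmm(obs, n_states=2, seed=seed)
    return align_states(fit, obs)


def hmm_recovery_experiment(seed: int, n_sequences: int = 200, n_steps: int = 50,
                            means=(0.0, 3.0), self_transition: float = 0.95) -> dict:
    """Parameter recovery from data simulated out of a known two-state
    Gaussian HMM (unit variance, sticky transitions).

    The simulator here is independent of the fitting code: plain numpy
    draws of the chain and emissions.  Returns absolute errors of the
    matched state means and self-transition probabilities.
    """
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n_sequences):
        states = np.empty(n_steps, dtype=int)
        states[0] = rng.integers(2)
        for t in range(1, n_steps):
            stay = rng.random() < self_transition
            states[t] = states[t - 1] if stay else 1 - states[t - 1]
        seqs.append(rng.normal(np.asarray(means)[states], 1.0).reshape(-1, 1))

    fit = fit_gaussian_hmm(seqs, n_states=2, seed=seed)
    est_means = fit.state_means[:, 0]
    order = np.argsort(est_means)          # match states by mean
    true_order = np.argsort(means)
    mean_err = np.abs(est_means[order] - np.asarray(means)[true_order])
    self_trans = np.diag(fit.transmat)[order]
    trans_err = np.abs(self_trans - self_transition)
    return {
        "state_means": est_means[order].tolist(),
        "self_transitions": self_trans.tolist(),
        "max_mean_error": float(mean_err.max()),
        "max_self_transition_error": float(trans_err.max()),
        "converged": fit.converged,
    }


def trajectory_experiment(seed: int, effect_size: float = 2.0,
                          n_per_class: int = 50, bin_width_days: int = 14) -> dict:
    """Full trajectory pipeline on the one-year cohort, with the
    generator's latent states as ground-truth oracle.

    Returns the fitted time course, the alignment result, and per-bin
    comparisons: affected vs healthy posterior means, and the true mean
    latent probability in each affected bin.
    """
    cfg = trajectory_config(effect_size, seed, n_per_class)
    users, tweets = generate_cohort(cfg)
    users, tweets, _ = apply_filters(
        users, tweets, condition=cfg.condition, prediagnosis_only=False)
    obs = extract_observations(
        tweets, users,
        happiness_lexicons=[toy_happiness_lexicon("toy_labmt"),
                            toy_happiness_lexicon("toy_anew")],
        category_lexicon=toy_category_lexicon(),
    )
    fit = fit_hmm(obs, n_states=2, seed=seed)
    alignment = align_states(fit, obs)
    tc = time_course(fit, users, alignment.affected_state_index,
                     anchor="diagnosis", bin_width_days=bin_width_days)

    # ground-truth latent probability binned the same way for affected users
    users_by_id = {u.user_id: u for u in users}
    rows = []
    for u in users:
        if u.group != "affected":
            continue
        p = latent_series(cfg, u)
        diag = (u.diagnosis_date - cfg.start_date).days
        for t, val in enumerate(p):
            offset = t - diag
            rows.append({"bin_start": int(np.floor(offset / bin_width_days)) * bin_width_days,
                         "p": val})
    truth = (pd.DataFrame(rows).groupby("bin_start")["p"].mean()
             .rename("true_latent").reset_index())

    aff = tc.bins[tc.bins["group"] == "affected"][["bin_start", "mean_prob", "n"]]
    hea = tc.bins[tc.bins["group"] == "healthy"][["bin_start", "mean_prob"]]
    merged = (aff.merge(hea, on="bin_start", suffixes=("_affected", "_healthy"))
              .merge(truth, on="bin_start", how="left"))
    return {
        "config": cfg,
        "time_course": tc,
        "alignment": alignment,
        "bins": merged,
    }
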