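"""Latent illness trajectories via a two-state Gaussian hidden Markov model.

Observations (one feature vector per user-day) are z-scored, pooled across
users — each user contributing one ordered sequence — and fit with a
two-state HMM with diagonal Gaussian emissions by expectation-maximization;
Viterbi paths and per-observation posterior state probabilities are
decoded from the same fit.  Class labels are stripped before fitting: the
model sees only the features.

State identity is established after the fact by the alignment-agreement
procedure: for every feature, the sign of the between-state difference in
fitted means is compared with the sign of the between-class difference in
the raw data, under the state-to-class mapping that maximizes agreement.
A high agreement fraction is evidence the latent states track the
affected/healthy distinction.

The "probability of illness" plotted in time courses is the posterior
probability of the affected latent state, binned by days from the anchor
event (diagnosis, or trauma for PTSD) with cubic polynomial trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .features import feature_columns, period_date
from .synthetic import UserRecord

logger = logging.getLogger(__name__)


@dataclass
class HMMFit:
    """A fitted pooled HMM plus per-observation decodings.

    ``state_means`` / ``state_covars`` are reported in the original
    feature units (the internal z-scoring is inverted).  ``posteriors``
    rows align with ``obs_index`` and sum to 1; ``transmat`` rows are
    stochastic.
    """

    feature_names: list[str]
    state_means: np.ndarray          # (n_states, p), raw units
    state_covars: np.ndarray         # (n_states, p), raw units (diagonal)
    transmat: np.ndarray
    startprob: np.ndarray
    posteriors: np.ndarray           # (n_obs, n_states)
    viterbi: np.ndarray              # (n_obs,)
    obs_index: pd.DataFrame | None   # columns: user_id, period (None for raw sequences)
    log_likelihood: float
    converged: bool
    separation: np.ndarray           # |mean diff| per feature, z-units (2-state fits)
    degenerate: bool


def fit_gaussian_hmm(
    sequences: list[np.ndarray],
    n_states: int = 2,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    zscore: bool = True,
    obs_index: pd.DataFrame | None = None,
) -> HMMFit:
    """Fit a diagonal-covariance Gaussian HMM to pooled sequences.

    Each element of ``sequences`` is a (T_i, p) array; one EM run fits a
    single model across all of them.  Means are initialized k-means-style
    with a fixed seed (hmmlearn's default), so fits are reproducible.
    """
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    seqs = [s.reshape(len(s), -1) for s in seqs]
    X = np.concatenate(seqs, axis=0)
    lengths = [len(s) for s in seqs]
    if len(X) < 10 * n_states:
        raise ValueError(
            f"{len(X)} observations is too few to fit {n_states} states "
            f"(need >= {10 * n_states})")
    if np.isnan(X).any():
        raise ValueError("HMM features must be complete; impute first")

    if zscore:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Z = (X - mu) / sd

    # start/transition probabilities start uniform (hmmlearn's random draws
    # can seed EM in a collapsed optimum); means start k-means-style.
    model = GaussianHMM(
        n_components=n_states, covariance_type="diag",
        n_iter=max_iter, tol=tol, random_state=seed, init_params="mc",
    )
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = np.full((n_states, n_states), 1.0 / n_states)
    model.fit(Z, lengths)
    converged = bool(model.monitor_.converged)
    if not converged:
        logger.warning("EM did not converge in %d iterations; loglik trace: %s",
                       max_iter, list(model.monitor_.history))

    posteriors = model.predict_proba(Z, lengths)
    viterbi = model.predict(Z, lengths)

    means_raw = model.means_ * sd + mu
    covars_raw = model.covars_
    if covars_raw.ndim == 3:  # hmmlearn returns (n, p, p) diagonal matrices
        covars_raw = np.array([np.diag(c) for c in covars_raw])
    covars_raw = covars_raw * sd**2

    if n_states == 2:
        separation = np.abs(model.means_[0] - model.means_[1])
    else:
        separation = np.zeros(X.shape[1])
    degenerate = n_states == 2 and bool(separation.max() < 0.2)
    if degenerate:
        logger.warning("degenerate fit: state means separated by < 0.2 sd "
                       "on every feature")

    return HMMFit(
        feature_names=[],
        state_means=means_raw,
        state_covars=covars_raw,
        transmat=model.transmat_,
        startprob=model.startprob_,
        posteriors=posteriors,
        viterbi=viterbi,
        obs_index=obs_index,
        log_likelihood=float(model.monitor_.history[-1]),
        converged=converged,
        separation=separation,
        degenerate=degenerate,
    )


def fit_hmm(
    observations: pd.DataFrame,
    n_states: int = 2,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> HMMFit:
    """Fit the pooled HMM to an observation table.

    Labels and identifiers are stripped internally — the fit depends only
    on the feature columns, each user forming one period-ordered sequence.
    Missing features are imputed with pooled medians before fitting.
    """
    feature_cols = feature_cols or feature_columns(observations)
    df = observations.copy()
    df["_pdate"] = df["period"].map(period_date)
    df = df.sort_values(["user_id", "_pdate"], kind="mergesort")

    X = df[feature_cols].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = np.take(med, nan_cols)

    lengths = df.groupby("user_id", sort=False).size().to_list()
    seqs = np.split(X, np.cumsum(lengths)[:-1])
    obs_index = df[["user_id", "period"]].reset_index(drop=True)

    fit = fit_gaussian_hmm(
        seqs, n_states=n_states, seed=seed, tol=tol, max_iter=max_iter,
        obs_index=obs_index)
    fit.feature_names = list(feature_cols)
    return fit


@dataclass
class AlignmentResult:
    """Outcome of the state/label sign-agreement check."""

    per_feature: dict[str, bool]
    agreement_fraction: float
    affected_state_index: int
    n_compared: int


def align_states(
    fit: HMMFit,
    observations: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> AlignmentResult:
    """Match HMM states to classes by sign agreement of mean differences.

    For each feature, the sign of (affected − healthy) in the raw data is
    compared to the sign of the between-state difference in fitted means;
    the mapping maximizing agreement wins.  Features whose raw difference
    is exactly zero are excluded from the denominator.
    """
    feature_cols = feature_cols or fit.feature_names or feature_columns(observations)
    aff = observations[observations["label"] == "affected"]
    hea = observations[observations["label"] == "healthy"]
    if aff.empty or hea.empty:
        raise ValueError("both classes required to align states")

    raw_diff = (aff[feature_cols].mean() - hea[feature_cols].mean()).to_numpy()
    nonzero = raw_diff != 0.0
    if not nonzero.any():
        raise ValueError("all raw class differences are zero; alignment undefined")

    means = pd.DataFrame(fit.state_means, columns=fit.feature_names or feature_cols)
    state_diff = (means.iloc[0] - means.iloc[1])[feature_cols].to_numpy()

    best_idx, best_agree = 0, -1
    for affected_state in (0, 1):
        diff = state_diff if affected_state == 0 else -state_diff
        agree = int((np.sign(diff[nonzero]) == np.sign(raw_diff[nonzero])).sum())
        if agree > best_agree:
            best_agree, best_idx = agree, affected_state

    diff = state_diff if best_idx == 0 else -state_diff
    per_feature = {
        f: bool(np.sign(d) == np.sign(r))
        for f, d, r, nz in zip(feature_cols, diff, raw_diff, nonzero) if nz
    }
    return AlignmentResult(
        per_feature=per_feature,
        agreement_fraction=best_agree / int(nonzero.sum()),
        affected_state_index=best_idx,
        n_compared=int(nonzero.sum()),
    )


@dataclass
class TimeCourse:
    """Binned, anchor-aligned affected-state probability course."""

    anchor: str
    bin_width_days: int
    bins: pd.DataFrame       # group, bin_start, bin_end, midpoint, mean_prob, ci_low, ci_high, n
    trends: dict             # group -> {"coeffs": ascending-power list, "cov": matrix}

    def trend_value(self, group: str, days) -> np.ndarray:
        c = np.asarray(self.trends[group]["coeffs"])
        x = np.asarray(days, dtype=float)
        return np.polynomial.polynomial.polyval(x, c)

    def trend_band(self, group: str, days, z: float = 1.96):
        """Trend with a 95% pointwise confidence band."""
        c = np.asarray(self.trends[group]["coeffs"])
        cov = np.asarray(self.trends[group]["cov"])
        x = np.asarray(days, dtype=float)
        V = np.vander(x, 4, increasing=True)
        yhat = V @ c
        se = np.sqrt(np.einsum("ij,jk,ik->i", V, cov, V))
        return yhat, yhat - z * se, yhat + z * se


def _cubic_trend(midpoints: np.ndarray, y: np.ndarray) -> dict:
    V = np.vander(midpoints.astype(float), 4, increasing=True)
    coeffs, res, rank, _ = np.linalg.lstsq(V, y, rcond=None)
    dof = max(len(y) - rank, 1)
    if res.size:
        s2 = float(res[0]) / dof
    else:
        s2 = float(((y - V @ coeffs) ** 2).sum()) / dof
    cov = s2 * np.linalg.pinv(V.T @ V)
    return {"coeffs": coeffs.tolist(), "cov": cov.tolist()}


def time_course(
    fit: HMMFit,
    users: list[UserRecord],
    affected_state_index: int,
    anchor: str = "diagnosis",
    bin_width_days: int = 14,
) -> TimeCourse:
    """Bin posterior affected-state probabilities by days from the anchor.

    Affected observations are offset from the user's anchor date (day 0 =
    anchor); healthy users, who have no anchor, are offset from the
    midpoint of their own observed span, giving a consecutive comparison
    span of equivalent length.  Bins are half-open ``[k*w, (k+1)*w)``;
    each bin reports the mean posterior probability with a
    normal-approximation 95% CI, and a cubic least-squares trend is fit
    per group over bin midpoints.
    """
    if fit.obs_index is None:
        raise ValueError("fit carries no observation index")
    if anchor not in ("diagnosis", "trauma"):
        raise ValueError(f"unknown anchor {anchor!r}")

    users_by_id = {u.user_id: u for u in users}
    df = fit.obs_index.copy()
    df["p_aff"] = fit.posteriors[:, affected_state_index]
    df["_pdate"] = df["period"].map(period_date)

    offsets = np.empty(len(df), dtype=float)
    groups = np.empty(len(df), dtype=object)
    keep = np.ones(len(df), dtype=bool)
    midpoints = {
        uid: dmin + (dmax - dmin) / 2
        for uid, (dmin, dmax) in df.groupby("user_id")["_pdate"].agg(["min", "max"]).iterrows()
    }
    for i, (uid, pdate) in enumerate(zip(df["user_id"], df["_pdate"])):
        user = users_by_id.get(uid)
        if user is None:
            keep[i] = False
            continue
        groups[i] = user.group
        if user.group == "affected":
            anchor_date = user.diagnosis_date if anchor == "diagnosis" else user.trauma_date
            if anchor_date is None:
                logger.warning("%s: missing %s date; user skipped", uid, anchor)
                keep[i] = False
                continue
        else:
            anchor_date = midpoints[uid]
        offsets[i] = (pdate - anchor_date).days

    df = df.loc[keep].assign(offset=offsets[keep], group=groups[keep])
    df["bin_start"] = (np.floor(df["offset"] / bin_width_days) * bin_width_days).astype(int)

    rows = []
    for (group, start), sub in df.groupby(["group", "bin_start"]):
        p = sub["p_aff"].to_numpy()
        n = len(p)
        se = p.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        m = float(p.mean())
        rows.append({
            "group": group, "bin_start": int(start),
            "bin_end": int(start + bin_width_days),
            "midpoint": start + bin_width_days / 2.0,
            "mean_prob": m,
            "ci_low": m - 1.96 * se, "ci_high": m + 1.96 * se,
            "n": n,
        })
    bins = pd.DataFrame(rows).sort_values(["group", "bin_start"]).reset_index(drop=True)

    trends = {}
    for group, sub in bins.groupby("group"):
        if len(sub) >= 4:
            trends[group] = _cubic_trend(
                sub["midpoint"].to_numpy(), sub["mean_prob"].to_numpy())
    return TimeCourse(anchor=anchor, bin_width_days=bin_width_days,
                      bins=bins, trends=trends)
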