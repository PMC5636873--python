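from datetime import date

import numpy as np
import pandas as pd
import pytest

from conftest import make_user
from tweetscreen.trajectory import (AlignmentResult, HMMFit, align_states,
                                    fit_gaussian_hmm, fit_hmm, time_course)


def two_state_sequences(n_seq=30, n_steps=40, means=(0.0, 3.0), stay=0.9,
                        seed=0, p=1):
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n_seq):
        states = np.empty(n_steps, dtype=int)
        states[0] = rng.integers(2)
        for t in range(1, n_steps):
            states[t] = states[t - 1] if rng.random() < stay else 1 - states[t - 1]
        mu = np.asarray(means)[states][:, None] * np.ones(p)
        seqs.append(rng.normal(mu, 1.0))
    return seqs


def observation_table(n_users=12, n_days=30, gap=3.0, seed=0):
    """Labeled observations with a clean 2-feature class separation."""
    rng = np.random.default_rng(seed)
    rows = []
    for u in range(n_users):
        affected = u < n_users // 2
        for d in range(n_days):
            rows.append({
                "user_id": f"u{u:02d}",
                "period": (date(2014, 1, 1) + pd.Timedelta(days=d)).isoformat(),
                "label": "affected" if affected else "healthy",
                "f_low": rng.normal(-gap / 2 if affected else gap / 2, 1.0),
                "f_high": rng.normal(gap / 2 if affected else -gap / 2, 1.0),
            })
    return pd.DataFrame(rows)


class TestFitContracts:
    def test_stochasticity_and_posterior_normalization(self):
        fit = fit_gaussian_hmm(two_state_sequences(), n_states=2, seed=0)
        assert np.allclose(fit.transmat.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert fit.startprob.sum() == pytest.approx(1.0)

    def test_recovers_separated_means_in_raw_units(self):
        fit = fit_gaussian_hmm(two_state_sequences(seed=3), n_states=2, seed=3)
        means = np.sort(fit.state_means[:, 0])
        assert means[0] == pytest.approx(0.0, abs=0.3)
        assert means[1] == pytest.approx(3.0, abs=0.3)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="too few"):
            fit_gaussian_hmm([np.zeros((5, 1))], n_states=2)

    def test_nan_rejected(self):
        bad = [np.array([[1.0], [np.nan]] * 15)]
        with pytest.raises(ValueError, match="impute"):
            fit_gaussian_hmm(bad, n_states=2)

    def test_single_state_data_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        seqs = [rng.normal(0, 1, (40, 1)) for _ in range(10)]
        fit = fit_gaussian_hmm(seqs, n_states=2, seed=0)
        assert fit.degenerate


class TestFitHMMOnObservations:
    def test_label_blindness(self):
        obs = observation_table()
        fit_with = fit_hmm(obs, seed=1, feature_cols=["f_low", "f_high"])
        fit_without = fit_hmm(obs.drop(columns="label"), seed=1,
                              feature_cols=["f_low", "f_high"])
        np.testing.assert_array_equal(fit_with.posteriors, fit_without.posteriors)
        np.testing.assert_array_equal(fit_with.state_means, fit_without.state_means)

    def test_imputation_of_missing_features(self):
        obs = observation_table()
        obs.loc[obs.index[:10], "f_low"] = np.nan
        fit = fit_hmm(obs, seed=0, feature_cols=["f_low", "f_high"])
        assert np.isfinite(fit.posteriors).all()

    def test_obs_index_aligns(self):
        obs = observation_table()
        fit = fit_hmm(obs, seed=0, feature_cols=["f_low", "f_high"])
        assert len(fit.obs_index) == len(obs)
        assert set(fit.obs_index["user_id"]) == set(obs["user_id"])


class TestAlignStates:
    def make_fit(self, state_means, features):
        n = len(features)
        return HMMFit(
            feature_names=list(features),
            state_means=np.asarray(state_means, dtype=float),
            state_covars=np.ones((2, n)),
            transmat=np.full((2, 2), 0.5),
            startprob=np.array([0.5, 0.5]),
            posteriors=np.full((4, 2), 0.5),
            viterbi=np.zeros(4, dtype=int),
            obs_index=None,
            log_likelihood=0.0, converged=True,
            separation=np.ones(n), degenerate=False,
        )

    def obs_with_diffs(self, diffs):
        """Two observations per class with per-feature class differences."""
        cols = [f"x{i}" for i in range(len(diffs))]
        rows = []
        for label, sign in (("affected", +0.5), ("healthy", -0.5)):
            for _ in range(2):
                rows.append({"user_id": "u", "period": "2014-01-01",
                             "label": label,
                             **{c: sign * d for c, d in zip(cols, diffs)}})
        return pd.DataFrame(rows), cols

    def test_two_features_full_agreement(self):
        obs, cols = self.obs_with_diffs([1.0, -1.0])
        fit = self.make_fit([[2.0, -2.0], [0.0, 0.0]], cols)  # state 0 = affected
        res = align_states(fit, obs, cols)
        assert res.agreement_fraction == 1.0
        assert res.affected_state_index == 0

    def test_38_of_40_agreement(self):
        diffs = [1.0] * 40
        obs, cols = self.obs_with_diffs(diffs)
        state0 = [1.0] * 38 + [-1.0, -1.0]    # two features disagree
        fit = self.make_fit([state0, [0.0] * 40], cols)
        res = align_states(fit, obs, cols)
        assert res.agreement_fraction == pytest.approx(0.95)
        assert res.n_compared == 40

    def test_mapping_chosen_by_agreement(self):
        obs, cols = self.obs_with_diffs([1.0, 1.0])
        fit = self.make_fit([[-1.0, -1.0], [1.0, 1.0]], cols)  # state 1 = affected
        res = align_states(fit, obs, cols)
        assert res.affected_state_index == 1
        assert res.agreement_fraction == 1.0

    def test_zero_difference_features_excluded(self):
        obs, cols = self.obs_with_diffs([1.0, 0.0])
        fit = self.make_fit([[1.0, 1.0], [0.0, 0.0]], cols)
        res = align_states(fit, obs, cols)
        assert res.n_compared == 1

    def test_all_zero_differences_error(self):
        obs, cols = self.obs_with_diffs([0.0, 0.0])
        fit = self.make_fit([[1.0, 1.0], [0.0, 0.0]], cols)
        with pytest.raises(ValueError, match="alignment undefined"):
            align_states(fit, obs, cols)


class TestTimeCourse:
    def small_fit_and_users(self, n_days=200, seed=0):
        """HMM fit on observations whose affected posterior is injected."""
        obs = observation_table(n_users=6, n_days=n_days, seed=seed)
        fit = fit_hmm(obs, seed=seed, feature_cols=["f_low", "f_high"])
        users = []
        for uid in sorted(set(obs["user_id"])):
            label = obs.loc[obs["user_id"] == uid, "label"].iloc[0]
            if label == "affected":
                users.append(make_user(uid, "affected", survey_score=30,
                                       diagnosis=date(2014, 1, 1) + pd.Timedelta(days=n_days // 2)))
            else:
                users.append(make_user(uid, "healthy"))
        return obs, fit, users

    def test_binning_convention(self):
        obs, fit, users = self.small_fit_and_users()
        tc = time_course(fit, users, affected_state_index=0, bin_width_days=14)
        starts = tc.bins["bin_start"].to_numpy()
        assert (starts % 14 == 0).all()
        # observation dated anchor - 1 day lands in bin [-14, 0)
        aff = tc.bins[tc.bins["group"] == "affected"]
        assert -14 in aff["bin_start"].to_numpy()
        assert (aff["bin_end"] - aff["bin_start"] == 14).all()

    def test_bin_means_in_unit_interval(self):
        obs, fit, users = self.small_fit_and_users()
        tc = time_course(fit, users, affected_state_index=1, bin_width_days=14)
        assert tc.bins["mean_prob"].between(0, 1).all()
        assert (tc.bins["ci_low"] <= tc.bins["mean_prob"]).all()
        assert (tc.bins["mean_prob"] <= tc.bins["ci_high"]).all()

    def test_state_permutation_invariance(self):
        obs, fit, users = self.small_fit_and_users()
        res = align_states(fit, obs, ["f_low", "f_high"])
        tc1 = time_course(fit, users, res.affected_state_index, bin_width_days=14)

        swapped = HMMFit(
            feature_names=fit.feature_names,
            state_means=fit.state_means[::-1].copy(),
            state_covars=fit.state_covars[::-1].copy(),
            transmat=fit.transmat[::-1, ::-1].copy(),
            startprob=fit.startprob[::-1].copy(),
            posteriors=fit.posteriors[:, ::-1].copy(),
            viterbi=1 - fit.viterbi,
            obs_index=fit.obs_index,
            log_likelihood=fit.log_likelihood, converged=fit.converged,
            separation=fit.separation, degenerate=fit.degenerate,
        )
        res2 = align_states(swapped, obs, ["f_low", "f_high"])
        assert res2.affected_state_index == 1 - res.affected_state_index
        tc2 = time_course(swapped, users, res2.affected_state_index,
                          bin_width_days=14)
        pd.testing.assert_frame_equal(tc1.bins, tc2.bins)

    def test_missing_anchor_user_skipped(self):
        obs, fit, users = self.small_fit_and_users()
        tc = time_course(fit, users, affected_state_index=0, anchor="trauma",
                         bin_width_days=14)
        assert (tc.bins["group"] == "healthy").all()  # no trauma dates present

    def test_flat_null_trend(self):
        # healthy-only course: cubic trend should be flat within its CI band
        obs, fit, users = self.small_fit_and_users(seed=4)
        healthy_users = [u for u in users if u.group == "healthy"]
        tc = time_course(fit, healthy_users, affected_state_index=0,
                         bin_width_days=14)
        days = np.linspace(-70, 70, 5)
        yhat, lo, hi = tc.trend_band("healthy", days)
        spread = yhat.max() - yhat.min()
        band = float(np.mean(hi - lo))
        assert spread < max(3 * band, 0.1)
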