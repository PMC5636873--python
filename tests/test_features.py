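from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_tweet, make_user
from tweetscreen.features import (aggregate, category_frequencies,
                                  extract_observations, extract_tweet_features,
                                  feature_columns, happiness_score,
                                  normalize_tokens, summary_stats, tokenize)
from tweetscreen.lexicon import HappinessLexicon


class TestTokenize:
    @pytest.mark.parametrize("text,n_raw,norm", [
        ("I am sad.", 3, ["i", "am", "sad"]),
        ("  a  b ", 2, ["a", "b"]),
        ("", 0, []),
        ("ok!!! ...", 2, ["ok"]),       # pure-punctuation token drops from norm
        ("Don't stop", 2, ["don't", "stop"]),
    ])
    def test_examples(self, text, n_raw, norm):
        raw = tokenize(text)
        assert len(raw) == n_raw
        assert normalize_tokens(raw) == norm


class TestHappinessScore:
    lex = HappinessLexicon("t", {"good": 7.0, "bad": 3.0, "meh": 5.0})

    def test_weighted_mean(self):
        s = happiness_score(["good", "good", "bad"], self.lex)
        assert s == pytest.approx(17 / 3)

    def test_band_word_removed_when_applied(self):
        assert happiness_score(["meh"], self.lex, apply_band=True) is None
        assert happiness_score(["meh"], self.lex, apply_band=False) == 5.0

    def test_no_hits_missing(self):
        assert happiness_score(["zzz"], self.lex) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["good", "bad", "meh", "zzz", "x"]),
                    min_size=0, max_size=30))
    def test_matches_brute_force_oracle(self, tokens):
        # oracle: explicit token-by-token accumulation
        hits = [self.lex.entries[t] for t in tokens if t in self.lex.entries]
        expected = sum(hits) / len(hits) if hits else None
        got = happiness_score(tokens, self.lex)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


class TestCategoryFrequencies:
    def test_basic(self, catlex):
        freqs = category_frequencies(["mom", "eat", "xyz"], catlex)
        assert freqs["family"] == pytest.approx(1 / 3)
        assert freqs["ingest"] == pytest.approx(1 / 3)
        assert freqs["negemo"] == 0.0

    def test_multilabel_counts_each(self, catlex):
        freqs = category_frequencies(["kiss"], catlex)  # social + posemo
        assert freqs["social"] == 1.0 and freqs["posemo"] == 1.0

    def test_empty_all_zero(self, catlex):
        freqs = category_frequencies([], catlex)
        assert set(freqs.values()) == {0.0}


class TestAggregate:
    users = [make_user("u1", "affected", survey_score=30,
                       diagnosis=date(2014, 6, 1)),
             make_user("u2", "healthy")]

    def obs(self, tweets, labmt, catlex, unit="day"):
        tf = extract_tweet_features(tweets, [labmt], catlex)
        return aggregate(tf, self.users, unit)

    def test_one_observation_per_user_day(self, labmt, catlex):
        tweets = [make_tweet("u1", date(2014, 3, 1), "happy love", seconds=s)
                  for s in (10, 20, 30)]
        obs = self.obs(tweets, labmt, catlex)
        assert len(obs) == 1
        row = obs.iloc[0]
        assert row["n_tweets"] == 3
        assert row["label"] == "affected"
        assert row["mean_word_count"] == 2.0
        assert row["toy_labmt_happy"] == pytest.approx((8.30 + 8.42) / 2)

    def test_retweet_fraction(self, labmt, catlex):
        tweets = [make_tweet("u2", text="happy", retweet=r, seconds=i)
                  for i, r in enumerate([True, False, False])]
        obs = self.obs(tweets, labmt, catlex)
        assert obs.iloc[0]["retweet_fraction"] == pytest.approx(1 / 3)

    def test_iso_week_groups_monday_to_sunday(self, labmt, catlex):
        monday, sunday = date(2014, 3, 3), date(2014, 3, 9)
        next_monday = date(2014, 3, 10)
        tweets = [make_tweet("u2", d, "happy") for d in (monday, sunday, next_monday)]
        obs = self.obs(tweets, labmt, catlex, unit="week")
        assert len(obs) == 2
        assert obs.iloc[0]["n_tweets"] == 2

    def test_happiness_missing_iff_all_tweets_missing(self, labmt, catlex):
        tweets = [make_tweet("u2", text="qqq zzz", seconds=1),
                  make_tweet("u2", text="xxx", seconds=2)]
        obs = self.obs(tweets, labmt, catlex)
        assert np.isnan(obs.iloc[0]["toy_labmt_happy"])
        assert obs.iloc[0]["toy_labmt_coverage"] == 0.0

    def test_conservation_of_tweets(self, labmt, catlex):
        tweets = ([make_tweet("u1", date(2014, 3, d), "happy", seconds=s)
                   for d in (1, 2, 3) for s in (1, 2)]
                  + [make_tweet("u2", date(2014, 3, 1), "sad")])
        obs = self.obs(tweets, labmt, catlex)
        assert obs["n_tweets"].sum() == len(tweets)

    def test_permutation_invariance(self, labmt, catlex):
        tweets = [make_tweet("u1", date(2014, 3, 1 + i % 3), f"happy sad t{i}",
                             seconds=i) for i in range(12)]
        obs1 = self.obs(tweets, labmt, catlex)
        obs2 = self.obs(tweets[::-1], labmt, catlex)
        pd.testing.assert_frame_equal(obs1, obs2)

    def test_unknown_user_errors(self, labmt, catlex):
        with pytest.raises(ValueError, match="unknown users"):
            self.obs([make_tweet("ghost", text="hi")], labmt, catlex)

    def test_category_token_weighting(self, labmt, catlex):
        # day with 1+3 tokens; 'mom' once among 4 tokens total
        tweets = [make_tweet("u2", text="mom", seconds=1),
                  make_tweet("u2", text="go go go", seconds=2)]
        obs = self.obs(tweets, labmt, catlex)
        assert obs.iloc[0]["cat_family"] == pytest.approx(1 / 4)

    def test_feature_roster_stable(self, labmt, catlex):
        tweets = [make_tweet("u2", text="happy")]
        obs = self.obs(tweets, labmt, catlex)
        cols = feature_columns(obs)
        assert cols[:4] == ["n_tweets", "mean_word_count", "retweet_fraction",
                            "reply_fraction"]
        assert "toy_labmt_happy" in cols
        assert all(c.startswith("cat_") for c in cols[5:])
        assert "toy_labmt_coverage" not in cols  # audit column, not a predictor


class TestSummaryStats:
    def test_single_user(self, labmt):
        users = [make_user("u1", "healthy")]
        tweets = [make_tweet("u1", date(2014, 3, 1), "hi", seconds=i)
                  for i in range(7)]
        stats = summary_stats(users, tweets)
        row = stats[stats["group"] == "total"].iloc[0]
        assert row["posts_mean"] == 7 and row["posts_median"] == 7
        assert row["posts_sd"] == 0.0

    def test_group_rows(self):
        users = [make_user("a1", "affected", survey_score=30,
                           diagnosis=date(2014, 6, 1)),
                 make_user("h1", "healthy")]
        tweets = ([make_tweet("a1", seconds=i) for i in range(3)]
                  + [make_tweet("h1", seconds=i) for i in range(5)])
        stats = summary_stats(users, tweets).set_index("group")
        assert stats.loc["affected", "posts"] == 3
        assert stats.loc["healthy", "posts"] == 5
        assert stats.loc["total", "posts_mean"] == pytest.approx(4.0)

    def test_affected_observation_fraction(self, labmt, catlex):
        users = [make_user("a1", "affected", survey_score=30,
                           diagnosis=date(2014, 6, 1)),
                 make_user("h1", "healthy")]
        tweets = [make_tweet("a1", date(2014, 3, 1), "sad"),
                  make_tweet("h1", date(2014, 3, 1), "happy"),
                  make_tweet("h1", date(2014, 3, 2), "happy")]
        obs = extract_observations(tweets, users, [labmt], catlex)
        stats = summary_stats(users, tweets, obs)
        assert stats.iloc[0]["affected_obs_fraction"] == pytest.approx(1 / 3)
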