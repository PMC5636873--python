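from datetime import date, datetime, timezone

import pytest

from tweetscreen.lexicon import toy_category_lexicon, toy_happiness_lexicon
from tweetscreen.synthetic import Tweet, UserRecord


@pytest.fixture(scope="session")
def labmt():
    return toy_happiness_lexicon("toy_labmt")


@pytest.fixture(scope="session")
def anew():
    return toy_happiness_lexicon("toy_anew")


@pytest.fixture(scope="session")
def catlex():
    return toy_category_lexicon()


def make_tweet(user_id="u1", day=date(2014, 3, 1), text="happy day",
               retweet=False, reply=False, seconds=43200):
    ts = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    from datetime import timedelta
    return Tweet(user_id=user_id, timestamp=ts + timedelta(seconds=seconds),
                 text=text, is_retweet=retweet, is_reply=reply)


def make_user(user_id="u1", group="healthy", condition="depression",
              survey_score=None, diagnosis=None, trauma=None, age=30):
    return UserRecord(user_id=user_id, group=group, condition=condition,
                      survey_score=survey_score, diagnosis_date=diagnosis,
                      trauma_date=trauma, age=age)
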