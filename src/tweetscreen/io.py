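"""Reading and writing the pipeline's external formats.

Tweets travel as JSON Lines (one object per tweet: ``user_id``,
``timestamp`` ISO-8601, ``text``, ``is_retweet``, ``is_reply``); user
metadata as CSV with ISO-8601 dates and empty fields for missing values.
"""

from __future__ import annotations

import json
from datetime import date, datetime, timezone
from pathlib import Path

import pandas as pd

from .synthetic import Tweet, UserRecord

USER_COLUMNS = [
    "user_id", "group", "condition", "survey_score",
    "diagnosis_date", "trauma_date", "age",
]


def write_tweets_jsonl(tweets: list[Tweet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps({
                "user_id": t.user_id,
                "timestamp": t.timestamp.isoformat(),
                "text": t.text,
                "is_retweet": t.is_retweet,
                "is_reply": t.is_reply,
            }) + "\n")


def read_tweets_jsonl(path: str | Path) -> list[Tweet]:
    tweets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                ts = datetime.fromisoformat(rec["timestamp"])
                if ts.tzinfo is None:
                    ts = ts.replace(tzinfo=timezone.utc)
                tweets.append(Tweet(
                    user_id=str(rec["user_id"]), timestamp=ts,
                    text=str(rec["text"]),
                    is_retweet=bool(rec.get("is_retweet", False)),
                    is_reply=bool(rec.get("is_reply", False)),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed tweet record: {exc}") from exc
    return tweets


def _fmt_date(d: date | None) -> str:
    return d.isoformat() if d is not None else ""


def write_users_csv(users: list[UserRecord], path: str | Path) -> None:
    rows = [{
        "user_id": u.user_id, "group": u.group, "condition": u.condition,
        "survey_score": "" if u.survey_score is None else u.survey_score,
        "diagnosis_date": _fmt_date(u.diagnosis_date),
        "trauma_date": _fmt_date(u.trauma_date),
        "age": u.age,
    } for u in users]
    pd.DataFrame(rows, columns=USER_COLUMNS).to_csv(path, index=False)


def read_users_csv(path: str | Path) -> list[UserRecord]:
    df = pd.read_csv(path, dtype={"user_id": str}, keep_default_na=False)
    users = []
    for rec in df.to_dict("records"):
        users.append(UserRecord(
            user_id=rec["user_id"],
            group=rec["group"],
            condition=rec["condition"],
            survey_score=int(rec["survey_score"]) if str(rec["survey_score"]).strip() else None,
            diagnosis_date=date.fromisoformat(rec["diagnosis_date"]) if rec["diagnosis_date"] else None,
            trauma_date=date.fromisoformat(rec["trauma_date"]) if rec["trauma_date"] else None,
            age=int(rec["age"]),
        ))
    return users
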