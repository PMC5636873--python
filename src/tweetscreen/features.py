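"""Per-tweet feature extraction and user-day / user-week aggregation.

A "word" is a maximal run of non-whitespace characters; the raw word count
uses that definition directly.  For lexicon lookups a parallel normalized
token list is produced: lowercased, leading/trailing punctuation stripped,
empty results dropped.  Tweet happiness is the frequency-weighted mean
lexicon score over matched tokens; category features are relative token
frequencies.

Observations are the atomic unit of the downstream analyses: all of one
user's tweets within one calendar day (or ISO week), aggregated into a
single feature vector.  Days on which a user posts nothing yield no
observation — activity enters the model through ``n_tweets`` on posting
days, not zero-padding.
"""

from __future__ import annotations

import string
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .lexicon import CategoryLexicon, HappinessLexicon
from .synthetic import Tweet, UserRecord

_STRIP = string.punctuation + "‘’“”…"

BASE_FEATURES = ["n_tweets", "mean_word_count", "retweet_fraction", "reply_fraction"]


def tokenize(text: str) -> list[str]:
    """Split on runs of whitespace.  ``len(tokenize(t))`` is the raw word
    count."""
    return text.split()


def normalize_tokens(tokens: list[str]) -> list[str]:
    """Lowercase and strip leading/trailing punctuation; drop tokens that
    normalize to the empty string."""
    out = []
    for t in tokens:
        t = t.strip(_STRIP).lower()
        if t:
            out.append(t)
    return out


def happiness_score(
    tokens: list[str], lexicon: HappinessLexicon, apply_band: bool = False
) -> float | None:
    """Frequency-weighted mean happiness of the matched tokens, or None if
    nothing matches.  With ``apply_band`` stop-band words are ignored."""
    total = 0.0
    n = 0
    for t in tokens:
        s = lexicon.entries.get(t)
        if s is None:
            continue
        if apply_band:
            lo, hi = lexicon.stop_band
            if lo < s < hi:
                continue
        total += s
        n += 1
    return total / n if n else None


def category_frequencies(
    tokens: list[str], catlex: CategoryLexicon
) -> dict[str, float]:
    """Relative frequency of each category among the tokens.  A token
    contributes once to every label it carries; with no tokens all
    frequencies are zero."""
    counts = dict.fromkeys(catlex.categories, 0)
    for t in tokens:
        for lab in catlex.labels(t):
            counts[lab] += 1
    n = len(tokens)
    return {lab: (c / n if n else 0.0) for lab, c in counts.items()}


def iso_week(d: date) -> str:
    y, w, _ = d.isocalendar()
    return f"{y}-W{w:02d}"


def period_key(d: date, unit: str) -> str:
    if unit == "day":
        return d.isoformat()
    if unit == "week":
        return iso_week(d)
    raise ValueError(f"unknown unit {unit!r}")


def period_date(key: str) -> date:
    """Representative date of a period key: the day itself, or the Monday
    of an ISO week."""
    if "W" in key:
        year, week = key.split("-W")
        return date.fromisocalendar(int(year), int(week), 1)
    return date.fromisoformat(key)


def extract_tweet_features(
    tweets: list[Tweet],
    happiness_lexicons: list[HappinessLexicon],
    category_lexicon: CategoryLexicon | None = None,
    apply_band: bool = False,
) -> pd.DataFrame:
    """Per-tweet feature table: word count, context flags, one happiness
    column per lexicon, one token-count column per category."""
    cats = list(category_lexicon.categories) if category_lexicon is not None else []
    rows = []
    for t in tweets:
        raw = tokenize(t.text)
        norm = normalize_tokens(raw)
        row: dict = {
            "user_id": t.user_id,
            "date": t.date,
            "word_count": len(raw),
            "n_norm_tokens": len(norm),
            "is_retweet": t.is_retweet,
            "is_reply": t.is_reply,
        }
        for lex in happiness_lexicons:
            row[f"{lex.name}_happy"] = happiness_score(norm, lex, apply_band)
        if category_lexicon is not None:
            counts = dict.fromkeys(cats, 0)
            for tok in norm:
                for lab in category_lexicon.labels(tok):
                    counts[lab] += 1
            for lab in cats:
                row[f"catn_{lab}"] = counts[lab]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(
    tweet_features: pd.DataFrame,
    users: list[UserRecord],
    unit: str = "day",
) -> pd.DataFrame:
    """Aggregate per-tweet features into labeled user-day (or user-week)
    observations.

    Columns: ``user_id, period, label, n_tweets, mean_word_count,
    retweet_fraction, reply_fraction``, one ``<lexicon>_happy`` and
    ``<lexicon>_coverage`` pair per happiness lexicon (happiness is the
    mean over scored tweets, NaN when no tweet scored), and one
    ``cat_<label>`` token-weighted frequency per category.
    """
    labels = {u.user_id: u.group for u in users}
    unknown = set(tweet_features["user_id"]) - set(labels)
    if unknown:
        raise ValueError(f"tweets from unknown users: {sorted(unknown)[:5]}")

    df = tweet_features.copy()
    df["period"] = [period_key(d, unit) for d in df["date"]]
    happy_cols = [c for c in df.columns if c.endswith("_happy")]
    catn_cols = [c for c in df.columns if c.startswith("catn_")]

    gb = df.groupby(["user_id", "period"], sort=True)
    out = pd.DataFrame({
        "n_tweets": gb.size(),
        "mean_word_count": gb["word_count"].mean(),
        "retweet_fraction": gb["is_retweet"].mean(),
        "reply_fraction": gb["is_reply"].mean(),
    })
    for c in happy_cols:
        out[c] = gb[c].mean()                      # NaN-aware: mean over scored tweets
        out[c.replace("_happy", "_coverage")] = gb[c].apply(lambda s: s.notna().mean())
    if catn_cols:
        tok_sum = gb["n_norm_tokens"].sum()
        for c in catn_cols:
            freq = gb[c].sum() / tok_sum.replace(0, np.nan)
            out[c.replace("catn_", "cat_")] = freq.fillna(0.0)
    out = out.reset_index()
    out.insert(2, "label", out["user_id"].map(labels))
    return out


def feature_columns(observations: pd.DataFrame) -> list[str]:
    """The fixed predictor roster: activity, word count, context fractions,
    every happiness measure, every category frequency.  Coverage columns
    are audit data, not predictors."""
    happy = [c for c in observations.columns if c.endswith("_happy")]
    cats = [c for c in observations.columns if c.startswith("cat_")]
    return BASE_FEATURES + happy + cats


def extract_observations(
    tweets: list[Tweet],
    users: list[UserRecord],
    happiness_lexicons: list[HappinessLexicon],
    category_lexicon: CategoryLexicon | None = None,
    unit: str = "day",
    apply_band: bool = False,
) -> pd.DataFrame:
    """End-to-end extraction: tweets -> labeled observation table."""
    tf = extract_tweet_features(tweets, happiness_lexicons, category_lexicon, apply_band)
    if tf.empty:
        raise ValueError("no tweets to extract features from")
    return aggregate(tf, users, unit)


def summary_stats(
    users: list[UserRecord],
    tweets: list[Tweet],
    observations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cohort summary: per group and overall, user count, post count,
    mean (sd) and median posts per user; plus the affected share of
    observations when an observation table is supplied."""
    counts = pd.Series({u.user_id: 0 for u in users}, dtype=float)
    for t in tweets:
        if t.user_id in counts.index:
            counts[t.user_id] += 1
    groups = {u.user_id: u.group for u in users}
    rows = []
    for name, uids in (
        ("total", list(counts.index)),
        ("affected", [u for u, g in groups.items() if g == "affected"]),
        ("healthy", [u for u, g in groups.items() if g == "healthy"]),
    ):
        c = counts[uids]
        rows.append({
            "group": name,
            "users": len(uids),
            "posts": int(c.sum()),
            "posts_mean": float(c.mean()) if len(c) else float("nan"),
            "posts_sd": float(c.std(ddof=1)) if len(c) > 1 else 0.0,
            "posts_median": float(c.median()) if len(c) else float("nan"),
        })
    out = pd.DataFrame(rows)
    if observations is not None and len(observations):
        frac = float((observations["label"] == "affected").mean())
        out["affected_obs_fraction"] = [frac, float("nan"), float("nan")]
    return out
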