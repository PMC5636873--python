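"""Cohort inclusion and data-quality filters.

The filters mirror the study protocol and are applied in a fixed order:

1. ``cap_history`` — keep each user's most recent 3,200 tweets (the
   history depth a one-time Twitter API collection can reach);
2. ``min_posts`` — drop users with fewer than five posts;
3. ``survey_cutoff`` — drop affected users below the clinical screening
   cutoff (CES-D >= 22 for depression, TSQ >= 6 for PTSD); healthy users
   were screened separately for no illness history and pass through;
4. ``restrict_prediagnosis`` — in screening mode only, keep affected
   users' tweets strictly before the calendar day of first diagnosis.

Every filter returns a subset of its input; ``FilterReport`` audits the
user/tweet counts through the sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .synthetic import CESD_CUTOFF, TSQ_CUTOFF, Tweet, UserRecord

logger = logging.getLogger(__name__)

DEFAULT_HISTORY_CAP = 3200
DEFAULT_MIN_POSTS = 5


@dataclass
class FilterStage:
    name: str
    n_users_before: int
    n_users_after: int
    n_tweets_before: int
    n_tweets_after: int


@dataclass
class FilterReport:
    """Audit trail of the filter cascade."""

    stages: list[FilterStage] = field(default_factory=list)

    def record(self, name: str, users_before, users_after, tweets_before, tweets_after) -> None:
        stage = FilterStage(
            name,
            len(users_before), len(users_after),
            len(tweets_before), len(tweets_after),
        )
        if stage.n_users_after > stage.n_users_before or stage.n_tweets_after > stage.n_tweets_before:
            raise ValueError(f"filter {name!r} increased record counts")
        self.stages.append(stage)

    def to_dict(self) -> dict:
        return {"stages": [vars(s) for s in self.stages]}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def cap_history(tweets: list[Tweet], cap: int = DEFAULT_HISTORY_CAP) -> list[Tweet]:
    """Keep each user's ``cap`` most recent tweets (stable order on ties)."""
    by_user: dict[str, list[tuple[int, Tweet]]] = {}
    for i, t in enumerate(tweets):
        by_user.setdefault(t.user_id, []).append((i, t))
    keep: set[int] = set()
    for entries in by_user.values():
        # most recent first; input index breaks timestamp ties stably
        entries.sort(key=lambda e: (e[1].timestamp, e[0]), reverse=True)
        keep.update(i for i, _ in entries[:cap])
    return [t for i, t in enumerate(tweets) if i in keep]


def min_posts(
    users: list[UserRecord], tweets: list[Tweet], minimum: int = DEFAULT_MIN_POSTS
) -> list[UserRecord]:
    """Drop users with fewer than ``minimum`` posts."""
    counts: dict[str, int] = {}
    for t in tweets:
        counts[t.user_id] = counts.get(t.user_id, 0) + 1
    kept = [u for u in users if counts.get(u.user_id, 0) >= minimum]
    if users and not kept:
        logger.warning("min_posts(%d) removed every user", minimum)
    return kept


def survey_cutoff(
    users: list[UserRecord],
    condition: str | None = None,
    cesd_cutoff: int = CESD_CUTOFF,
    tsq_cutoff: int = TSQ_CUTOFF,
) -> list[UserRecord]:
    """Drop affected users below the clinical screening cutoff.

    Depression uses CES-D (keep score >= 22); PTSD uses TSQ (keep >= 6).
    Healthy users pass through regardless of score.  Non-default cutoffs
    are logged.
    """
    if (cesd_cutoff, tsq_cutoff) != (CESD_CUTOFF, TSQ_CUTOFF):
        logger.info("non-default survey cutoffs: CES-D %d, TSQ %d",
                    cesd_cutoff, tsq_cutoff)
    kept = []
    for u in users:
        if u.group != "affected":
            kept.append(u)
            continue
        cond = condition or u.condition
        if u.survey_score is None:
            raise ValueError(f"{u.user_id}: affected user with missing survey score")
        cutoff = cesd_cutoff if cond == "depression" else tsq_cutoff
        if u.survey_score >= cutoff:
            kept.append(u)
    return kept


def restrict_prediagnosis(tweets: list[Tweet], users: list[UserRecord]) -> list[Tweet]:
    """Keep only tweets from strictly before each affected user's diagnosis
    day (the diagnosis day itself is excluded); healthy users' tweets are
    untouched.  Screening mode only — trajectory analysis uses the full span.
    """
    diag = {u.user_id: u.diagnosis_date for u in users if u.group == "affected"}
    out = []
    for t in tweets:
        d = diag.get(t.user_id)
        if d is not None and t.date >= d:
            continue
        out.append(t)
    return out


def apply_filters(
    users: list[UserRecord],
    tweets: list[Tweet],
    cap: int = DEFAULT_HISTORY_CAP,
    minimum: int = DEFAULT_MIN_POSTS,
    condition: str | None = None,
    prediagnosis_only: bool = False,
    cesd_cutoff: int = CESD_CUTOFF,
    tsq_cutoff: int = TSQ_CUTOFF,
) -> tuple[list[UserRecord], list[Tweet], FilterReport]:
    """Run the full cascade in protocol order and return the audit report.

    ``prediagnosis_only=True`` selects screening mode (affected users'
    post-diagnosis tweets removed); trajectory runs leave it off.
    """
    report = FilterReport()

    capped = cap_history(tweets, cap)
    report.record("cap_history", users, users, tweets, capped)

    kept_users = min_posts(users, capped, minimum)
    report.record("min_posts", users, kept_users, capped, capped)

    screened = survey_cutoff(kept_users, condition, cesd_cutoff, tsq_cutoff)
    report.record("survey_cutoff", kept_users, screened, capped, capped)

    uids = {u.user_id for u in screened}
    kept_tweets = [t for t in capped if t.user_id in uids]
    if prediagnosis_only:
        kept_tweets = restrict_prediagnosis(kept_tweets, screened)
    report.record("restrict_prediagnosis" if prediagnosis_only else "user_subset",
                  screened, screened, capped, kept_tweets)
    return screened, kept_tweets, report
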