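"""Synthetic cohort generator.

Emulates the statistical structure the screening and trajectory analyses
assume: two user classes (affected / healthy), per-user Poisson posting
processes with log-normally distributed rates, and — for affected users — a
latent daily illness state that ramps up ahead of a clinical diagnosis
(depression) or follows a trauma event (PTSD), plateaus, and declines after
treatment begins.

Each tweet is drawn from one of two unigram emission distributions
("healthy-state" vs "affected-state"), mixed by that day's latent affected
probability.  The two distributions are exponential tilts of a base word
distribution over a happiness lexicon, separated in mean happiness by
``effect_size`` lexicon units.  All other class-linked behaviours (words per
tweet, retweet/reply rates, posting rate) are scaled by the same
``effect_size`` so that ``effect_size = 0`` yields an exact null: affected
and healthy users are then statistically indistinguishable.

The generator is fully deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone

import numpy as np
from scipy.optimize import brentq

from .lexicon import HappinessLexicon, toy_happiness_lexicon

logger = logging.getLogger(__name__)

#: Common function words deliberately absent from the bundled lexicons, so
#: that out-of-lexicon handling is exercised on every synthetic corpus.
FILLER_TOKENS = (
    "and", "to", "a", "in", "it", "is", "i", "you", "for", "on",
    "my", "at", "this", "so", "was", "but", "with", "have", "that", "be",
)

#: Vocabulary for promotional retweets ("win a free gift" spam).
PROMO_TOKENS = ("win", "free", "gift", "giveaway", "prize", "enter", "contest")

CESD_CUTOFF = 22  # minimum clinically relevant CES-D score
TSQ_CUTOFF = 6    # minimum clinically relevant TSQ score


@dataclass(frozen=True)
class UserRecord:
    """One study participant."""

    user_id: str
    group: str                    # "affected" | "healthy"
    condition: str                # "depression" | "ptsd"
    survey_score: int | None      # CES-D 0-60 or TSQ 0-10; None for healthy
    diagnosis_date: date | None
    trauma_date: date | None
    age: int

    def __post_init__(self) -> None:
        if self.group == "affected":
            if self.diagnosis_date is None:
                raise ValueError(f"{self.user_id}: affected user lacks diagnosis date")
            if self.condition == "ptsd":
                if self.trauma_date is None:
                    raise ValueError(f"{self.user_id}: PTSD user lacks trauma date")
                if self.trauma_date > self.diagnosis_date:
                    raise ValueError(f"{self.user_id}: trauma after diagnosis")
        elif self.group == "healthy":
            if self.diagnosis_date is not None or self.trauma_date is not None:
                raise ValueError(f"{self.user_id}: healthy user carries anchor dates")
        else:
            raise ValueError(f"{self.user_id}: unknown group {self.group!r}")


@dataclass(frozen=True)
class Tweet:
    """One authored post."""

    user_id: str
    timestamp: datetime           # UTC
    text: str
    is_retweet: bool = False
    is_reply: bool = False

    @property
    def date(self) -> date:
        return self.timestamp.date()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The defaults describe the standard study-like condition: ~1 year of
    history per user, diagnosis about two-thirds of the way through the
    span, latent onset 90 days before diagnosis, and recovery beginning
    90 days after it.
    """

    n_affected: int = 50
    n_healthy: int = 50
    condition: str = "depression"          # or "ptsd"
    days_span: int = 365
    post_rate: float = 5.0                 # mean tweets per user-day
    effect_size: float = 1.0               # happiness gap, lexicon units
    onset_lead_days: int = 90              # ramp length before diagnosis (or after trauma)
    recovery_start_days: int = 90          # plateau length after diagnosis
    recovery_duration_days: int = 120      # linear decline length
    trauma_to_diagnosis_days: float = 586  # mean trauma->diagnosis gap (PTSD)
    plateau: float = 0.9                   # peak latent affected probability
    start_date: date = date(2014, 1, 1)
    diagnosis_day: int | None = None       # day index of diagnosis; default 2/3 span
    diagnosis_jitter_days: int = 10
    rate_sigma: float = 0.4                # log-normal sd of per-user rates
    healthy_happy_mean: float = 6.2        # target token happiness, healthy state
    words_per_tweet: float = 9.0
    retweet_rate: float = 0.20
    reply_rate: float = 0.15
    out_of_lexicon_rate: float = 0.30
    promo_retweet_rate: float = 0.05       # fraction of retweets that are promotional
    survey_leak_rate: float = 0.20         # affected scores drawn below cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected < 0 or self.n_healthy < 0:
            raise ValueError("user counts must be >= 0")
        if self.post_rate <= 0:
            raise ValueError("post_rate must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.condition not in ("depression", "ptsd"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (0.0 <= self.plateau <= 1.0):
            raise ValueError("plateau must be in [0, 1]")


# ---------------------------------------------------------------------------
# Emission distributions

def tilted_distribution(scores: np.ndarray, target_mean: float) -> np.ndarray:
    """Probabilities ``p_w ∝ exp(theta * h_w)`` with theta chosen so the
    distribution's mean happiness equals ``target_mean``.

    Exponential tilting keeps every lexicon word in play while shifting
    frequency mass smoothly toward one end of the valence scale, so every
    category of words changes frequency monotonically with the tilt.
    """
    lo, hi = scores.min(), scores.max()
    if not (lo < target_mean < hi):
        raise ValueError(f"target mean {target_mean} outside lexicon range ({lo}, {hi})")

    def mean_at(theta: float) -> float:
        w = np.exp(theta * (scores - scores.max()))
        return float((scores * w).sum() / w.sum()) - target_mean

    theta = brentq(mean_at, -20.0, 20.0, xtol=1e-12)
    w = np.exp(theta * (scores - scores.max()))
    return w / w.sum()


def _state_params(cfg: SimulationConfig) -> dict:
    """Per-state behavioural parameters.  All class-linked differences
    scale with ``effect_size`` so the null (effect 0) carries no signal."""
    e = cfg.effect_size
    return {
        "happy_mean": (cfg.healthy_happy_mean, cfg.healthy_happy_mean - e),
        "words_per_tweet": (cfg.words_per_tweet, cfg.words_per_tweet + 0.75 * e),
        "retweet_rate": (
            cfg.retweet_rate,
            float(np.clip(cfg.retweet_rate - 0.04 * e, 0.01, 0.95)),
        ),
        "reply_rate": (
            cfg.reply_rate,
            float(np.clip(cfg.reply_rate + 0.04 * e, 0.01, 0.95)),
        ),
        # affected-state days are slightly quieter
        "rate_factor": (1.0, float(np.clip(1.0 - 0.08 * e, 0.3, 1.0))),
    }


# ---------------------------------------------------------------------------
# Latent trajectory

def latent_series(cfg: SimulationConfig, user: UserRecord) -> np.ndarray:
    """Daily latent affected probability over the simulated span.

    Healthy users: all zeros.  Affected users: zero until onset, linear
    ramp of length ``onset_lead_days`` up to ``plateau``, plateau until
    ``recovery_start_days`` after diagnosis, then linear decline to zero
    over ``recovery_duration_days``.  For depression the ramp is anchored
    so the plateau is reached at diagnosis; for PTSD the ramp starts at
    the trauma date.
    """
    t = np.arange(cfg.days_span, dtype=float)
    if user.group == "healthy":
        return np.zeros(cfg.days_span)

    diag = (user.diagnosis_date - cfg.start_date).days
    if user.condition == "ptsd":
        onset = (user.trauma_date - cfg.start_date).days
    else:
        onset = diag - cfg.onset_lead_days
    ramp_len = max(cfg.onset_lead_days, 1)
    rec_start = diag + cfg.recovery_start_days
    rec_len = max(cfg.recovery_duration_days, 1)

    p = np.clip((t - onset) / ramp_len, 0.0, 1.0) * cfg.plateau
    decline = np.clip(1.0 - (t - rec_start) / rec_len, 0.0, 1.0)
    p = np.where(t >= rec_start, cfg.plateau * decline, p)
    return p


def ground_truth_states(
    cfg: SimulationConfig, users: list[UserRecord]
) -> dict[tuple[str, date], float]:
    """Exact latent mixture weight used at generation time, keyed by
    ``(user_id, date)`` over each user's simulated span."""
    out: dict[tuple[str, date], float] = {}
    for user in users:
        p = latent_series(cfg, user)
        for i, val in enumerate(p):
            out[(user.user_id, cfg.start_date + timedelta(days=i))] = float(val)
    return out


# ---------------------------------------------------------------------------
# Cohort generation

def _draw_survey_score(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    leak = rng.random() < cfg.survey_leak_rate
    if cfg.condition == "depression":
        if leak:
            return int(rng.integers(5, CESD_CUTOFF))
        return int(np.clip(round(rng.normal(33, 7)), CESD_CUTOFF, 60))
    if leak:
        return int(rng.integers(0, TSQ_CUTOFF))
    return int(rng.integers(TSQ_CUTOFF, 11))


def _make_users(cfg: SimulationConfig, rng: np.random.Generator) -> list[UserRecord]:
    users: list[UserRecord] = []
    n_total = cfg.n_affected + cfg.n_healthy
    width = max(3, len(str(max(n_total, 1))))
    diag_day0 = cfg.diagnosis_day if cfg.diagnosis_day is not None else 2 * cfg.days_span // 3
    for i in range(n_total):
        affected = i < cfg.n_affected
        uid = f"u{i:0{width}d}"
        if affected:
            jitter = int(rng.integers(-cfg.diagnosis_jitter_days, cfg.diagnosis_jitter_days + 1)) \
                if cfg.diagnosis_jitter_days > 0 else 0
            diag_day = int(np.clip(diag_day0 + jitter, 0, cfg.days_span - 1))
            diagnosis = cfg.start_date + timedelta(days=diag_day)
            trauma = None
            if cfg.condition == "ptsd":
                gap = int(rng.geometric(1.0 / max(cfg.trauma_to_diagnosis_days, 1.0)))
                trauma = diagnosis - timedelta(days=gap)
            users.append(UserRecord(
                user_id=uid, group="affected", condition=cfg.condition,
                survey_score=_draw_survey_score(cfg, rng),
                diagnosis_date=diagnosis, trauma_date=trauma,
                age=int(np.clip(round(rng.normal(30.3, 8.3)), 18, 64)),
            ))
        else:
            users.append(UserRecord(
                user_id=uid, group="healthy", condition=cfg.condition,
                survey_score=None, diagnosis_date=None, trauma_date=None,
                age=int(np.clip(round(rng.normal(33.9, 8.3)), 19, 63)),
            ))
    return users


def _user_tweets(
    cfg: SimulationConfig,
    user: UserRecord,
    rng: np.random.Generator,
    probs_by_state: tuple[np.ndarray, np.ndarray],
    words: np.ndarray,
    params: dict,
) -> list[Tweet]:
    p_day = latent_series(cfg, user)
    lam_user = rng.lognormal(
        np.log(cfg.post_rate) - cfg.rate_sigma ** 2 / 2.0, cfg.rate_sigma
    )
    f_h, f_a = params["rate_factor"]
    lam_day = lam_user * (f_h + (f_a - f_h) * p_day)
    n_day = rng.poisson(lam_day)
    total = int(n_day.sum())
    if total == 0:
        return []

    day_idx = np.repeat(np.arange(cfg.days_span), n_day)
    p_tweet = p_day[day_idx]
    state = rng.random(total) < p_tweet                       # True = affected state

    wpm_h, wpm_a = params["words_per_tweet"]
    lengths = 1 + rng.poisson(np.where(state, wpm_a, wpm_h) - 1.0)
    rt_h, rt_a = params["retweet_rate"]
    rp_h, rp_a = params["reply_rate"]
    is_rt = rng.random(total) < np.where(state, rt_a, rt_h)
    is_rp = ~is_rt & (rng.random(total) < np.where(state, rp_a, rp_h))

    n_tokens = int(lengths.sum())
    token_state = np.repeat(state, lengths)
    ool = rng.random(n_tokens) < cfg.out_of_lexicon_rate
    tok = np.empty(n_tokens, dtype=object)
    for s, probs in ((False, probs_by_state[0]), (True, probs_by_state[1])):
        mask = (token_state == s) & ~ool
        k = int(mask.sum())
        if k:
            tok[mask] = words[rng.choice(len(words), size=k, p=probs)]
    k_ool = int(ool.sum())
    if k_ool:
        tok[ool] = np.array(FILLER_TOKENS, dtype=object)[
            rng.integers(0, len(FILLER_TOKENS), k_ool)
        ]

    bounds = np.cumsum(lengths)[:-1]
    texts = [" ".join(chunk) for chunk in np.split(tok, bounds)]

    promo = is_rt & (rng.random(total) < cfg.promo_retweet_rate)
    for i in np.flatnonzero(promo):
        k = int(rng.integers(3, 7))
        texts[i] = " ".join(rng.choice(np.array(PROMO_TOKENS, dtype=object), size=k))

    secs = rng.integers(0, 86400, total)
    order = np.lexsort((secs, day_idx))
    tweets = []
    for i in order:
        ts = datetime.combine(
            cfg.start_date + timedelta(days=int(day_idx[i])),
            datetime.min.time(),
            tzinfo=timezone.utc,
        ) + timedelta(seconds=int(secs[i]))
        tweets.append(Tweet(
            user_id=user.user_id, timestamp=ts, text=texts[i],
            is_retweet=bool(is_rt[i]), is_reply=bool(is_rp[i]),
        ))
    return tweets


def generate_cohort(
    cfg: SimulationConfig,
    lexicon: HappinessLexicon | None = None,
) -> tuple[list[UserRecord], list[Tweet]]:
    """Generate a full synthetic cohort: user records plus tweet stream.

    ``lexicon`` is the happiness instrument defining the emission
    vocabulary; defaults to the bundled toy lexicon.  The same instrument
    should then be used for feature extraction so that measured happiness
    gaps equal the configured ``effect_size``.
    """
    if cfg.n_affected + cfg.n_healthy == 0:
        logger.warning("zero users requested; returning empty cohort")
        return [], []
    lexicon = lexicon or toy_happiness_lexicon()
    words = np.array(sorted(lexicon.entries), dtype=object)
    scores = np.array([lexicon.entries[w] for w in words])
    params = _state_params(cfg)
    mu_h, mu_a = params["happy_mean"]
    probs_h = tilted_distribution(scores, mu_h)
    probs_a = tilted_distribution(scores, mu_a) if cfg.effect_size > 0 else probs_h

    rng = np.random.default_rng(cfg.seed)
    users = _make_users(cfg, rng)
    tweets: list[Tweet] = []
    for user in users:
        tweets.extend(_user_tweets(cfg, user, rng, (probs_h, probs_a), words, params))
    return users, tweets
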