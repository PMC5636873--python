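"""Word-shift decomposition of between-class happiness differences.

Class happiness is the frequency-weighted mean lexicon score over a pooled
class corpus, computed after two removals: neutral stop-band words (scores
strictly between 4 and 6 by default — articles, pronouns and other valence-
free filler) and obviously promotional retweets ("win a free gift"
giveaways, which inflate one class's positivity without reflecting what
users personally tweet about).

The difference h_comp − h_ref is then decomposed into additive per-word
contributions

    delta_w = (h_w − h_ref) · (p_comp,w − p_ref,w)

where p_c,w is word w's normalized frequency in class c over scorable,
non-band words.  The contributions sum exactly to the total difference
(the conservation identity — the defining correctness check).  A word is
tagged ``+``/``−`` as its score sits above/below the reference-class
happiness, and ``up``/``down`` as the comparison class used it more/less.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .features import normalize_tokens, tokenize
from .lexicon import HappinessLexicon
from .synthetic import Tweet

DEFAULT_PROMO_PATTERNS = ("win", "free", "giveaway", "promo")


@dataclass(frozen=True)
class ShiftFilters:
    """Corpus cleaning applied before happiness averaging."""

    apply_band: bool = True
    promotional_patterns: tuple[str, ...] = DEFAULT_PROMO_PATTERNS

    def is_promotional(self, tweet: Tweet) -> bool:
        """Case-insensitive whole-word pattern match, retweets only."""
        if not tweet.is_retweet or not self.promotional_patterns:
            return False
        pat = re.compile(
            r"\b(?:" + "|".join(re.escape(p) for p in self.promotional_patterns) + r")\b",
            re.IGNORECASE,
        )
        return bool(pat.search(tweet.text))


def corpus_counts(
    tweets: list[Tweet],
    lexicon: HappinessLexicon,
    filters: ShiftFilters | None = None,
) -> Counter:
    """Pooled counts of scorable words in a tweet collection, after
    promotional-retweet removal and (optionally) stop-band removal."""
    filters = filters or ShiftFilters()
    entries = lexicon.banded_entries() if filters.apply_band else lexicon.entries
    counts: Counter = Counter()
    for t in tweets:
        if filters.is_promotional(t):
            continue
        for tok in normalize_tokens(tokenize(t.text)):
            if tok in entries:
                counts[tok] += 1
    return counts


def happiness_of_counts(counts: Counter, lexicon: HappinessLexicon) -> float:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("corpus has no scorable tokens")
    return sum(lexicon.entries[w] * c for w, c in counts.items()) / total


def class_happiness(
    tweets_by_class: dict[str, list[Tweet]],
    lexicon: HappinessLexicon,
    filters: ShiftFilters | None = None,
) -> dict[str, float]:
    """Average happiness per class corpus after the removals."""
    out = {}
    for cls, tweets in tweets_by_class.items():
        counts = corpus_counts(tweets, lexicon, filters)
        if not counts:
            raise ValueError(f"class {cls!r} has no scorable tokens")
        out[cls] = happiness_of_counts(counts, lexicon)
    return out


@dataclass
class WordShiftResult:
    """Ranked per-word contributions to h_comp − h_ref."""

    h_ref: float
    h_comp: float
    contributions: pd.DataFrame  # word, h_w, p_ref, p_comp, delta, sign_tag, usage_tag

    @property
    def total_shift(self) -> float:
        return self.h_comp - self.h_ref

    def write_tsv(self, path: str | Path) -> None:
        self.contributions.to_csv(path, sep="\t", index=False)


def word_shift(
    ref_counts: Counter,
    comp_counts: Counter,
    lexicon: HappinessLexicon,
) -> WordShiftResult:
    """First-order decomposition of the happiness difference between a
    reference corpus (healthy) and a comparison corpus (affected).

    Both corpora must already be restricted to scorable words (see
    :func:`corpus_counts`).  Conservation holds exactly:
    ``sum(delta) == h_comp − h_ref``.
    """
    n_ref = sum(ref_counts.values())
    n_comp = sum(comp_counts.values())
    if n_ref == 0 or n_comp == 0:
        raise ValueError("both corpora must contain scorable tokens")
    h_ref = happiness_of_counts(ref_counts, lexicon)
    h_comp = happiness_of_counts(comp_counts, lexicon)

    rows = []
    for w in set(ref_counts) | set(comp_counts):
        h_w = lexicon.entries[w]
        p_ref = ref_counts.get(w, 0) / n_ref
        p_comp = comp_counts.get(w, 0) / n_comp
        delta = (h_w - h_ref) * (p_comp - p_ref)
        rows.append({
            "word": w, "h_w": h_w, "p_ref": p_ref, "p_comp": p_comp,
            "delta": delta,
            "sign_tag": "+" if h_w > h_ref else "-",
            "usage_tag": "up" if p_comp > p_ref else "down",
        })
    df = (pd.DataFrame(rows)
          .sort_values("delta", key=lambda s: s.abs(), ascending=False,
                       kind="mergesort")
          .reset_index(drop=True))
    return WordShiftResult(h_ref=h_ref, h_comp=h_comp, contributions=df)


def shift_from_tweets(
    ref_tweets: list[Tweet],
    comp_tweets: list[Tweet],
    lexicon: HappinessLexicon,
    filters: ShiftFilters | None = None,
) -> WordShiftResult:
    """Word shift straight from two tweet collections (reference =
    healthy, comparison = affected)."""
    return word_shift(
        corpus_counts(ref_tweets, lexicon, filters),
        corpus_counts(comp_tweets, lexicon, filters),
        lexicon,
    )


def render_shift(
    result: WordShiftResult,
    top_n: int = 50,
    path: str | Path | None = None,
) -> str:
    """Two-sided ranked rendering of the top contributions.

    Words contributing to a decrease in the comparison class's happiness
    bar to the left (negative delta), increases to the right.  Each row is
    annotated ``+``/``−`` (word valence relative to h_ref) and ``↑``/``↓``
    (used more/less by the comparison class).  Zero-delta words are
    omitted.  When ``path`` is given a matplotlib horizontal-bar version
    is also written.
    """
    df = result.contributions
    df = df[df["delta"] != 0.0].head(top_n)
    lines = [
        f"h_ref = {result.h_ref:.4f}   h_comp = {result.h_comp:.4f}   "
        f"shift = {result.total_shift:+.4f}",
        "",
    ]
    max_abs = df["delta"].abs().max() if len(df) else 1.0
    for _, r in df.iterrows():
        bar_len = max(1, int(round(20 * abs(r["delta"]) / max_abs)))
        bar = "█" * bar_len
        arrow = "↑" if r["usage_tag"] == "up" else "↓"
        tag = f"{r['sign_tag']}{arrow}"
        if r["delta"] < 0:
            lines.append(f"{bar:>20}| {r['word']} ({tag}) {r['delta']:+.5f}")
        else:
            lines.append(f"{'':>20}|{bar} {r['word']} ({tag}) {r['delta']:+.5f}")
    text = "\n".join(lines)

    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_df = df.iloc[::-1]
        fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(plot_df) + 1)))
        colors = ["#b2182b" if d < 0 else "#2166ac" for d in plot_df["delta"]]
        labels = [
            f"{w} ({s}{'↑' if u == 'up' else '↓'})"
            for w, s, u in zip(plot_df["word"], plot_df["sign_tag"], plot_df["usage_tag"])
        ]
        ax.barh(labels, plot_df["delta"], color=colors)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("contribution to $h_{comp} - h_{ref}$")
        ax.set_title(f"word shift: {result.h_ref:.2f} → {result.h_comp:.2f}")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return text
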