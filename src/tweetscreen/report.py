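"""Report constants and summary arithmetic.

``BENCHMARKS`` carries published point estimates used for side-by-side
display only: unassisted general-practitioner diagnostic accuracy for
depression (MVR: Mitchell, Vaze & Rao) and PTSD (TBA: Taubman-Ben-Ari et
al.), and earlier computational screens (DC: De Choudhury et al. for
depression; NHC: Nadeem, Horn & Coppersmith for PTSD).  These are
literature values and are never recomputed here.

``REFERENCE_COHORTS`` records the published cohort sizes of the study
population this pipeline's design mirrors, used to verify the summary
arithmetic (posts per user, affected observation share).
"""

from __future__ import annotations

BENCHMARKS: dict[str, dict[str, dict[str, float | None]]] = {
    "depression": {
        "MVR": {"recall": 0.510, "specificity": 0.813, "precision": 0.42,
                "npv": 0.858, "f1": 0.461},
        "DC": {"recall": 0.614, "specificity": None, "precision": 0.742,
               "npv": None, "f1": 0.672},
    },
    "ptsd": {
        "TBA": {"recall": 0.249, "specificity": 0.979, "precision": 0.429,
                "npv": 0.602, "f1": 0.315},
        "NHC": {"recall": 0.82, "specificity": None, "precision": 0.86,
                "npv": None, "f1": 0.84},
    },
}

#: Published cohort sizes: (n_users, n_posts) per group, and
#: (n_affected_observations, n_total_observations) per condition.
REFERENCE_COHORTS = {
    "depression": {
        "affected": {"users": 105, "posts": 164_218},
        "healthy": {"users": 99, "posts": 115_733},
        "total": {"users": 204, "posts": 279_951},
        "observations": {"affected": 23_541, "total": 74_990},
    },
    "ptsd": {
        "affected": {"users": 63, "posts": 91_589},
        "healthy": {"users": 111, "posts": 152_186},
        "total": {"users": 174, "posts": 243_775},
        "observations": {"affected": 13_008, "total": 54_197},
    },
}


def mean_posts_per_user(n_posts: int, n_users: int) -> int:
    """Mean posts per user, rounded to the nearest integer as printed in
    cohort summary tables."""
    if n_users <= 0:
        raise ValueError("n_users must be positive")
    return round(n_posts / n_users)


def affected_fraction_pct(n_affected: int, n_total: int, digits: int = 1) -> float:
    """Affected share of observations as a percentage, rounded to the
    printed precision."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_affected / n_total, digits)
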