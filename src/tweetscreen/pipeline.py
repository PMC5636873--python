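"""End-to-end run orchestration.

A run is configured by a YAML file (all keys optional; defaults follow the
study protocol: 3,200-post history cap, CES-D/TSQ cutoffs 22/6, 70/30
split, 1200 trees, five folds, five runs, two HMM states, 14-day bins for
diagnosis-anchored and 30-day bins for trauma-anchored courses) and
executed stage by stage:

    simulate -> filter -> extract -> screen / trajectory / wordshift -> report

The master seed propagates deterministically to every stage, so a full
synthetic run is exactly reproducible.  Each stage writes its artifact
into the output directory; the consolidated report records the exact
config, per-stage outputs, and the literature benchmark constants for
side-by-side display.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tsio
from .features import extract_observations, summary_stats
from .filters import DEFAULT_HISTORY_CAP, DEFAULT_MIN_POSTS, apply_filters
from .lexicon import (load_category_lexicon, load_happiness_lexicon,
                      toy_category_lexicon, toy_happiness_lexicon)
from .report import BENCHMARKS
from .screening import ScreeningConfig, run_screening
from .synthetic import SimulationConfig, generate_cohort
from .trajectory import align_states, fit_hmm, time_course
from .wordshift import ShiftFilters, render_shift, shift_from_tweets

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "extract", "screen", "trajectory",
              "wordshift", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    condition: str = "depression"
    unit: str = "day"
    seed: int = 0
    output_dir: Path = Path("runs/default")
    history_cap: int = DEFAULT_HISTORY_CAP
    min_posts: int = DEFAULT_MIN_POSTS
    cesd_cutoff: int = 22
    tsq_cutoff: int = 6
    bin_width_days: int | None = None        # default: 14 (diagnosis) / 30 (trauma)
    anchor: str | None = None                # default: diagnosis, trauma for ptsd
    n_states: int = 2
    happiness_lexicon_paths: list[str] = field(default_factory=list)
    category_lexicon_path: str | None = None
    tweets_path: str | None = None           # load instead of simulating
    users_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    shift_filters: ShiftFilters = field(default_factory=ShiftFilters)

    def resolved_anchor(self) -> str:
        if self.anchor:
            return self.anchor
        return "trauma" if self.condition == "ptsd" else "diagnosis"

    def resolved_bin_width(self) -> int:
        if self.bin_width_days is not None:
            if self.bin_width_days <= 0:
                raise ValueError("bin_width_days must be positive")
            return self.bin_width_days
        return 30 if self.resolved_anchor() == "trauma" else 14

    def lexicons(self):
        if self.happiness_lexicon_paths:
            happy = [load_happiness_lexicon(p) for p in self.happiness_lexicon_paths]
        else:
            happy = [toy_happiness_lexicon("toy_labmt"), toy_happiness_lexicon("toy_anew")]
        if self.category_lexicon_path:
            cats = load_category_lexicon(self.category_lexicon_path)
        else:
            cats = toy_category_lexicon()
        return happy, cats


def _build_section(cls, data: dict, path_keys=()):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse and validate a YAML run config, filling protocol defaults.

    Unknown keys raise, listing the offenders.  An absent/empty file
    yields the all-defaults config.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    if overrides:
        data.update(overrides)

    sim = _build_section(SimulationConfig, data.pop("simulation", {}) or {})
    scr_data = data.pop("screening", {}) or {}
    if "hyperparameter_grid" in scr_data and scr_data["hyperparameter_grid"] is not None:
        scr_data["hyperparameter_grid"] = dict(scr_data["hyperparameter_grid"])
    scr = _build_section(ScreeningConfig, scr_data)
    shf_data = data.pop("shift_filters", {}) or {}
    if "promotional_patterns" in shf_data:
        shf_data["promotional_patterns"] = tuple(shf_data["promotional_patterns"])
    shf = _build_section(ShiftFilters, shf_data)

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data["output_dir"] = Path(data.get("output_dir", "runs/default"))
    cfg = RunConfig(simulation=sim, screening=scr, shift_filters=shf, **data)
    cfg.resolved_bin_width()  # validates
    if cfg.unit not in ("day", "week"):
        raise ValueError(f"unknown unit {cfg.unit!r}")
    # master seed propagates to every stage
    cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed,
                                         condition=cfg.condition)
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages in dependency order.

    Artifacts flow in memory between requested stages; a stage whose
    upstream artifact is neither in memory nor on disk raises
    :class:`PipelineError` naming the stage.  Returns the consolidated
    run report (also written to ``output_dir/report.json``).
    """
    stages = tuple(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    happy_lexicons, cat_lexicon = config.lexicons()
    art: dict = {}
    report: dict = {"config": _config_dict(config), "stages": {}, "benchmarks": BENCHMARKS}

    def stage_done(name: str, t0: float, **info):
        report["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    def need(key: str, stage: str, loader=None, path: Path | None = None):
        if key in art:
            return art[key]
        if loader is not None and path is not None and path.exists():
            art[key] = loader(path)
            return art[key]
        raise PipelineError(
            f"stage {stage!r} requires missing upstream artifact {key!r}; "
            f"run the producing stage first")

    if "simulate" in stages:
        t0 = time.time()
        users, tweets = generate_cohort(config.simulation, happy_lexicons[0])
        tsio.write_users_csv(users, out / "users.csv")
        tsio.write_tweets_jsonl(tweets, out / "tweets.jsonl")
        art["users_raw"], art["tweets_raw"] = users, tweets
        stage_done("simulate", t0, n_users=len(users), n_tweets=len(tweets),
                   users_digest=_digest(out / "users.csv"),
                   tweets_digest=_digest(out / "tweets.jsonl"))
    elif config.users_path and config.tweets_path:
        art["users_raw"] = tsio.read_users_csv(config.users_path)
        art["tweets_raw"] = tsio.read_tweets_jsonl(config.tweets_path)

    if "filter" in stages:
        t0 = time.time()
        users = need("users_raw", "filter", tsio.read_users_csv, out / "users.csv")
        tweets = need("tweets_raw", "filter", tsio.read_tweets_jsonl, out / "tweets.jsonl")
        f_users, f_tweets, rep = apply_filters(
            users, tweets, cap=config.history_cap, minimum=config.min_posts,
            condition=config.condition, prediagnosis_only=False,
            cesd_cutoff=config.cesd_cutoff, tsq_cutoff=config.tsq_cutoff)
        _, s_tweets, rep_s = apply_filters(
            users, tweets, cap=config.history_cap, minimum=config.min_posts,
            condition=config.condition, prediagnosis_only=True,
            cesd_cutoff=config.cesd_cutoff, tsq_cutoff=config.tsq_cutoff)
        rep_s.write(out / "filter_report.json")
        art.update(users=f_users, tweets_full=f_tweets, tweets_screen=s_tweets)
        stage_done("filter", t0, report=rep_s.to_dict())

    if "extract" in stages:
        t0 = time.time()
        users = need("users", "extract")
        obs_full = extract_observations(
            need("tweets_full", "extract"), users, happy_lexicons, cat_lexicon,
            unit=config.unit)
        obs_screen = extract_observations(
            need("tweets_screen", "extract"), users, happy_lexicons, cat_lexicon,
            unit=config.unit)
        obs_full.to_csv(out / "observations_full.csv", index=False)
        obs_screen.to_csv(out / "observations_screening.csv", index=False)
        stats = summary_stats(users, need("tweets_full", "extract"), obs_full)
        stats.to_csv(out / "summary_stats.csv", index=False)
        art.update(obs_full=obs_full, obs_screen=obs_screen)
        stage_done("extract", t0,
                   n_observations_full=len(obs_full),
                   n_observations_screening=len(obs_screen),
                   summary=stats.to_dict("records"))

    if "screen" in stages:
        t0 = time.time()
        obs = need("obs_screen", "screen")
        metrics = run_screening(obs, config.screening, master_seed=config.seed)
        (out / "metric_report.json").write_text(json.dumps(metrics.to_dict(), indent=2))
        metrics.importances.to_csv(out / "importances.csv", index=False)
        if metrics.runs and "roc" in metrics.runs[0]:
            import pandas as pd
            pd.DataFrame(metrics.runs[0]["roc"]).to_csv(out / "roc.csv", index=False)
        art["metrics"] = metrics
        stage_done("screen", t0, mean=metrics.mean, sd=metrics.sd)

    if "trajectory" in stages:
        t0 = time.time()
        obs = need("obs_full", "trajectory")
        users = need("users", "trajectory")
        fit = fit_hmm(obs, n_states=config.n_states, seed=config.seed)
        alignment = align_states(fit, obs)
        tc = time_course(fit, users, alignment.affected_state_index,
                         anchor=config.resolved_anchor(),
                         bin_width_days=config.resolved_bin_width())
        tc.bins.to_csv(out / "time_course.csv", index=False)
        (out / "trend.json").write_text(json.dumps(tc.trends, indent=2))
        post = fit.obs_index.copy()
        post["p_affected"] = fit.posteriors[:, alignment.affected_state_index]
        post.to_csv(out / "posteriors.csv", index=False)
        art.update(hmm_fit=fit, alignment=alignment, time_course=tc)
        stage_done("trajectory", t0,
                   agreement_fraction=alignment.agreement_fraction,
                   affected_state_index=alignment.affected_state_index,
                   converged=fit.converged)

    if "wordshift" in stages:
        t0 = time.time()
        users = need("users", "wordshift")
        tweets = need("tweets_full", "wordshift")
        groups = {u.user_id: u.group for u in users}
        ref = [t for t in tweets if groups.get(t.user_id) == "healthy"]
        comp = [t for t in tweets if groups.get(t.user_id) == "affected"]
        result = shift_from_tweets(ref, comp, happy_lexicons[0], config.shift_filters)
        result.write_tsv(out / "wordshift.tsv")
        text = render_shift(result, top_n=50, path=out / "wordshift.png")
        (out / "wordshift.txt").write_text(text)
        art["wordshift"] = result
        stage_done("wordshift", t0, h_ref=result.h_ref, h_comp=result.h_comp)

    if "report" in stages:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(config.output_dir)
    return d
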