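"""End-to-end orchestration: read -> filter -> tokenize -> score -> regress.

``run_pipeline`` executes the whole analysis from a :class:`RunConfig`,
writes tidy CSV outputs plus a JSON manifest (config hash, package versions,
row counts per stage, seeds) so every output is re-derivable, and aborts with
the failing stage's name on error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import screen_then_fit
from .corpus import (DEFAULT_TIMEZONE, MIN_POSTINGS_DEFAULT, covariate_table,
                     filter_active_users, read_corpus)
from .lexicon import load_lexicon
from .scoring import accumulate_user_hour, diurnal_summary

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "age_group", "education", "geolocation", "hometown", "bmi_class", "sex_role",
    "log_followers", "log_followees", "log_chat_groups",
]
DEFAULT_EXPOSURES = ["sexual", "health"]
DEFAULT_OUTCOMES = [
    "positive_affect", "negative_affect", "positive_sentiment_score",
    "joy", "sadness", "anger", "fear", "disgust", "positive_emotion_score",
]


@dataclass
class RunConfig:
    lexicon_path: str
    corpus_path: str
    profiles_path: str
    output_dir: str
    lexicon_dialect: str = "tsv"
    timezone: str = DEFAULT_TIMEZONE
    min_postings: int = MIN_POSTINGS_DEFAULT
    tokenize_mode: str = "whitespace"
    match_mode: str = "token"
    baseline_mode: str = "active_hours"
    outcomes: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    exposures: list[str] = field(default_factory=lambda: list(DEFAULT_EXPOSURES))
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    scheme: str = "freedman_lane"
    permutations: int = 999
    screen_alpha: float = 0.20
    final_alpha: float = 0.05
    seed: int = 0
    column_map: dict | None = None

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_user_summary(baselines: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """One regression row per active user: outcome and exposure baselines
    joined to the coded covariates."""
    base = baselines.reset_index().rename(columns={"index": "user_id"})
    if "user_id" not in base.columns:
        base = base.rename(columns={base.columns[0]: "user_id"})
    return base.merge(covariates, on="user_id", how="inner")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output tables plus manifest."""
    cfg = config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.digest(),
        "versions": {
            "lexaffect": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise StageError(name, exc) from exc

    lexicon = run_stage("lexicon", lambda: load_lexicon(cfg.lexicon_path,
                                                        dialect=cfg.lexicon_dialect))
    manifest["stages"]["lexicon"] = {"n_dimensions": len(lexicon.dimension_names)}

    postings, profiles = run_stage("read", lambda: read_corpus(
        cfg.corpus_path, cfg.profiles_path, timezone=cfg.timezone,
        column_map=cfg.column_map))
    manifest["stages"]["read"] = {
        "n_postings": int(len(postings)), "n_profiles": int(len(profiles)),
        "n_skipped": postings.attrs["read_report"].n_skipped,
    }

    active = run_stage("filter", lambda: filter_active_users(postings, cfg.min_postings))
    kept = postings[postings["user_id"].isin(active)]
    manifest["stages"]["filter"] = {
        "min_postings": cfg.min_postings,
        "n_active_users": len(active), "n_postings_kept": int(len(kept)),
    }

    counts = run_stage("score", lambda: accumulate_user_hour(
        kept, lexicon, tokenize_mode=cfg.tokenize_mode, match_mode=cfg.match_mode))
    manifest["stages"]["score"] = {"n_user_hours": int(len(counts))}

    summary = run_stage("diurnal", lambda: diurnal_summary(
        counts, denominator_mode=cfg.baseline_mode))
    baselines, curves = summary["baselines"], summary["curves"]
    manifest["stages"]["diurnal"] = {"n_users": int(len(baselines))}

    def _summarize():
        cov = covariate_table(profiles[profiles["user_id"].isin(active)])
        return build_user_summary(baselines, cov)

    user_summary = run_stage("summarize", _summarize)
    manifest["stages"]["summarize"] = {"n_rows": int(len(user_summary))}

    def _regress():
        frames = []
        candidates = cfg.exposures + cfg.covariates
        rows = user_summary.copy()
        numeric = [t for t in candidates if t in rows.columns
                   and pd.api.types.is_numeric_dtype(rows[t])]
        keep = np.ones(len(rows), dtype=bool)
        for t in numeric + cfg.outcomes:
            if t in rows.columns:
                keep &= np.isfinite(pd.to_numeric(rows[t], errors="coerce"))
        dropped = int((~keep).sum())
        rows = rows[keep]
        for i, outcome in enumerate(cfg.outcomes):
            if outcome not in rows.columns:
                continue
            res = screen_then_fit(rows, outcome, [c for c in candidates if c in rows.columns],
                                  screen_alpha=cfg.screen_alpha, final_alpha=cfg.final_alpha,
                                  B=cfg.permutations, seed=cfg.seed + 10000 * i)
            res.insert(0, "outcome", outcome)
            frames.append(res)
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        out.attrs["n_dropped_rows"] = dropped
        return out

    regression = run_stage("regress", _regress)
    manifest["stages"]["regress"] = {
        "n_results": int(len(regression)), "B": cfg.permutations, "seed": cfg.seed,
        "n_dropped_rows": regression.attrs.get("n_dropped_rows", 0),
    }

    counts.to_csv(outdir / "user_hour_counts.csv")
    baselines.to_csv(outdir / "baselines.csv", index_label="user_id")
    curves.to_csv(outdir / "diurnal_curves.csv", index_label="hour")
    user_summary.to_csv(outdir / "user_summary.csv", index=False)
    regression.to_csv(outdir / "regression_results.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "lexicon": lexicon, "postings": kept, "profiles": profiles,
        "counts": counts, "baselines": baselines, "curves": curves,
        "user_summary": user_summary, "regression": regression,
        "manifest": manifest,
    }
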