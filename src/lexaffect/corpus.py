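"""Posting corpora, user profiles, the activity filter, and covariate coding.

Postings are (user_id, timestamp, text) records read from JSONL or CSV;
timestamps are localized to the study timezone before the clock hour is
extracted, and postings are pooled by clock hour across calendar days.
Profiles carry the demographic and social-network fields that become
regression covariates: age band, education, geolocation, hometown, BMI class
(NIH cut-points), self-reported sex role, and log-transformed follower /
followee / chat-group counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TIMEZONE = "Asia/Shanghai"
MIN_POSTINGS_DEFAULT = 25

#: Reference level first; the association module drops it in treatment coding.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("le25", "gt25"),
    "education": ("high_school_or_below", "above_high_school", "unknown"),
    "geolocation": ("guangzhou", "shenzhen", "dongguan", "other"),
    "hometown": ("guangdong", "non_guangdong", "unknown"),
    "bmi_class": ("normal", "underweight", "overweight", "obese", "unknown"),
    "sex_role": ("receptive", "insertive", "versatile", "unknown"),
}

PROFILE_COLUMNS = (
    "user_id", "age", "education", "geolocation", "hometown",
    "height", "weight", "sex_role", "followers", "followees", "chat_groups",
)


class CorpusError(ValueError):
    pass


@dataclass
class ReadReport:
    n_read: int
    n_skipped: int


def read_postings(
    path: str | Path,
    timezone: str = DEFAULT_TIMEZONE,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a posting table (JSONL or CSV by extension) into a DataFrame.

    Returns columns ``user_id``, ``ts`` (tz-aware, localized to *timezone*),
    ``hour`` (0-23 clock hour), ``text``.  Rows with missing user ids or
    unparseable timestamps are skipped with a logged count; more than 50%
    malformed rows is a hard error.
    """
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        records = []
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError:
                records.append(None)
        n_bad_json = sum(r is None for r in records)
        df = pd.DataFrame([r for r in records if r is not None])
    else:
        df = pd.read_csv(path, dtype=str)
        n_bad_json = 0

    cmap = {"user_id": "user_id", "ts": "ts", "text": "text"}
    if column_map:
        cmap.update(column_map)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise CorpusError(f"{path}: missing columns {missing}; have {list(df.columns)}")
    df = df.rename(columns={v: k for k, v in cmap.items()})[["user_id", "ts", "text"]]

    n_total = len(df) + n_bad_json
    ts = pd.to_datetime(df["ts"], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna() | df["user_id"].isna() | (df["user_id"].astype(str).str.len() == 0)
    n_skipped = int(bad.sum()) + n_bad_json
    if n_skipped:
        logger.warning("%s: skipped %d of %d malformed rows", path, n_skipped, n_total)
    if n_total and n_skipped > 0.5 * n_total:
        raise CorpusError(f"{path}: {n_skipped}/{n_total} rows malformed")

    out = df.loc[~bad].copy()
    out["user_id"] = out["user_id"].astype(str)
    out["ts"] = ts[~bad].dt.tz_convert(timezone)
    out["hour"] = out["ts"].dt.hour.astype(int)
    out["text"] = out["text"].fillna("").astype(str)
    out.attrs["read_report"] = ReadReport(n_read=len(out), n_skipped=n_skipped)
    return out.reset_index(drop=True)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read the user-profile CSV; absent columns are created as missing."""
    df = pd.read_csv(path)
    if "user_id" not in df.columns:
        raise CorpusError(f"{path}: profile table needs a user_id column")
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["user_id"] = df["user_id"].astype(str)
    return df[list(PROFILE_COLUMNS)]


def read_corpus(
    postings_path: str | Path,
    profiles_path: str | Path,
    timezone: str = DEFAULT_TIMEZONE,
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return (
        read_postings(postings_path, timezone=timezone, column_map=column_map),
        read_profiles(profiles_path),
    )


def filter_active_users(postings: pd.DataFrame, min_postings: int = MIN_POSTINGS_DEFAULT) -> set[str]:
    """Users meeting the study inclusion rule of >= *min_postings* postings."""
    if min_postings < 1:
        raise ValueError("min_postings must be >= 1")
    counts = postings.groupby("user_id").size()
    return set(counts.index[counts >= min_postings].astype(str))


# ---------------------------------------------------------------------------
# Covariate coding

def classify_bmi(height_m: float, weight_kg: float) -> str:
    """NIH BMI classes; boundaries closed on the left (BMI of exactly 25 is
    overweight)."""
    if not np.isfinite(height_m) or not np.isfinite(weight_kg) or height_m <= 0:
        return "unknown"
    with np.errstate(over="ignore", divide="ignore"):
        bmi = np.float64(weight_kg) / np.float64(height_m) ** 2
    if not np.isfinite(bmi):
        return "unknown"
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"


def _log10p1(x: float) -> float:
    # "log transformed" network counts: log10(x + 1) keeps zeros finite and
    # matches the magnitude of published summary means for counts in the
    # hundreds.
    if not np.isfinite(x) or x < 0:
        return np.nan
    return float(np.log10(x + 1))


_EDUCATION_MAP = {
    "high_school_or_below": "high_school_or_below",
    "high school or below": "high_school_or_below",
    "above_high_school": "above_high_school",
    "above high school": "above_high_school",
}
_GEO_MAP = {"guangzhou": "guangzhou", "shenzhen": "shenzhen", "dongguan": "dongguan"}
_HOMETOWN_MAP = {"guangdong": "guangdong", "non_guangdong": "non_guangdong",
                 "non-guangdong": "non_guangdong"}
_SEXROLE_MAP = {"insertive": "insertive", "receptive": "receptive", "versatile": "versatile"}


def _map_level(raw, mapping: dict[str, str], default: str) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return default
    return mapping.get(str(raw).strip().lower(), default)


def derive_covariates(profile: pd.Series | dict) -> dict:
    """Code one profile row into the regression covariates.

    Age is banded at 25 (``<=25`` vs ``>25``); geolocation collapses to the
    three named cities vs ``other``; BMI comes from weight/height**2; network
    counts get log10(x+1).  Missing categoricals map to their ``unknown``
    level rather than dropping the user.
    """
    p = dict(profile)
    age = pd.to_numeric(p.get("age"), errors="coerce")
    if pd.isna(age):
        age_group = "unknown"
    else:
        age_group = "le25" if age <= 25 else "gt25"

    height = pd.to_numeric(p.get("height"), errors="coerce")
    weight = pd.to_numeric(p.get("weight"), errors="coerce")
    if pd.notna(weight) and (pd.isna(height) or height <= 0):
        logger.warning("user %s: non-positive/missing height with weight present; BMI missing",
                       p.get("user_id"))
    bmi_class = classify_bmi(
        float(height) if pd.notna(height) else np.nan,
        float(weight) if pd.notna(weight) else np.nan,
    )

    geo = _map_level(p.get("geolocation"), _GEO_MAP, "other")
    if p.get("geolocation") is None or (isinstance(p.get("geolocation"), float)
                                        and np.isnan(p["geolocation"])):
        geo = "other"

    return {
        "user_id": str(p.get("user_id", "")),
        "age_group": age_group,
        "education": _map_level(p.get("education"), _EDUCATION_MAP, "unknown"),
        "geolocation": geo,
        "hometown": _map_level(p.get("hometown"), _HOMETOWN_MAP, "unknown"),
        "bmi_class": bmi_class,
        "sex_role": _map_level(p.get("sex_role"), _SEXROLE_MAP, "unknown"),
        "log_followers": _log10p1(pd.to_numeric(p.get("followers"), errors="coerce")),
        "log_followees": _log10p1(pd.to_numeric(p.get("followees"), errors="coerce")),
        "log_chat_groups": _log10p1(pd.to_numeric(p.get("chat_groups"), errors="coerce")),
    }


def covariate_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Vector of ``derive_covariates`` over a profile table, with factor
    columns cast to ordered categoricals (reference level first)."""
    rows = [derive_covariates(r) for _, r in profiles.iterrows()]
    df = pd.DataFrame(rows)
    for col, levels in FACTOR_LEVELS.items():
        extra = tuple(l for l in df[col].unique() if l not in levels)
        df[col] = pd.Categorical(df[col], categories=levels + extra)
    return df
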