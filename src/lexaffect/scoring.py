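"""Per-user-hour affect probabilities, baselines, and diurnal curves.

The measurement model: for a user u and clock hour h (postings pooled across
calendar days), the probability that a token belongs to a dimension's word
list is

    PA(u, h) = ||matched words(u, h)|| / ||all words(u, h)||

Two signed composites collapse the multi-dimension measurement into single
scores per user-hour, computed from pooled counts:

    positive_emotion_score  numerator:  joy - (sadness + anger + fear + disgust)
    positive_sentiment_score numerator: positive_affect - negative_affect

A user's baseline is the average of PA(u, h) over hours — by default over the
hours in which the user actually posted (``active_hours``); the literal
divide-by-24 convention (``all_hours``), which treats silent hours as zero
affect, is available for comparison.  The relative probability recenters each
user-hour by the user's own baseline plus the grand mean,

    RPA(u, h) = PA(u, h) - PA(u) + grand_mean,

and the population diurnal curve averages RPA(u, h) over the users active at
each hour.  User-hours with zero tokens are missing (NaN), not zero, and are
excluded from baselines, the grand mean, and active-user sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lexicon import Lexicon, tokenize

HOURS = tuple(range(24))

#: composite name -> (positive dims, negative dims); numerators are signed
#: differences of pooled counts.
COMPOSITES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "positive_emotion_score": (("joy",), ("sadness", "anger", "fear", "disgust")),
    "positive_sentiment_score": (("positive_affect",), ("negative_affect",)),
}


def composite_columns(dim_names: tuple[str, ...]) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Composites whose constituent dimensions are all present in the lexicon."""
    return {
        name: (pos, neg)
        for name, (pos, neg) in COMPOSITES.items()
        if all(d in dim_names for d in pos + neg)
    }


def accumulate_user_hour(
    postings: pd.DataFrame,
    lexicon: Lexicon,
    tokenize_mode: str = "whitespace",
    match_mode: str = "token",
    segmenter=None,
) -> pd.DataFrame:
    """Tally token totals and per-dimension match counts per (user, hour).

    *postings* needs columns ``user_id``, ``hour``, ``text``.  Counts from all
    of a user's postings in the same clock hour merge additively.  Composite
    count columns are appended per :data:`COMPOSITES`.

    Token mode uses a reverse word->dimensions index for literal entries (the
    standard dictionary-count implementation) plus a prefix scan for wildcard
    stems; substring mode runs the longest-first non-overlapping scanner on
    the raw text.
    """
    dims = lexicon.dimension_names
    literal = lexicon.literal_index()
    wildcards = {d: w for d, w in lexicon.wildcard_entries().items() if w}
    dim_pos = {d: i for i, d in enumerate(dims)}

    keys: dict[tuple[str, int], int] = {}
    totals: list[int] = []
    counts: list[np.ndarray] = []

    from .lexicon import count_matches  # local import avoids cycle at module load

    for user_id, hour, text in postings[["user_id", "hour", "text"]].itertuples(index=False):
        key = (user_id, int(hour))
        if key not in keys:
            keys[key] = len(totals)
            totals.append(0)
            counts.append(np.zeros(len(dims), dtype=np.int64))
        idx = keys[key]
        row = counts[idx]
        if match_mode == "token":
            tokens = tokenize(text, mode=tokenize_mode, segmenter=segmenter)
            totals[idx] += len(tokens)
            for tok in tokens:
                for d in literal.get(tok, ()):
                    row[dim_pos[d]] += 1
                for d, entries in wildcards.items():
                    if any(e.matches_token(tok) for e in entries):
                        row[dim_pos[d]] += 1
        elif match_mode == "substring":
            tokens = tokenize(text, mode=tokenize_mode, segmenter=segmenter)
            totals[idx] += len(tokens)
            for d in dims:
                row[dim_pos[d]] += count_matches(text, lexicon, d, match_mode="substring")
        else:
            raise ValueError(f"unknown match mode {match_mode!r}")

    index = pd.MultiIndex.from_tuples(keys.keys(), names=["user_id", "hour"])
    out = pd.DataFrame(np.vstack(counts) if counts else np.empty((0, len(dims)), dtype=np.int64),
                       index=index, columns=list(dims))
    out.insert(0, "token_total", pd.Series(totals, index=index, dtype=np.int64))
    for name, (pos, neg) in composite_columns(dims).items():
        out[name] = sum(out[d] for d in pos) - sum(out[d] for d in neg)
    return out.sort_index()


def hour_probability(counts: pd.DataFrame, dimension: str) -> pd.Series:
    """PA(u, h) = dimension count / token total; NaN where no tokens."""
    if dimension not in counts.columns:
        raise KeyError(f"unknown dimension {dimension!r}; have {list(counts.columns)}")
    total = counts["token_total"].astype(float)
    return (counts[dimension] / total.where(total > 0)).rename(dimension)


def probability_table(counts: pd.DataFrame) -> pd.DataFrame:
    """PA(u, h) for every dimension and composite, indexed by (user, hour)."""
    cols = [c for c in counts.columns if c != "token_total"]
    total = counts["token_total"].astype(float).where(counts["token_total"] > 0)
    return counts[cols].div(total, axis=0)


def baseline(pa: pd.Series, denominator_mode: str = "active_hours") -> pd.Series:
    """Per-user baseline PA(u): the user's average probability across hours.

    ``active_hours`` averages over defined (posted-in) hours; ``all_hours``
    divides the same sum by 24, the literal convention in which silent hours
    count as zero affect.
    """
    defined = pa.dropna()
    if defined.empty:
        raise ValueError("no defined user-hours; cannot compute baselines")
    by_user = defined.groupby(level="user_id")
    if denominator_mode == "active_hours":
        return by_user.mean()
    if denominator_mode == "all_hours":
        return by_user.sum() / len(HOURS)
    raise ValueError(f"unknown denominator mode {denominator_mode!r}")


def relative_probability(pa: pd.Series, denominator_mode: str = "active_hours") -> pd.Series:
    """RPA(u, h) = PA(u, h) - PA(u) + grand mean over defined user-hours."""
    base = baseline(pa, denominator_mode)
    grand_mean = float(pa.dropna().mean())
    users = pa.index.get_level_values("user_id")
    return pa - base.reindex(users).to_numpy() + grand_mean


def diurnal_curve(rpa: pd.Series) -> pd.DataFrame:
    """Population curve RPA(h): mean of RPA(u, h) over users defined at h.

    Returns a 24-row frame with columns ``rpa`` and ``n_users`` (|U(h)|);
    hours where no user posted are NaN with n_users 0.
    """
    defined = rpa.dropna()
    by_hour = defined.groupby(level="hour")
    curve = by_hour.mean().reindex(HOURS)
    n_users = by_hour.size().reindex(HOURS, fill_value=0).astype(int)
    return pd.DataFrame({"rpa": curve, "n_users": n_users}, index=pd.Index(HOURS, name="hour"))


def peak_window(curve: pd.Series, width: int = 3) -> tuple[int, int, float]:
    """Contiguous circular window of *width* hours maximizing the mean curve.

    Returns (start_hour, end_hour, mean_value); end is inclusive and may wrap
    past midnight (e.g. width 3 starting at 23 ends at 1).  Ties break to the
    earliest start hour.  Windows touching undefined hours are skipped; at
    least *width* defined hours are required.
    """
    if not 1 <= width <= 24:
        raise ValueError("width must be in 1..24")
    values = np.asarray(curve.reindex(HOURS), dtype=float) if isinstance(curve, pd.Series) \
        else np.asarray(curve, dtype=float)
    if values.shape != (24,):
        raise ValueError("curve must have 24 hourly values")
    if np.sum(np.isfinite(values)) < width:
        raise ValueError(f"need at least {width} defined hours")
    best: tuple[int, int, float] | None = None
    ext = np.concatenate([values, values])
    for start in range(24):
        window = ext[start:start + width]
        if not np.all(np.isfinite(window)):
            continue
        mean = float(window.mean())
        if best is None or mean > best[2] + 1e-15:
            best = (start, (start + width - 1) % 24, mean)
    if best is None:
        raise ValueError("no fully-defined window of the requested width")
    return best


def window_hours(start: int, end: int) -> tuple[int, ...]:
    """Hours covered by an inclusive circular window."""
    if end >= start:
        return tuple(range(start, end + 1))
    return tuple(range(start, 24)) + tuple(range(0, end + 1))


def diurnal_summary(
    counts: pd.DataFrame,
    denominator_mode: str = "active_hours",
) -> dict[str, pd.DataFrame | pd.Series]:
    """Full per-dimension scoring pass over a user-hour count table.

    Returns baselines (users x dimensions), curves (24 x dimensions), and the
    underlying RPA table.
    """
    pa = probability_table(counts)
    baselines = {}
    curves = {}
    rpa_cols = {}
    for col in pa.columns:
        baselines[col] = baseline(pa[col], denominator_mode)
        rpa = relative_probability(pa[col], denominator_mode)
        rpa_cols[col] = rpa
        curves[col] = diurnal_curve(rpa)["rpa"]
    return {
        "baselines": pd.DataFrame(baselines),
        "curves": pd.DataFrame(curves),
        "rpa": pd.DataFrame(rpa_cols),
    }
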