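"""Synthetic posting corpus with known diurnal and covariate structure.

The generator stands in for the real (undeposited) app corpus: each user
draws demographic covariates from published sample marginals, a posting count
and posting times, and every token is emitted i.i.d. from an hour-dependent
categorical distribution over per-dimension vocabularies plus neutral filler.
A dimension's emission probability for user u at hour h is

    p_d(u, h) = sigmoid( logit(base_d) + amp_d * cos(2*pi*(h - peak_d)/24)
                         + sd_d * z[u, d] + covariate effects )

so diurnal modulation lives on the logit scale (probabilities stay in (0, 1)
at any amplitude), users are heterogeneous through the standard-normal
random effects z, and configured effects couple a user's propensity on one
dimension (or a covariate level) into another dimension's emission rate —
the ground truth that the regression stage is asked to recover.

Vocabularies are disjoint synthetic word lists (``joy00`` ... ``joy19``),
whitespace-delimited, so every counting path is exercised without a Chinese
segmenter; an overlap fraction can borrow words across dimensions to test
multi-dimension matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import CORE_DIMENSIONS, Lexicon

#: Published per-token baseline rates (sample means of the baseline
#: probabilities) used as the generator's stated world.
DEFAULT_BASELINE_RATES: dict[str, float] = {
    "positive_affect": 0.014,
    "negative_affect": 0.016,
    "joy": 0.015,
    "sadness": 0.005,
    "anger": 0.0005,
    "fear": 0.0006,
    "disgust": 0.004,
    "sexual": 0.009,
    "health": 0.008,
}

#: (peak hour, logit amplitude) per dimension.  Morning peak (8) for positive
#: affect/joy, small-hours peak (3) for negative affect, sadness, disgust and
#: health, a late-night peak for sexual content; anger and fear are flat, as
#: observed.
DEFAULT_DIURNAL: dict[str, tuple[int, float]] = {
    "positive_affect": (8, 0.5),
    "negative_affect": (3, 0.5),
    "joy": (8, 0.5),
    "sadness": (3, 0.5),
    "anger": (0, 0.0),
    "fear": (0, 0.0),
    "disgust": (3, 0.5),
    "sexual": (23, 0.3),
    "health": (3, 0.5),
}

#: Sample demographic marginals (levels, probabilities).
DEFAULT_DEMOGRAPHICS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "age_group": (("le25", "gt25"), (0.5401, 0.4599)),
    "education": (("high_school_or_below", "above_high_school", ""),
                  (0.1310, 0.3533, 0.5157)),
    "geolocation": (("guangzhou", "shenzhen", "dongguan", "other"),
                    (0.3405, 0.3170, 0.0869, 0.2556)),
    "hometown": (("guangdong", "non_guangdong", ""), (0.4839, 0.3648, 0.1513)),
    "bmi_class": (("underweight", "normal", "overweight", "obese"),
                  (0.1639, 0.7576, 0.0664, 0.0121)),
    "sex_role": (("receptive", "insertive", "versatile", ""),
                 (0.2035, 0.2892, 0.2255, 0.2818)),
}

#: Log-scale (log10(x+1)) mean and SD for the network-count covariates.
DEFAULT_NETWORK_LOG: dict[str, tuple[float, float]] = {
    "followers": (2.341, 0.430),
    "followees": (1.786, 0.889),
    "chat_groups": (0.277, 0.331),
}

_BMI_RANGES = {
    "underweight": (16.0, 18.5),
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, 35.0),
}


class ConfigError(ValueError):
    pass


def build_synthetic_lexicon(
    words_per_dim: int = 20,
    n_filler: int = 200,
    overlap_fraction: float = 0.0,
    dims: tuple[str, ...] = CORE_DIMENSIONS,
) -> tuple[Lexicon, dict[str, list[str]], list[str]]:
    """Disjoint per-dimension vocabularies plus a filler list.

    Returns (lexicon, emission vocab per dimension, filler words).  With
    ``overlap_fraction`` > 0 each dimension's *lexicon* entry list also
    includes that fraction of the next dimension's words (cyclically), so a
    single token can match several dimensions — the emission vocabularies
    stay disjoint so the ground truth is unambiguous.
    """
    vocab = {d: [f"{d}{i:02d}" for i in range(words_per_dim)] for d in dims}
    filler = [f"filler{i:03d}" for i in range(n_filler)]
    n_shared = int(round(overlap_fraction * words_per_dim))
    lex_words = {}
    for i, d in enumerate(dims):
        words = list(vocab[d])
        if n_shared:
            words += vocab[dims[(i + 1) % len(dims)]][:n_shared]
        lex_words[d] = words
    return Lexicon.from_words(lex_words), vocab, filler


def _default_activity() -> np.ndarray:
    # Evening-skewed posting-time profile (peak ~21h), every hour positive.
    h = np.arange(24)
    w = np.exp(0.6 * np.cos(2 * np.pi * (h - 21) / 24))
    return w / w.sum()


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic corpus.

    ``covariate_effects`` maps ``(source, target_dimension) -> slope`` where
    source is either another dimension name (the slope multiplies that
    dimension's standard-normal user effect z) or ``"column=level"`` (the
    slope adds to the target's logit for users at that covariate level).
    """

    seed: int
    n_users: int = 500
    postings_per_user_mean: float = 81.0   # 477,374 / 5,871 postings per active user
    postings_per_user_dispersion: float = 2.0
    tokens_per_posting_mean: float = 30.0
    baseline_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    diurnal: dict[str, tuple[int, float]] = field(default_factory=lambda: dict(DEFAULT_DIURNAL))
    user_sd: dict[str, float] | float = 0.3
    covariate_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    activity_profile: np.ndarray = field(default_factory=_default_activity)
    demographics: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    network_log: dict = field(default_factory=lambda: dict(DEFAULT_NETWORK_LOG))
    words_per_dim: int = 20
    n_filler: int = 200
    overlap_fraction: float = 0.0
    n_days: int = 180
    start_date: str = "2016-01-01"
    timezone_offset: str = "+08:00"

    def user_sd_for(self, dim: str) -> float:
        if isinstance(self.user_sd, dict):
            return float(self.user_sd.get(dim, 0.0))
        return float(self.user_sd)

    @property
    def dims(self) -> tuple[str, ...]:
        return tuple(self.baseline_rates)


@dataclass
class SyntheticTruth:
    """Ground truth needed to score recovery without re-deriving anything."""

    config: GeneratorConfig
    user_effects: pd.DataFrame        # z[u, d], standard normal draws
    logit_offsets: pd.DataFrame       # sd_d * z + covariate effects, per user x dim
    expected_user_rate: pd.DataFrame  # mean over 24 h of p_d(u, h)
    emission_probs: np.ndarray        # (n_users, 24, n_dims)
    peak_hours: dict[str, int]
    amplitudes: dict[str, float]
    effects: dict[tuple[str, str], float]


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_profiles(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_users
    cols: dict[str, np.ndarray] = {"user_id": np.array([f"u{i:05d}" for i in range(n)])}
    draws = {}
    for col, (levels, probs) in cfg.demographics.items():
        probs = np.asarray(probs, dtype=float)
        draws[col] = rng.choice(len(levels), size=n, p=probs / probs.sum())
        cols[col] = np.asarray(levels, dtype=object)[draws[col]]

    age_band = cols.pop("age_group")
    cols["age"] = np.where(age_band == "le25",
                           rng.integers(18, 26, size=n),
                           rng.integers(26, 46, size=n)).astype(int)

    bmi_class = cols.pop("bmi_class")
    height = rng.normal(1.72, 0.06, size=n).clip(1.5, 2.0)
    bmi = np.empty(n)
    for cls, (lo, hi) in _BMI_RANGES.items():
        mask = bmi_class == cls
        bmi[mask] = rng.uniform(lo, hi - 1e-6, size=int(mask.sum()))
    cols["height"] = np.round(height, 2)
    cols["weight"] = np.round(bmi * height**2, 1)

    for col, (mean, sd) in cfg.network_log.items():
        v = rng.normal(mean, sd, size=n).clip(min=0)
        cols[col] = np.round(10**v - 1).astype(int).clip(min=0)

    return pd.DataFrame(cols)


def _emission_probs(cfg: GeneratorConfig, profiles: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    dims = cfg.dims
    n, D = cfg.n_users, len(dims)
    z = rng.standard_normal((n, D))
    offsets = z * np.array([cfg.user_sd_for(d) for d in dims])

    for (source, target), slope in cfg.covariate_effects.items():
        if target not in dims:
            raise ConfigError(f"effect target {target!r} is not a generated dimension")
        j = dims.index(target)
        if source in dims:
            offsets[:, j] += slope * z[:, dims.index(source)]
        elif "=" in source:
            col, level = source.split("=", 1)
            if col not in profiles.columns:
                raise ConfigError(f"effect source column {col!r} not in profiles")
            offsets[:, j] += slope * (profiles[col].astype(str) == level).to_numpy(float)
        else:
            raise ConfigError(f"effect source {source!r} is neither a dimension nor 'column=level'")

    h = np.arange(24)
    probs = np.empty((n, 24, D))
    for j, d in enumerate(dims):
        peak, amp = cfg.diurnal.get(d, (0, 0.0))
        diurnal = amp * np.cos(2 * np.pi * (h - peak) / 24)
        probs[:, :, j] = _sigmoid(_logit(cfg.baseline_rates[d]) + diurnal[None, :]
                                  + offsets[:, j][:, None])
    total = probs.sum(axis=2)
    if np.any(total >= 1.0):
        raise ConfigError(
            f"emission probabilities sum to {total.max():.3f} >= 1 at some user-hour; "
            "reduce baseline rates, amplitudes or effect sizes")
    uid = [f"u{i:05d}" for i in range(n)]
    z_df = pd.DataFrame(z, index=uid, columns=list(dims))
    off_df = pd.DataFrame(offsets, index=uid, columns=list(dims))
    return probs, z_df, off_df


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic corpus.

    Returns (postings, profiles, truth).  Postings have columns ``user_id``,
    ``ts`` (ISO-8601 with the configured UTC offset) and ``text``; the frame
    is byte-identical for a fixed config and seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dims = cfg.dims
    D = len(dims)

    profiles = _draw_profiles(cfg, rng)
    probs, z_df, off_df = _emission_probs(cfg, profiles, rng)

    # posting counts and times
    mean, size = cfg.postings_per_user_mean, cfg.postings_per_user_dispersion
    n_post = rng.negative_binomial(size, size / (size + mean), size=cfg.n_users)
    user_idx = np.repeat(np.arange(cfg.n_users), n_post)
    P = len(user_idx)
    act = np.asarray(cfg.activity_profile, dtype=float)
    act = act / act.sum()
    hours = rng.choice(24, size=P, p=act)
    days = rng.integers(0, cfg.n_days, size=P)
    minutes = rng.integers(0, 60, size=P)
    seconds = rng.integers(0, 60, size=P)

    # token emission, flattened over all tokens of all postings
    n_tok = 1 + rng.poisson(max(cfg.tokens_per_posting_mean - 1, 0.0), size=P)
    tok_post = np.repeat(np.arange(P), n_tok)
    T = len(tok_post)
    tok_user = user_idx[tok_post]
    tok_hour = hours[tok_post]
    cum = np.cumsum(probs, axis=2)                  # (n_users, 24, D)
    r = rng.random(T)
    cat = (r[:, None] > cum[tok_user, tok_hour, :]).sum(axis=1)  # D == filler

    _, vocab, filler = build_synthetic_lexicon(
        cfg.words_per_dim, cfg.n_filler, cfg.overlap_fraction, dims)
    vocab_arrays = [np.array(vocab[d], dtype=object) for d in dims]
    vocab_arrays.append(np.array(filler, dtype=object))
    words = np.empty(T, dtype=object)
    for c, arr in enumerate(vocab_arrays):
        mask = cat == c
        if mask.any():
            words[mask] = arr[rng.integers(0, len(arr), size=int(mask.sum()))]

    texts = pd.Series(words).groupby(tok_post).agg(" ".join)
    texts = texts.reindex(np.arange(P), fill_value="")

    base = pd.Timestamp(cfg.start_date)
    ts = (base + pd.to_timedelta(days * 86400 + hours * 3600 + minutes * 60 + seconds,
                                 unit="s"))
    ts_str = ts.strftime("%Y-%m-%dT%H:%M:%S") + cfg.timezone_offset

    postings = pd.DataFrame({
        "user_id": profiles["user_id"].to_numpy()[user_idx],
        "ts": ts_str,
        "text": texts.to_numpy(),
    })

    expected = pd.DataFrame(probs.mean(axis=1), index=z_df.index, columns=list(dims))
    truth = SyntheticTruth(
        config=cfg,
        user_effects=z_df,
        logit_offsets=off_df,
        expected_user_rate=expected,
        emission_probs=probs,
        peak_hours={d: cfg.diurnal.get(d, (0, 0.0))[0] for d in dims},
        amplitudes={d: cfg.diurnal.get(d, (0, 0.0))[1] for d in dims},
        effects=dict(cfg.covariate_effects),
    )
    return postings, profiles, truth


def write_corpus(postings: pd.DataFrame, profiles: pd.DataFrame, outdir) -> dict:
    """Write the JSONL/CSV files the corpus module reads; returns the paths."""
    from pathlib import Path
    import json as _json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus_path = outdir / "postings.jsonl"
    with corpus_path.open("w", encoding="utf-8") as fh:
        for rec in postings.to_dict(orient="records"):
            fh.write(_json.dumps(rec, ensure_ascii=False) + "\n")
    profiles_path = outdir / "profiles.csv"
    profiles.to_csv(profiles_path, index=False)
    return {"postings": corpus_path, "profiles": profiles_path}


def recovery_report(
    truth: SyntheticTruth,
    baselines: pd.DataFrame,
    curves: pd.DataFrame | None = None,
    regression: pd.DataFrame | None = None,
    peak_width: int = 3,
) -> dict:
    """Score a pipeline run against the generator's ground truth.

    Reports per-dimension bias and RMSE of recovered user baselines versus
    the generating 24-hour mean emission rates; circular peak-hour error of
    each diurnal curve versus the generating peak; and, when a screened
    regression table is supplied, whether each true-effect term was selected
    with the correct sign and which null terms were flagged.
    """
    from .scoring import peak_window

    report: dict = {"baseline": {}, "peaks": {}, "regression": {}}
    common = baselines.index.intersection(truth.expected_user_rate.index)
    for d in truth.config.dims:
        if d not in baselines.columns:
            continue
        est = baselines.loc[common, d].astype(float)
        true = truth.expected_user_rate.loc[common, d].astype(float)
        err = est - true
        report["baseline"][d] = {
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "n_users": int(len(common)),
        }
    if curves is not None:
        for d, peak in truth.peak_hours.items():
            if d not in curves.columns or truth.amplitudes.get(d, 0.0) == 0.0:
                continue
            start, end, _ = peak_window(curves[d], width=peak_width)
            from .scoring import window_hours
            hours = window_hours(start, end)
            circ_err = min(abs(h - peak) % 24 for h in hours)
            circ_err = min(circ_err, 24 - circ_err)
            report["peaks"][d] = {
                "true_peak": int(peak), "window": [int(start), int(end)],
                "peak_in_window": peak in hours, "circular_error": int(circ_err),
            }
    if regression is not None:
        multi = regression[regression["stage"] == "multivariate"]
        truth_slopes = {src: slope for (src, _tgt), slope in truth.effects.items()}
        for _, row in multi.iterrows():
            true_slope = truth_slopes.get(row["term"], 0.0)
            report["regression"][row["term"]] = {
                "true_slope": float(true_slope),
                "beta": float(row["beta"]),
                "significant": bool(row["significant"]),
                "sign_correct": bool(np.sign(row["beta"]) == np.sign(true_slope))
                if true_slope else None,
            }
    return report
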