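"""User-hour tallies, probabilities, baselines, RPA, and diurnal curves."""

import numpy as np
import pandas as pd
import pytest

from lexaffect.lexicon import Lexicon, count_matches, tokenize
from lexaffect.scoring import (HOURS, accumulate_user_hour, baseline,
                               diurnal_curve, diurnal_summary, hour_probability,
                               peak_window, probability_table,
                               relative_probability, window_hours)
from conftest import make_postings


@pytest.fixture
def counts_one(small_lexicon):
    postings = make_postings([("u1", 0, "love tear love")])
    return accumulate_user_hour(postings, small_lexicon)


class TestAccumulate:
    def test_single_posting_counts_and_composites(self, counts_one):
        row = counts_one.loc[("u1", 0)]
        assert row["token_total"] == 3
        assert row["joy"] == 2 and row["sadness"] == 1
        # joy - (sadness+anger+fear+disgust) = 2 - 1
        assert row["positive_emotion_score"] == 1

    def test_sentiment_score_is_signed_difference(self, small_lexicon):
        postings = make_postings([("u1", 0, "love sweet tear hurt tear tear hurt")])
        row = accumulate_user_hour(postings, small_lexicon).loc[("u1", 0)]
        assert row["positive_affect"] == 2 and row["negative_affect"] == 5
        assert row["positive_sentiment_score"] == -3

    def test_same_hour_postings_merge_additively(self, small_lexicon):
        texts = ["love tear", "excited", "tear tear roar"]
        merged = accumulate_user_hour(
            make_postings([("u1", 5, t) for t in texts]), small_lexicon)
        # brute-force per-posting recount
        for dim in small_lexicon.dimension_names:
            expected = sum(count_matches(tokenize(t), small_lexicon, dim) for t in texts)
            assert merged.loc[("u1", 5), dim] == expected
        assert merged.loc[("u1", 5), "token_total"] == sum(len(tokenize(t)) for t in texts)

    def test_counts_bounded_by_token_total(self, medium_run):
        counts = medium_run["counts"]
        for dim in medium_run["lexicon"].dimension_names:
            assert (counts[dim] <= counts["token_total"]).all()
            assert (counts[dim] >= 0).all()


class TestProbability:
    def test_fraction_of_tokens(self, small_lexicon):
        postings = make_postings([("u1", 0, "love excited w1 w2 w3 w4 w5 w6 w7 w8")])
        counts = accumulate_user_hour(postings, small_lexicon)
        assert hour_probability(counts, "joy").loc[("u1", 0)] == pytest.approx(0.2)

    def test_composite_can_be_negative(self, small_lexicon):
        postings = make_postings(
            [("u1", 0, "love sweet tear hurt tear tear hurt w1 w2 w3")])
        counts = accumulate_user_hour(postings, small_lexicon)
        assert hour_probability(counts, "positive_sentiment_score").loc[("u1", 0)] \
            == pytest.approx(-0.3)

    def test_zero_tokens_is_missing_not_zero(self, small_lexicon):
        postings = make_postings([("u1", 0, "!!!"), ("u1", 1, "love")])
        counts = accumulate_user_hour(postings, small_lexicon)
        pa = hour_probability(counts, "joy")
        assert np.isnan(pa.loc[("u1", 0)])
        assert pa.loc[("u1", 1)] == 1.0

    def test_bounds(self, medium_run):
        pa = probability_table(medium_run["counts"])
        uni = [c for c in pa.columns if not c.endswith("_score")]
        assert ((pa[uni] >= 0) & (pa[uni] <= 1) | pa[uni].isna()).all().all()
        comp = [c for c in pa.columns if c.endswith("_score")]
        assert ((pa[comp] >= -1) & (pa[comp] <= 1) | pa[comp].isna()).all().all()


def series_from(entries):
    """entries: {(user, hour): value} -> PA series with full index."""
    idx = pd.MultiIndex.from_tuples(entries.keys(), names=["user_id", "hour"])
    return pd.Series(list(entries.values()), index=idx, dtype=float)


class TestBaseline:
    def test_constant_user_same_in_both_modes(self):
        pa = series_from({("u", h): 0.4 for h in HOURS})
        for mode in ("active_hours", "all_hours"):
            assert baseline(pa, mode).loc["u"] == pytest.approx(0.4)

    def test_sparse_user_modes_differ(self):
        pa = series_from({("u", 0): 0.24})
        assert baseline(pa, "all_hours").loc["u"] == pytest.approx(0.01)
        assert baseline(pa, "active_hours").loc["u"] == pytest.approx(0.24)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(42)
        entries = {}
        for u in range(10):
            for h in rng.choice(24, size=rng.integers(1, 24), replace=False):
                entries[(f"u{u}", int(h))] = rng.random()
        pa = series_from(entries)
        base = baseline(pa, "active_hours")
        for u in {k[0] for k in entries}:
            vals = [v for (uu, _), v in entries.items() if uu == u]
            assert base.loc[u] == pytest.approx(np.mean(vals))

    def test_no_defined_hours_raises(self):
        pa = series_from({("u", 0): np.nan})
        with pytest.raises(ValueError):
            baseline(pa)


class TestRelativeProbability:
    def test_constant_user_is_fixed_point(self):
        pa = series_from({("u", h): 0.3 for h in range(5)})
        rpa = relative_probability(pa)
        assert np.allclose(rpa, 0.3)

    def test_two_user_hand_example(self):
        pa = series_from({("u1", 0): 0.1, ("u1", 1): 0.3,
                          ("u2", 0): 0.2, ("u2", 1): 0.2})
        rpa = relative_probability(pa)
        assert rpa.loc[("u1", 0)] == pytest.approx(0.1)
        assert rpa.loc[("u1", 1)] == pytest.approx(0.3)
        assert np.allclose(rpa.loc["u2"], 0.2)
        curve = diurnal_curve(rpa)
        assert curve.loc[0, "rpa"] == pytest.approx(0.15)
        assert curve.loc[1, "rpa"] == pytest.approx(0.25)
        assert curve.loc[0, "n_users"] == 2
        assert curve.loc[2:, "rpa"].isna().all()

    def test_centering_identity(self, medium_run):
        for dim in ("joy", "positive_sentiment_score"):
            pa = probability_table(medium_run["counts"])[dim]
            rpa = relative_probability(pa)
            assert rpa.dropna().mean() == pytest.approx(pa.dropna().mean(), abs=1e-12)

    def test_per_user_deviations_sum_to_zero(self, medium_run):
        pa = probability_table(medium_run["counts"])["joy"]
        base = baseline(pa, "active_hours")
        dev = (pa.dropna().groupby(level="user_id").mean() - base)
        assert np.abs(dev).max() < 1e-12


class TestDiurnalCurve:
    def test_single_user_curve_is_that_user(self):
        pa = series_from({("u", 0): 0.1, ("u", 3): 0.5})
        rpa = relative_probability(pa)
        curve = diurnal_curve(rpa)
        assert curve.loc[0, "rpa"] == pytest.approx(rpa.loc[("u", 0)])
        assert (curve["n_users"] <= 1).all()

    def test_identical_users_give_flat_curve(self):
        pa = series_from({(f"u{k}", h): 0.2 for k in range(3) for h in range(6)})
        curve = diurnal_curve(relative_probability(pa))
        assert np.allclose(curve["rpa"].dropna(), 0.2)


class TestPeakWindow:
    def test_unique_max_width_one(self):
        curve = pd.Series(0.0, index=range(24))
        curve[8] = 1.0
        assert peak_window(curve, 1) == (8, 8, 1.0)

    def test_sinusoid_window_contains_peak(self):
        h = np.arange(24)
        curve = pd.Series(np.cos(2 * np.pi * (h - 3) / 24), index=h)
        start, end, _ = peak_window(curve, 3)
        assert 3 in window_hours(start, end)
        # exhaustive scan oracle
        means = [np.mean([curve[(s + i) % 24] for i in range(3)]) for s in range(24)]
        assert start == int(np.argmax(means))

    def test_constant_curve_ties_to_earliest(self):
        curve = pd.Series(0.5, index=range(24))
        assert peak_window(curve, 4)[:2] == (0, 3)

    def test_wraps_past_midnight(self):
        curve = pd.Series(0.0, index=range(24))
        curve[23] = curve[0] = 1.0
        assert peak_window(curve, 2)[:2] == (23, 0)

    def test_insufficient_defined_hours(self):
        curve = pd.Series(np.nan, index=range(24))
        curve[0] = 1.0
        with pytest.raises(ValueError):
            peak_window(curve, 3)


class TestShiftInvariance:
    def test_neutral_filler_rescales_pa_but_not_argmax(self, small_lexicon):
        rng = np.random.default_rng(3)
        rows, rows_padded = [], []
        for u in range(6):
            for h in range(0, 24, 2):
                n_joy = rng.integers(0, 4)
                text = " ".join(["love"] * n_joy + ["w"] * (4 - n_joy))
                rows.append((f"u{u}", h, text))
                rows_padded.append((f"u{u}", h, text + " pad pad pad pad"))
        c1 = accumulate_user_hour(make_postings(rows), small_lexicon)
        c2 = accumulate_user_hour(make_postings(rows_padded), small_lexicon)
        pa1 = probability_table(c1)["joy"]
        pa2 = probability_table(c2)["joy"]
        assert np.allclose(pa2.dropna(), pa1.dropna() / 2)  # 4 -> 8 tokens
        curve1 = diurnal_curve(relative_probability(pa1))["rpa"]
        curve2 = diurnal_curve(relative_probability(pa2))["rpa"]
        assert curve1.idxmax() == curve2.idxmax()


def test_diurnal_summary_shapes(medium_run):
    assert set(medium_run["curves"].index) == set(HOURS)
    assert medium_run["baselines"].shape[1] == medium_run["curves"].shape[1]
    n_users = medium_run["counts"].index.get_level_values("user_id").nunique()
    assert len(medium_run["baselines"]) == n_users
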