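import numpy as np
import pandas as pd
import pytest

from lexaffect.lexicon import Lexicon
from lexaffect.synthetic import GeneratorConfig, build_synthetic_lexicon, generate_corpus


@pytest.fixture
def small_lexicon():
    return Lexicon.from_words({
        "joy": ["love", "excited"],
        "sadness": ["tear"],
        "anger": ["roar"],
        "fear": ["panic"],
        "disgust": ["wordy"],
        "positive_affect": ["love", "sweet", "happ*"],
        "negative_affect": ["tear", "hurt"],
    })


@pytest.fixture
def lexicon_tsv(tmp_path):
    path = tmp_path / "lexicon.tsv"
    path.write_text(
        "joy\tlove\njoy\texcited\nsadness\ttear\npositive_affect\thapp*\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def lexicon_json(tmp_path):
    path = tmp_path / "lexicon.json"
    path.write_text(
        '{"joy": ["love", "excited"], "sadness": ["tear"]}', encoding="utf-8"
    )
    return path


@pytest.fixture
def lexicon_dic(tmp_path):
    path = tmp_path / "lexicon.dic"
    path.write_text(
        "%\n1\tjoy\n2\tsadness\n%\nlove\t1\nhapp*\t1\ntear\t2\nalone\t2\n",
        encoding="utf-8",
    )
    return path


def make_postings(rows):
    """rows: (user_id, hour, text) triples -> postings frame."""
    return pd.DataFrame(rows, columns=["user_id", "hour", "text"])


@pytest.fixture(scope="session")
def medium_run():
    """One moderately sized synthetic corpus scored end to end, shared by
    read-only tests."""
    from lexaffect.scoring import accumulate_user_hour, diurnal_summary

    cfg = GeneratorConfig(seed=11, n_users=120, postings_per_user_mean=45,
                          tokens_per_posting_mean=20)
    postings, profiles, truth = generate_corpus(cfg)
    postings = postings.assign(hour=pd.to_datetime(postings["ts"]).dt.hour)
    lex, _, _ = build_synthetic_lexicon()
    counts = accumulate_user_hour(postings, lex)
    summary = diurnal_summary(counts)
    return {
        "config": cfg, "postings": postings, "profiles": profiles,
        "truth": truth, "lexicon": lex, "counts": counts, **summary,
    }
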