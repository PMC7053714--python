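"""Generate the synthetic study corpus.

Draws a posting corpus at the study's per-user scale (default diurnal
structure, a positive coupling of sexual-word propensity into
positive-affect emission) together with user profiles and the generator's
ground truth, and writes them under results/data/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from lexaffect.synthetic import (GeneratorConfig, build_synthetic_lexicon,
                                 generate_corpus, write_corpus)

SEED = 20_260_918
OUT = ROOT / "results" / "data"


def main():
    cfg = GeneratorConfig(seed=SEED, n_users=300,
                          covariate_effects={("sexual", "positive_affect"): 0.6})
    postings, profiles, truth = generate_corpus(cfg)
    paths = write_corpus(postings, profiles, OUT)

    lex, _, _ = build_synthetic_lexicon()
    lex_path = OUT / "lexicon.tsv"
    lex_path.write_text("\n".join(
        f"{dim}\t{e.text}" for dim, entries in lex.dimensions.items()
        for e in entries), encoding="utf-8")
    truth.expected_user_rate.to_csv(OUT / "truth_user_rates.csv",
                                    index_label="user_id")
    (OUT / "truth.json").write_text(json.dumps({
        "seed": cfg.seed, "n_users": cfg.n_users,
        "peak_hours": truth.peak_hours, "amplitudes": truth.amplitudes,
        "effects": {f"{s}->{t}": v for (s, t), v in truth.effects.items()},
    }, indent=2))

    print(f"simulated {len(postings)} postings for {cfg.n_users} users "
          f"(seed {cfg.seed})")
    print(f"generating effect: sexual propensity -> positive-affect logit, "
          f"slope {cfg.covariate_effects[('sexual', 'positive_affect')]}")
    print(f"wrote {paths['postings']}, {paths['profiles']}, {lex_path}")


if __name__ == "__main__":
    main()
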