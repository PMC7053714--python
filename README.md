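# lexaffect

Lexicon-based affective-state analysis for time-stamped social-media
corpora: per-user-hour affect probabilities, diurnal mood-rhythm curves,
composite sentiment/emotion scores, and permutation-test regression of
affect baselines on behavior/health word usage and demographic covariates.

The intended user is a digital-epidemiology or computational-social-science
researcher with (a) a word-list dictionary (LIWC-style `.dic`, TSV, or
JSON), (b) a posting corpus of `(user_id, timestamp, text)` records (JSONL
or CSV), and (c) a user-profile table. Because corpora of this kind are
rarely distributable, the package also ships a synthetic-corpus generator
with known ground truth, so the whole pipeline is testable end to end.

## The model

For user *u* and clock hour *h* (pooled across days), with ‖W(u,h)‖ tokens
of which ‖D(u,h)‖ match dimension *D*:

* probability `PA(u,h) = ‖D(u,h)‖ / ‖W(u,h)‖`;
* user baseline `PA(u) = mean over hours of PA(u,h)`;
* relative probability `RPA(u,h) = PA(u,h) − PA(u) + grand mean`;
* diurnal curve `RPA(h) = mean of RPA(u,h) over users active at h`.

Composite scores per user-hour: positive emotion score
`joy − (sadness+anger+fear+disgust)` and positive sentiment score
`positive_affect − negative_affect`, each normalized by the token total.
User baselines are then regressed on sexual/health word-usage baselines and
covariates with permutation tests (response permutation for the univariate
screen at P<.20, Freedman–Lane for the adjusted model, significance at
P<.05). See `docs/methods.md` for assumptions and numerical choices.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_score_diurnal.py
python analysis/03_associations.py
python analysis/04_themes_kappa.py
```

`01` draws a 300-user synthetic corpus (study-scale postings per user, a
generating +0.6 logit slope of sexual propensity on positive-affect
emission). `02` runs the measurement pipeline and prints, among others:

```
26216 postings read; 269 users pass the >=25-posting activity filter
3-hour peak windows of the population diurnal curves:
  positive_affect            06:00-08:59  mean RPA +0.0268
  negative_affect            01:00-03:59  mean RPA +0.0267
  joy                        07:00-09:59  mean RPA +0.0258
  sexual                     22:00-00:59  mean RPA +0.0133
```

i.e. the recovered morning peak of positive affect/joy, the small-hours
peak of negative affect, and the late-night sexual-content peak match the
generating configuration. `03` prints the screened multivariate results:

```
  positive_affect            ~ sexual           beta +2.1390  P 0.0010
generating truth: positive sexual->positive_affect coupling;
recovered beta +2.1390 (correct sign), P 0.0010
```

The coefficient is on the baseline-probability scale per unit exposure
baseline, so only its sign and significance are compared with the
generating logit-scale slope. `04` tabulates theme proportions from
published counts and demonstrates the kappa computation on synthetic rater
pairs. Outputs land under `results/`.

The same stages are exposed as a CLI (`lexaffect simulate | run-all |
regress | kappa`) and as library functions (`lexaffect.run_pipeline`,
`lexaffect.diurnal_summary`, ...).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main analysis from scratch — simulates a corpus,
runs the full pipeline, recovers the diurnal joy peak and the generating
covariate effect — and writes the result-summary JSON to `--out`.
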