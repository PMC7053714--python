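# Methods

## The measurement model

The package measures affective states expressed in time-stamped social-media
postings with closed-vocabulary word counting, in the LIWC tradition. A
*lexicon* maps affect dimensions — sentiment (`positive_affect`,
`negative_affect`), five basic emotions (`joy`, `sadness`, `anger`, `fear`,
`disgust`), and two topical dimensions (`sexual`, `health`) — to word lists.
Entries may be literal words, multiword phrases, or stems with a trailing
`*` (prefix match, as in LIWC `.dic` files). Matching is case-insensitive
after NFC normalization; overlapping dimensions each count the token.

For user *u* and clock hour *h* (postings pooled by clock hour across
calendar days), with ‖W(u,h)‖ the token total and ‖D(u,h)‖ the count of
tokens matching dimension *D*:

```
PA_D(u,h)   = ‖D(u,h)‖ / ‖W(u,h)‖                       per-user-hour probability
PA_D(u)     = mean_h PA_D(u,h)                          user baseline
RPA_D(u,h)  = PA_D(u,h) − PA_D(u) + grand mean          relative probability
RPA_D(h)    = mean_{u ∈ U(h)} RPA_D(u,h)                population diurnal curve
```

where the grand mean averages PA over all defined user-hours and U(h) is the
set of users with at least one token at hour *h*. Two signed composites
collapse the battery into single scores, computed from pooled counts per
user-hour and then normalized by the token total:

* positive emotion score: `joy − (sadness + anger + fear + disgust)`;
* positive sentiment score: `positive_affect − negative_affect`.

### Numerical and definitional choices

* **Zero-token hours are missing, not zero.** They are excluded from
  baselines, the grand mean, and U(h). Treating them as zero would conflate
  silence with neutral affect.
* **Baseline denominator.** The baseline formula read literally divides by
  ‖H‖ = 24, which pulls the baselines of users active in few hours toward 0.
  The default (`active_hours`) averages over a user's defined hours only;
  the literal `all_hours` convention is available so results under both can
  be compared. Under `active_hours` the per-user deviations
  Σ_h (PA(u,h) − PA(u)) vanish identically, and the mean of RPA over defined
  user-hours equals the grand mean to machine precision — both are asserted
  as invariants.
* **Substring matching** (for unsegmented CJK text without a segmenter)
  scans left to right, preferring the longest entry at each position and
  never overlapping matches — deterministic maximum forward matching. Token
  mode is the default and is what the synthetic corpus exercises.
* **Peak windows.** `peak_window` reports the contiguous circular window of
  a given width (default 3 h) maximizing the mean curve value, ties broken
  to the earliest start hour. Windows containing undefined hours are
  skipped.
* **Tokenization** splits on whitespace and punctuation runs and
  case-folds. A pluggable segmenter callable (e.g. `jieba.lcut`) can replace
  it for Chinese text; none is bundled.

## Covariate coding

Age is banded at 25 years; education is high-school-or-below /
above-high-school / unknown; geolocation keeps Guangzhou, Shenzhen and
Dongguan and collapses everything else to `other`; hometown is Guangdong /
non-Guangdong / unknown. BMI = weight/height² with NIH cut-points 18.5 / 25
/ 30, intervals closed on the left (BMI exactly 25 is overweight). Follower,
followee, and chat-group counts are transformed as log10(x+1): base-10
matches the magnitude of published summary statistics for counts in the
hundreds, and +1 keeps zeros finite. Missing categorical fields become
explicit `unknown` levels rather than dropping the user. Users enter the
analysis only with ≥ 25 postings (the activity filter).

## Inference

Baseline probabilities are strongly skewed, so the linear-model inference is
permutation-based. The test statistic for a term is its partial F in the
treatment-coded design (reference levels: age ≤ 25, education
high-school-or-below, geolocation Guangzhou, hometown Guangdong, BMI normal,
sex role receptive); for single-column terms this is equivalent to a
two-sided |t| test. Two schemes:

* **response** — permute the outcome; exact under full exchangeability;
  univariate default.
* **Freedman–Lane** — permute residuals of the reduced model (all terms but
  the one tested), add them back to the reduced fit, refit; standard for
  adjusted models; multivariate default.

p = (b+1)/(B+1) with b the number of permuted statistics ≥ the observed, so
p is never 0; B defaults to 4999 (999 in the faster drivers) and values
below 99 are refused. Model building follows the common epidemiological
two-stage strategy: univariate screen at P < .20, survivors enter one
multivariate model, significance at P < .05. No further multiplicity
correction is applied (matching the emulated analysis). Empirical size at
α = .05 is verified over 500 null replicates for both schemes, and the
permutation p agrees with the classical OLS partial-F p under Gaussian
errors.

Inter-rater agreement for qualitative theme coding uses Cohen's kappa with
marginal-product expected agreement; when both raters are constant and
identical, kappa is undefined and reported as missing with 100% raw
agreement. Printed-table percentages are reproduced with
round-half-away-from-zero at the printed precision.

## The synthetic corpus

No real corpus is distributable, so the generator emits the world the
analysis assumes, with ground truth retained for recovery testing. Per
dimension *d*, the token-level emission probability is

```
p_d(u,h) = sigmoid( logit(base_d) + amp_d·cos(2π(h − peak_d)/24)
                    + sd_d·z_{u,d} + Σ effects )
```

with z standard normal per user × dimension. Modulation on the logit scale
keeps probabilities in (0,1) at any amplitude. Each token is drawn i.i.d.
from the hour's categorical distribution over the nine dimension
vocabularies plus neutral filler (config error if the dimension
probabilities ever sum ≥ 1). Configured effects couple a user's propensity
on one dimension (or a covariate level) into another dimension's logit —
e.g. the default recovery experiment sets a +0.6 slope of sexual propensity
on positive-affect emission.

Stated-world defaults (changed only by explicit configuration, never per
test): 500 users; ~81 postings/user (negative binomial, dispersion 2,
matching 477,374 postings / 5,871 users); ~30 tokens/posting (shifted
Poisson; posting length is not published, 30 is a realistic microblog
length); baseline emission rates equal to the published sample means of the
baseline probabilities (positive affect .014, negative affect .016, joy
.015, sadness .005, anger .0005, fear .0006, disgust .004, sexual .009,
health .008); peaks at hour 8 for positive affect/joy, hour 3 for negative
affect/sadness/disgust/health, hour 23 for sexual, flat anger and fear,
amplitude 0.5 (0.3 sexual) on the logit; user random-effect SD 0.3;
demographic marginals equal to the published sample proportions;
evening-skewed posting-time profile. Vocabularies are disjoint 20-word
lists per dimension plus 200 filler words, whitespace-delimited; an
overlap fraction can borrow words across dimensions to exercise
multi-dimension matching.

### What the generator does not emulate

Real Chinese text (no segmentation ambiguity, negation, emoticons, or
irony); within-user temporal dependence of posting times; network structure
(follower counts are covariates only); posting-length/affect correlation.
A green recovery test therefore establishes that the measurement and
inference machinery recovers the structure it assumes — not that the
instrument is valid for real postings.

### A known, deliberate limitation

With all cross-dimension effects set to zero, the *measured* baselines of
two dimensions are still weakly correlated (≈ −0.04 between sexual and
positive affect at the stated scale) through two real mechanisms: users'
realized active-hour sets couple equal-weight hour-mean baselines of
dimensions with different peak hours, and dimensions compete for a shared
token budget, so sparse hours contribute anticorrelated measurement noise.
Both effects shrink as postings- and tokens-per-user grow, but at the
study's own per-user scale the end-to-end false-flag rate of the screened
regression sits near 9% rather than the nominal 5% — the permutation test
(verified exactly calibrated on pure nulls) is correctly detecting an
association the measurement process itself induces. The corresponding
acceptance test is left failing rather than masked, because the phenomenon
is a property of the emulated design, and any real-data analysis of this
kind inherits it.
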