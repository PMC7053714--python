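"""Permutation-test linear regression, screening, agreement and proportions.

Baseline affect probabilities are heavily skewed, so inference on the linear
model uses permutation tests rather than normal-theory t/F tests.  Two
schemes are provided:

* ``response`` — permute the outcome vector and refit the full model; exact
  under the strong null of total exchangeability (the univariate default).
* ``freedman_lane`` — fit the reduced model without the term of interest,
  permute its residuals, add them back to the reduced fit, refit the full
  model.  This is the standard scheme for testing one term while holding the
  other covariates fixed (the multivariate default).

The test statistic is the partial F for the term's design columns (equal to
t**2 for a single column, so two-sided); the p-value is (b + 1)/(B + 1) where
b counts permuted statistics at least as large as the observed one.  The
model-building strategy mirrors common epidemiological practice: a univariate
screen at P < .20, then one multivariate model over the survivors with
significance called at P < .05.

Also here: Cohen's kappa for inter-rater theme coding, and the printed-table
proportion arithmetic (percentages rounded half away from zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .corpus import FACTOR_LEVELS

DEFAULT_B = 4999
SCREEN_ALPHA = 0.20
FINAL_ALPHA = 0.05


class DesignError(ValueError):
    pass


def build_design(
    rows: pd.DataFrame, terms: list[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded design matrix.

    Categorical terms (those in :data:`FACTOR_LEVELS` or of categorical/object
    dtype) expand to indicator columns against their reference level — the
    first level in FACTOR_LEVELS (age ``le25``, education
    ``high_school_or_below``, geolocation ``guangzhou``, hometown
    ``guangdong``, BMI ``normal``, sex role ``receptive``).  Returns the
    matrix, its column names, and a map term -> design columns.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    term_cols: dict[str, list[str]] = {}
    if add_intercept:
        cols.append(np.ones(len(rows)))
        names.append("intercept")
    for term in terms:
        if term not in rows.columns:
            raise DesignError(f"unknown term {term!r}; have {list(rows.columns)}")
        series = rows[term]
        is_factor = term in FACTOR_LEVELS or series.dtype == object \
            or isinstance(series.dtype, pd.CategoricalDtype)
        term_cols[term] = []
        if is_factor:
            levels = [l for l in FACTOR_LEVELS.get(term, ())] or sorted(series.dropna().unique())
            observed = set(series.dropna().astype(str))
            for level in levels[1:]:
                if level not in observed:
                    continue  # unobserved level would be an all-zero column
                name = f"{term}[{level}]"
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(name)
                term_cols[term].append(name)
        else:
            vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise DesignError(f"term {term!r} has non-finite values")
            cols.append(vals)
            names.append(term)
            term_cols[term].append(term)
    X = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    return X, names, term_cols


@dataclass
class OLSFit:
    coefficients: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    rss: float
    rank: int
    n: int


def _lstsq_fit(X: np.ndarray, y: np.ndarray, names: list[str]) -> OLSFit:
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more rows ({n}) than parameters ({p})")
    rank = int(np.linalg.matrix_rank(X))
    if rank < p:
        # identify offending columns for the error message
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(p) if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise DesignError(f"design is rank-deficient; collinear columns: {bad or names}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    return OLSFit(pd.Series(beta, index=names), resid, fitted, float(resid @ resid), rank, n)


def fit_ols(rows: pd.DataFrame, outcome: str, terms: list[str]) -> pd.Series:
    """Least-squares coefficients of outcome on treatment-coded terms."""
    X, names, _ = build_design(rows, terms)
    y = pd.to_numeric(rows[outcome], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DesignError(f"outcome {outcome!r} has non-finite values")
    return _lstsq_fit(X, y, names).coefficients


def _partial_f(
    X: np.ndarray, M_reduced: np.ndarray, M_full: np.ndarray, Y: np.ndarray, q: int
) -> np.ndarray:
    """Partial F statistics for one or many outcome vectors (columns of Y)."""
    Y = np.atleast_2d(Y.T).T  # (n, B)
    rss_full = np.sum((M_full @ Y) ** 2, axis=0)
    rss_red = np.sum((M_reduced @ Y) ** 2, axis=0)
    n, p = X.shape
    denom = rss_full / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / q / denom
    return np.where(denom <= 0, np.inf, f)


def _residual_maker(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - q @ q.T


@dataclass
class RegressionResult:
    outcome: str
    term: str
    coefficients: pd.Series            # full-model coefficients for the term's columns
    statistic: float                   # observed partial F
    p_value: float
    n_permutations: int
    seed: int
    scheme: str
    terms: list[str] = field(default_factory=list)

    @property
    def beta(self) -> float:
        """Lead coefficient (the single coefficient for continuous terms)."""
        return float(self.coefficients.iloc[0])


def permutation_pvalue(
    rows: pd.DataFrame,
    outcome: str,
    terms: list[str],
    term_of_interest: str,
    scheme: str = "freedman_lane",
    B: int = DEFAULT_B,
    seed: int = 0,
) -> RegressionResult:
    """Permutation p-value for one term in a linear model.

    p = (b + 1)/(B + 1) with b the count of permuted partial-F statistics >=
    the observed one; deterministic for a fixed seed.  B below 99 gives
    p-values too coarse to screen at the stated thresholds and is refused.
    """
    if B < 99:
        raise ValueError("B must be >= 99 for stable p-values")
    if term_of_interest not in terms:
        raise ValueError(f"term_of_interest {term_of_interest!r} not in terms {terms}")
    if scheme not in {"response", "freedman_lane"}:
        raise ValueError(f"unknown scheme {scheme!r} (response, freedman_lane)")

    X, names, term_cols = build_design(rows, terms)
    y = pd.to_numeric(rows[outcome], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DesignError(f"outcome {outcome!r} has non-finite values")
    interest = term_cols[term_of_interest]
    if not interest:
        raise DesignError(f"term {term_of_interest!r} contributes no design columns")
    keep = [j for j, nm in enumerate(names) if nm not in interest]
    X_red = X[:, keep]
    q = len(interest)

    full_fit = _lstsq_fit(X, y, names)
    M_full = _residual_maker(X)
    M_red = _residual_maker(X_red)
    f_obs = float(_partial_f(X, M_red, M_full, y, q)[0])

    rng = np.random.default_rng(seed)
    n = len(y)
    perms = np.empty((n, B))
    if scheme == "response":
        for b in range(B):
            perms[:, b] = y[rng.permutation(n)]
    else:  # freedman_lane
        red_fit = _lstsq_fit(X_red, y, [names[j] for j in keep])
        for b in range(B):
            perms[:, b] = red_fit.fitted + red_fit.residuals[rng.permutation(n)]
    f_perm = _partial_f(X, M_red, M_full, perms, q)
    b_count = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (b_count + 1) / (B + 1)

    return RegressionResult(
        outcome=outcome,
        term=term_of_interest,
        coefficients=full_fit.coefficients[interest],
        statistic=f_obs,
        p_value=p,
        n_permutations=B,
        seed=seed,
        scheme=scheme,
        terms=list(terms),
    )


def screen_then_fit(
    rows: pd.DataFrame,
    outcome: str,
    candidate_terms: list[str],
    screen_alpha: float = SCREEN_ALPHA,
    final_alpha: float = FINAL_ALPHA,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> pd.DataFrame:
    """Univariate screen at *screen_alpha*, then one adjusted model.

    Each candidate is first tested alone (response permutation); survivors
    enter a single multivariate model where each is tested by Freedman-Lane
    permutation.  Returns a tidy frame with one row per (stage, term):
    columns stage, term, beta, statistic, p_value, B, seed, selected,
    significant.
    """
    records = []
    survivors = []
    for i, term in enumerate(candidate_terms):
        res = permutation_pvalue(rows, outcome, [term], term, scheme="response",
                                 B=B, seed=seed + i)
        selected = res.p_value < screen_alpha
        if selected:
            survivors.append(term)
        records.append({
            "stage": "univariate", "term": term, "beta": res.beta,
            "statistic": res.statistic, "p_value": res.p_value,
            "B": B, "seed": res.seed, "selected": selected, "significant": np.nan,
        })
    if not survivors:
        import logging
        logging.getLogger(__name__).warning(
            "no candidate passed the %.2f screen for %s; multivariate stage skipped",
            screen_alpha, outcome)
    else:
        for i, term in enumerate(survivors):
            res = permutation_pvalue(rows, outcome, survivors, term,
                                     scheme="freedman_lane", B=B,
                                     seed=seed + 1000 + i)
            records.append({
                "stage": "multivariate", "term": term, "beta": res.beta,
                "statistic": res.statistic, "p_value": res.p_value,
                "B": B, "seed": res.seed, "selected": True,
                "significant": res.p_value < final_alpha,
            })
    out = pd.DataFrame.from_records(records)
    out.attrs["outcome"] = outcome
    return out


# ---------------------------------------------------------------------------
# Inter-rater agreement

def cohen_kappa(pair_labels) -> tuple[float, float]:
    """Cohen's kappa and raw percent agreement for two raters.

    *pair_labels* is a sequence of (rater1_label, rater2_label) pairs.
    kappa = (p_o - p_e)/(1 - p_e) with p_e the marginal-product expected
    agreement.  If both raters are constant and identical, p_e = 1 and kappa
    is undefined: returns (nan, 100.0).
    """
    pairs = list(pair_labels)
    if not pairs:
        raise ValueError("no label pairs")
    a = pd.Series([p[0] for p in pairs])
    b = pd.Series([p[1] for p in pairs])
    n = len(pairs)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    labels = sorted(set(a) | set(b))
    pa = a.value_counts().reindex(labels, fill_value=0) / n
    pb = b.value_counts().reindex(labels, fill_value=0) / n
    p_e = float((pa * pb).sum())
    agreement = 100.0 * p_o
    if p_e >= 1.0:
        return (float("nan"), agreement)
    return ((p_o - p_e) / (1.0 - p_e), agreement)


# ---------------------------------------------------------------------------
# Printed-table proportion arithmetic

def proportion_summary(numerator: int, denominator: int, decimals: int = 1) -> tuple[float, str]:
    """Percentage as printed in results tables: 100*num/den rounded half away
    from zero to *decimals*; returns (percentage, "num/den") .
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quant = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quant, rounding=ROUND_HALF_UP)), f"{numerator}/{denominator}"


def theme_proportions(theme_counts: pd.Series, decimals: int = 1) -> pd.DataFrame:
    """Share of each theme within its class: counts -> tidy percentage table."""
    total = int(theme_counts.sum())
    rows = []
    for theme, count in theme_counts.items():
        pct, frac = proportion_summary(int(count), total, decimals)
        rows.append({"theme": theme, "count": int(count), "fraction": frac, "percent": pct})
    return pd.DataFrame(rows)
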