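"""Duration-difference response construction and the regression machinery.

The response is *duration difference*: observed token duration is regressed
(OLS, with intercept) on *baseline duration* — the sum of corpus-mean segment
durations of the word's phones — and the residuals become the response.  This
removes the part of duration explained by segmental makeup, allowing a
non-constant (affine) relationship between the two.

Model fitting mirrors standard morpho-phonetic practice: standard multiple
linear regression on all tokens, and a random-intercept-by-word-type mixed
model restricted to word types observed more than once.  Both are trimmed
once at 2.5 SD of the residuals and simplified by backward stepwise
elimination at alpha = 0.05 with speech rate forced to stay.  Collinearity is
screened with variance inflation factors, and explained variance is
decomposed over predictors with the lmg (ordering-averaged incremental R^2)
metric.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

STANDARD = "standard"
MIXED = "mixed"


class AliasedDesignError(ValueError):
    """Raised when the fixed-effect design is rank deficient."""

    def __init__(self, aliased: Sequence[str]):
        self.aliased = list(aliased)
        super().__init__(f"rank-deficient design; aliased terms: {self.aliased}")


def baseline_duration(
    transcription: str, segment_table: Mapping[str, float]
) -> float:
    """Sum of mean segment durations (ms) over the word's phones."""
    total = 0.0
    for phone in transcription:
        if phone not in segment_table:
            raise KeyError(f"no mean duration for phone {phone!r}")
        total += float(segment_table[phone])
    return total


def duration_difference(
    tokens: pd.DataFrame,
    observed_col: str = "observed_duration_ms",
    baseline_col: str = "baseline_duration_ms",
) -> pd.DataFrame:
    """Attach the duration-difference response (residual of observed on baseline).

    Fits observed ~ 1 + baseline across all tokens by OLS and stores the
    residuals in a ``duration_difference`` column.  Residuals sum to zero and
    are uncorrelated with baseline duration by construction.
    """
    if len(tokens) < 3:
        raise ValueError("need at least 3 tokens")
    y = tokens[observed_col].to_numpy(dtype=float)
    x = tokens[baseline_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("baseline duration is constant; residualization undefined")
    exog = sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    out = tokens.copy()
    out["duration_difference"] = fit.resid
    return out


@dataclass
class FitResult:
    """A fitted duration model with everything needed to trim and simplify it."""

    kind: str  # "standard" | "mixed"
    response: str
    terms: list[str]
    forced: frozenset[str]
    group: str | None
    coefficients: pd.DataFrame  # estimate, se, p_value per term (+ Intercept)
    n: int
    r_squared: dict[str, float]
    data: pd.DataFrame = field(repr=False)
    dropped_terms: list[str] = field(default_factory=list)
    n_trimmed: int = 0
    trim_fraction: float = 0.0
    n_hapax_types_excluded: int = 0
    n_hapax_tokens_excluded: int = 0
    singular: bool = False
    residuals: pd.Series = field(default=None, repr=False)

    def summary_table(self) -> str:
        """Human-readable coefficient table (estimate, SE, significance stars)."""
        lines = [f"{self.kind} model for {self.response} (n = {self.n})"]
        lines.append(f"{'term':<28}{'estimate':>14}{'SE':>12}  sig")
        for term, row in self.coefficients.iterrows():
            p = row["p_value"]
            stars = (
                "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            )
            lines.append(
                f"{term:<28}{row['estimate']:>14.6f}{row['se']:>12.6f}  {stars}"
            )
        for name, value in self.r_squared.items():
            lines.append(f"R2 {name}: {value:.4f}")
        if self.n_trimmed:
            lines.append(
                f"trimmed: {self.n_trimmed} observations ({100 * self.trim_fraction:.1f}%)"
            )
        if self.dropped_terms:
            lines.append("dropped terms: " + ", ".join(self.dropped_terms))
        return "\n".join(lines)


def _find_aliased(exog: pd.DataFrame) -> list[str]:
    x = exog.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return []
    aliased = []
    kept: list[int] = []
    for j in range(x.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(x[:, trial]) == len(trial):
            kept.append(j)
        else:
            aliased.append(exog.columns[j])
    return aliased


def _design(
    data: pd.DataFrame, terms: Sequence[str], on_aliased: str = "error"
) -> pd.DataFrame:
    exog = data[list(terms)].astype(float)
    exog.insert(0, "Intercept", 1.0)
    aliased = _find_aliased(exog)
    if aliased:
        if on_aliased == "drop":
            logger.warning("dropping aliased terms: %s", aliased)
            exog = exog.drop(columns=aliased)
        else:
            raise AliasedDesignError(aliased)
    return exog


def fit_standard(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    forced: Sequence[str] = ("speech_rate",),
    on_aliased: str = "error",
) -> FitResult:
    """Ordinary least squares on complete cases, reporting adjusted R^2."""
    cols = [response, *terms]
    complete = data.dropna(subset=cols)
    n = len(complete)
    if terms and n < 10 * len(terms):
        logger.warning(
            "only %d observations for %d terms (< 10 per term)", n, len(terms)
        )
    exog = _design(complete, terms, on_aliased)
    fit = sm.OLS(complete[response].to_numpy(dtype=float), exog).fit()
    coefficients = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p_value": fit.pvalues}
    )
    return FitResult(
        kind=STANDARD,
        response=response,
        terms=[t for t in terms if t in exog.columns],
        forced=frozenset(t for t in forced if t in exog.columns),
        group=None,
        coefficients=coefficients,
        n=n,
        r_squared={"adjusted": float(fit.rsquared_adj), "plain": float(fit.rsquared)},
        data=complete,
        residuals=pd.Series(np.asarray(fit.resid), index=complete.index),
    )


def _nakagawa_r2(
    fitted_fixed: np.ndarray, tau2: float, sigma2: float
) -> dict[str, float]:
    """Marginal and conditional R^2 from variance components.

    Marginal R^2 is the fixed-effect variance share, conditional R^2 the
    fixed-plus-random share, of total variance var(Xb) + tau^2 + sigma^2.
    """
    var_f = float(np.var(fitted_fixed))
    total = var_f + tau2 + sigma2
    return {
        "marginal": var_f / total,
        "conditional": (var_f + tau2) / total,
    }


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    group: str = "word_id",
    forced: Sequence[str] = ("speech_rate",),
    on_aliased: str = "error",
) -> FitResult:
    """Random-intercept-by-word-type linear mixed model (REML).

    Word types observed only once are excluded before fitting (their counts
    are recorded); marginal and conditional R^2 follow the variance-components
    formulas.  A near-zero random-intercept variance is flagged as singular.
    """
    cols = [response, *terms, group]
    complete = data.dropna(subset=cols)
    counts = complete[group].value_counts()
    repeated = counts[counts > 1].index
    n_hapax_types = int((counts == 1).sum())
    kept = complete[complete[group].isin(repeated)]
    n_hapax_tokens = len(complete) - len(kept)
    if n_hapax_types:
        logger.info(
            "fit_mixed: excluded %d hapax types (%d tokens)",
            n_hapax_types,
            n_hapax_tokens,
        )
    if kept[group].nunique() < 2:
        raise ValueError("need at least 2 repeated word types for a mixed model")
    exog = _design(kept, terms, on_aliased)
    model = sm.MixedLM(
        kept[response].to_numpy(dtype=float), exog, groups=kept[group].to_numpy()
    )
    fit = model.fit(reml=True)
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    sigma2 = float(fit.scale)
    singular = tau2 < 1e-8 * (tau2 + sigma2) or not fit.converged
    if singular:
        logger.warning("fit_mixed: singular or non-converged fit (tau2=%.3g)", tau2)
    fe = fit.fe_params
    coefficients = pd.DataFrame(
        {
            "estimate": fe,
            "se": fit.bse_fe,
            "p_value": fit.pvalues.loc[fe.index],
        }
    )
    fitted_fixed = exog.to_numpy(dtype=float) @ fe.to_numpy()
    return FitResult(
        kind=MIXED,
        response=response,
        terms=[t for t in terms if t in exog.columns],
        forced=frozenset(t for t in forced if t in exog.columns),
        group=group,
        coefficients=coefficients,
        n=len(kept),
        r_squared={**_nakagawa_r2(fitted_fixed, tau2, sigma2), "tau2": tau2, "sigma2": sigma2},
        data=kept,
        n_hapax_types_excluded=n_hapax_types,
        n_hapax_tokens_excluded=n_hapax_tokens,
        singular=singular,
        residuals=pd.Series(np.asarray(fit.resid), index=kept.index),
    )


def _refit(fit: FitResult, data: pd.DataFrame, terms: Sequence[str]) -> FitResult:
    if fit.kind == STANDARD:
        return fit_standard(data, fit.response, terms, forced=sorted(fit.forced))
    return fit_mixed(
        data, fit.response, terms, group=fit.group, forced=sorted(fit.forced)
    )


def trim_refit(fit: FitResult, threshold: float = 2.5) -> FitResult:
    """Drop observations whose standardized residual exceeds the threshold
    in absolute value, then refit once.

    Fails when more than 20% of the data would be removed (suspect data).
    """
    resid = fit.residuals.to_numpy(dtype=float)
    z = (resid - resid.mean()) / resid.std(ddof=1)
    keep = np.abs(z) <= threshold
    n_trimmed = int((~keep).sum())
    fraction = n_trimmed / len(resid)
    if fraction > 0.20:
        raise ValueError(
            f"trimming would remove {100 * fraction:.1f}% of observations"
        )
    if n_trimmed == 0:
        return fit
    refit = _refit(fit, fit.data.loc[keep], fit.terms)
    return replace(
        refit,
        n_trimmed=n_trimmed,
        trim_fraction=fraction,
        dropped_terms=list(fit.dropped_terms),
    )


def stepwise_eliminate(
    fit: FitResult, alpha: float = 0.05
) -> FitResult:
    """Backward elimination: repeatedly drop the non-forced term with the
    largest p-value >= alpha and refit, until all retained terms are
    significant.  The elimination order is recorded."""
    current = fit
    dropped = list(fit.dropped_terms)
    while True:
        candidates = [t for t in current.terms if t not in current.forced]
        if not candidates:
            break
        pvals = current.coefficients.loc[candidates, "p_value"]
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        dropped.append(worst)
        logger.info("stepwise: dropping %s (p = %.4f)", worst, pvals[worst])
        remaining = [t for t in current.terms if t != worst]
        current = _refit(current, current.data, remaining)
        current = replace(
            current,
            n_trimmed=fit.n_trimmed,
            trim_fraction=fit.trim_fraction,
        )
    return replace(current, dropped_terms=dropped)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    predictor j on all others (with intercept).  Perfect collinearity yields
    an infinite VIF."""
    if design.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    out = {}
    x = design.astype(float)
    for col in x.columns:
        others = sm.add_constant(x.drop(columns=col).to_numpy())
        r2 = sm.OLS(x[col].to_numpy(), others).fit().rsquared
        out[col] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class RelativeImportance:
    """lmg shares: per-predictor ordering-averaged incremental R^2."""

    shares: pd.Series
    total_r_squared: float


def _subset_r2_ols(y: np.ndarray, x: np.ndarray, subset: tuple[int, ...]) -> float:
    if not subset:
        return 0.0
    exog = np.column_stack([np.ones(len(y)), x[:, subset]])
    beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss)


def lmg_importance(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    kind: str = STANDARD,
    group: str | None = None,
) -> RelativeImportance:
    """Decompose explained variance over predictors with the lmg metric.

    For each predictor the incremental R^2 of adding it is averaged over all
    orderings of entry (computed by subset enumeration with combinatorial
    weights).  For standard models the shares sum exactly to the full model's
    R^2.  For mixed models the decomposition runs on the marginal
    (fixed-effect) R^2, refitting the mixed model per subset.
    """
    p = len(predictors)
    if p > 10:
        raise ValueError("more than 10 predictors; restrict to a subset")
    if p == 0:
        raise ValueError("no predictors")
    complete = data.dropna(subset=[response, *predictors] + ([group] if group else []))

    if kind == STANDARD:
        y = complete[response].to_numpy(dtype=float)
        x = complete[list(predictors)].to_numpy(dtype=float)

        def r2(subset: tuple[int, ...]) -> float:
            return _subset_r2_ols(y, x, subset)

    elif kind == MIXED:
        if group is None:
            raise ValueError("mixed lmg requires a grouping column")

        def r2(subset: tuple[int, ...]) -> float:
            if not subset:
                return 0.0
            terms = [predictors[j] for j in subset]
            return fit_mixed(complete, response, terms, group=group, forced=())\
                .r_squared["marginal"]

    else:
        raise ValueError(f"unknown model kind {kind!r}")

    cache: dict[tuple[int, ...], float] = {}

    def r2_cached(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = r2(subset)
        return cache[subset]

    shares = {}
    indices = range(p)
    factorial = math.factorial
    for j in indices:
        others = [i for i in indices if i != j]
        share = 0.0
        for size in range(p):
            weight = factorial(size) * factorial(p - size - 1) / factorial(p)
            for subset in itertools.combinations(others, size):
                share += weight * (
                    r2_cached(tuple(sorted(subset + (j,)))) - r2_cached(subset)
                )
        shares[predictors[j]] = share
    total = r2_cached(tuple(indices))
    return RelativeImportance(
        shares=pd.Series(shares, name="lmg"), total_r_squared=total
    )


def log_plus_one(values: np.ndarray | pd.Series | Sequence[float]) -> np.ndarray:
    """Natural log of (x + 1); the standard transform for count-like covariates."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log_plus_one requires non-negative values")
    return np.log1p(arr)
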