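"""Cohort association statistics.

Implements the modelling toolkit used on autopsy-cohort analyte and
seeding-assay data: per-variable transforms (identity / square root /
natural log), percentile ordinalization of skewed assay outcomes,
covariate-adjusted ordinary least squares and proportional-odds
(cumulative-logit) regression with Wald intervals, Bonferroni families,
and the small-sample group-comparison dispatch rule (rank tests for n > 8
per group, t/ANOVA otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.miscmodels.ordinal_model import OrderedModel
import statsmodels.api as sm

__all__ = [
    "TRANSFORMS",
    "OrdinalSpec",
    "ModelFit",
    "GroupTestResult",
    "apply_transform",
    "inverse_transform",
    "ordinalize",
    "fit_linear",
    "fit_prop_odds",
    "bonferroni_threshold",
    "group_compare",
    "PAR_ORDINAL_SPEC",
    "MAXFL_ORDINAL_SPEC",
]

TRANSFORMS = ("identity", "square_root", "natural_log")


def apply_transform(values, transform: str, name: str = "") -> np.ndarray:
    """Elementwise transform with domain checks.

    ``square_root`` requires non-negative values, ``natural_log`` strictly
    positive ones; violations raise with the offending positions so the case
    can be traced.
    """
    values = np.asarray(values, dtype=float)
    label = name or "values"
    if transform == "identity":
        return values
    if transform == "square_root":
        bad = np.nonzero(values < 0)[0]
        if bad.size:
            raise ValueError(f"square root of negative {label} at rows {bad[:5].tolist()}")
        return np.sqrt(values)
    if transform == "natural_log":
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise ValueError(f"log of non-positive {label} at rows {bad[:5].tolist()}")
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}; use one of {TRANSFORMS}")


def inverse_transform(values, transform: str) -> np.ndarray:
    """Inverse of :func:`apply_transform`, for back-transforming reports."""
    values = np.asarray(values, dtype=float)
    if transform == "identity":
        return values
    if transform == "square_root":
        return values**2
    if transform == "natural_log":
        return np.exp(values)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class OrdinalSpec:
    """Percentile cutpoints for converting a skewed outcome to ordinal levels.

    K levels = len(quantiles) + 1.  The assay conventions: the aggregation
    rate (PAR) uses the 50th and 75th percentiles (3 levels); the plateau
    fluorescence (MaxFL) uses the 25th, 50th and 75th (4 levels).
    """

    variable: str
    quantiles: tuple[float, ...]

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles, dtype=float)
        if q.size < 1 or np.any((q <= 0) | (q >= 1)) or np.any(np.diff(q) <= 0):
            raise ValueError("quantiles must be strictly increasing within (0, 1)")

    @property
    def n_levels(self) -> int:
        return len(self.quantiles) + 1


PAR_ORDINAL_SPEC = OrdinalSpec("PAR", (0.50, 0.75))
MAXFL_ORDINAL_SPEC = OrdinalSpec("MaxFL", (0.25, 0.50, 0.75))


def ordinalize(values, spec: OrdinalSpec) -> np.ndarray:
    """Convert values to ordinal levels 1..K at the spec's percentiles.

    Quantiles use linear interpolation between order statistics and are
    computed on the supplied values themselves (the analysis set).  Level j
    covers (q_{j-1}, q_j]; ties at a cutpoint fall to the lower level.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to ordinalize")
    if np.all(values == values[0]):
        warnings.warn("all values equal: single ordinal level", stacklevel=2)
        return np.ones(values.size, dtype=int)
    cuts = np.quantile(values, spec.quantiles)  # linear interpolation default
    return 1 + np.searchsorted(cuts, values, side="left").astype(int)


@dataclass(frozen=True)
class ModelFit:
    """A fitted association model, reported for one predictor of interest."""

    kind: str                     # "linear" | "cumulative-logit"
    predictor: str
    coef: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None
    converged: bool = True
    params: dict | None = None    # full coefficient vector incl. covariates


def _design(data: pd.DataFrame, predictor: str, covariates) -> pd.DataFrame:
    cols = [predictor] + [c for c in (covariates or []) if c != predictor]
    X = data[cols].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if X.shape[1] > 1 else (predictor,)
        raise ValueError(f"rank-deficient design; near-collinear columns: {worst}")
    return X


def fit_linear(data: pd.DataFrame, outcome: str, predictor: str,
               covariates=(), outcome_transform: str = "identity",
               predictor_transform: str = "identity") -> ModelFit:
    """Covariate-adjusted OLS association of one predictor with an outcome.

    Transforms are applied before fitting; the coefficient is the change in
    the mean (transformed) outcome per 1-unit increase of the (transformed)
    predictor.  Wald 95% CI.
    """
    df = data.copy()
    df[outcome] = apply_transform(df[outcome], outcome_transform, outcome)
    df[predictor] = apply_transform(df[predictor], predictor_transform, predictor)
    X = _design(df, predictor, covariates)
    if len(df) <= X.shape[1] + 1:
        raise ValueError("more parameters than observations")
    res = sm.OLS(df[outcome].to_numpy(), sm.add_constant(X)).fit()
    coef = float(res.params[predictor])
    se = float(res.bse[predictor])
    ci = res.conf_int().loc[predictor]
    return ModelFit("linear", predictor, coef, se, float(ci[0]), float(ci[1]),
                    float(res.pvalues[predictor]), int(res.nobs),
                    params=dict(res.params))


def fit_prop_odds(data: pd.DataFrame, outcome: str, predictor: str,
                  covariates=(), predictor_transform: str = "identity"
                  ) -> ModelFit:
    """Proportional-odds (cumulative-logit) regression.

    Maximizes the likelihood of P(Y <= j | x) = logistic(alpha_j - beta'x)
    over strictly increasing intercepts alpha and shared slopes beta.  The
    reported odds ratio exp(beta) is the multiplicative change in the odds
    of a higher outcome category per 1-unit predictor increase.  Wald CIs
    from the observed information.  Non-convergence (e.g. separation) is
    reported on the fit, never silently ignored.
    """
    df = data.copy()
    df[predictor] = apply_transform(df[predictor], predictor_transform, predictor)
    y = pd.Categorical(df[outcome], ordered=True)
    if len(y.categories) < 3:
        raise ValueError("ordinal outcome needs >= 3 populated levels")
    X = _design(df, predictor, covariates)
    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=200, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    coef = float(res.params[predictor])
    se = float(res.bse[predictor])
    ci_low, ci_high = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    return ModelFit("cumulative-logit", predictor, coef, se, ci_low, ci_high,
                    float(res.pvalues[predictor]), int(res.nobs),
                    odds_ratio=float(np.exp(coef)),
                    or_ci=(float(np.exp(ci_low)), float(np.exp(ci_high))),
                    converged=converged, params=dict(res.params))


def bonferroni_threshold(m_tests: int, alpha: float = 0.05,
                         decimals: int = 4) -> float:
    """Per-test significance threshold alpha / m, rounded for table footnotes.

    Examples: a 12-test family gives 0.0042, a 16-test family 0.0031.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return round(alpha / m_tests, decimals)


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    significant: bool | None = None
    alpha_corrected: float | None = None


def group_compare(values, groups, small_n: int = 8, m_tests: int = 1,
                  alpha: float = 0.05) -> GroupTestResult:
    """Two-sided group comparison with small-sample dispatch.

    Nonparametric tests (Mann–Whitney U for two groups, Kruskal–Wallis for
    more) are robust to non-normality but underpowered at tiny n, so groups
    of size <= ``small_n`` fall back to a Student t test / one-way ANOVA.
    The returned significance flag applies the Bonferroni-corrected level
    ``alpha / m_tests``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [values[groups == g] for g in labels]
    sizes = tuple(int(a.size) for a in arrays)
    if min(sizes) < 2:
        raise ValueError("every group needs n >= 2")

    parametric = min(sizes) <= small_n
    if len(labels) == 2:
        if parametric:
            stat, p = sps.ttest_ind(arrays[0], arrays[1])
            test = "t-test"
        else:
            stat, p = sps.mannwhitneyu(arrays[0], arrays[1],
                                       alternative="two-sided")
            test = "mann-whitney-u"
    else:
        if parametric:
            stat, p = sps.f_oneway(*arrays)
            test = "one-way-anova"
        else:
            stat, p = sps.kruskal(*arrays)
            test = "kruskal-wallis"
    level = alpha / m_tests
    return GroupTestResult(test, float(stat), float(p), sizes,
                           significant=bool(p <= level),
                           alpha_corrected=level)
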