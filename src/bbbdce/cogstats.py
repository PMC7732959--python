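"""Cognitive-decline statistics: transforms, adjusted regression, FDR, power.

Decline is previous minus current score (Stroop interference, a completion
time, is sign-reversed so larger always means more decline).  Leakage
predictors are cube-root transformed; normalised volumes are log(vol/ICV).
Associations are tested by ordinary least squares with age, sex and
education as covariates, corrected across the four cognitive domains by the
Benjamini–Hochberg step-up rule, with an a priori noncentral-F power
analysis and the two worked-example calculators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DOMAINS",
    "STROOP_DOMAIN",
    "DeclineScore",
    "RegressionResult",
    "FDRResult",
    "PowerSpec",
    "decline_score",
    "cube_root",
    "icv_normalize_log",
    "fit_adjusted_regression",
    "benjamini_hochberg",
    "regression_power",
    "required_sample_size",
    "ageing_equivalent_decline",
]

DOMAINS = (
    "immediate_recall",
    "delayed_recall",
    "processing_speed",
    "stroop_interference",
)
#: The one domain scored as a completion time (larger difference = less
#: decline), hence reversed.
STROOP_DOMAIN = "stroop_interference"

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass(frozen=True)
class DeclineScore:
    domain: str
    value: float


def decline_score(previous: float, current: float, domain: str) -> DeclineScore:
    """Decline = previous - current; reversed (* -1) for Stroop interference,
    so a larger value always means more decline."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    for name, score in (("previous", previous), ("current", current)):
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise ValueError(f"missing {name} score for domain {domain!r}")
    value = float(previous) - float(current)
    if domain == STROOP_DOMAIN:
        value = -value
    return DeclineScore(domain=domain, value=value)


def cube_root(x):
    """Sign-preserving cube root (``cube_root(x) ** 3 == x``)."""
    return np.cbrt(x)


def icv_normalize_log(volume: float, icv: float) -> float:
    """Head-size correction: natural log of volume / intracranial volume."""
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(volume <= 0) or np.any(icv <= 0):
        raise ValueError("volume and ICV must be positive")
    out = np.log(volume / icv)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RegressionResult:
    """Focal-predictor coefficient from a covariate-adjusted OLS fit."""

    outcome: str
    predictor: str
    covariates: tuple
    n: int
    standardized_beta: float
    unstandardized_beta: float
    p_value: float
    df_residual: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must be in (0, 1]")


def fit_adjusted_regression(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> RegressionResult:
    """OLS of ``outcome`` on ``predictor`` adjusted for ``covariates``.

    The standardized coefficient is the slope the same model yields with the
    outcome and focal predictor z-scored (covariates left on their native
    scale), i.e. ``b * sd(predictor) / sd(outcome)``.  The p-value is the
    two-sided t-test on the predictor coefficient.
    """
    columns = [outcome, predictor, *covariates]
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    data = table[columns].dropna()
    n = len(data)
    n_params = 2 + len(covariates)
    if n <= n_params:
        raise ValueError(f"need more than {n_params} rows, got {n}")

    y = data[outcome].to_numpy(dtype=float)
    x = data[[predictor, *covariates]].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(y, design).fit()

    b = float(fit.params[1])
    sd_x = float(np.std(x[:, 0], ddof=1))
    sd_y = float(np.std(y, ddof=1))
    if sd_x == 0 or sd_y == 0:
        raise ValueError("predictor or outcome has zero variance")
    return RegressionResult(
        outcome=outcome,
        predictor=predictor,
        covariates=tuple(covariates),
        n=n,
        standardized_beta=b * sd_x / sd_y,
        unstandardized_beta=b,
        p_value=float(fit.pvalues[1]),
        df_residual=int(fit.df_resid),
    )


@dataclass(frozen=True)
class FDRResult:
    """Outcome of the Benjamini–Hochberg step-up procedure."""

    m: int
    q: float
    p_values: np.ndarray  # as given
    rejected: tuple  # indices into p_values

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "p_values", np.asarray(self.p_values, dtype=float)
        )


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg step-up rule at false-discovery rate ``q``.

    Rejects every test with ``p <= p_(k)`` where ``k`` is the largest rank
    with ``p_(k) <= k * q / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a 1-D array of at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * q / m)
    if np.any(below):
        k = int(np.max(np.nonzero(below)[0]))
        rejected = tuple(sorted(order[: k + 1].tolist()))
    else:
        rejected = ()
    return FDRResult(m=m, q=q, p_values=p, rejected=rejected)


@dataclass(frozen=True)
class PowerSpec:
    """A priori power analysis for a linear-regression F-test."""

    effect_size_f2: float = 0.15
    alpha: float = 0.05
    power: float = 0.80
    total_predictors: int = 4
    tested_predictors: int = 1

    def __post_init__(self) -> None:
        if self.effect_size_f2 <= 0:
            raise ValueError("effect size f^2 must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.total_predictors < 1 or self.tested_predictors < 1:
            raise ValueError("predictor counts must be >= 1")
        if self.tested_predictors > self.total_predictors:
            raise ValueError("cannot test more predictors than the model has")


def regression_power(n: int, spec: PowerSpec) -> float:
    """Power of the F-test of ``tested_predictors`` coefficients at sample
    size ``n``: noncentrality ``f^2 * n``, df ``(tested, n - total - 1)``."""
    df2 = n - spec.total_predictors - 1
    if df2 < 1:
        return 0.0
    df1 = spec.tested_predictors
    lam = spec.effect_size_f2 * n
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 1_000_000) -> int:
    """Smallest total N reaching the requested power, by linear scan."""
    for n in range(spec.total_predictors + 2, max_n + 1):
        if regression_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"power {spec.power} not reachable below N = {max_n}")


def ageing_equivalent_decline(
    unstd_beta: float,
    per_year_leakage_coeff: float,
    years: float,
    normative_slope: float | None = None,
):
    """Decline implied by an age-related change in transformed leakage.

    ``unstd_beta`` is the decline per unit of transformed leakage;
    ``per_year_leakage_coeff`` the change in transformed leakage per year of
    age.  Returns the decline in score units; if ``normative_slope``
    (decline units per year of normative ageing, externally supplied) is
    given, returns ``(decline, equivalent_ageing_years)`` instead.
    """
    if years < 0:
        raise ValueError("years cannot be negative")
    decline = float(unstd_beta) * (float(per_year_leakage_coeff) * float(years))
    if normative_slope is None:
        return decline
    if normative_slope <= 0:
        raise ValueError("normative slope must be positive")
    return decline, decline / float(normative_slope)
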