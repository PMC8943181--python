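"""Study-level statistics for the randomized smoke-exposure design.

Two-group comparisons across the randomized factors use Welch's two-sided
two-sample t-test (the reported group standard deviations are clearly
unequal, so the unequal-variance form is the safe default).  The effect
decomposition is an ordinary least-squares fit of a chosen response on one
0/1 indicator per factor plus an intercept — one indicator, not one per
level, so the design matrix has full rank and coefficients are unique.  The
timing analysis pools, per operation, the times-of-maximum of the K
highest-concentration channels (as fractions of operation length) and tests
them against a uniform null — the distribution expected if maxima showed no
systematic early- or late-operation clustering — with a one-sample
Kolmogorov–Smirnov statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DecompositionError, GroupingError, ParameterError
from .signal import OperationSummary

__all__ = [
    "ComparisonResult",
    "DecompositionResult",
    "MaxTimeResult",
    "compare_groups",
    "effect_decomposition",
    "max_time_distribution",
    "sample_size_two_group",
]

_FACTOR_LEVELS = {
    "ses": ("with_ses", "without_ses"),
    "approach": ("open", "minimally_invasive"),
    "location": ("surgeon_level", "room_air"),
}

#: Indicator coding used by the decomposition: factor -> level coded 1.
INDICATOR_LEVEL = {"ses": "with_ses", "approach": "open", "location": "surgeon_level"}


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-group comparison of one response across one factor."""

    factor: str
    response: str
    groups: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    mean_difference: float
    p_value: float

    def render_text(self) -> str:
        (a, b), (na, nb) = self.groups, self.n
        return (
            f"{self.response} by {self.factor}: "
            f"{self.mean[0]:.2f} ± {self.sd[0]:.2f} ({a}, n={na}) vs "
            f"{self.mean[1]:.2f} ± {self.sd[1]:.2f} ({b}, n={nb}), "
            f"p = {self.p_value:.2g}"
        )


def _response_values(summaries: Sequence[OperationSummary], response: str) -> np.ndarray:
    return np.array([s.response(response) for s in summaries], dtype=float)


def compare_groups(
    summaries: Sequence[OperationSummary],
    factor: str,
    response: str,
) -> ComparisonResult:
    """Welch's two-sided t-test of a response between the two factor levels."""
    if factor not in _FACTOR_LEVELS:
        raise ParameterError(f"unknown factor {factor!r}")
    level_a, level_b = _FACTOR_LEVELS[factor]
    group_a = [s for s in summaries if getattr(s.design, factor) == level_a]
    group_b = [s for s in summaries if getattr(s.design, factor) == level_b]
    for level, group in ((level_a, group_a), (level_b, group_b)):
        if len(group) < 2:
            raise GroupingError(
                f"factor {factor!r}: level {level!r} has {len(group)} operation(s); need >= 2"
            )
    xa, xb = _response_values(group_a, response), _response_values(group_b, response)
    welch = sps.ttest_ind(xa, xb, equal_var=False)
    return ComparisonResult(
        factor=factor,
        response=response,
        groups=(level_a, level_b),
        n=(xa.size, xb.size),
        mean=(float(xa.mean()), float(xb.mean())),
        sd=(float(xa.std(ddof=1)), float(xb.std(ddof=1))),
        mean_difference=float(xa.mean() - xb.mean()),
        p_value=float(welch.pvalue),
    )


def usable_factors(
    summaries: Sequence[OperationSummary],
    factors: Sequence[str] = ("ses", "approach", "location"),
) -> list[str]:
    """Factors with at least two operations at each level (analysable)."""
    out = []
    for f in factors:
        counts = [
            sum(getattr(s.design, f) == lv for s in summaries) for lv in _FACTOR_LEVELS[f]
        ]
        if min(counts) >= 2:
            out.append(f)
    return out


@dataclass(frozen=True)
class DecompositionResult:
    """OLS effect decomposition of a response on 0/1 factor indicators."""

    response: str
    coefficients: dict[str, float]
    intercept: float
    multiple_r: float
    residual_sd: float
    n: int

    def render_text(self) -> str:
        terms = ", ".join(f"{k}: {v:+.2f} ppb" for k, v in self.coefficients.items())
        return (
            f"{self.response} ~ {terms}; intercept {self.intercept:.2f} ppb, "
            f"R = {self.multiple_r:.2f}, residual sd {self.residual_sd:.2f} (n={self.n})"
        )


def effect_decomposition(
    summaries: Sequence[OperationSummary],
    response: str,
    factors: Sequence[str] = ("ses", "approach", "location"),
) -> DecompositionResult:
    """Least-squares decomposition of a response into factor effects.

    Each factor contributes one indicator column (1 for ``with_ses`` /
    ``open`` / ``surgeon_level`` respectively); the fit returns the effect of
    each indicator in ppb, the multiple correlation R and the residual sd.
    """
    for f in factors:
        if f not in INDICATOR_LEVEL:
            raise ParameterError(f"unknown factor {f!r}")
        levels = {getattr(s.design, f) for s in summaries}
        counts = [sum(getattr(s.design, f) == lv for s in summaries) for lv in _FACTOR_LEVELS[f]]
        if min(counts) < 2:
            raise DecompositionError(
                f"factor {f!r} needs >= 2 operations per level, got {dict(zip(_FACTOR_LEVELS[f], counts))}"
            )
        del levels
    y = _response_values(summaries, response)
    columns = {f: np.array([float(getattr(s.design, f) == INDICATOR_LEVEL[f]) for s in summaries])
               for f in factors}
    X = pd.DataFrame({"intercept": np.ones(y.size), **columns})
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c for c in X.columns if c != "intercept"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise DecompositionError(f"design matrix is rank deficient; collinear columns: {collinear}")
    fit = sm.OLS(y, X).fit()
    return DecompositionResult(
        response=response,
        coefficients={f: float(fit.params[f]) for f in factors},
        intercept=float(fit.params["intercept"]),
        multiple_r=float(np.sqrt(max(fit.rsquared, 0.0))),
        residual_sd=float(np.sqrt(fit.scale)),
        n=int(y.size),
    )


@dataclass(frozen=True)
class MaxTimeResult:
    """Uniformity test of pooled times-of-maximum across operations."""

    fractions: np.ndarray
    k: int
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    ks_statistic: float
    p_value: float

    @property
    def n(self) -> int:
        return int(self.fractions.size)


def max_time_distribution(
    summaries: Sequence[OperationSummary],
    k: int = 100,
    bins: int = 20,
) -> MaxTimeResult:
    """Pooled argmax-time test against the no-pattern (uniform) null.

    Per operation, the ``k`` channels with the highest maximum concentration
    are selected (all channels when fewer are present) and their
    argmax-time fractions pooled; the one-sample Kolmogorov–Smirnov test
    compares the pooled sample with the uniform distribution on [0, 1].
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    pooled = []
    for s in summaries:
        cs = s.channel_stats
        if len(cs) == 0:
            raise ParameterError(f"{s.op_id}: operation has no channels")
        top = cs.nlargest(min(k, len(cs)), "max_ppb")
        pooled.append(top["argmax_time_fraction"].to_numpy(dtype=float))
    fractions = np.concatenate(pooled) if pooled else np.empty(0)
    counts, edges = np.histogram(fractions, bins=bins, range=(0.0, 1.0))
    ks = sps.kstest(fractions, "uniform")
    return MaxTimeResult(
        fractions=fractions,
        k=k,
        histogram_counts=counts,
        histogram_edges=edges,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
    )


def sample_size_two_group(
    effect_mean_diff: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.90,
    method: str = "normal",
) -> int:
    """Per-group sample size for a two-sided two-sample t-test.

    ``method="normal"`` (default) uses the classical normal-approximation
    formula ``n = 2·((z_{1−α/2} + z_{power}) / d)²`` with ``d`` the
    standardized effect, rounded up — the form used by common clinical
    power calculators.  ``method="exact"`` searches for the smallest ``n``
    whose exact noncentral-t power reaches the target; near the rounding
    boundary it can require one more operation per group than the
    approximation.  The minimum supported size is 2 per group.
    """
    if sd <= 0:
        raise ParameterError(f"sd must be > 0, got {sd}")
    if effect_mean_diff <= 0:
        raise ParameterError(f"effect size must be > 0, got {effect_mean_diff}")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("alpha and power must lie strictly between 0 and 1")
    d = effect_mean_diff / sd
    if method == "normal":
        z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
        return max(2, int(np.ceil(2 * (z / d) ** 2)))
    if method != "exact":
        raise ParameterError(f"unknown method {method!r}")
    for n in range(2, 1_000_000):
        df = 2 * n - 2
        crit = sps.t.isf(alpha / 2, df)
        ncp = d * np.sqrt(n / 2)
        achieved = sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp)
        if achieved >= power:
            return n
    raise ParameterError("no attainable sample size below 10^6; effect too small")
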