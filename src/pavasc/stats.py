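"""Group-level longitudinal inference.

- Linear mixed-effects interaction test (group x time, random intercept per
  subject) on baseline-normalized biomarkers.
- Per-subject cross-correlation between biomarker and skin-score series with
  lag estimation (negative lag = biomarker leads the score).
- One-sided one-sample t-tests for positive mean correlation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "InteractionTestResult",
    "LagResult",
    "fit_group_time_interaction",
    "xcorr_lag",
    "ttest_positive_correlation",
    "lag_results_for_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class InteractionTestResult:
    biomarker: str
    p_value: float
    model: str
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class LagResult:
    subject_id: str
    biomarker: str
    coefficient: float
    lag_weeks: float
    n_overlap: int

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-9:
            raise ValueError(f"|correlation| > 1: {self.coefficient}")
        if self.n_overlap < 3:
            raise ValueError("fewer than 3 overlapping points at the reported lag")


def fit_group_time_interaction(
    long_table: pd.DataFrame,
    biomarker: Optional[str] = None,
    value_col: str = "normalized",
) -> InteractionTestResult:
    """Mixed-effects interaction test of group x time on a biomarker.

    Fits ``value ~ week * group`` with a subject-specific random intercept
    and returns the Wald p-value of the interaction coefficient (time as a
    continuous covariate, group as a two-level factor).  A singular or
    non-converging mixed fit falls back to ordinary least squares with the
    same mean structure (documented simpler variance structure).
    """
    df = long_table
    if biomarker is not None and "biomarker" in df.columns:
        df = df[df["biomarker"] == biomarker]
    df = df.rename(columns={value_col: "value"})[
        ["value", "week", "group", "subject"]
    ].dropna()
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    sizes = df.groupby("group")["subject"].nunique().to_dict()
    if min(sizes.values()) < 2:
        raise ValueError(f"need >=2 subjects per group, got {sizes}")
    if df["week"].nunique() < 3:
        raise ValueError("need >=3 time points for the interaction test")

    term = f"week:C(group)[T.{groups[1]}]"
    formula = "value ~ week * C(group)"
    model_desc = "MixedLM: value ~ week * group + (1 | subject)"
    try:
        # boundary estimates of the random-intercept variance are routine for
        # baseline-normalized data and do not invalidate the Wald test, so
        # convergence warnings are tolerated; only hard failures fall back
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            fit = smf.mixedlm(formula, df, groups=df["subject"]).fit(reml=True)
        p = float(fit.pvalues[term])
        if not math.isfinite(p):
            raise ValueError("non-finite interaction p-value from mixed fit")
    except Exception as exc:  # singular fit / optimizer failure
        logger.warning("mixed model failed (%s); falling back to OLS", exc)
        fit = smf.ols(formula, df).fit()
        p = float(fit.pvalues[term])
        model_desc = "OLS fallback: value ~ week * group"
    return InteractionTestResult(
        biomarker=biomarker or "",
        p_value=p,
        model=model_desc,
        group_sizes={k: int(v) for k, v in sizes.items()},
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def xcorr_lag(
    weeks: Sequence[float],
    biomarker: Sequence[float],
    scores: Sequence[float],
    max_lag_weeks: float = 8.0,
    subject_id: str = "",
    biomarker_name: str = "",
    min_overlap: int = 4,
) -> LagResult:
    """Cross-correlation with lag estimation on a common week grid.

    For each integer shift ``k`` (in sampling steps) the Pearson correlation
    is computed between ``biomarker(w)`` and ``scores(w + k * step)`` over
    the overlapping weeks; the reported lag is ``-k * step`` weeks, so a
    negative lag means the biomarker changes precede the score changes.
    Ties in maximum correlation are broken toward the smallest ``|lag|``,
    then toward the negative lag.  Lags whose overlap is constant in either
    series are skipped.  The default minimum overlap of 4 points guards
    against spurious perfect correlations on 3-point overlaps at extreme
    lags; pass ``min_overlap=3`` for the permissive contract minimum.
    """
    weeks = np.asarray(weeks, dtype=float)
    b = np.asarray(biomarker, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (len(weeks) == len(b) == len(s)):
        raise ValueError("weeks, biomarker and scores must have equal length")
    if len(weeks) < min_overlap:
        raise ValueError(f"need at least {min_overlap} points")
    steps = np.diff(np.sort(weeks))
    step = float(np.min(steps))
    if step <= 0:
        raise ValueError("weeks must be distinct")
    week_index = {float(w): i for i, w in enumerate(weeks)}
    max_k = int(max_lag_weeks // step)

    candidates: list[tuple[float, float, int]] = []  # (r, lag_weeks, n)
    for k in range(-max_k, max_k + 1):
        ib, isc = [], []
        for w in weeks:
            target = float(w + k * step)
            if target in week_index:
                ib.append(week_index[float(w)])
                isc.append(week_index[target])
        if len(ib) < min_overlap:
            continue
        r = _pearson(b[np.array(ib)], s[np.array(isc)])
        if r is None:
            continue
        candidates.append((r, -k * step, len(ib)))
    if not candidates:
        raise ValueError("correlation undefined for constant series at every lag")
    best = max(candidates, key=lambda c: (c[0], -abs(c[1]), -c[1]))
    return LagResult(
        subject_id=subject_id,
        biomarker=biomarker_name,
        coefficient=min(max(best[0], -1.0), 1.0),
        lag_weeks=float(best[1]),
        n_overlap=int(best[2]),
    )


def ttest_positive_correlation(coefficients: Sequence[float]) -> float:
    """One-sided one-sample t-test of mean correlation > 0; returns p."""
    coeffs = np.asarray(coefficients, dtype=float)
    if len(coeffs) < 2:
        raise ValueError("need at least 2 correlation coefficients")
    res = sps.ttest_1samp(coeffs, popmean=0.0, alternative="greater")
    return float(res.pvalue)


def lag_results_for_cohort(
    long_table: pd.DataFrame,
    max_lag_weeks: float = 8.0,
    value_col: str = "normalized",
) -> list[LagResult]:
    """Per-subject, per-biomarker lag results from a tidy long table.

    Subjects whose score series is strictly constant over every admissible
    overlap (e.g. healthy subjects scoring 5 throughout) have no defined
    correlation and are skipped with a logged notice.
    """
    out = []
    for (sid, name), sub in long_table.groupby(["subject", "biomarker"]):
        sub = sub.sort_values("week")
        try:
            out.append(
                xcorr_lag(
                    sub["week"].to_numpy(),
                    sub[value_col].to_numpy(),
                    sub["score"].to_numpy(),
                    max_lag_weeks=max_lag_weeks,
                    subject_id=str(sid),
                    biomarker_name=str(name),
                )
            )
        except ValueError as exc:
            logger.info("skipping %s/%s: %s", sid, name, exc)
    return out
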