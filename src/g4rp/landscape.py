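"""Landscape statistics: feature regressions, top-vs-bottom contrasts, list overlap.

These are the comparisons run on ranked enrichment tables: ordinary
least-squares regression of ES or dES against a per-gene covariate (G/C
content, gene length, read abundance, pG4 density), two-sample t-tests
between the top-k and bottom-k ranked genes, and exact set overlap between
ligand target lists. Regressions are reported unadjusted; a Bonferroni
helper is provided for grouped reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary (R^2 = r^2 for one covariate)."""

    n: int
    r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
        }


def feature_regression(values, feature) -> RegressionResult:
    """OLS of ``values`` (ES or dES) on ``feature``; two-sided slope p-value.

    Accepts aligned pandas Series or equal-length arrays; NaN pairs are
    dropped. Raises on fewer than 3 finite pairs or a constant input.
    """
    if isinstance(values, pd.Series) and isinstance(feature, pd.Series):
        df = pd.concat({"y": values, "x": feature}, axis=1, join="inner")
        y = df["y"].to_numpy(dtype=float)
        x = df["x"].to_numpy(dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        x = np.asarray(feature, dtype=float)
        if y.shape != x.shape:
            raise ValueError("values and feature must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"regression needs at least 3 finite pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("correlation undefined: feature is constant")
    if np.ptp(y) == 0:
        raise ValueError("correlation undefined: values are constant")
    res = stats.linregress(x, y)
    return RegressionResult(
        n=n,
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Top-k vs bottom-k contrast with a two-tailed t-test."""

    k: int
    mean_top: float
    mean_bottom: float
    fold: float
    t_stat: float
    p_value: float
    equal_var: bool

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "mean_top": self.mean_top,
            "mean_bottom": self.mean_bottom,
            "fold": self.fold,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "equal_var": self.equal_var,
        }


def top_bottom_comparison(
    ranked_genes: Sequence[Hashable],
    metric: Mapping[Hashable, float] | pd.Series,
    k: int = 100,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare a per-gene metric between the top-k and bottom-k ranked genes.

    ``ranked_genes`` is ordered best-to-worst; ``fold`` is mean(top)/mean(bottom).
    Student's t (equal variances) by default; ``equal_var=False`` for Welch.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranked_genes) < 2 * k:
        raise ValueError(
            f"ranked list of length {len(ranked_genes)} is too short for k={k}"
        )
    top = np.array([float(metric[g]) for g in ranked_genes[:k]])
    bottom = np.array([float(metric[g]) for g in ranked_genes[-k:]])
    mean_top, mean_bottom = float(top.mean()), float(bottom.mean())
    fold = mean_top / mean_bottom if mean_bottom != 0 else float("inf")
    if np.ptp(top) == 0 and np.ptp(bottom) == 0:
        # degenerate case: identical-variance-free groups
        t_stat, p = (0.0, 1.0) if mean_top == mean_bottom else (float("inf"), 0.0)
    else:
        t_stat, p = stats.ttest_ind(top, bottom, equal_var=equal_var)
    return GroupComparison(
        k=k,
        mean_top=mean_top,
        mean_bottom=mean_bottom,
        fold=fold,
        t_stat=float(t_stat),
        p_value=float(p),
        equal_var=equal_var,
    )


@dataclass(frozen=True)
class OverlapResult:
    """Exact set partition of two gene lists (Venn counts and members)."""

    a_only: frozenset
    b_only: frozenset
    shared: frozenset

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.a_only), len(self.b_only), len(self.shared))

    def to_dict(self) -> dict:
        return {
            "a_only": sorted(self.a_only),
            "b_only": sorted(self.b_only),
            "shared": sorted(self.shared),
            "sizes": list(self.sizes),
        }


def list_overlap(a: Iterable[Hashable], b: Iterable[Hashable]) -> OverlapResult:
    """Partition two (deduplicated) gene lists into A-only, B-only, shared."""
    sa, sb = set(a), set(b)
    return OverlapResult(
        a_only=frozenset(sa - sb), b_only=frozenset(sb - sa), shared=frozenset(sa & sb)
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F and p across two or more groups (plumbing utility)."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def anova_twoway(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-way ANOVA table (type-II sums of squares) via an OLS fit."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    op = "*" if interaction else "+"
    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))", data=data
    ).fit()
    return sm.stats.anova_lm(model, typ=2)
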