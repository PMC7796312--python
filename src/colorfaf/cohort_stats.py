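"""Cohort statistics: two-sample t-tests, one-way ANOVA with Scheffé
post-hoc comparisons, Pearson correlation, and sector-wise group tables.

The default two-sample test is the pooled-variance (Student) unpaired
t-test; Welch's variant is available via ``variant="welch"``.  Both a
raw-sample form and a summary-statistic form (mean, SD, n per group) are
provided — the latter lets printed cohort tables be re-analyzed without
raw data, and the two forms agree to machine precision for the pooled
variant.

ANOVA reports least-squares means (which for a one-way layout are the
group arithmetic means) and Scheffé pairwise p-values
p_ij = SF_F((Δm)² / ((k−1)·MSW·(1/nᵢ+1/nⱼ)); k−1, N−k),
conservative relative to unadjusted pairwise tests.  Significance is
judged two-sided at p ≤ 0.05 throughout; no multiplicity correction is
applied across sectors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging_io import SECTORS

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one group, as printed in cohort tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got n = {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    a: GroupSummary
    b: GroupSummary
    degenerate: bool = False  # both samples constant: p undefined

    @property
    def significant(self) -> bool:
        return bool(self.p <= ALPHA)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ls_means: tuple[float, ...]
    group_ns: tuple[int, ...]
    scheffe_p: np.ndarray = field(repr=False)  # k x k symmetric, unit diagonal


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> TTestResult:
    """Two-sided unpaired t-test from per-group mean/SD/n.

    ``variant="pooled"`` uses the common-variance Student test
    (df = n₁+n₂−2); ``"welch"`` uses Welch's unequal-variance test with
    Welch–Satterthwaite degrees of freedom.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be pooled or welch, got {variant!r}")
    equal_var = variant == "pooled"
    degenerate = a.sd == 0 and b.sd == 0
    if degenerate and a.mean == b.mean:
        # identical constant samples: no evidence of difference
        return TTestResult(0.0, a.n + b.n - 2, 1.0, variant, a, b, degenerate=False)
    if degenerate:
        logger.warning("zero variance in both samples: p undefined")
        return TTestResult(
            math.inf, a.n + b.n - 2, math.nan, variant, a, b, degenerate=True
        )
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    if a.mean == b.mean:
        t, p = 0.0, 1.0
    return TTestResult(float(t), df, float(p), variant, a, b)


def ttest_raw(x, y, variant: str = "pooled") -> TTestResult:
    """Two-sided unpaired t-test on raw samples.

    Agrees with :func:`ttest_from_summary` applied to the samples' own
    mean/SD/n (pooled variant) to machine precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    return ttest_from_summary(
        GroupSummary.from_sample(x), GroupSummary.from_sample(y), variant
    )


# ---------------------------------------------------------------------------
# one-way ANOVA + Scheffé
# ---------------------------------------------------------------------------

def anova_scheffe(groups: list) -> AnovaResult:
    """One-way ANOVA with least-squares means and Scheffé pairwise tests.

    For a one-way layout the least-squares (marginal) means equal the
    group arithmetic means.  Pairwise Scheffé p-values are returned as a
    symmetric k × k matrix with unit diagonal; with all-identical data
    the F statistic is 0 and every p is 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} needs n >= 2")
    ns = np.array([len(g) for g in arrays])
    means = np.array([g.mean() for g in arrays])
    n_total = int(ns.sum())
    df_b, df_w = k - 1, n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_w
    if msw == 0 and np.ptp(means) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
    scheffe = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if msw == 0:
            pij = 1.0 if means[i] == means[j] else 0.0
        else:
            fij = (means[i] - means[j]) ** 2 / (df_b * msw * (1 / ns[i] + 1 / ns[j]))
            pij = float(sps.f.sf(fij, df_b, df_w))
        scheffe[i, j] = scheffe[j, i] = pij
    return AnovaResult(
        f=f_stat,
        df_between=df_b,
        df_within=df_w,
        p=p,
        ls_means=tuple(float(m) for m in means),
        group_ns=tuple(int(n) for n in ns),
        scheffe_p=scheffe,
    )


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# sector-wise group comparison tables
# ---------------------------------------------------------------------------

def compare_groups_table(
    cohort: pd.DataFrame,
    grouping: str = "dme",
    variant: str = "pooled",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Sector × component comparison table between two strata of a cohort.

    ``grouping`` is ``"dme"`` (eyes with vs without center-involving
    macular edema) or ``"irf"`` (per-sector intraretinal-fluid flag).
    Controls are excluded by default, mirroring within-diabetic
    comparisons.  Strata with fewer than 2 eyes cause the sector to be
    skipped with a log entry.

    Returns a DataFrame with columns sector, component, mean0, sd0, n0,
    mean1, sd1, n1, t, df, p.
    """
    if grouping not in ("dme", "irf"):
        raise ValueError(f"grouping must be 'dme' or 'irf', got {grouping!r}")
    df = cohort if include_controls else cohort[cohort["group"] != "control"]
    rows = []
    for sector in SECTORS:
        flag = df["dme"] if grouping == "dme" else df[f"irf_{sector}"]
        flag = flag.astype(bool)
        for component in ("gefc", "refc"):
            col = f"{component}_{sector}"
            g0 = df.loc[~flag, col].dropna()
            g1 = df.loc[flag, col].dropna()
            if len(g0) < 2 or len(g1) < 2:
                logger.warning(
                    "sector %s (%s) skipped: stratum sizes %d/%d",
                    sector, component, len(g0), len(g1),
                )
                continue
            res = ttest_raw(g0, g1, variant)
            rows.append(
                {
                    "sector": sector,
                    "component": component.upper(),
                    "mean0": res.a.mean, "sd0": res.a.sd, "n0": res.a.n,
                    "mean1": res.b.mean, "sd1": res.b.sd, "n1": res.b.n,
                    "t": res.t, "df": res.df, "p": res.p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sector", "component", "mean0", "sd0", "n0",
                 "mean1", "sd1", "n1", "t", "df", "p"],
    )


def severity_anova_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of each sector × component across DR severity groups.

    Diabetic eyes only, grouped by DR grade; returns F, dfs and p per
    sector and component.
    """
    df = cohort[cohort["group"] != "control"]
    rows = []
    for sector in SECTORS:
        for component in ("gefc", "refc"):
            col = f"{component}_{sector}"
            groups = [
                sub[col].dropna().to_numpy()
                for _, sub in df.groupby("group", observed=True)
            ]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) < 2:
                continue
            res = anova_scheffe(groups)
            rows.append(
                {
                    "sector": sector, "component": component.upper(),
                    "F": res.f, "df_between": res.df_between,
                    "df_within": res.df_within, "p": res.p,
                }
            )
    return pd.DataFrame(rows)
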