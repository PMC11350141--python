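"""Group-comparison statistics used across the pipeline.

Standard tests (Mann-Whitney, Spearman, Fisher's exact, mixed two-way
ANOVA) are delegated to scipy/pingouin behind a uniform ``TestResult``
surface.  Two procedures are implemented here because no installed
library provides them in the required form: the ROUT outlier screen
(robust fit + FDR-style residual test at rate Q) degenerated to a robust
constant fit for group vectors, and the step-up Benjamini-Hochberg
utility returning monotone q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "mixed_anova_bonferroni",
    "rout_outliers",
    "spearman",
    "fishers_exact",
    "cohens_d_summary",
    "fdr_bh",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = ()
    effect_size: float | None = None
    post_hoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with tie correction; exact null for small
    samples (n <= 8 per group, no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    small = max(x.size, y.size) <= 8
    ties = len(np.unique(np.r_[x, y])) < x.size + y.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method=f"mann-whitney ({method})", n=(x.size, y.size),
    )


def mixed_anova_bonferroni(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
) -> TestResult:
    """Mixed two-way ANOVA (between-subject group x within-subject task)
    with Bonferroni-adjusted group comparisons at each task level.

    Subjects missing any task level are excluded listwise.  The headline
    statistic/p-value is the group main effect; the full ANOVA table and
    the interaction live in ``extra``.
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    complete = counts[counts == n_levels].index
    if len(complete) < len(counts):
        import warnings

        warnings.warn(
            f"{len(counts) - len(complete)} subject(s) missing task levels; excluded"
        )
    d = data[data[subject].isin(complete)]
    if d[between].nunique() < 2 or n_levels < 2:
        raise ValueError("need >= 2 levels of both factors")
    aov = pg.mixed_anova(
        data=d, dv=dv, within=within, between=between, subject=subject,
        correction=False,
    )
    row_g = aov[aov["Source"] == between].iloc[0]
    # Bonferroni post hocs: group contrast within each task level
    rows = []
    groups = sorted(d[between].unique())
    for level, sub in d.groupby(within, observed=True):
        a = sub.loc[sub[between] == groups[0], dv].to_numpy()
        b = sub.loc[sub[between] == groups[1], dv].to_numpy()
        t, p = sps.ttest_ind(a, b)
        rows.append({
            "comparison": f"{groups[0]} vs {groups[1]} @ {level}",
            "t": float(t), "p_raw": float(p),
            "p_adj": float(min(1.0, p * n_levels)),
        })
    return TestResult(
        statistic=float(row_g["F"]), p_value=float(row_g["p_unc"]),
        method="mixed two-way ANOVA + Bonferroni",
        n=tuple(int((d[between] == g).sum() // n_levels) for g in groups),
        post_hoc=pd.DataFrame(rows),
        extra={"anova_table": aov},
    )


def rout_outliers(x, Q: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """ROUT-style outlier screen on a group vector at rate ``Q``.

    The regression model degenerates to a robust constant fit: location =
    median, scale = robust SD of residuals (68.27th percentile of
    |residuals|, small-sample corrected).  Residual t statistics are
    screened by a step-up FDR test at rate Q; flagged points are removed.
    Returns (clean values, outlier indices).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not 0 < Q < 1:
        raise ValueError("Q must be in (0, 1)")
    resid = x - np.median(x)
    k = 1  # parameters of the constant fit
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - k)
    if rsdr == 0:
        return x, np.array([], dtype=int)
    t = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - k)
    _, reject = fdr_bh(p, q=Q, strict=False)
    outliers = np.flatnonzero(reject)
    return x[~reject], outliers


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired data with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        import warnings

        warnings.warn("constant vector: Spearman correlation undefined")
        return TestResult(np.nan, np.nan, "spearman", n=(x.size,))
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        statistic=float(rho), p_value=float(p), method="spearman",
        n=(x.size,), effect_size=float(rho),
    )


def fishers_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    tab = np.asarray(table)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if tab.shape != (2, 2) or (tab < 0).any() or np.any(tab != np.round(tab)):
            raise ValueError("need a 2x2 table of nonnegative integers")
        tab = tab.astype(int)
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult(
        statistic=float(odds), p_value=float(p), method="fisher exact",
        n=(int(tab[0].sum()), int(tab[1].sum())),
    )


def cohens_d_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    variant: str = "rms",
) -> float:
    """Standardized group difference from summary statistics.

    ``rms`` (default): |m1 - m2| / sqrt((s1^2 + s2^2)/2).
    ``pooled``: |m1 - m2| / pooled SD weighted by degrees of freedom.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    diff = abs(m1 - m2)
    if variant == "rms":
        return diff / np.sqrt((s1**2 + s2**2) / 2.0)
    if variant == "pooled":
        sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        return diff / sp
    raise ValueError(f"unknown variant {variant!r}")


def fdr_bh(p_values, q: float = 0.05, strict: bool = True):
    """Benjamini-Hochberg step-up: monotone q-values and rejection flags.

    NaN p-values are excluded from the family and stay NaN/unrejected.
    ``strict`` rejects at q_value < q (the convention used for the
    channel-wise maps); ``strict=False`` uses <=.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    qv = np.full(p.shape, np.nan)
    m = int(finite.sum())
    if m:
        pf = p[finite]
        order = np.argsort(pf, kind="stable")
        ranked = pf[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        qv[finite] = out
    if strict:
        reject = qv < q
    else:
        reject = qv <= q
    reject &= np.isfinite(qv)
    return qv, reject
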