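"""Classical statistics for morphometric population tables.

Summaries, Pearson correlation, simple linear regression with the
slope F test, paired and independent t tests, one-way ANOVA, and
Student-Newman-Keuls (SNK) stepwise pairwise comparisons — the toolbox
a morphometric cohort analysis reports.  Each statistic is computed
from its defining formula; p-values come from the corresponding scipy
reference distributions (t, F, studentized range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionFit",
    "TestResult",
    "SNKComparison",
    "summarize",
    "format_summary",
    "pearson_r",
    "linreg",
    "paired_t",
    "independent_t",
    "one_way_anova",
    "snk_pairwise",
]

REGION_COLUMNS: tuple[str, ...] = ("lpr_mm", "lqr_mm", "lir_mm", "total_mm")


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear regression y = slope*x + intercept.

    ``F`` and ``p`` test slope = 0; for one predictor the identity
    F = r^2 (n-2) / (1 - r^2) holds exactly.
    """

    slope: float
    intercept: float
    r: float
    r2: float
    F: float
    p: float
    n: int
    residual_sd: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    groups: tuple[str, ...] = ()


@dataclass(frozen=True)
class SNKComparison:
    """One SNK pairwise verdict: groups, range statistic q, stretch p."""

    groups: tuple[str, str]
    q: float
    q_critical: float
    stretch: int
    p: float
    significant: bool


def _vec(x, name: str = "x") -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def summarize(
    table: pd.DataFrame,
    by: str | None = None,
    columns: Sequence[str] = REGION_COLUMNS,
) -> pd.DataFrame:
    """Per-group n, mean and SD (n-1 denominator) for the length columns.

    Returns a frame indexed by group (single row ``'all'`` when
    ``by=None``) with a (column, stat) MultiIndex.
    """
    if by is None:
        groups = {"all": table}
    else:
        groups = {str(k): g for k, g in table.groupby(by, observed=True)}
    rows = {}
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 rows")
        rows[name] = {
            (c, stat): val
            for c in columns
            for stat, val in (
                ("n", float(len(g))),
                ("mean", float(g[c].mean())),
                ("sd", float(g[c].std(ddof=1))),
            )
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["column", "stat"])
    out.index.name = by or "group"
    return out


def format_summary(
    table: pd.DataFrame,
    by: str | None = None,
    columns: Sequence[str] = REGION_COLUMNS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Render summaries as ``mean ± SD`` or ``median (IQR)`` strings.

    A Shapiro-Wilk check at ``alpha`` per group/column picks the
    format, mirroring the convention of reporting mean ± SD only for
    approximately normal variables; it does not alter any test.
    """
    if by is None:
        groups = {"all": table}
    else:
        groups = {str(k): g for k, g in table.groupby(by, observed=True)}
    rows = {}
    for name, g in groups.items():
        cells = {}
        for c in columns:
            v = _vec(g[c], c)
            normal = True
            if 3 <= len(v) <= 5000 and np.ptp(v) > 0:
                normal = sps.shapiro(v).pvalue >= alpha
            if normal:
                cells[c] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
            else:
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                cells[c] = f"{med:.2f} ({q1:.2f}–{q3:.2f})"
        rows[name] = cells
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = by or "group"
    return out


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with a two-sided t test."""
    xv, yv = _vec(x, "x"), _vec(y, "y")
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx = xv - xv.mean()
    sy = yv - yv.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        raise ValueError("undefined correlation: a variable is constant")
    r = float(np.clip((sx @ sy) / denom, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf, 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=r, df=df, p=p, method="pearson")


def linreg(x, y) -> RegressionFit:
    """Least-squares simple regression with the slope F test."""
    xv, yv = _vec(x, "x"), _vec(y, "y")
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(np.sum((xv - xv.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate x: zero variance")
    sxy = float(np.sum((xv - xv.mean()) * (yv - yv.mean())))
    syy = float(np.sum((yv - yv.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(yv.mean()) - slope * float(xv.mean())
    sse = max(syy - slope * sxy, 0.0)
    r2 = 0.0 if syy == 0.0 else max(1.0 - sse / syy, 0.0)
    r = math.copysign(math.sqrt(r2), slope) if syy > 0 else 0.0
    df = n - 2
    resid_sd = math.sqrt(sse / df)
    if sse == 0.0:
        F, p = (math.inf, 0.0) if syy > 0 else (0.0, 1.0)
    else:
        F = (syy - sse) / (sse / df)
        p = float(sps.f.sf(F, 1, df))
    return RegressionFit(
        slope=slope, intercept=intercept, r=r, r2=r2, F=F, p=p, n=n, residual_sd=resid_sd
    )


def paired_t(a, b) -> TestResult:
    """Paired-sample t test: t = mean(d) / (SD(d)/sqrt(n)), df = n-1."""
    av, bv = _vec(a, "a"), _vec(b, "b")
    if len(av) != len(bv):
        raise ValueError("paired samples must have equal length")
    n = len(av)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = av - bv
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    df = n - 1
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p=p, method="paired t")


def independent_t(a, b, welch: bool = False) -> TestResult:
    """Two-sample t test, pooled-variance by default (``welch=True`` opts out)."""
    av, bv = _vec(a, "a"), _vec(b, "b")
    n1, n2 = len(av), len(bv)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = float(av.var(ddof=1)), float(bv.var(ddof=1))
    diff = float(av.mean() - bv.mean())
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            return TestResult(t, n1 + n2 - 2, 1.0 if diff == 0.0 else 0.0, "welch t")
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = diff / math.sqrt(se2)
        method = "welch t"
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            return TestResult(t, df, 1.0 if diff == 0.0 else 0.0, "pooled t")
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        method = "pooled t"
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p=p, method=method)


def _anova_parts(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int]:
    k = len(groups)
    ns = [len(g) for g in groups]
    N = sum(ns)
    grand = float(np.concatenate(groups).mean())
    ssb = sum(n * (float(g.mean()) - grand) ** 2 for n, g in zip(ns, groups))
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    return ssb, ssw, k - 1, N - k


def one_way_anova(groups: Sequence, labels: Sequence[str] | None = None) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within, df = (k-1, N-k)."""
    gs = [_vec(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    ssb, ssw, dfb, dfw = _anova_parts(gs)
    if ssw == 0.0:
        F = 0.0 if ssb == 0.0 else math.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(F, dfb, dfw))
    return TestResult(
        statistic=F,
        df=(dfb, dfw),
        p=p,
        method="one-way ANOVA",
        groups=tuple(labels) if labels else tuple(str(i) for i in range(len(gs))),
    )


def snk_pairwise(
    groups: Sequence,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[SNKComparison]:
    """Student-Newman-Keuls stepwise pairwise comparisons after ANOVA.

    Group means are ordered; the range statistic for a pair spanning
    ``p`` ordered means is compared with the studentized-range quantile
    q(1-alpha; p, df_within).  Testing proceeds from the widest range
    inward, and any range inside a non-significant range is declared
    non-significant without testing (the step-down rule that keeps the
    procedure coherent).  Unequal group sizes use the Tukey-Kramer
    standard error sqrt(MSW/2 * (1/n_i + 1/n_j)).
    """
    gs = [_vec(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    names = list(labels) if labels else [str(i) for i in range(k)]
    _, ssw, _, dfw = _anova_parts(gs)
    msw = ssw / dfw

    order = sorted(range(k), key=lambda i: float(gs[i].mean()))
    means = [float(gs[i].mean()) for i in order]
    ns = [len(gs[i]) for i in order]

    verdicts: dict[tuple[int, int], SNKComparison] = {}

    def test_range(lo: int, hi: int, blocked: bool) -> None:
        if (lo, hi) in verdicts:
            # keep the first (outermost) verdict; a blocked revisit may not
            # overturn an already-recorded one
            return
        stretch = hi - lo + 1
        se = math.sqrt(msw / 2.0 * (1.0 / ns[lo] + 1.0 / ns[hi]))
        q = (means[hi] - means[lo]) / se if se > 0 else (0.0 if means[hi] == means[lo] else math.inf)
        q_crit = float(sps.studentized_range.ppf(1.0 - alpha, stretch, dfw))
        p = float(sps.studentized_range.sf(q, stretch, dfw)) if math.isfinite(q) else 0.0
        sig = (not blocked) and q > q_crit
        verdicts[(lo, hi)] = SNKComparison(
            groups=(names[order[lo]], names[order[hi]]),
            q=q,
            q_critical=q_crit,
            stretch=stretch,
            p=p,
            significant=sig,
        )
        child_blocked = blocked or not sig
        if stretch > 2:
            test_range(lo + 1, hi, child_blocked)
            test_range(lo, hi - 1, child_blocked)

    test_range(0, k - 1, False)
    # recursion above can reach an inner range first through a significant
    # branch while another branch is blocked; resolve by re-running until
    # stable with proper containment logic
    changed = True
    while changed:
        changed = False
        for (lo, hi), v in sorted(verdicts.items(), key=lambda kv: kv[1].stretch, reverse=True):
            if not v.significant:
                continue
            # a range is significant only if every containing range is
            containers = [
                verdicts[(a, b)]
                for (a, b) in verdicts
                if a <= lo and hi <= b and (a, b) != (lo, hi)
            ]
            if any(not c.significant for c in containers):
                verdicts[(lo, hi)] = SNKComparison(
                    groups=v.groups, q=v.q, q_critical=v.q_critical,
                    stretch=v.stretch, p=v.p, significant=False,
                )
                changed = True
    return [verdicts[key] for key in sorted(verdicts)]
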