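"""Nonparametric statistics for OSA cohort analysis.

Spearman rank correlation with a verbal strength scale (Fowler bins:
|r| < .2 very weak, .2-.39 weak, .40-.69 modest, .70-.89 strong, >= .90
very strong) and two-tailed significance tiers at .05/.01; Mann-Whitney U
rank-sum contrasts (normal approximation with tie and continuity
correction, exact enumeration for small samples); AHI severity grouping;
matched-subset construction with a verification battery; and deterministic
table rendering that follows the reporting convention of omitting
nonsignificant correlation cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ContrastResult",
    "SeverityPolicy",
    "MatchedSubsetSpec",
    "fowler_label",
    "spearman",
    "correlation_table",
    "mann_whitney",
    "assign_severity",
    "build_matched_subset",
    "render_correlation_table",
    "render_contrast_table",
    "render_descriptive_table",
]

FOWLER_BINS = (
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.40, "modest"),
    (0.20, "weak"),
    (0.00, "very weak"),
)


def fowler_label(r: float) -> str:
    """Verbal strength of a correlation magnitude."""
    a = abs(r)
    for lo, label in FOWLER_BINS:
        if a >= lo:
            return label
    return "very weak"


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    tier: str  # "ns" | ".05" | ".01"
    fowler: str


@dataclass(frozen=True)
class ContrastResult:
    variable: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    medians: tuple[float, float]
    ns: tuple[int, int]
    U: float
    p: float
    significant_at_05: bool


@dataclass(frozen=True)
class SeverityPolicy:
    """AHI cutpoints: control below 10 events/h, severe above 30."""

    control_upper: float = 10.0
    severe_lower: float = 30.0

    def __post_init__(self) -> None:
        if not self.control_upper < self.severe_lower:
            raise ValueError("control_upper must be < severe_lower")


@dataclass(frozen=True)
class MatchedSubsetSpec:
    """Covariate filters plus the verification significance level.

    ``filters`` maps a variable name to an inclusive (low, high) range
    (use -inf/inf for one-sided thresholds).
    """

    filters: dict = field(default_factory=dict)
    alpha: float = 0.05


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------

def _tier(p: float, alpha05: float = 0.05, alpha01: float = 0.01) -> str:
    if p <= alpha01:
        return ".01"
    if p <= alpha05:
        return ".05"
    return "ns"


def spearman(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with a two-tailed p value.

    Ranks use midranks for ties; r is the Pearson correlation of the ranks.
    The p value uses the t approximation with n-2 degrees of freedom, or
    exact permutation enumeration for n <= 9.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input has zero rank variance")
    r = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 9:
        # exact permutation null of the rank correlation
        obs = abs(r)
        count = 0
        total = 0
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = sqrt(float(np.sum(rx_c**2) * np.sum(ry_c**2)))
        for perm in itertools.permutations(range(n)):
            rp = float(np.dot(rx_c[list(perm)], ry_c)) / denom
            count += abs(rp) >= obs - 1e-12
            total += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(var_x, var_y, r, float(p), n, _tier(p), fowler_label(r))


def correlation_table(
    cohort: pd.DataFrame,
    feature_vars: list[str],
    clinical_vars: list[str],
) -> list[CorrelationResult]:
    """All feature-by-clinical Spearman correlations on a cohort table."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    results = []
    for f in feature_vars:
        for c in clinical_vars:
            results.append(spearman(cohort[f], cohort[c], var_x=f, var_y=c))
    return results


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def _exact_mw_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-tailed p by enumerating all group-A assignments of the pooled data."""
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    idx = range(n)
    us = []
    for combo in itertools.combinations(idx, n1):
        r1 = ranks[list(combo)].sum()
        us.append(r1 - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    mid = n1 * (n - n1) / 2.0
    # two-tailed: as or more extreme in distance from the null centre
    return float(np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12))


def mann_whitney(
    group_a, group_b, variable: str = "x",
    group_names: tuple[str, str] = ("A", "B"),
    exact_max_n: int = 12,
) -> ContrastResult:
    """Mann-Whitney U (Wilcoxon rank-sum) two-sample contrast.

    U is the statistic for group A computed from midranks.  The two-tailed
    p value uses the normal approximation with tie and continuity
    correction, or exact enumeration of all assignments when
    ``n1 + n2 <= exact_max_n``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 3 or n2 < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= exact_max_n:
        p = _exact_mw_p(pooled, n1, u)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / sqrt(var)
            p = 2.0 * sps.norm.sf(max(z, 0.0))
    p = min(float(p), 1.0)
    return ContrastResult(
        variable=variable,
        group_names=group_names,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        medians=(float(np.median(a)), float(np.median(b))),
        ns=(n1, n2),
        U=float(u),
        p=p,
        significant_at_05=p <= 0.05,
    )


# --------------------------------------------------------------------------
# severity grouping and matched subsets
# --------------------------------------------------------------------------

def assign_severity(
    ahi, policy: SeverityPolicy | None = None, ternary: bool = False
):
    """Label AHI values: control/osa, or control/mild/severe.

    Boundary convention: AHI exactly at the control cut belongs to the OSA
    (respectively mild) group; AHI exactly at the severe cut is mild.
    """
    policy = policy or SeverityPolicy()
    arr = np.asarray(ahi, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValueError("AHI must be non-negative")
    if ternary:
        labels = np.where(
            arr < policy.control_upper, "control",
            np.where(arr <= policy.severe_lower, "mild", "severe"),
        )
    else:
        labels = np.where(arr < policy.control_upper, "control", "osa")
    return labels[0] if scalar else labels


def build_matched_subset(
    cohort: pd.DataFrame,
    spec: MatchedSubsetSpec,
    clinical_vars: tuple[str, ...] = ("weight", "height", "age", "bmi",
                                      "cervical_perimeter"),
    policy: SeverityPolicy | None = None,
):
    """Filter the cohort and verify clinical matching between groups.

    Returns (control subset, OSA subset, verification report).  The report
    is a DataFrame with one Mann-Whitney contrast per clinical variable and
    for AHI; matching passes iff every clinical variable has p > alpha while
    the AHI contrast has p <= alpha.
    """
    sub = cohort
    for var, (lo, hi) in spec.filters.items():
        if var not in cohort.columns:
            raise ValueError(f"filter references unknown variable {var!r}")
        sub = sub[(sub[var] >= lo) & (sub[var] <= hi)]
    labels = assign_severity(sub["ahi"].to_numpy(), policy)
    control = sub[labels == "control"]
    osa = sub[labels == "osa"]
    if len(control) < 3 or len(osa) < 3:
        raise ValueError("a group is (nearly) empty after filtering")

    rows = []
    passed = True
    for var in ("ahi",) + tuple(v for v in clinical_vars if v in sub.columns):
        res = mann_whitney(control[var], osa[var], variable=var,
                           group_names=("control", "osa"))
        ok = (res.p <= spec.alpha) if var == "ahi" else (res.p > spec.alpha)
        passed &= ok
        rows.append({
            "variable": var,
            "control_mean": res.means[0], "control_sd": res.sds[0],
            "osa_mean": res.means[1], "osa_sd": res.sds[1],
            "U": res.U, "p": res.p, "matched_ok": ok,
        })
    report = pd.DataFrame(rows)
    report.attrs["passed"] = bool(passed)
    return control, osa, report


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Feature-by-clinical matrix; nonsignificant cells rendered empty.

    Footnote convention: ``**`` marks significance at the .01 level,
    ``*`` at the .05 level (two-tailed).
    """
    feats = list(dict.fromkeys(r.var_x for r in results))
    clins = list(dict.fromkeys(r.var_y for r in results))
    table = pd.DataFrame("", index=feats, columns=clins)
    for r in results:
        if r.tier == "ns":
            continue
        mark = "**" if r.tier == ".01" else "*"
        table.loc[r.var_x, r.var_y] = f"{r.r:.2f}{mark}"
    return table


def render_contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    """One row per variable: mean (sd) and median per group, U, p."""
    rows = []
    for r in results:
        rows.append({
            "variable": r.variable,
            f"{r.group_names[0]} mean (sd)": f"{r.means[0]:.1f} ({r.sds[0]:.1f})",
            f"{r.group_names[1]} mean (sd)": f"{r.means[1]:.1f} ({r.sds[1]:.1f})",
            f"{r.group_names[0]} median": round(r.medians[0], 1),
            f"{r.group_names[1]} median": round(r.medians[1], 1),
            "U": r.U,
            "p": round(r.p, 3),
            "sig": "*" if r.significant_at_05 else "",
        })
    cols = ["variable"]
    if results:
        cols = list(rows[0].keys())
    return pd.DataFrame(rows, columns=cols)


def render_descriptive_table(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Mean (SD) and range per variable, the descriptive-table layout."""
    rows = []
    for v in variables:
        col = cohort[v].astype(float)
        rows.append({
            "variable": v,
            "mean (sd)": f"{col.mean():.1f} ({col.std(ddof=1):.1f})",
            "range": f"{col.min():.1f}-{col.max():.1f}",
            "n": int(col.notna().sum()),
        })
    return pd.DataFrame(rows, columns=["variable", "mean (sd)", "range", "n"])
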