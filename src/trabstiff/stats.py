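"""Nonparametric statistics for the two-group, three-level study design.

Between-group differences at the same vertebral level use the Mann-Whitney U
test; differences among levels (L4-L6) within a group use the Kruskal-Wallis
H test with Mann-Whitney follow-ups; associations between structural
parameters and the stiffness index use the Pearson correlation coefficient
with a two-tailed t-transform p-value.  Results are reported as mean +/- SD
with significance at p < 0.05 (asymptotic p-values by default, matching
common statistical-package output; exact enumeration is used for small
tie-free samples when requested or in 'auto' mode).  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "pearson",
    "summarize_study",
    "pooled_total_mean",
]

LEVELS = ("L4", "L5", "L6")


@dataclass(frozen=True)
class TestResult:
    """A single test: statistic (U, H, or r), two-tailed p, and sample sizes."""

    statistic: float
    p: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p outside [0, 1]: {self.p}")


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    ``mode='exact'`` enumerates the null distribution (valid without ties),
    ``'asymptotic'`` uses the tie-corrected normal approximation with
    continuity correction, and ``'auto'`` picks exact when both samples have
    at most 10 observations and the pooled data are tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # degenerate: all observations identical in both samples
        return TestResult(x.size * y.size / 2.0, 1.0,
                          "mann-whitney-u/degenerate", (x.size, y.size))
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    if mode == "exact" and has_ties:
        raise ValueError("exact Mann-Whitney distribution is invalid with ties")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"mann-whitney-u/{method}", (x.size, y.size))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square asymptotic p).

    Degenerate all-identical data yield H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(g.size for g in groups))
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "kruskal-wallis", tuple(g.size for g in groups))


def pearson(x, y) -> TestResult:
    """Pearson r with two-tailed p from the t-transform (n - 2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "pearson", (x.size,))


def pooled_total_mean(level_means, ns=None) -> float:
    """Pooled group mean across levels.

    With equal per-level sample sizes this equals the unweighted mean of the
    level means (how a 'Total' column over all specimens of a group is
    formed); unequal sizes are weighted accordingly.
    """
    m = np.asarray(level_means, dtype=float)
    if ns is None:
        return float(m.mean())
    w = np.asarray(ns, dtype=float)
    return float((m * w).sum() / w.sum())


def summarize_study(data: pd.DataFrame, alpha: float = 0.05,
                    mode: str = "asymptotic") -> pd.DataFrame:
    """Group-by-level summary table with significance annotations.

    ``data`` is a tidy frame with columns (specimen, group, level, parameter,
    value) and one value per (specimen, level, parameter).  For every
    parameter and group the table carries per-level mean and SD, the pooled
    Total column, the between-group Mann-Whitney p at each level, the
    within-group Kruskal-Wallis omnibus p, and pairwise level letters: a
    level is tagged 'a'/'b'/'c' when it differs (pairwise Mann-Whitney,
    p < alpha) from L4/L5/L6 respectively.
    """
    required = {"specimen", "group", "level", "parameter", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"missing columns: {sorted(required - set(data.columns))}")
    dup = data.duplicated(subset=["specimen", "level", "parameter"], keep=False)
    if dup.any():
        raise ValueError("duplicate (specimen, level, parameter) records")
    groups = sorted(data["group"].unique())
    levels = [lv for lv in LEVELS if lv in set(data["level"])] or sorted(data["level"].unique())
    letters = dict(zip(LEVELS, "abc"))
    rows = []
    for param in data["parameter"].unique():
        dp = data[data["parameter"] == param]
        for grp in groups:
            dg = dp[dp["group"] == grp]
            samples = {lv: dg.loc[dg["level"] == lv, "value"].to_numpy() for lv in levels}
            missing = [lv for lv, s in samples.items() if s.size == 0]
            if missing:
                raise ValueError(f"missing cells for {param}/{grp}: {missing}")
            omnibus = (kruskal_wallis([samples[lv] for lv in levels]).p
                       if len(levels) >= 2 else float("nan"))
            sig = {lv: "" for lv in levels}
            for i, li in enumerate(levels):
                for lj in levels[i + 1:]:
                    if np.array_equal(samples[li], samples[lj]):
                        continue
                    p = mann_whitney_u(samples[li], samples[lj], mode=mode).p
                    if p < alpha:
                        sig[li] += letters.get(lj, "?")
                        sig[lj] += letters.get(li, "?")
            row = {"parameter": param, "group": grp,
                   "kruskal_wallis_p": omnibus}
            total = np.concatenate([samples[lv] for lv in levels])
            for lv in levels:
                row[f"{lv}_mean"] = samples[lv].mean()
                row[f"{lv}_sd"] = samples[lv].std(ddof=1) if samples[lv].size > 1 else float("nan")
                row[f"{lv}_sig"] = "".join(sorted(sig[lv]))
            row["total_mean"] = total.mean()
            row["total_sd"] = total.std(ddof=1)
            rows.append(row)
        # between-group tests per level
        if len(groups) == 2:
            g1, g2 = groups
            for lv in levels:
                a = dp[(dp["group"] == g1) & (dp["level"] == lv)]["value"].to_numpy()
                b = dp[(dp["group"] == g2) & (dp["level"] == lv)]["value"].to_numpy()
                p = mann_whitney_u(a, b, mode=mode).p if a.size and b.size else float("nan")
                for row in rows:
                    if row["parameter"] == param:
                        row[f"between_{lv}_p"] = p
    return pd.DataFrame(rows).sort_values(["parameter", "group"]).reset_index(drop=True)
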