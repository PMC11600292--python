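"""Two-group and correlation statistics, FDR control and the simplified
rank-based differential-expression stage.

The DE stage deliberately replaces negative-binomial Wald testing with a
Mann-Whitney test on size-factor-normalized counts: it is robust and
assumption-light, at the cost of power on small groups. Fold changes are
computed on normalized-count group means with a 0.5 pseudocount, with
positive log2FC meaning higher expression in group A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


EXACT_MAX_N = 20


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when n_x + n_y <= 20 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # perfect symmetry: U at its null mean, no evidence either way
        return TestResult(x.size * y.size / 2.0, 1.0, "mann_whitney_degenerate", x.size, y.size)
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "mann_whitney_exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "mann_whitney_normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method, x.size, y.size)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("spearman needs n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_expr(
    circ_counts: pd.DataFrame,
    s: pd.Series,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based differential expression on normalized counts.

    Returns a table with feature_id, baseMeanA, baseMeanB, log2FC, p, q and
    significant (|log2FC| > lfc_threshold and q < alpha).
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(circ_counts.columns)
    if missing:
        raise ValueError(f"samples missing from count matrix: {sorted(missing)}")
    norm = circ_counts / s[circ_counts.columns]
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    pvals = np.array([mann_whitney(a[i], b[i]).p_value for i in range(a.shape[0])])
    qvals = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "feature_id": circ_counts.index,
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2FC": log2fc,
            "p": pvals,
            "q": qvals,
        }
    ).set_index("feature_id", drop=False)
    table["significant"] = (np.abs(table["log2FC"]) > lfc_threshold) & (table["q"] < alpha)
    return table
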