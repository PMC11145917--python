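"""Group-comparison statistics over per-region cell-count tables.

Input is a tidy counts table (one row per ``animal, group, region, count``).
Two experimental groups are compared region by region with a pooled-variance
Student's t-test; p-values are adjusted across regions by Benjamini-Hochberg
FDR; effect size is reported as a signed fold change (the ratio of group
means, written as ``-1/ratio`` when below 1, so symmetric up/down cuts read
naturally on a volcano plot).  Individual variability is summarised by
relative z-scores and the coefficient of variation, and between-region
co-activation structure by all-pairs Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "student_ttest",
    "bh_fdr",
    "signed_fold_change",
    "volcano_classify",
    "relative_zscore",
    "coefficient_of_variation",
    "spearman",
    "correlation_map",
    "CorrelationMap",
    "compare_groups",
    "counts_matrix",
]


def student_ttest(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance, df = n_a + n_b - 2).

    ``welch=True`` switches to the unequal-variance form. Degenerate input
    (zero pooled variance with unequal means) raises rather than returning a
    fabricated p-value of 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not welch and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() != b.mean():
            raise ValueError("degenerate variance: zero pooled variance with unequal means")
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_a: float, mean_b: float, epsilon: float = 0.5) -> float:
    """Ratio of (pseudo-counted) group means, signed: -1/r when the ratio r < 1."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    r = (mean_a + epsilon) / (mean_b + epsilon)
    return float(r) if r >= 1 else float(-1.0 / r)


def volcano_classify(stats: pd.DataFrame, fc_cut: float = 1.4, q_cut: float = 0.05) -> pd.DataFrame:
    """Label each region up/down/ns by strict fold-change and q cuts."""
    out = stats.copy()
    fc = out["signed_fold_change"].to_numpy(dtype=float)
    q = out["q"].to_numpy(dtype=float)
    cls = np.where(
        (fc > fc_cut) & (q < q_cut), "up", np.where((fc < -fc_cut) & (q < q_cut), "down", "ns")
    )
    out["significance_class"] = cls
    return out


def relative_zscore(
    counts: pd.DataFrame,
    groups: pd.Series | None = None,
    baseline: str = "pooled",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-region z-scores of per-animal counts.

    ``counts`` is animals x regions. The normalising mean/SD (sample SD,
    ddof 1) are taken over all animals pooled (default) or, with
    ``baseline=<group name>``, over that group's animals only. Regions with
    zero variance get z = 0 and are flagged degenerate.
    """
    counts = pd.DataFrame(counts)
    if len(counts) < 2:
        raise ValueError("need at least 2 animals")
    if baseline == "pooled":
        ref = counts
    else:
        if groups is None:
            raise ValueError("group labels required for a group baseline")
        ref = counts.loc[np.asarray(groups) == baseline]
        if len(ref) < 2:
            raise ValueError(f"baseline group {baseline!r} has fewer than 2 animals")
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    degenerate = sd == 0
    safe_sd = sd.mask(degenerate, 1.0)
    z = (counts - mu) / safe_sd
    z.loc[:, degenerate] = 0.0
    return z, degenerate


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = sample SD / mean of one group's counts in one region."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=ddof) / mean)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks; p from the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMap:
    """All-pairs Spearman structure of one group's region counts."""

    rho: pd.DataFrame           # symmetric, NaN diagonal
    p: pd.DataFrame
    q: pd.DataFrame             # BH over the upper-triangle pair set
    best_partner: pd.Series     # per region: partner with max |rho| (ties: lower id)


def correlation_map(counts: pd.DataFrame) -> CorrelationMap:
    """Spearman correlation of every region pair within one group.

    ``counts`` is animals x regions for a single group (>= 3 animals).
    The per-region "best partner" is the other region with the largest
    absolute correlation, ties resolved toward the lower region id.
    """
    counts = pd.DataFrame(counts)
    if len(counts) < 3:
        raise ValueError("need at least 3 animals for correlation")
    regions = list(counts.columns)
    m = len(regions)
    rho = np.full((m, m), np.nan)
    pval = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            r, p = spearman(counts.iloc[:, i], counts.iloc[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    iu = np.triu_indices(m, k=1)
    qflat = bh_fdr(pval[iu]) if iu[0].size else np.array([])
    qmat = np.full((m, m), np.nan)
    qmat[iu] = qflat
    qmat[(iu[1], iu[0])] = qflat

    best = {}
    for i, region in enumerate(regions):
        absr = np.abs(rho[i])
        absr_i = np.where(np.isnan(absr), -np.inf, absr)
        best[region] = regions[int(np.argmax(absr_i))]  # argmax takes first = lower id on ties
    idx = pd.Index(regions, name="region")
    return CorrelationMap(
        rho=pd.DataFrame(rho, index=idx, columns=regions),
        p=pd.DataFrame(pval, index=idx, columns=regions),
        q=pd.DataFrame(qmat, index=idx, columns=regions),
        best_partner=pd.Series(best, name="best_partner"),
    )


def counts_matrix(counts: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Pivot a tidy (animal, group, region, count) table to animals x regions."""
    df = counts if group is None else counts[counts["group"] == group]
    return df.pivot_table(index="animal", columns="region", values="count", aggfunc="sum")


def compare_groups(
    counts: pd.DataFrame,
    group_a: str,
    group_b: str,
    fc_cut: float = 1.4,
    q_cut: float = 0.05,
    epsilon: float = 0.5,
    welch: bool = False,
) -> pd.DataFrame:
    """Region-wise two-group comparison table, sorted by adjusted p-value.

    Returns one row per region with group means and standard errors, the
    pooled-variance t statistic (group_a vs group_b), BH-adjusted q, signed
    fold change (a over b) and the volcano class at ``(fc_cut, q_cut)``.
    """
    a = counts_matrix(counts, group_a)
    b = counts_matrix(counts, group_b)
    regions = sorted(set(a.columns) | set(b.columns))
    rows = []
    for region in regions:
        xa = a[region].dropna().to_numpy() if region in a else np.array([])
        xb = b[region].dropna().to_numpy() if region in b else np.array([])
        t, p = student_ttest(xa, xb, welch=welch)
        rows.append(
            {
                "region": region,
                "n_a": xa.size,
                "n_b": xb.size,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "se_a": xa.std(ddof=1) / np.sqrt(xa.size),
                "se_b": xb.std(ddof=1) / np.sqrt(xb.size),
                "t": t,
                "p": p,
                "signed_fold_change": signed_fold_change(xa.mean(), xb.mean(), epsilon),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table = volcano_classify(table, fc_cut=fc_cut, q_cut=q_cut)
    return table.sort_values("q", kind="mergesort").reset_index(drop=True)
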