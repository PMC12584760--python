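"""Two-group differential testing for feature tables and phenotypes.

Taxon / pathway tables are compared with Wilcoxon rank-sum tests and
Benjamini-Hochberg FDR control across features; phenotype traits use
independent-samples t-tests (Welch by default) without multiplicity
adjustment, mirroring how omics features and physiological traits are
conventionally treated in cohort studies. Summaries are mean ± SE.
A "tendency" flag marks 0.05 < P < 0.10.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import AbundanceTable, PhenotypeTable

__all__ = [
    "wilcoxon_rank_sum",
    "bh_fdr",
    "compare_features",
    "t_test",
    "compare_phenotypes",
    "fat_corrected_milk",
    "summarize_mean_se",
]

_EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when ``n_x + n_y <= 12`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections. Returns ``(U statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size + y.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, in input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def summarize_mean_se(values) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)); SE of a single
    value is reported as 0 with a warning."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values")
    if v.size == 1:
        warnings.warn("SE undefined for a single value; reporting 0", stacklevel=2)
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def _two_groups(labels: pd.Series):
    uniq = sorted(pd.unique(labels.dropna()))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, found {uniq}")
    return uniq


def compare_features(
    table: AbundanceTable, groups, q_cutoff: float = 0.05
) -> pd.DataFrame:
    """Per-feature Wilcoxon tests with BH-FDR across features.

    Returns a DataFrame indexed by feature with per-group mean/SE, the
    rank-sum statistic, raw p, BH q, the enrichment direction (group with
    the larger mean, set only when ``q < q_cutoff``), and a tendency flag
    for 0.05 < p < 0.10.
    """
    labels = (
        groups
        if isinstance(groups, pd.Series)
        else pd.Series(np.asarray(groups), index=table.sample_ids)
    )
    labels = labels.loc[table.sample_ids]
    ga, gb = _two_groups(labels)
    a = table.data.loc[labels == ga]
    b = table.data.loc[labels == gb]

    rows = []
    for feat in table.taxon_ids:
        stat, p = wilcoxon_rank_sum(a[feat].values, b[feat].values)
        ma, sa = summarize_mean_se(a[feat].values)
        mb, sb = summarize_mean_se(b[feat].values)
        rows.append((feat, ma, sa, mb, sb, stat, p))
    out = pd.DataFrame(
        rows,
        columns=["feature", "mean_a", "se_a", "mean_b", "se_b", "statistic", "p_value"],
    ).set_index("feature")
    out["q_value"] = bh_fdr(out["p_value"].values)
    direction = np.where(out["mean_a"] >= out["mean_b"], ga, gb)
    out["enriched_in"] = np.where(out["q_value"] < q_cutoff, direction, None)
    out["tendency"] = (out["p_value"] > 0.05) & (out["p_value"] < 0.10)
    out.attrs["groups"] = (ga, gb)
    return out


def t_test(x, y, welch: bool = True) -> tuple[float, float]:
    """Independent two-sided t-test; Welch (unequal variances) by default.

    Two constant groups with equal means return ``(0, 1)`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_phenotypes(
    pheno: PhenotypeTable, groups, welch: bool = True
) -> pd.DataFrame:
    """Per-trait t-tests with mean ± SE summaries (no multiplicity
    adjustment; significance and tendency flags at 0.05 / 0.05-0.10)."""
    labels = (
        groups
        if isinstance(groups, pd.Series)
        else pd.Series(np.asarray(groups), index=pheno.sample_ids)
    )
    labels = labels.loc[pheno.sample_ids]
    ga, gb = _two_groups(labels)
    rows = []
    for trait in pheno.trait_ids:
        xa = pheno.data.loc[labels == ga, trait].dropna().values
        xb = pheno.data.loc[labels == gb, trait].dropna().values
        t, p = t_test(xa, xb, welch=welch)
        ma, sa = summarize_mean_se(xa)
        mb, sb = summarize_mean_se(xb)
        rows.append((trait, ma, sa, mb, sb, t, p, p < 0.05, 0.05 < p < 0.10))
    out = pd.DataFrame(
        rows,
        columns=[
            "trait", "mean_a", "se_a", "mean_b", "se_b",
            "t", "p_value", "significant", "tendency",
        ],
    ).set_index("trait")
    out.attrs["groups"] = (ga, gb)
    return out


def fat_corrected_milk(M, F):
    """Fat-corrected milk yield ``0.4·M + 15·F`` (kg).

    ``M`` is the non-standard milk weight and ``F`` the fat mass of that
    milk, both in kg; either may be a scalar or array.
    """
    M = np.asarray(M, dtype=float)
    F = np.asarray(F, dtype=float)
    if (M < 0).any() or (F < 0).any():
        raise ValueError("milk and fat masses must be non-negative")
    out = 0.4 * M + 15.0 * F
    return float(out) if out.ndim == 0 else out
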