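"""Alpha-diversity estimators and rank-based beta-diversity testing.

Alpha diversity (Sobs, Shannon, Chao1, ACE) is computed on integer count
vectors — the richness estimators are undefined on relative abundances,
so :func:`alpha_diversity` refuses to estimate Chao1/ACE from fractions
unless an explicit sequencing depth is supplied to de-normalize. Beta
diversity is Bray-Curtis dissimilarity with group separation tested by
ANOSIM (999 permutations by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy, rankdata

from .enterotypes import DistanceMatrix
from .io_tables import AbundanceTable

__all__ = [
    "AnosimResult",
    "sobs",
    "shannon",
    "chao1",
    "ace",
    "alpha_diversity",
    "bray_curtis",
    "anosim",
]


def _counts(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if (v < 0).any():
        raise ValueError("negative counts")
    return v


def sobs(counts) -> int:
    """Observed richness: number of taxa with count > 0."""
    return int((_counts(counts) > 0).sum())


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity −Σ p·log p (natural log unless ``base`` given)."""
    v = _counts(counts)
    if v.sum() <= 0:
        raise ValueError("all-zero count vector")
    return float(entropy(v, base=base))


def _f(counts, i: int) -> int:
    v = np.asarray(counts)
    return int((v == i).sum())


def chao1(counts) -> float:
    """Chao1 richness: ``S_obs + F1²/(2·F2)``; bias-corrected
    ``S_obs + F1(F1−1)/2`` when there are no doubletons."""
    v = _counts(counts)
    if not np.allclose(v, np.round(v)):
        raise ValueError("chao1 requires integer counts")
    s = sobs(v)
    f1, f2 = _f(v, 1), _f(v, 2)
    if f2 > 0:
        return s + f1**2 / (2 * f2)
    return s + f1 * (f1 - 1) / 2


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator.

    ``S_abund + S_rare/C_ace + (F1/C_ace)·γ²`` with coverage
    ``C_ace = 1 − F1/N_rare`` and γ² the coefficient-of-variation term
    (floored at 0). Falls back to :func:`chao1` when every rare
    individual is a singleton (``C_ace = 0``).
    """
    v = _counts(counts)
    if not np.allclose(v, np.round(v)):
        raise ValueError("ace requires integer counts")
    v = np.round(v).astype(int)
    rare = v[(v > 0) & (v <= rare_threshold)]
    s_abund = int((v > rare_threshold).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = _f(v, 1)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0:
        return chao1(v)
    ssum = sum(i * (i - 1) * _f(v, i) for i in range(1, rare_threshold + 1))
    gamma2 = max((s_rare / c_ace) * ssum / (n_rare * (n_rare - 1)) - 1.0, 0.0) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def alpha_diversity(
    table: AbundanceTable, depths: int | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-sample diversity profile (sobs, shannon, chao1, ace).

    ``table`` should hold integer counts. Relative abundances are accepted
    only together with ``depths`` (scalar or per-sample) used to
    de-normalize; without depths, richness estimators are reported as NaN
    (Shannon is scale-invariant and always computed).
    """
    values = table.values
    is_int = np.allclose(values, np.round(values)) and values.max(initial=0) > 1
    if not is_int and depths is not None:
        depths = np.broadcast_to(np.asarray(depths), (table.n_samples,))
        values = np.round(values * depths[:, None])
        is_int = True
    rows = {}
    if not is_int:
        warnings.warn(
            "relative abundances without depths: chao1/ACE undefined, reporting NaN",
            stacklevel=2,
        )
    for sid, row in zip(table.sample_ids, values):
        rows[sid] = {
            "sobs": sobs(row),
            "shannon": shannon(row),
            "chao1": chao1(row) if is_int else np.nan,
            "ace": ace(row) if is_int else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity ``Σ|x−y| / Σ(x+y)``."""
    values = table.values
    if (values.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _anosim_r(ranks: np.ndarray, between: np.ndarray) -> float:
    m = ranks.size
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    D: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    ``R = (mean between-group rank − mean within-group rank) / (M/2)``
    over the ``M = n(n−1)/2`` ranked distances (midranks for ties). The
    permutation p-value uses the plus-one rule
    ``(#{R_perm ≥ R_obs} + 1)/(n_permutations + 1)`` so it is never 0.
    """
    labels = np.asarray(
        groups.loc[D.ids].values if isinstance(groups, pd.Series) else groups
    )
    if labels.shape[0] != D.n:
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("anosim needs >=2 groups with >=2 samples each")

    iu, ju = np.triu_indices(D.n, k=1)
    ranks = rankdata(D.values[iu, ju])
    observed = _anosim_r(ranks, labels[iu] != labels[ju])

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] != perm[ju]) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(observed, p, n_permutations, seed)
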