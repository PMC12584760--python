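"""Genus–phenotype association via Spearman rank correlation.

Builds the full correlation grid between a caller-supplied genus subset
(typically the differentially abundant genera) and phenotype traits
(milk production, serum parameters, fecal VFA). Significance is raw
P < alpha by default — an optional BH flag is available but off, since
the conventional presentation of such association heatmaps reports
unadjusted P values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .io_tables import AbundanceTable, PhenotypeTable

__all__ = ["AssociationMatrix", "spearman", "associate"]


@dataclass
class AssociationMatrix:
    rho: pd.DataFrame  # taxa × traits
    p_value: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    def to_long(self) -> pd.DataFrame:
        long = (
            self.rho.stack().rename("rho").to_frame()
            .join(self.p_value.stack().rename("p_value"))
            .join(self.significant.stack().rename("significant"))
        )
        long.index.names = ["taxon", "trait"]
        return long.reset_index()


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (t approximation).

    Missing values are dropped pairwise. A constant vector has no defined
    rank correlation: returns ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def associate(
    table: AbundanceTable,
    pheno: PhenotypeTable,
    taxa_subset=None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> AssociationMatrix:
    """Spearman rho/p grid over ``taxa_subset`` × phenotype traits.

    Samples are aligned by id; missing phenotype values are dropped
    pairwise. With ``fdr=True`` the significance mask uses BH q-values
    across the whole grid instead of raw p.
    """
    shared = [s for s in table.sample_ids if s in set(pheno.sample_ids)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    taxa = list(taxa_subset) if taxa_subset is not None else table.taxon_ids
    missing = [t for t in taxa if t not in table.data.columns]
    if missing:
        raise KeyError(f"taxa not in table: {missing}")
    abund = table.data.loc[shared, taxa]
    traits = pheno.data.loc[shared]

    rho = pd.DataFrame(index=taxa, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=taxa, columns=traits.columns, dtype=float)
    for taxon in taxa:
        for trait in traits.columns:
            r, pv = spearman(abund[taxon].values, traits[trait].values)
            rho.loc[taxon, trait] = r
            p.loc[taxon, trait] = pv
    if fdr:
        flat = p.to_numpy().ravel()
        q = bh_fdr(np.nan_to_num(flat, nan=1.0)).reshape(p.shape)
        significant = pd.DataFrame(q < alpha, index=p.index, columns=p.columns)
    else:
        significant = p < alpha
    return AssociationMatrix(rho, p, significant, alpha)
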