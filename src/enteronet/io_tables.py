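"""Tabular containers and TSV I/O shared by every analysis stage.

Two table kinds circulate through the package:

* :class:`AbundanceTable` — samples × taxa relative abundances (or raw
  counts before :func:`relative_abundance`), tagged with a taxonomic rank.
* :class:`PhenotypeTable` — samples × traits real-valued measurements
  (milk yield, serum chemistry, fecal VFA ...); missing values allowed.

The on-disk format is plain TSV: UTF-8, tab separated, ``.`` decimal,
header row of taxon/trait names, first column the sample id. Abundances
are stored as fractions (0.005 means 0.5 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "PhenotypeTable",
    "TableError",
    "read_table",
    "write_table",
    "relative_abundance",
    "filter_taxa",
    "filter_by_detection",
]

RANKS = ("genus", "asv", "family", "phylum", "pathway")


class TableError(ValueError):
    """Raised when a table fails validation or parsing."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what} id(s): {dup}")


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix.

    ``data`` is a DataFrame with sample ids as the index and taxon ids as
    columns; all values must be finite and non-negative.
    """

    data: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableError("abundance table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


@dataclass
class PhenotypeTable:
    """Samples × traits measurements; NaN marks a missing observation."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "trait")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def read_table(path, kind: str = "abundance", rank: str = "genus"):
    """Read a TSV into an :class:`AbundanceTable` or :class:`PhenotypeTable`.

    Parameters
    ----------
    path : str or Path
        TSV file with a header row; first column holds sample ids.
    kind : {"abundance", "phenotype"}
    rank : str
        Taxonomic rank recorded on an abundance table.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableError(f"non-numeric cell in {path}: {exc}") from exc
    if kind == "abundance":
        if df.isna().any().any():
            sample = df.index[df.isna().any(axis=1)][0]
            raise TableError(f"missing value in abundance row {sample!r}")
        return AbundanceTable(df, rank=rank)
    if kind == "phenotype":
        return PhenotypeTable(df)
    raise ValueError(f"unknown table kind {kind!r}")


def write_table(table, path) -> None:
    """Write a table as canonical TSV (first column ``sample_id``)."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Row-normalize to relative abundances (each row sums to 1).

    Idempotent on tables already on the simplex. An all-zero row is a
    hard error because it has no defined composition.
    """
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        sample = table.sample_ids[int(np.argmax(sums <= 0))]
        raise TableError(f"sample {sample!r} has zero total abundance")
    out = pd.DataFrame(
        values / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(out, rank=table.rank)


def _detection_fraction(table: AbundanceTable) -> np.ndarray:
    return (table.values > 0).mean(axis=0)


def filter_taxa(
    table: AbundanceTable, min_mean_abund: float = 0.005, min_prevalence: float = 0.5
) -> AbundanceTable:
    """Keep taxa with mean relative abundance strictly above ``min_mean_abund``
    AND detected (value > 0) in strictly more than ``min_prevalence`` of samples.

    This is the genus-level network pre-filter (abundance > 0.5 % and
    present in > 50 % of samples). The filter only drops columns; retained
    values are untouched, so it is a projection (applying twice == once).
    """
    if not (0 <= min_mean_abund <= 1 and 0 <= min_prevalence <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    means = table.values.mean(axis=0)
    prev = _detection_fraction(table)
    keep = (means > min_mean_abund) & (prev > min_prevalence)
    if not keep.any():
        warnings.warn("filter_taxa removed every taxon", stacklevel=2)
    return AbundanceTable(table.data.loc[:, keep], rank=table.rank)


def filter_by_detection(table: AbundanceTable, min_detection: float = 0.6) -> AbundanceTable:
    """Keep taxa detected in at least ``min_detection`` of samples.

    Mirrors the ASV-level network rule: taxa detected in fewer than 60 % of
    a cluster's samples are excluded (i.e. a taxon at exactly the threshold
    is retained).
    """
    if not 0 <= min_detection <= 1:
        raise ValueError("min_detection must lie in [0, 1]")
    keep = _detection_fraction(table) >= min_detection
    return AbundanceTable(table.data.loc[:, keep], rank=table.rank)
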