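"""Synthetic cohort generator with planted, recoverable structure.

The generator emulates the statistical shape of a lactating dairy-goat
cohort profiled at the genus level: 134 animals split into two latent
enterotypes of 43 and 91, each enterotype driven by a small set of
signature genera, compositional abundance rows, and phenotypes (milk
yield, serum chemistry, fecal VFA) whose means differ by enterotype.

Two generative models are used, matching what each downstream consumer
assumes:

* :func:`generate_cohort` — a Dirichlet mixture. Sample *i* in cluster
  *c* draws its abundance row from ``Dirichlet(alpha_c)`` where
  ``alpha_c`` equals the base concentration with the cluster's driver
  taxa multiplied by ``driver_effect``. This is the input for
  enterotyping, diversity, and differential testing.
* :func:`generate_correlated_counts` — a log-normal latent-factor model
  planting correlated taxon modules with a designated hub per module,
  the input for co-occurrence network inference.

Every planted fact is recorded in :class:`GroundTruth` so tests can score
recovery. All randomness flows from ``config.seed`` through a single
``numpy.random.Generator`` per call; identical config ⇒ bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import AbundanceTable, PhenotypeTable

__all__ = [
    "SimConfig",
    "PhenotypeSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_correlated_counts",
    "largest_remainder_counts",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """One simulated trait: per-cluster means, common SD, and a unit tag."""

    name: str
    means: tuple[float, ...]
    sd: float
    unit: str = ""


# Default traits mirror the measured panel: milk production, serum
# chemistry (means from the study population's printed serum table, SDs
# back-computed from SE·sqrt(n) at n≈43/91), and fecal VFA.
_DEFAULT_PHENOTYPES = (
    PhenotypeSpec("milk_yield", (3.6, 3.1), 0.6, "kg/d"),
    PhenotypeSpec("milk_fat", (0.13, 0.11), 0.03, "kg/d"),
    PhenotypeSpec("glucose", (2.89, 2.65), 0.50, "mmol/L"),
    PhenotypeSpec("albumin", (24.03, 25.39), 2.70, "g/L"),
    PhenotypeSpec("total_bile_acid", (13.88, 10.22), 3.20, "umol/L"),
    PhenotypeSpec("butyrate", (12.0, 9.0), 3.0, "mmol/kg"),
    PhenotypeSpec("total_vfa", (95.0, 82.0), 18.0, "mmol/kg"),
)


@dataclass
class SimConfig:
    """Parameters of the planted cohort.

    Attributes
    ----------
    n_samples, n_taxa : int
        Cohort and feature dimensions (134 animals, 80 genera by default).
    k_enterotypes : int
        Number of latent community types.
    cluster_proportions : sequence of float
        Must sum to 1; default 43/134 and 91/134, the study's split.
    driver_effect : float
        Fold-change applied to driver taxa's Dirichlet concentration in
        their own cluster; 1 plants no effect.
    base_concentration : float or sequence
        Dirichlet prior; a scalar below 1 (default 0.5) yields the
        long-tailed, sparse genus profiles typical of gut communities.
    n_driver_taxa_per_cluster : int
        Signature genera per enterotype (disjoint across clusters).
    n_modules, module_size, module_rho, hub_loading_boost
        Correlated-module plant used by :func:`generate_correlated_counts`;
        ``module_rho`` is the target pairwise log-scale correlation within
        a module and the hub loads ``hub_loading_boost``× stronger.
    phenotype_specs : tuple of PhenotypeSpec
        Traits drawn ``Normal(mean[cluster], sd)``.
    count_depth : int
        Library size for the optional multinomial count table (richness
        estimators need integer counts).
    seed : int
        Single source of randomness.
    """

    n_samples: int = 134
    n_taxa: int = 80
    k_enterotypes: int = 2
    cluster_proportions: tuple[float, ...] = (43 / 134, 91 / 134)
    driver_effect: float = 10.0
    base_concentration: float | np.ndarray = 0.5
    n_driver_taxa_per_cluster: int = 5
    n_modules: int = 3
    module_size: int = 6
    module_rho: float = 0.8
    hub_loading_boost: float = 1.5
    log_sd: float = 0.8
    phenotype_specs: tuple[PhenotypeSpec, ...] = _DEFAULT_PHENOTYPES
    count_depth: int = 20000
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.k_enterotypes:
            raise ValueError("cluster_proportions length must equal k_enterotypes")
        if abs(props.sum() - 1.0) > 1e-9 or (props <= 0).any():
            raise ValueError("cluster_proportions must be positive and sum to 1")
        base = np.asarray(self.base_concentration, dtype=float)
        if (base <= 0).any():
            raise ValueError("base_concentration must be positive")
        if self.driver_effect < 1:
            raise ValueError("driver_effect must be >= 1")
        if not 0 <= self.module_rho < 1:
            raise ValueError("module_rho must lie in [0, 1)")
        if self.n_modules * self.module_size > self.n_taxa:
            raise ValueError("planted modules exceed n_taxa")
        if self.k_enterotypes * self.n_driver_taxa_per_cluster > self.n_taxa:
            raise ValueError("driver taxa exceed n_taxa")


@dataclass
class GroundTruth:
    """Planted structure, for scoring recovery (never consumed by the pipeline)."""

    enterotype_label: pd.Series | None = None
    driver_taxa: dict[int, list[str]] = field(default_factory=dict)
    module_membership: pd.Series | None = None
    hub_taxa: dict[int, str] = field(default_factory=dict)
    phenotype_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    # pre-closure log abundances (samples × taxa); carries the planted
    # correlation structure untouched by compositional renormalization
    latent_log: pd.DataFrame | None = None

    def write(self, sample_path=None, taxon_path=None) -> None:
        """Sidecar TSVs: per-sample labels and per-taxon annotations."""
        if sample_path is not None and self.enterotype_label is not None:
            df = self.enterotype_label.rename("enterotype").to_frame()
            df.index.name = "sample_id"
            df.to_csv(sample_path, sep="\t", lineterminator="\n")
        if taxon_path is not None:
            taxa: dict[str, dict] = {}
            for c, ts in self.driver_taxa.items():
                for t in ts:
                    taxa.setdefault(t, {})["driver_of_cluster"] = c
            if self.module_membership is not None:
                for t, m in self.module_membership.items():
                    taxa.setdefault(t, {})["module"] = m
            for m, t in self.hub_taxa.items():
                taxa.setdefault(t, {})["hub_of_module"] = m
            df = pd.DataFrame.from_dict(taxa, orient="index")
            df.index.name = "taxon_id"
            df.to_csv(taxon_path, sep="\t", lineterminator="\n")


def largest_remainder_counts(proportions, n: int) -> np.ndarray:
    """Deterministic integer allocation of ``n`` items to proportions.

    Floors the exact shares, then hands the leftover units to the largest
    fractional remainders (ties to the lowest cluster index). Guarantees
    e.g. (43/134, 91/134) × 134 → exactly (43, 91), so tests can assert
    exact cluster sizes.
    """
    props = np.asarray(proportions, dtype=float)
    exact = props * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    # stable sort descending on remainder → ties favour lower index
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def _sample_ids(n: int) -> list[str]:
    return [f"s{i + 1:04d}" for i in range(n)]


def _taxon_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def generate_cohort(config: SimConfig):
    """Draw a Dirichlet-mixture cohort with planted enterotypes.

    Returns
    -------
    (AbundanceTable, PhenotypeTable, GroundTruth)
        Abundance rows sum to 1 (within 1e-9); phenotype trait *t* of a
        sample in cluster *c* is ``Normal(mean[t][c], sd[t])``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k_enterotypes
    sizes = largest_remainder_counts(config.cluster_proportions, config.n_samples)
    labels = np.repeat(np.arange(k), sizes)

    taxa = _taxon_ids(config.n_taxa, "g")
    base = np.broadcast_to(
        np.asarray(config.base_concentration, dtype=float), (config.n_taxa,)
    ).copy()

    nd = config.n_driver_taxa_per_cluster
    driver_idx = {c: list(range(c * nd, (c + 1) * nd)) for c in range(k)}
    alphas = np.tile(base, (k, 1))
    for c in range(k):
        alphas[c, driver_idx[c]] *= config.driver_effect

    rows = np.empty((config.n_samples, config.n_taxa))
    for c in range(k):
        mask = labels == c
        rows[mask] = rng.dirichlet(alphas[c], size=int(mask.sum()))

    samples = _sample_ids(config.n_samples)
    abundance = AbundanceTable(
        pd.DataFrame(rows, index=samples, columns=taxa), rank="genus"
    )

    pheno = {}
    units = {}
    for spec in config.phenotype_specs:
        if len(spec.means) != k:
            raise ValueError(f"phenotype {spec.name!r} needs {k} per-cluster means")
        means = np.asarray(spec.means)[labels]
        pheno[spec.name] = rng.normal(means, spec.sd)
        units[spec.name] = spec.unit
    phenotypes = PhenotypeTable(pd.DataFrame(pheno, index=samples), units=units)

    truth = GroundTruth(
        enterotype_label=pd.Series(labels, index=samples, name="enterotype"),
        driver_taxa={c: [taxa[i] for i in idx] for c, idx in driver_idx.items()},
        phenotype_effects={s.name: s.means for s in config.phenotype_specs},
    )
    return abundance, phenotypes, truth


def multinomial_counts(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Resample a relative-abundance table into integer counts at fixed depth."""
    rng = np.random.default_rng(seed)
    counts = np.vstack([rng.multinomial(depth, row) for row in table.values])
    return AbundanceTable(
        pd.DataFrame(counts, index=table.data.index, columns=table.data.columns),
        rank=table.rank,
    )


def generate_correlated_counts(config: SimConfig):
    """Plant correlated taxon modules via a log-normal latent-factor model.

    Taxa in module *m* share a standard-normal latent factor; a member
    loads ``lam = sqrt(rho / (1 - rho))`` against unit residual noise so
    its pairwise log-scale correlation with other members is
    ``module_rho``. The designated hub (first member) loads
    ``hub_loading_boost``× stronger, giving it the strongest correlations
    with its module and making it the best-connected node. Non-module
    taxa are independent. Each taxon's total log-scale SD is rescaled to
    ``config.log_sd`` (correlations are unaffected) so the exponentiated
    abundances have realistic, moderate dispersion. Rows are renormalized
    to the simplex; the pre-closure log matrix is kept in
    ``GroundTruth.latent_log``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_taxa
    taxa = _taxon_ids(p, "asv")

    signal = rng.normal(size=(n, p))  # residual noise, unit variance
    loading = np.zeros(p)

    membership = np.full(p, -1)
    hub_taxa: dict[int, str] = {}
    if config.module_rho > 0:
        lam = np.sqrt(config.module_rho / (1.0 - config.module_rho))
    else:
        lam = 0.0
    for m in range(config.n_modules):
        idx = np.arange(m * config.module_size, (m + 1) * config.module_size)
        membership[idx] = m
        hub_taxa[m] = taxa[idx[0]]
        factor = rng.normal(size=n)
        loadings = np.full(len(idx), lam)
        loadings[0] *= config.hub_loading_boost
        signal[:, idx] += factor[:, None] * loadings[None, :]
        loading[idx] = loadings

    # rescale every taxon to total log-SD = config.log_sd
    scale = config.log_sd / np.sqrt(1.0 + loading**2)
    log_mean = rng.normal(0.0, 0.5, size=p)  # mild baseline heterogeneity
    log_x = log_mean + signal * scale

    rows = np.exp(log_x)
    rows /= rows.sum(axis=1, keepdims=True)
    samples = _sample_ids(n)
    table = AbundanceTable(pd.DataFrame(rows, index=samples, columns=taxa), rank="asv")
    truth = GroundTruth(
        module_membership=pd.Series(membership, index=taxa, name="module"),
        hub_taxa=hub_taxa,
        latent_log=pd.DataFrame(log_x, index=samples, columns=taxa),
    )
    return table, truth
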