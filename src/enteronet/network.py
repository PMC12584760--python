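"""Co-occurrence network construction, RMT thresholding, modules, Zi/Pi roles.

Two network flavours share this machinery:

* **Genus networks** — taxa pre-filtered to >0.5 % mean abundance and
  >50 % prevalence, edges from Spearman correlations at P < 0.05 with
  sign retained (:func:`spearman_network`).
* **ASV modular networks** — taxa detected in ≥60 % of a cluster's
  samples, Pearson similarity matrix, correlation cutoff chosen by a
  random-matrix-theory (RMT) scan, modules from fast-greedy
  (Clauset-Newman-Moore) modularity optimization, and per-node
  within-module connectivity Zi / among-module connectivity Pi with the
  standard topological role classification: peripheral (Zi ≤ 2.5,
  Pi ≤ 0.62), connector (Zi ≤ 2.5, Pi > 0.62), module hub (Zi > 2.5,
  Pi ≤ 0.62), network hub (Zi > 2.5, Pi > 0.62).

The RMT scan walks candidate cutoffs; at each, entries below the cutoff
(in absolute value) are zeroed and the nearest-neighbour spacing
distribution (NNSD) of the unfolded eigenvalues is tested against the
Poisson law ``exp(−s)`` (uncorrelated spectrum — signal only) and the
GOE Wigner surmise ``(π/2)·s·exp(−πs²/4)`` (correlated — noise still
present). The chosen threshold is the smallest cutoff whose NNSD is
Poisson-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceTable

__all__ = [
    "CooccurrenceNetwork",
    "RmtThresholdScan",
    "ModularNetwork",
    "spearman_network",
    "pearson_matrix",
    "nnsd_fit",
    "rmt_threshold",
    "threshold_graph",
    "fast_greedy_modules",
    "zi_pi",
    "classify_roles",
    "build_rmt_network",
    "export_network",
    "read_network",
]

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"


@dataclass
class CooccurrenceNetwork:
    """Signed correlation network: node weights are mean relative abundances."""

    nodes: pd.DataFrame  # index taxon id, column 'abundance'
    edges: pd.DataFrame  # columns source, target, rho, p_value, sign
    alpha: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for taxon, row in self.nodes.iterrows():
            g.add_node(taxon, abundance=float(row["abundance"]))
        for _, e in self.edges.iterrows():
            g.add_edge(
                e["source"], e["target"],
                rho=float(e["rho"]), p_value=float(e["p_value"]), sign=e["sign"],
            )
        return g


@dataclass
class RmtThresholdScan:
    candidate_thresholds: np.ndarray
    nnsd_poisson_fit: np.ndarray  # per-threshold goodness-of-fit p vs Poisson
    nnsd_goe_fit: np.ndarray  # per-threshold goodness-of-fit p vs GOE
    chosen_threshold: float
    fallback: bool = False  # True when no candidate satisfied the rule

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.candidate_thresholds,
                "p_poisson": self.nnsd_poisson_fit,
                "p_goe": self.nnsd_goe_fit,
                "chosen": np.isclose(self.candidate_thresholds, self.chosen_threshold),
            }
        )


@dataclass
class ModularNetwork:
    graph: nx.Graph
    module_of: dict = field(default_factory=dict)
    zi: dict = field(default_factory=dict)
    pi: dict = field(default_factory=dict)
    role: dict = field(default_factory=dict)
    modularity_q: float = 0.0
    threshold_scan: RmtThresholdScan | None = None

    def node_table(self) -> pd.DataFrame:
        rows = {
            n: {
                "module": self.module_of.get(n),
                "zi": self.zi.get(n, np.nan),
                "pi": self.pi.get(n, np.nan),
                "role": self.role.get(n),
                "abundance": self.graph.nodes[n].get("abundance", np.nan),
            }
            for n in self.graph.nodes
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "taxon_id"
        return df


def spearman_network(table: AbundanceTable, alpha: float = 0.05) -> CooccurrenceNetwork:
    """All-pairs Spearman correlation network keeping edges with p < alpha.

    The caller is expected to have pre-filtered the table (mean abundance
    > 0.5 %, prevalence > 50 % for the genus preset). Constant taxa yield
    undefined correlations; their pairs are skipped with a warning.
    """
    values = table.values
    taxa = table.taxon_ids
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    constant = np.ptp(values, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant taxa skipped: {[t for t, c in zip(taxa, constant) if c]}",
            stacklevel=2,
        )
    ok_idx = np.flatnonzero(~constant)
    rho = np.full((len(taxa), len(taxa)), np.nan)
    p = np.full((len(taxa), len(taxa)), np.nan)
    if ok_idx.size >= 2:
        sub_rho, sub_p = stats.spearmanr(values[:, ok_idx])
        sub_rho, sub_p = np.atleast_2d(sub_rho), np.atleast_2d(sub_p)
        rho[np.ix_(ok_idx, ok_idx)] = sub_rho
        p[np.ix_(ok_idx, ok_idx)] = sub_p
    rows = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if constant[i] or constant[j]:
                continue
            if p[i, j] < alpha:
                rows.append(
                    (
                        taxa[i], taxa[j], rho[i, j], p[i, j],
                        "positive" if rho[i, j] >= 0 else "negative",
                    )
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p_value", "sign"])
    nodes = pd.DataFrame({"abundance": values.mean(axis=0)}, index=taxa)
    return CooccurrenceNetwork(nodes, edges, alpha)


def pearson_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pearson similarity matrix over taxa (unit diagonal); constant taxa
    get correlation 0 with a warning."""
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    values = table.values
    constant = np.ptp(values, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    if constant.any():
        warnings.warn("constant taxa: correlations set to 0", stacklevel=2)
        corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=table.taxon_ids, columns=table.taxon_ids)


# ---------------------------------------------------------------------------
# RMT threshold scan

def _unfold_spacings(eigvals: np.ndarray, dedup_tol: float = 1e-8) -> np.ndarray:
    """Nearest-neighbour spacings of Gaussian-kernel-unfolded eigenvalues.

    Exact degeneracies are collapsed first (standard practice: they carry
    no level-repulsion information). The cumulative spectral function is
    smoothed with a Gaussian-kernel empirical CDF (Silverman bandwidth)
    and spacings are normalized to unit mean.
    """
    e = np.sort(eigvals)
    keep = np.concatenate([[True], np.diff(e) > dedup_tol])
    e = e[keep]
    n = e.size
    if n < 3:
        return np.array([])
    sd = e.std()
    if sd == 0:
        return np.array([])
    h = 1.06 * sd * n ** (-1 / 5)
    # N(x) = sum_i Phi((x - e_i)/h), evaluated at the levels themselves
    cdf = stats.norm.cdf((e[:, None] - e[None, :]) / h).sum(axis=1)
    s = np.diff(cdf)
    mean = s.mean()
    if mean <= 0:
        return np.array([])
    return s / mean


def _gof_p(spacings: np.ndarray, cdf) -> float:
    """Chi-square goodness of fit of spacings against a spacing law CDF."""
    n = spacings.size
    nbins = max(int(np.ceil(np.log2(n) + 1)), 3)  # Sturges
    edges = np.linspace(0.0, spacings.max(), nbins + 1)
    observed, _ = np.histogram(spacings, bins=edges)
    probs = np.diff(cdf(edges))
    probs[-1] += 1.0 - cdf(edges[-1])  # fold the tail into the last bin
    expected = probs * n
    ok = expected > 0
    chi2 = float(((observed[ok] - expected[ok]) ** 2 / expected[ok]).sum())
    dof = max(int(ok.sum()) - 1, 1)
    return float(stats.chi2.sf(chi2, dof))


def _poisson_cdf(s):
    return 1.0 - np.exp(-np.asarray(s, dtype=float))


def _goe_cdf(s):
    s = np.asarray(s, dtype=float)
    return 1.0 - np.exp(-np.pi * s**2 / 4.0)


def nnsd_fit(corr: np.ndarray, t: float, min_spacings: int = 10) -> tuple[float, float]:
    """Goodness-of-fit p-values (Poisson, GOE) of the NNSD at cutoff ``t``.

    Entries with ``|corr| < t`` are zeroed (diagonal kept). A spectrum so
    degenerate that fewer than ``min_spacings`` distinct spacings remain
    is classified as Poisson-like ``(1, 0)``: massive exact degeneracy is
    the extreme opposite of GOE level repulsion and arises when the
    thresholded matrix has decomposed into disconnected rigid blocks.
    """
    a = np.asarray(corr, dtype=float)
    m = np.where(np.abs(a) >= t, a, 0.0)
    np.fill_diagonal(m, np.diag(a))
    eig = np.linalg.eigvalsh(m)
    spacings = _unfold_spacings(eig)
    if spacings.size < min_spacings:
        return 1.0, 0.0
    return _gof_p(spacings, _poisson_cdf), _gof_p(spacings, _goe_cdf)


def rmt_threshold(
    corr,
    t_min: float = 0.3,
    t_max: float = 0.95,
    step: float = 0.01,
    alpha: float = 0.05,
    min_spacings: int = 10,
) -> RmtThresholdScan:
    """Random-matrix-theory scan for the signal/noise correlation cutoff.

    For every candidate ``t`` the NNSD of the |corr|-thresholded matrix
    is tested against Poisson and GOE. The chosen threshold is the
    smallest ``t`` where Poisson is not rejected (``p > alpha``) and the
    GOE law fits worse (rejected at ``alpha`` or simply a poorer fit than
    Poisson) — the point where the spectrum has shed its noise component.
    If no candidate qualifies, the maximum candidate is returned with
    ``fallback=True`` and a warning.
    """
    a = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.abs(a).max() > 1 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if a.shape[0] < 20:
        warnings.warn("RMT scan on fewer than 20 taxa is unreliable", stacklevel=2)

    thresholds = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    p_poisson = np.empty(thresholds.size)
    p_goe = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        p_poisson[i], p_goe[i] = nnsd_fit(a, float(t), min_spacings=min_spacings)

    chosen = None
    for i, t in enumerate(thresholds):
        if p_poisson[i] > alpha and (p_goe[i] <= alpha or p_goe[i] < p_poisson[i]):
            chosen = float(t)
            break
    fallback = chosen is None
    if fallback:
        warnings.warn("no threshold satisfied the RMT rule; using t_max", stacklevel=2)
        chosen = float(thresholds[-1])
    return RmtThresholdScan(thresholds, p_poisson, p_goe, chosen, fallback)


# ---------------------------------------------------------------------------
# Graph construction, modules, roles

def threshold_graph(corr, t: float, ids=None) -> nx.Graph:
    """Undirected graph with an edge wherever ``|corr| >= t`` (i ≠ j);
    isolated nodes are retained."""
    if isinstance(corr, pd.DataFrame):
        ids = list(corr.columns)
        a = corr.to_numpy()
    else:
        a = np.asarray(corr, dtype=float)
        ids = list(range(a.shape[0])) if ids is None else list(ids)
    if not 0 < t <= 1:
        raise ValueError("t must lie in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = a.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(a[i, j]) >= t:
                g.add_edge(ids[i], ids[j], corr=float(a[i, j]))
    return g


def fast_greedy_modules(graph: nx.Graph) -> tuple[dict, float]:
    """Clauset-Newman-Moore greedy modularity maximization.

    Returns ``(module_of, Q)``. An edgeless graph gives every node its
    own module and Q = 0.
    """
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(graph.nodes)}, 0.0
    communities = nx.community.greedy_modularity_communities(graph)
    module_of = {n: m for m, comm in enumerate(communities) for n in comm}
    q = float(nx.community.modularity(graph, communities))
    return module_of, q


def zi_pi(graph: nx.Graph, module_of: dict) -> tuple[dict, dict]:
    """Within-module connectivity Zi and participation coefficient Pi.

    ``Zi = (κ_i − mean κ)/sd(κ)`` over node i's module, κ the
    within-module degree (population SD; degenerate modules give Zi = 0).
    ``Pi = 1 − Σ_s (k_is/k_i)²`` over modules s; isolated nodes get
    Pi = 0.
    """
    missing = [n for n in graph.nodes if n not in module_of]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    kappa = {
        n: sum(1 for nb in graph.neighbors(n) if module_of[nb] == module_of[n])
        for n in graph.nodes
    }
    zi: dict = {}
    modules: dict = {}
    for n in graph.nodes:
        modules.setdefault(module_of[n], []).append(n)
    for members in modules.values():
        ks = np.array([kappa[n] for n in members], dtype=float)
        sd = ks.std()  # population SD
        mean = ks.mean()
        for n in members:
            zi[n] = 0.0 if sd == 0 else float((kappa[n] - mean) / sd)
    pi: dict = {}
    for n in graph.nodes:
        k_i = graph.degree(n)
        if k_i == 0:
            pi[n] = 0.0
            continue
        per_module: dict = {}
        for nb in graph.neighbors(n):
            per_module[module_of[nb]] = per_module.get(module_of[nb], 0) + 1
        pi[n] = float(1.0 - sum((k / k_i) ** 2 for k in per_module.values()))
    return zi, pi


def classify_roles(
    zi: dict, pi: dict, zi_cut: float = 2.5, pi_cut: float = 0.62
) -> dict:
    """Four-way topological role classification (boundaries inclusive on
    the ≤ side: Zi = 2.5, Pi = 0.62 is peripheral)."""
    roles = {}
    for n in zi:
        hi_z = zi[n] > zi_cut
        hi_p = pi[n] > pi_cut
        if hi_z and hi_p:
            roles[n] = ROLE_NETWORK_HUB
        elif hi_z:
            roles[n] = ROLE_MODULE_HUB
        elif hi_p:
            roles[n] = ROLE_CONNECTOR
        else:
            roles[n] = ROLE_PERIPHERAL
    return roles


def build_rmt_network(
    table: AbundanceTable,
    t_min: float = 0.3,
    t_max: float = 0.95,
    step: float = 0.01,
    threshold: float | None = None,
) -> ModularNetwork:
    """ASV-level pipeline: Pearson matrix → RMT threshold → modules → roles.

    ``threshold`` overrides the RMT scan when given (useful for audits).
    The caller applies the ≥60 % detection filter beforehand.
    """
    corr = pearson_matrix(table)
    scan = None
    if threshold is None:
        scan = rmt_threshold(corr, t_min=t_min, t_max=t_max, step=step)
        threshold = scan.chosen_threshold
    graph = threshold_graph(corr, threshold)
    abundances = table.data.mean(axis=0)
    nx.set_node_attributes(graph, abundances.to_dict(), "abundance")
    module_of, q = fast_greedy_modules(graph)
    zi, pi = zi_pi(graph, module_of)
    roles = classify_roles(zi, pi)
    return ModularNetwork(graph, module_of, zi, pi, roles, q, scan)


# ---------------------------------------------------------------------------
# Export

def export_network(network, out_dir, prefix: str = "network") -> dict:
    """Write GraphML plus Cytoscape-ready edge and node attribute TSVs.

    Accepts either a :class:`CooccurrenceNetwork` or a
    :class:`ModularNetwork`; returns the written paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": out_dir / f"{prefix}.graphml",
        "edges": out_dir / f"{prefix}_edges.tsv",
        "nodes": out_dir / f"{prefix}_nodes.tsv",
    }
    if isinstance(network, CooccurrenceNetwork):
        g = network.to_networkx()
        edges = network.edges
        nodes = network.nodes.copy()
        nodes.index.name = "taxon_id"
    else:
        g = network.graph.copy()
        for attr, values in (
            ("module", network.module_of),
            ("zi", network.zi),
            ("pi", network.pi),
            ("role", network.role),
        ):
            nx.set_node_attributes(g, values, attr)
        edges = pd.DataFrame(
            [
                (u, v, data.get("corr", np.nan))
                for u, v, data in g.edges(data=True)
            ],
            columns=["source", "target", "corr"],
        )
        nodes = network.node_table()
    nx.write_graphml(g, paths["graphml"])
    edges.to_csv(paths["edges"], sep="\t", index=False, lineterminator="\n")
    nodes.to_csv(paths["nodes"], sep="\t", lineterminator="\n")
    return paths


def read_network(graphml_path) -> nx.Graph:
    """Re-read an exported GraphML network."""
    return nx.read_graphml(graphml_path)
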