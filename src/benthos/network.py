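"""Correlation networks with an RMT-chosen threshold and Zi-Pi roles.

A molecular ecological network (MEN) is built per sample group: Pearson
correlations between taxa, a hard threshold on |r| selected by random
matrix theory (the lowest cutoff at which the nearest-neighbour spacing
distribution of the thresholded matrix's unfolded eigenvalues follows
the Poisson law rather than the Wigner/GOE law), greedy modularity
modules, and per-node within-module degree z-score (Zi) and
participation coefficient (Pi).  Nodes with Zi > 2.5 are module hubs,
Pi > 0.62 connectors, both: network hubs; together the keystone taxa.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.stats

from .data import GroupMap, OtuTable
from .diversity import presence_filter

__all__ = [
    "CorrelationMatrix",
    "Network",
    "RmtScan",
    "correlation_matrix",
    "rmt_threshold",
    "build_network",
    "detect_modules",
    "zi_pi",
    "classify_keystones",
    "ZI_THRESHOLD",
    "PI_THRESHOLD",
]

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame
    transform: str = "relative_abundance"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(arr)) > 1 + 1e-8:
            raise ValueError("correlations outside [-1, 1]")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Network:
    graph: nx.Graph
    threshold: float
    dropped: list[str]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree), name="degree")

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": a, "taxon_b": b, "r": d.get("r", np.nan)}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r"])


@dataclass
class RmtScan:
    threshold: float | None
    report: pd.DataFrame          # columns: s, n_spacings, p_poisson
    fallback: bool


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(
    table: OtuTable,
    groups: GroupMap | None = None,
    group: str | None = None,
    transform: str = "relative_abundance",
) -> CorrelationMatrix:
    """Taxon-taxon Pearson correlations across a group's samples.

    When ``group`` is given the table is restricted to that group's
    samples and taxa present in at least half of them (the same
    presence rule used group-wide); constant taxa are dropped.
    """
    if group is not None:
        if groups is None:
            raise ValueError("a GroupMap is required to select a group")
        samples = [s for s in groups.groups().get(group, []) if s in set(table.sample_ids)]
        if len(samples) < 4:
            raise ValueError(f"group {group!r} has fewer than 4 samples")
        sub = table.select_samples(samples)
        present = presence_filter(sub, GroupMap({s: group for s in samples})).loc[group]
        sub = sub.select_taxa(list(present.index[present]))
    else:
        sub = table
    if transform == "relative_abundance":
        mat = sub.relative_abundance()
    elif transform == "counts":
        mat = sub.counts.astype(float)
    elif transform == "log":
        mat = np.log1p(sub.counts.astype(float))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    sd = mat.std(axis=0, ddof=0)
    mat = mat.loc[:, sd > 0]
    if mat.shape[1] < 3:
        raise ValueError("fewer than 3 non-constant taxa retained")
    corr = np.corrcoef(mat.to_numpy(), rowvar=False)
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(np.clip(corr, -1, 1), index=mat.columns, columns=mat.columns)
    return CorrelationMatrix(df, transform=transform)


# ---------------------------------------------------------------------------
# RMT threshold
# ---------------------------------------------------------------------------

def _nnsd_poisson_p(eigvals: np.ndarray) -> tuple[float, int]:
    """Chi-square goodness-of-fit p of the NNSD against P(d) = exp(-d).

    The spectrum is unfolded by fitting a smoothing cubic spline to the
    cumulative spectral density; degenerate eigenvalues (repeated mass)
    are collapsed first.  Returns (p, number of spacings); p is NaN when
    too few distinct eigenvalues remain.
    """
    vals = np.sort(eigvals)
    # collapse near-duplicate eigenvalues (thresholding creates large
    # degenerate blocks at 1 that would swamp the spacing statistics)
    distinct = [vals[0]]
    for v in vals[1:]:
        if v - distinct[-1] > 1e-8:
            distinct.append(v)
    vals = np.asarray(distinct)
    n = vals.size
    if n < 20:
        return np.nan, max(n - 1, 0)
    ranks = np.arange(1, n + 1, dtype=float)
    # smoothing target ~2 ranks of residual per point: tight enough to
    # follow the spectral density, loose enough not to fit the staircase
    # (an over-fitted unfolding yields picket-fence spacings, never Poisson)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spline = scipy.interpolate.UnivariateSpline(vals, ranks, k=3, s=2.0 * n)
        unfolded = spline(vals)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 15:
        return np.nan, spacings.size
    spacings = spacings / spacings.mean()
    k = int(np.ceil(np.sqrt(spacings.size)))
    # equal-probability bins under the exponential law
    edges = np.append(-np.log1p(-np.arange(0, k) / k), np.inf)
    observed, _ = np.histogram(spacings, bins=edges)
    expected = spacings.size / k
    stat = ((observed - expected) ** 2 / expected).sum()
    p = float(scipy.stats.chi2.sf(stat, df=k - 1))
    return p, spacings.size


def rmt_threshold(
    corr: CorrelationMatrix,
    scan: tuple[float, float, float] = (0.30, 0.99, 0.01),
    alpha: float = 0.05,
    persistence: int = 2,
    fallback: float = 0.80,
) -> RmtScan:
    """Scan |r| cutoffs; keep the lowest whose NNSD is Poisson-consistent.

    For each candidate s the correlation matrix is hard-thresholded
    (|r| < s zeroed, unit diagonal kept) and the nearest-neighbour
    spacing distribution of its unfolded eigenvalues is tested against
    the Poisson law.  The chosen threshold is the lowest s with
    p > alpha that stays consistent for ``persistence`` further steps.
    Matrices under 20 nodes are flagged and the configured fallback is
    returned.
    """
    start, stop, step = scan
    if not (0 < start < stop < 1):
        raise ValueError("scan bounds must satisfy 0 < start < stop < 1")
    arr = corr.values.to_numpy()
    if corr.n < 20:
        logger.warning("correlation matrix too small for spectral statistics; using fallback")
        report = pd.DataFrame(columns=["s", "n_spacings", "p_poisson"])
        return RmtScan(threshold=fallback, report=report, fallback=True)
    candidates = np.arange(start, stop + step / 2, step)
    rows = []
    for s in candidates:
        a = np.where(np.abs(arr) >= s, arr, 0.0)
        np.fill_diagonal(a, 1.0)
        eig = np.linalg.eigvalsh(a)
        p, nsp = _nnsd_poisson_p(eig)
        rows.append({"s": round(float(s), 10), "n_spacings": nsp, "p_poisson": p})
    report = pd.DataFrame(rows)
    ps = report["p_poisson"].to_numpy()
    chosen = None
    for i in range(len(ps)):
        window = ps[i : i + persistence + 1]
        if len(window) < persistence + 1:
            window = ps[i:]
        if np.all(np.nan_to_num(window, nan=-1.0) > alpha):
            chosen = float(report["s"].iloc[i])
            break
    if chosen is None:
        logger.warning("no Poisson-consistent threshold in scan range; using fallback")
        return RmtScan(threshold=fallback, report=report, fallback=True)
    return RmtScan(threshold=chosen, report=report, fallback=False)


# ---------------------------------------------------------------------------
# graph construction and modules
# ---------------------------------------------------------------------------

def build_network(corr: CorrelationMatrix, s_t: float) -> Network:
    """Undirected unweighted graph with an edge wherever |r| >= s_t."""
    if not 0.0 < s_t < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    arr = corr.values.to_numpy()
    ids = corr.taxon_ids
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = np.abs(arr[iu, ju]) >= s_t
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], r=float(arr[i, j]))
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges at threshold {s_t}")
    isolated = [nd for nd in g.nodes if g.degree(nd) == 0]
    if isolated:
        logger.info("dropping %d isolated node(s)", len(isolated))
        g.remove_nodes_from(isolated)
    return Network(graph=g, threshold=float(s_t), dropped=isolated)


def detect_modules(net: Network, seed: int | None = None) -> tuple[dict[str, int], float]:
    """Greedy (CNM) modularity maximisation.

    Returns a node -> module-id map (modules numbered by decreasing
    size, ties broken by lowest member id) and the modularity Q.  The
    greedy algorithm is deterministic; ``seed`` is accepted for
    interface stability and unused.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.greedy_modularity_communities(net.graph)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    partition = {node: i for i, comm in enumerate(ordered) for node in comm}
    q = nx.community.modularity(net.graph, ordered)
    return partition, float(q)


def zi_pi(net: Network, partition: dict[str, int]) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient.

    Zi = (k_i,within - mean_module) / sd_module (0, flagged, when the
    module's within-degree sd is 0); Pi = 1 - sum_t (k_it / k_i)^2.
    """
    g = net.graph
    missing = [nd for nd in g.nodes if nd not in partition]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    nodes = list(g.nodes)
    mod_of = {nd: partition[nd] for nd in nodes}
    modules = sorted(set(mod_of.values()))
    k_within = {}
    k_to_module = {}
    for nd in nodes:
        if g.degree(nd) == 0:
            raise ValueError(f"node of degree 0: {nd!r}")
        counts: dict[int, int] = {}
        for nb in g.neighbors(nd):
            counts[mod_of[nb]] = counts.get(mod_of[nb], 0) + 1
        k_to_module[nd] = counts
        k_within[nd] = counts.get(mod_of[nd], 0)
    stats = {}
    for m in modules:
        ks = np.array([k_within[nd] for nd in nodes if mod_of[nd] == m], dtype=float)
        stats[m] = (ks.mean(), ks.std(ddof=0))
    rows = []
    for nd in nodes:
        m = mod_of[nd]
        mean, sd = stats[m]
        zi = 0.0 if sd == 0 else (k_within[nd] - mean) / sd
        k = g.degree(nd)
        pi = 1.0 - sum((kt / k) ** 2 for kt in k_to_module[nd].values())
        rows.append(
            {
                "taxon": nd,
                "module": m,
                "degree": k,
                "zi": zi,
                "pi": pi,
                "zi_degenerate": sd == 0,
            }
        )
    df = pd.DataFrame(rows).set_index("taxon")
    df["role"] = [
        _role(z, p) for z, p in zip(df["zi"], df["pi"])
    ]
    return df


def _role(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network_hub"
    if zi > ZI_THRESHOLD:
        return "module_hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


def classify_keystones(roles: pd.DataFrame) -> pd.DataFrame:
    """Keystone taxa: module hubs, connectors and network hubs."""
    return roles.loc[roles["role"] != "peripheral"].copy()
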