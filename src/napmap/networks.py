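"""Gene networks: construction, interconnectedness tests, modules.

Networks are weighted undirected :class:`networkx.Graph` objects whose
nodes carry two covariates — ``cds_length`` (coding-sequence length, bp)
and ``connectivity`` (weighted degree) — used to draw covariate-matched
random gene sets.  The interconnectedness of a gene set is the sum of
edge weights among its members; significance comes from comparing that
sum to 1000 permuted sets matched for CDS length and connectivity, with
the empirical p the fraction of permuted sets strictly more
interconnected than the observed one.  Module detection is Louvain greedy
modularity maximisation at resolution 1 (best of several seeded restarts).

Co-expression networks are built from an expression matrix by dropping
genes expressed (value >= 1) in at most 5% of samples and connecting the
survivors by the Pearson correlation of their expression vectors, keeping
the strongest |r| edges.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm

from .phenosim import PermutationTestResult

logger = logging.getLogger(__name__)


def attach_connectivity(net: nx.Graph) -> nx.Graph:
    """(Re)compute the weighted-degree covariate on every node."""
    deg = dict(net.degree(weight="weight"))
    nx.set_node_attributes(net, {n: float(d) for n, d in deg.items()}, "connectivity")
    return net


def build_coexpression(
    expr: pd.DataFrame,
    min_value: float = 1.0,
    max_low_frac: float = 0.95,
    r_quantile: float = 0.99,
    cds_lengths: pd.Series | None = None,
) -> nx.Graph:
    """Co-expression network from a genes x samples expression matrix.

    Genes with expression below ``min_value`` in more than ``max_low_frac``
    of samples are excluded (the FPKM < 1 in > 95% filter), as are genes
    with constant expression (correlation undefined, logged).  Remaining
    gene pairs are scored by Pearson r; edges above the ``r_quantile``
    quantile of |r| are kept with weight |r|.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate expression")
    low_frac = (expr < min_value).mean(axis=1)
    keep = expr.index[low_frac <= max_low_frac]
    dropped = len(expr) - len(keep)
    if dropped:
        logger.info("expression filter removed %d genes", dropped)
    sub = expr.loc[keep]
    sd = sub.std(axis=1, ddof=1)
    const = sd.index[sd == 0]
    if len(const):
        logger.warning("excluding %d constant-expression genes", len(const))
        sub = sub.drop(index=const)
    genes = list(sub.index)
    R = np.corrcoef(sub.to_numpy(dtype=float))
    R = np.atleast_2d(R)
    iu, ju = np.triu_indices(len(genes), k=1)
    absr = np.abs(R[iu, ju])
    thr = np.quantile(absr, r_quantile) if len(absr) else 1.0
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b, w in zip(iu, ju, absr):
        if w >= thr and w > 0:
            g.add_edge(genes[a], genes[b], weight=float(w))
    if cds_lengths is not None:
        nx.set_node_attributes(
            g, {n: float(cds_lengths.get(n, np.nan)) for n in g.nodes}, "cds_length"
        )
    return attach_connectivity(g)


def interconnectedness(net: nx.Graph, genes: set[str]) -> float:
    """Sum of edge weights among the gene set's members present in the net.

    Genes absent from the network are skipped (counted in a log message).
    """
    present = set(genes) & set(net.nodes)
    absent = len(genes) - len(present)
    if absent:
        logger.info("interconnectedness: %d genes absent from the network", absent)
    if len(present) < 2:
        raise ValueError("need at least 2 in-network genes")
    total = 0.0
    for a, b, data in net.subgraph(present).edges(data=True):
        total += data.get("weight", 1.0)
    return float(total)


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin index per value; degenerate distributions collapse bins."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    qs = np.unique(qs)
    if len(qs) <= 2:
        return np.zeros(len(values), dtype=int)
    return np.clip(np.searchsorted(qs, values, side="right") - 1, 0, len(qs) - 2)


def matched_random_sets(
    net: nx.Graph,
    target: set[str],
    n_perm: int,
    n_bins: int = 5,
    seed: int = 0,
) -> list[set[str]]:
    """Random gene sets matched to the target's CDS/connectivity profile.

    Network nodes are cross-stratified into ``n_bins`` quantile bins of
    log CDS length times ``n_bins`` bins of connectivity; each sampled set
    draws, per stratum, as many genes as the target holds there.  Strata
    too small to supply their quota borrow the nearest neighbouring strata
    (logged).
    """
    nodes = list(net.nodes)
    cds = np.array([net.nodes[n].get("cds_length", np.nan) for n in nodes], float)
    conn = np.array([net.nodes[n].get("connectivity", np.nan) for n in nodes], float)
    if np.isnan(cds).any() or np.isnan(conn).any():
        raise ValueError("cds_length and connectivity covariates required on all nodes")
    missing = set(target) - set(nodes)
    if missing:
        raise KeyError(f"target genes absent from the network: {sorted(missing)}")
    b_cds = _quantile_bins(np.log(np.maximum(cds, 1e-12)), n_bins)
    b_conn = _quantile_bins(conn, n_bins)
    strata = b_cds * (b_conn.max() + 1) + b_conn
    node_idx = {n: i for i, n in enumerate(nodes)}
    target_strata = np.array([strata[node_idx[g]] for g in target])
    need = pd.Series(target_strata).value_counts()

    # per-stratum candidate pools with nearest-stratum fallback
    pools: dict[int, np.ndarray] = {}
    for s, k in need.items():
        pool = np.flatnonzero(strata == s)
        if len(pool) < k:
            sc, sk = divmod(int(s), b_conn.max() + 1)
            order = sorted(
                set(strata),
                key=lambda t: abs(t // (b_conn.max() + 1) - sc)
                + abs(t % (b_conn.max() + 1) - sk),
            )
            widened = []
            for t in order:
                widened.extend(np.flatnonzero(strata == t))
                if len(widened) >= k:
                    break
            logger.info(
                "stratum %d short of candidates (%d < %d); widened to %d",
                s, len(pool), k, len(widened),
            )
            pool = np.asarray(widened)
        if len(pool) < k:
            raise ValueError(f"stratum {s}: not enough candidates even after fallback")
        pools[int(s)] = pool

    rng = np.random.default_rng(seed)
    sets: list[set[str]] = []
    for _ in range(n_perm):
        chosen: list[str] = []
        for s, k in need.items():
            picks = rng.choice(pools[int(s)], size=int(k), replace=False)
            chosen.extend(nodes[i] for i in picks)
        sets.append(set(chosen))
    return sets


def interconnectedness_test(
    net: nx.Graph,
    genes: set[str],
    n_perm: int = 1000,
    n_bins: int = 5,
    seed: int = 0,
    smoothed: bool = False,
) -> PermutationTestResult:
    """Permutation test of a gene set's network interconnectedness.

    p = fraction of covariate-matched random sets whose internal edge-weight
    sum is strictly greater than the observed one (``(r+1)/(n+1)`` with
    ``smoothed=True``).
    """
    observed = interconnectedness(net, genes)
    null_sets = matched_random_sets(net, set(genes) & set(net.nodes),
                                    n_perm, n_bins, seed)
    # vectorised internal-sum over permuted sets
    nodes = list(net.nodes)
    node_idx = {n: i for i, n in enumerate(nodes)}
    edges = np.array(
        [(node_idx[a], node_idx[b], d.get("weight", 1.0))
         for a, b, d in net.edges(data=True)]
    )
    null = np.zeros(n_perm)
    if len(edges):
        ea = edges[:, 0].astype(int)
        eb = edges[:, 1].astype(int)
        ew = edges[:, 2]
        member = np.zeros(len(nodes), dtype=bool)
        for i, s in enumerate(null_sets):
            member[:] = False
            member[[node_idx[g] for g in s]] = True
            null[i] = ew[member[ea] & member[eb]].sum()
    r = int((null > observed).sum())
    p = (r + 1) / (n_perm + 1) if smoothed else r / n_perm
    return PermutationTestResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        n_perm=n_perm,
        p_empirical=float(p),
        null_values=null,
    )


def modularity(
    net: nx.Graph, assignment: dict[str, int], resolution: float = 1.0
) -> float:
    """Weighted Newman modularity of a node -> module assignment."""
    if set(assignment) != set(net.nodes):
        raise ValueError("assignment must cover exactly the network's nodes")
    comms: dict[int, set] = {}
    for node, mod in assignment.items():
        comms.setdefault(mod, set()).add(node)
    if net.number_of_edges() == 0:
        return 0.0
    return float(
        nx_comm.modularity(net, list(comms.values()), weight="weight",
                           resolution=resolution)
    )


def louvain_partition(
    net: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[dict[str, int], float]:
    """Louvain community detection; best of ``n_restarts`` seeded runs.

    Returns (node -> module assignment, achieved modularity).  An
    edgeless network puts every node in its own module with modularity 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if net.number_of_edges() == 0:
        return {n: i for i, n in enumerate(net.nodes)}, 0.0
    best_q, best_comms = -np.inf, None
    for k in range(n_restarts):
        comms = nx_comm.louvain_communities(
            net, weight="weight", resolution=resolution, seed=seed * 1000 + k
        )
        q = nx_comm.modularity(net, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_comms = q, comms
    assignment = {n: i for i, c in enumerate(best_comms) for n in c}
    return assignment, float(best_q)
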