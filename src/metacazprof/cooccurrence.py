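"""Proportionality co-occurrence networks on CLR data.

Association between two features of a compositional matrix is measured by
the symmetric proportionality coefficient

    rho = 1 − var(a − b) / (var(a) + var(b)) = 2 cov(a, b) / (var(a) + var(b))

computed on CLR-transformed rows a and b across samples (sample variance,
n−1 denominator).  rho lies in [−1, 1]; the network retains the top-K
most positive pairs and reports its connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import ValidationError, logger


def _node_label(key) -> str:
    if isinstance(key, tuple):
        return "|".join(str(k) for k in key)
    return str(key)


def rho_pairs(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs symmetric rho between rows of a CLR matrix.

    Returns a DataFrame with columns ``node_a``, ``node_b``, ``rho``,
    nodes in canonical (sorted) order within each pair.  Pairs involving a
    zero-variance feature have undefined rho and are dropped (count
    logged).
    """
    if clr_matrix.shape[0] < 2:
        raise ValidationError("need at least 2 features for pairwise rho")
    if clr_matrix.shape[1] < 3:
        raise ValidationError("need at least 3 samples for pairwise rho")
    X = clr_matrix.values
    var = X.var(axis=1, ddof=1)
    ok = var > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("rho_pairs: dropping %d zero-variance feature(s)", n_bad)
    Xok = X[ok]
    labels = [_node_label(k) for k in clr_matrix.index[ok]]
    vok = var[ok]
    cov = np.cov(Xok)
    denom = vok[:, None] + vok[None, :]
    rho = 2.0 * cov / denom
    iu, ju = np.triu_indices(len(labels), k=1)
    rows = []
    for i, j in zip(iu, ju):
        a, b = labels[i], labels[j]
        if b < a:
            a, b = b, a
        rows.append((a, b, rho[i, j]))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "rho"])


@dataclass
class CooccurrenceNetwork:
    """Top-K proportionality network with its connected components."""

    graph: nx.Graph
    edges: pd.DataFrame  # columns node_a, node_b, rho, rank
    components: list[frozenset[str]] = field(default_factory=list)


def build_network(edges: pd.DataFrame, top_k: int) -> CooccurrenceNetwork:
    """Retain the ``top_k`` most positive edges and compute components.

    Edges are ranked by rho descending; ties at the cutoff are broken by
    canonical node-name order so the result is deterministic.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    ranked = edges.sort_values(
        by=["rho", "node_a", "node_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    kept = ranked.head(top_k).copy()
    kept["rank"] = np.arange(1, len(kept) + 1)
    g = nx.Graph()
    for row in kept.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, rho=row.rho)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    return CooccurrenceNetwork(graph=g, edges=kept, components=components)


def permutation_significance(
    clr_matrix: pd.DataFrame,
    node_a,
    node_b,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Optional permutation screen for one edge.

    The sample order of feature ``node_b`` is permuted ``n_perm`` times;
    p = (1 + #{rho_perm >= rho_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    a = clr_matrix.loc[node_a].values.astype(float)
    b = clr_matrix.loc[node_b].values.astype(float)

    def _rho(u, v):
        return 2.0 * np.cov(u, v, ddof=1)[0, 1] / (u.var(ddof=1) + v.var(ddof=1))

    rho_obs = _rho(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _rho(a, rng.permutation(b)) >= rho_obs - 1e-12
    return (1 + hits) / (1 + n_perm)


def write_edges(network: CooccurrenceNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(network: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
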