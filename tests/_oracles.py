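"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with different tools than the
package (dense distance matrices, networkx graph components, direct
predicate coding) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform


def _dense_adjacency(xy: np.ndarray, radius: float) -> np.ndarray:
    n = len(xy)
    if n <= 1:
        return np.zeros((n, n), dtype=bool)
    return squareform(pdist(xy)) <= radius


def density_cluster_oracle(xy: np.ndarray, eps: float, min_pts: int):
    """Explicit ε-neighbourhood-graph clustering on small instances.

    A point is core when its ε-neighbourhood (itself included) holds at
    least ``min_pts`` points.  Clusters are connected components of the
    core-core ε-graph; non-core points adjacent to a core are border cells
    of (at least) that core's component; the rest is noise.

    Returns (core_component: core index -> component id,
    border_candidates: border index -> set of adjacent component ids,
    noise index set).
    """
    neigh = _dense_adjacency(xy, eps)
    np.fill_diagonal(neigh, True)
    core = neigh.sum(axis=1) >= min_pts
    core_idx = np.flatnonzero(core)
    sub = neigh[np.ix_(core_idx, core_idx)].copy()
    np.fill_diagonal(sub, False)
    g = nx.from_numpy_array(sub)
    comp_of: dict[int, int] = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for local in comp:
            comp_of[int(core_idx[local])] = cid
    border: dict[int, set[int]] = {}
    noise: set[int] = set()
    for i in np.flatnonzero(~core):
        adjacent = {comp_of[int(j)] for j in core_idx[neigh[i, core_idx]]}
        if adjacent:
            border[int(i)] = adjacent
        else:
            noise.add(int(i))
    return comp_of, border, noise


def strand_merge_oracle(
    memberships: list[set[int]],
    xy: np.ndarray,
    link_radius: float,
    min_path_cells: int,
) -> list[set[int]]:
    """Bridge-connectivity oracle for strand merging.

    Builds the ε′-graph over unclustered cells with networkx; any
    unclustered component of at least ``min_path_cells`` cells lying
    within ε′ of two or more clusters fuses them (transitively).  Returns
    the merged cluster membership sets (cluster cells only).
    """
    clustered = set().union(*memberships) if memberships else set()
    noise = np.array([i for i in range(len(xy)) if i not in clustered], dtype=int)
    adj = _dense_adjacency(xy, link_radius)

    sub = adj[np.ix_(noise, noise)].copy()
    if len(noise):
        np.fill_diagonal(sub, False)
    g = nx.from_numpy_array(sub)

    merge_graph = nx.Graph()
    merge_graph.add_nodes_from(range(len(memberships)))
    for comp in nx.connected_components(g):
        if len(comp) < min_path_cells:
            continue
        comp_idx = noise[list(comp)]
        touched = {
            ci
            for ci, members in enumerate(memberships)
            if adj[np.ix_(comp_idx, list(members))].any()
        }
        for a in touched:
            for b in touched:
                if a < b:
                    merge_graph.add_edge(a, b)

    merged = []
    for group in nx.connected_components(merge_graph):
        merged.append(set().union(*(memberships[ci] for ci in group)))
    return sorted(merged, key=min)


def qualification_oracle(n_total: int, n_lymph: int, min_cells=250, min_frac=0.5) -> bool:
    """Independently coded inclusion predicate."""
    if n_total < min_cells:
        return False
    return n_lymph / n_total > min_frac


def permutation_p_value(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo permutation p for |Spearman rho| (two-sided)."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    obs = abs(np.mean(rx * ry))
    hits = 0
    for _ in range(n_perm):
        hits += abs(np.mean(rx * rng.permutation(ry))) >= obs - 1e-12
    return (hits + 1) / (n_perm + 1)


def disc_union_area(xy: np.ndarray, radius: float, n_mc: int, rng: np.random.Generator) -> float:
    """Monte-Carlo area of the union of discs of ``radius`` around points."""
    lo = xy.min(axis=0) - radius
    hi = xy.max(axis=0) + radius
    samples = rng.uniform(lo, hi, size=(n_mc, 2))
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    d, _ = tree.query(samples, k=1)
    frac = (d <= radius).mean()
    return frac * np.prod(hi - lo)
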