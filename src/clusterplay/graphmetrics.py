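"""Directed small-world metrics of the recurrent E-to-E graph.

The small-world index (SWI) locates a directed graph between a
one-dimensional ring lattice and an Erdős–Rényi random graph of the same
size and density:

    SWI = (L - L_l) / (L_r - L_l) * (C - C_r) / (C_l - C_r)

with closed-form references C_r = p, L_r = (ln n - γ)/ln k + 1/2,
C_l = 3(k-2) / (4(k-1)), L_l = n/(2k) + 1/2 (γ is the Euler–Mascheroni
constant, k the mean degree).  A lattice-like graph (L ≈ L_l or C ≈ C_r)
scores near 0; an ideal small-world graph (short paths like a random
graph, clustering like a lattice) scores near 1.

C follows the directed-triplet (Fagiolo-style) definition on the
symmetrized graph: the headline value is the global ratio of closed
directed triplets over possible triplets; the per-node mean is also
reported.  L is the mean shortest directed path length over ordered
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

EULER_GAMMA = 0.5772156649015329

__all__ = [
    "GraphSummary",
    "directed_clustering",
    "mean_shortest_path",
    "clustering_and_path",
    "swi_references",
    "swi",
    "summarize_graph",
    "EULER_GAMMA",
]


@dataclass(frozen=True)
class GraphSummary:
    n: int
    mean_degree: float
    density: float
    clustering: float  # global triplet ratio
    clustering_per_node: float
    path_length: float
    unreachable_fraction: float
    c_lattice: float
    c_random: float
    l_lattice: float
    l_random: float
    swi: float


def directed_clustering(adj: np.ndarray) -> tuple[float, float]:
    """Directed clustering: (global triplet ratio, mean per-node coefficient).

    For node i with total degree ``d_i = in + out`` and ``d_bi`` reciprocal
    neighbors, the number of closed directed triangles through i is
    ``t_i = ((A + A^T)^3)_ii / 2`` and the number of possible triplets is
    ``T_i = d_i (d_i - 1) - 2 d_bi``.  The global ratio is
    ``sum_i t_i / sum_i T_i``; the per-node mean averages ``t_i / T_i``
    over nodes with ``T_i > 0``.
    """
    a = np.asarray(adj, dtype=np.float64)
    np.fill_diagonal(a, 0.0)
    s = a + a.T
    t = np.diagonal(s @ s @ s) / 2.0
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = np.diagonal(a @ a)
    possible = d_tot * (d_tot - 1) - 2 * d_bi
    ok = possible > 0
    global_ratio = float(t[ok].sum() / possible[ok].sum()) if ok.any() else 0.0
    per_node = float(np.mean(t[ok] / possible[ok])) if ok.any() else 0.0
    return global_ratio, per_node


def mean_shortest_path(adj: np.ndarray) -> tuple[float, float]:
    """Mean shortest directed path over ordered pairs.

    Unreachable ordered pairs are excluded from the mean; the second
    return value is the fraction of ordered pairs that were unreachable
    (zero on strongly connected graphs).
    """
    a = csr_matrix(np.asarray(adj, dtype=bool))
    d = shortest_path(a, method="D", directed=True, unweighted=True)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    unreachable = 1.0 - finite.sum() / off.sum()
    if not finite.any():
        return float("inf"), 1.0
    return float(d[finite].mean()), float(unreachable)


def clustering_and_path(adj: np.ndarray) -> tuple[float, float]:
    """(C, L) of a directed graph: global triplet ratio and mean shortest
    directed path length."""
    c, _ = directed_clustering(adj)
    length, _ = mean_shortest_path(adj)
    return c, length


def swi_references(n: int, k: float, p: float) -> tuple[float, float, float, float]:
    """Closed-form lattice/random references (C_l, C_r, L_l, L_r)."""
    if k <= 2 or n <= k:
        raise ValueError("references require mean degree k > 2 and n > k")
    c_l = 3.0 * (k - 2.0) / (4.0 * (k - 1.0))
    c_r = p
    l_l = n / (2.0 * k) + 0.5
    l_r = (np.log(n) - EULER_GAMMA) / np.log(k) + 0.5
    return c_l, c_r, l_l, l_r


def swi(n: int, k: float, p: float, clustering: float, path_length: float) -> float:
    """Small-world index from measured (C, L) and closed-form references."""
    c_l, c_r, l_l, l_r = swi_references(n, k, p)
    if l_r == l_l or c_l == c_r:
        raise ValueError("degenerate references: SWI undefined")
    return float(
        (path_length - l_l) / (l_r - l_l) * (clustering - c_r) / (c_l - c_r)
    )


def summarize_graph(adj: np.ndarray) -> GraphSummary:
    """Full small-world summary of a directed adjacency matrix.

    The mean degree k for the closed forms is the empirical mean
    out-degree, and p the empirical density.
    """
    a = np.asarray(adj, dtype=bool).copy()
    np.fill_diagonal(a, False)
    n = a.shape[0]
    k = float(a.sum() / n)
    p = float(a.sum() / (n * (n - 1)))
    c_global, c_node = directed_clustering(a)
    length, unreach = mean_shortest_path(a)
    c_l, c_r, l_l, l_r = swi_references(n, k, p)
    value = (length - l_l) / (l_r - l_l) * (c_global - c_r) / (c_l - c_r)
    return GraphSummary(
        n=n,
        mean_degree=k,
        density=p,
        clustering=c_global,
        clustering_per_node=c_node,
        path_length=length,
        unreachable_fraction=unreach,
        c_lattice=c_l,
        c_random=c_r,
        l_lattice=l_l,
        l_random=l_r,
        swi=float(value),
    )
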