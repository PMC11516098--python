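"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: the MCS oracle is an
exhaustive connected common-edge-subgraph enumeration over networkx graphs,
and the BEDROC oracle is the closed-form direct-sum expression.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def mol_to_nx(mol) -> nx.Graph:
    g = nx.Graph()
    rd = mol.rdkit_mol
    for a in rd.GetAtoms():
        g.add_node(a.GetIdx(), in_ring=a.IsInRing())
    for b in rd.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), in_ring=b.IsInRing())
    return g


def _connected_edge_subsets(g: nx.Graph, k: int):
    for combo in itertools.combinations(g.edges, k):
        sg = nx.Graph()
        for u, v in combo:
            sg.add_node(u, **g.nodes[u])
            sg.add_node(v, **g.nodes[v])
            sg.add_edge(u, v, **g.edges[u, v])
        if nx.is_connected(sg):
            yield sg


def brute_force_mces_bonds(a, b) -> int:
    """Largest connected common edge subgraph, atoms matched element-agnostic
    (ring membership only), bonds matched on ring membership."""
    ga, gb = mol_to_nx(a), mol_to_nx(b)
    small, big = (ga, gb) if ga.number_of_edges() <= gb.number_of_edges() else (gb, ga)

    def match(x, y):
        return x["in_ring"] == y["in_ring"]

    for k in range(small.number_of_edges(), 0, -1):
        for sg in _connected_edge_subsets(small, k):
            gm = nx.algorithms.isomorphism.GraphMatcher(
                big, sg, node_match=match, edge_match=match
            )
            if gm.subgraph_is_monomorphic():
                return k
    return 0


def bedroc_direct(active_ranks, n: int, N: int, alpha: float) -> float:
    """Closed-form BEDROC (direct sums, no shared code with the package)."""
    r = np.asarray(active_ranks, dtype=float)
    s = np.exp(-alpha * r / N).sum()
    ra = n / N
    rand = ra * (1 - np.exp(-alpha)) / (np.exp(alpha / N) - 1)
    rie = s / rand

    def rie_of(ranks):
        return np.exp(-alpha * np.asarray(ranks, dtype=float) / N).sum() / rand

    rie_max = rie_of(np.arange(1, n + 1))
    rie_min = rie_of(np.arange(N - n + 1, N + 1))
    return (rie - rie_min) / (rie_max - rie_min)
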