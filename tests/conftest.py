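import numpy as np
import pytest

from mipscan.msa_phylo import distance_matrix, neighbor_joining, progressive_msa
from mipscan.synthetic_data import make_family

FAMILY_SEED = 1


@pytest.fixture(scope="session")
def family():
    """The synthetic 66-member family plus 23 pseudogene lesions (seed 1)."""
    return make_family(seed=FAMILY_SEED, with_cds=True)


@pytest.fixture(scope="session")
def family_truth(family):
    return family.truth.set_index("gene")


@pytest.fixture(scope="session")
def family_msa(family):
    return progressive_msa(family.proteins)


@pytest.fixture(scope="session")
def family_tree(family_msa):
    return neighbor_joining(distance_matrix(family_msa))


def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-distance matrix (oracle for NJ recovery)."""
    # start from a star over 3 taxa and repeatedly attach new leaves
    # represented implicitly through the distance matrix update
    import itertools

    # build explicit adjacency with branch lengths
    nodes = {i: {} for i in range(n_taxa)}
    next_internal = n_taxa

    def add_edge(a, b, w):
        nodes.setdefault(a, {})[b] = w
        nodes.setdefault(b, {})[a] = w

    def split_edge(a, b):
        nonlocal next_internal
        w = nodes[a].pop(b)
        nodes[b].pop(a)
        mid = next_internal
        next_internal += 1
        t = rng.uniform(0.2, 0.8)
        add_edge(a, mid, w * t)
        add_edge(mid, b, w * (1 - t))
        return mid

    add_edge(0, "r", rng.uniform(0.5, 3.0))
    add_edge(1, "r", rng.uniform(0.5, 3.0))
    add_edge(2, "r", rng.uniform(0.5, 3.0))
    for leaf in range(3, n_taxa):
        edges = [(a, b) for a in nodes for b in nodes[a] if str(a) < str(b)]
        a, b = edges[rng.integers(len(edges))]
        mid = split_edge(a, b)
        add_edge(leaf, mid, rng.uniform(0.5, 3.0))

    # all-pairs path lengths between leaves by BFS/Dijkstra (tree: unique path)
    import collections

    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, w in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    # summation order along a path differs by direction: symmetrize the
    # last float ulps away
    return (d + d.T) / 2.0
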