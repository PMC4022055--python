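"""Genotype networks: swap-adjacency graphs over V(n) and their components.

Two genotypes of equal size n are adjacent when they share all but one
reaction (swap distance 1).  Edges are discovered by generating each node's
n x (N - n) swap neighbors and hashing them into the node set — never by
all-pairs comparison — and components come from standard graph traversal.

For climbing the size ladder without rebuilding networks, the module also
implements the parent-clique propagation rules: the N - n parents of a
genotype form a clique, parent images of connected sets stay connected, and
only childless (minimal) genotypes can seed new components at size n + 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .fba import get_engine
from .universe import Environment, Genotype, ReactionUniverse


def _sorted_components(
    blocks: Iterable[frozenset[Genotype]],
) -> tuple[frozenset[Genotype], ...]:
    """Deterministic component order: size descending, then smallest member."""
    return tuple(
        sorted(blocks, key=lambda b: (-len(b), min(g.to_hex() for g in b)))
    )


@dataclass
class GenotypeNetwork:
    n: int
    nodes: frozenset[Genotype]
    edges: frozenset[tuple[Genotype, Genotype]]
    components: tuple[frozenset[Genotype], ...]

    @property
    def largest_fraction(self) -> float:
        if not self.nodes:
            raise ValueError("empty genotype network has no largest component")
        return len(self.components[0]) / len(self.nodes)


def swap_neighbors_in(node: Genotype, node_masks: set[int]) -> list[Genotype]:
    """Swap neighbors of ``node`` that are themselves members of the node set."""
    found = []
    present = node.present_indices()
    absent = node.absent_indices()
    for i in present:
        base = node.mask ^ (1 << i)
        for j in absent:
            cand = base | (1 << j)
            if cand in node_masks:
                found.append(Genotype(cand, node.N))
    return found


def build_network(
    viable_set: Iterable[Genotype], universe: ReactionUniverse
) -> GenotypeNetwork:
    """Swap-adjacency network over a set of equal-size genotypes."""
    nodes = frozenset(viable_set)
    if not nodes:
        raise ValueError("cannot build a network over an empty genotype set")
    sizes = {g.n for g in nodes}
    if len(sizes) > 1:
        raise ValueError(f"mixed genotype sizes in node set: {sorted(sizes)}")
    (n,) = sizes
    node_masks = {g.mask for g in nodes}
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for g in nodes:
        for nb in swap_neighbors_in(g, node_masks):
            if nb.mask > g.mask:
                graph.add_edge(g, nb)
    edges = frozenset(
        (a, b) if a.mask < b.mask else (b, a) for a, b in graph.edges()
    )
    components = _sorted_components(
        frozenset(c) for c in nx.connected_components(graph)
    )
    return GenotypeNetwork(n, nodes, edges, components)


def parent_set(genotype: Genotype, universe: ReactionUniverse) -> set[Genotype]:
    """The N - n genotypes of size n + 1 obtained by single reaction addition.

    They are pairwise adjacent (each pair differs only in which reaction was
    added), hence form a clique; if the input is viable they are all viable
    because reaction addition never abolishes viability.
    """
    if genotype.N != universe.N:
        raise ValueError("genotype does not belong to this universe")
    return {genotype.with_reaction(j) for j in genotype.absent_indices()}


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def propagate_connectivity(
    components_at_n: Sequence[Iterable[Genotype]],
    minimal_at_n_plus_1: Iterable[Genotype],
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
) -> tuple[frozenset[Genotype], ...]:
    """Components of V(n+1) from the components of V(n) plus the new minimal genotypes.

    The parent image of each size-n component is connected (parent-clique
    theorem) and is merged into one block; blocks sharing a genotype or
    joined by a swap edge merge; minimal genotypes attach to any block they
    are adjacent to, and unattached ones form new blocks.  The result equals
    the partition :func:`build_network` computes directly on the same nodes.

    Every non-minimal viable genotype at size n+1 has a viable child in
    V(n), so the node set ``parents union minimals`` is exactly V(n+1)
    when the inputs are complete.
    """
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    minimal = set(minimal_at_n_plus_1)
    for g in minimal:
        if not engine.is_viable_all(g, env_list):
            raise ValueError(f"supplied minimal genotype {g.to_hex()} is not viable")
        for i in g.present_indices():
            if engine.is_viable_all(g.without_reaction(i), env_list):
                raise ValueError(
                    f"supplied minimal genotype {g.to_hex()} has a viable child "
                    "(the minimal set is inconsistent)"
                )

    uf = _UnionFind()
    nodes: dict[int, Genotype] = {}
    for block in components_at_n:
        anchor: int | None = None
        for child in block:
            for parent in parent_set(child, universe):
                uf.add(parent.mask)
                nodes[parent.mask] = parent
                if anchor is None:
                    anchor = parent.mask
                else:
                    uf.union(anchor, parent.mask)
    for g in minimal:
        uf.add(g.mask)
        nodes[g.mask] = g

    node_masks = set(nodes)
    for mask, g in nodes.items():
        for nb in swap_neighbors_in(g, node_masks):
            uf.union(mask, nb.mask)

    blocks: dict[int, set[Genotype]] = {}
    for mask, g in nodes.items():
        blocks.setdefault(uf.find(mask), set()).add(g)
    return _sorted_components(frozenset(b) for b in blocks.values())


def fragmentation_report(
    census: pd.DataFrame | None,
    networks: Mapping[int, GenotypeNetwork],
) -> pd.DataFrame:
    """Per-size component counts and largest-component fractions.

    Sizes where the largest component holds less than the whole viable set
    are flagged as fragmented.
    """
    rows = []
    for n in sorted(networks):
        net = networks[n]
        rows.append(
            {
                "n": n,
                "viable_count": len(net.nodes),
                "component_count": len(net.components),
                "largest_component_fraction": net.largest_fraction,
                "fragmented": len(net.components) > 1,
            }
        )
    report = pd.DataFrame(rows)
    if census is not None and len(census):
        extra = census[
            [c for c in ("n", "omega_n", "minimal_count") if c in census.columns]
        ]
        report = report.merge(extra, on="n", how="left")
    return report


def export_edges_csv(network: GenotypeNetwork, path) -> None:
    pd.DataFrame(
        [(a.to_hex(), b.to_hex()) for a, b in sorted(network.edges)],
        columns=["genotype_a", "genotype_b"],
    ).to_csv(path, index=False)


def export_graphml(network: GenotypeNetwork, path) -> None:
    graph = nx.Graph()
    graph.add_nodes_from(g.to_hex() for g in network.nodes)
    graph.add_edges_from((a.to_hex(), b.to_hex()) for a, b in network.edges)
    nx.write_graphml(graph, path)


def export_components_csv(network: GenotypeNetwork, path) -> None:
    rows = [
        {"component": k, "genotype": g.to_hex()}
        for k, block in enumerate(network.components)
        for g in sorted(block)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
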