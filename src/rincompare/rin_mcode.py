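"""Calpha residue-interaction networks and MCODE density clustering.

A structure becomes an undirected graph with one node per residue (its
Calpha the representative point) and an edge between every residue pair whose
Calpha–Calpha distance is within a cutoff (7 Å by default, inclusive).
Node ids are 0-based; the author residue number travels as a label.

The clustering is a from-scratch implementation of the MCODE procedure
(vertex weighting by the core-clustering coefficient of the closed
neighborhood, greedy seeded expansion, optional haircut/fluff
post-processing).  A cluster's score is its edge density times its node
count, with the loop-less density 2E / (n(n−1)); a 6-residue clique
therefore scores 6.00, and a retained cluster needs a score of at least
5.00 under the defaults used for the lysozyme analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from rincompare.structure_io import ResidueKey, StructureModel

__all__ = [
    "ContactNetwork",
    "MCODEParams",
    "MCODECluster",
    "build_contact_network",
    "mcode_vertex_weight",
    "mcode_find_clusters",
    "export_gml",
    "compare_clusters",
    "clusters_tsv",
]


@dataclass
class ContactNetwork:
    """Residue contact graph with provenance.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are the
    0-based residue indices; node attributes carry ``residue_key``,
    ``resnum`` (author number) and ``resname``.
    """

    graph: nx.Graph
    cutoff: float
    structure_id: str = ""
    atom_rule: str = "ca_ca"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def residue_numbers(self, nodes: Iterable[int]) -> List[int]:
        return sorted(self.graph.nodes[v]["resnum"] for v in nodes)

    def node_for_resnum(self, resnum: int) -> Optional[int]:
        for v, data in self.graph.nodes(data=True):
            if data["resnum"] == resnum:
                return v
        return None


@dataclass
class MCODEParams:
    """MCODE tuning knobs; defaults match the Cytoscape app's defaults,
    plus the 5.00 retention score used in the lysozyme cluster analysis."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    min_cluster_score: float = 5.0
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class MCODECluster:
    """A ranked MCODE cluster: member node ids, score, rank, seed node."""

    members: Set[int]
    score: float
    rank: int
    seed: int

    def residue_numbers(self, network: ContactNetwork) -> List[int]:
        return network.residue_numbers(self.members)


def graph_density(g: nx.Graph) -> float:
    """Loop-less density 2E / (n(n−1)); 0 for graphs with < 2 nodes."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def cluster_score(g: nx.Graph, members: Iterable[int]) -> float:
    """MCODE cluster score: density × node count of the induced subgraph."""
    sub = g.subgraph(set(members))
    return graph_density(sub) * sub.number_of_nodes()


def build_contact_network(model: StructureModel, cutoff: float = 7.0) -> ContactNetwork:
    """Build the Calpha contact network at the given inclusive cutoff (Å).

    Residues without a Calpha are skipped.  Sequence neighbors are treated
    like any other pair.
    """
    residues = [r for r in model.residues() if r.ca is not None]
    if len(residues) < 2:
        raise ValueError("need at least two residues with Calpha atoms")
    coords = np.array([r.ca.coords for r in residues])
    g = nx.Graph()
    for i, r in enumerate(residues):
        g.add_node(i, residue_key=r.key, resnum=r.seq_number, resname=r.res_name)
    tree = cKDTree(coords)
    # KD-tree radius query; cutoff is inclusive and the query honors <=
    for i, j in sorted(tree.query_pairs(cutoff)):
        g.add_edge(i, j)
    return ContactNetwork(graph=g, cutoff=cutoff, structure_id=model.id)


def _highest_k_core(g: nx.Graph) -> Tuple[int, nx.Graph]:
    """(k, subgraph) of the highest non-empty k-core of *g*."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values())
    nodes = [v for v, c in core_numbers.items() if c >= k]
    return k, g.subgraph(nodes)


def mcode_vertex_weight(
    network: ContactNetwork | nx.Graph, v: int, params: MCODEParams | None = None
) -> float:
    """MCODE vertex weight: k × density of the highest k-core of the closed
    neighborhood N[v]; 0 when deg(v) is below the degree cutoff."""
    params = params or MCODEParams()
    g = network.graph if isinstance(network, ContactNetwork) else network
    if v not in g:
        raise KeyError(f"node {v} not in network")
    if g.degree(v) < params.degree_cutoff:
        return 0.0
    closed = g.subgraph(set(g[v]) | {v})
    k, core = _highest_k_core(closed)
    return k * graph_density(core)


def _expand_cluster(
    g: nx.Graph,
    seed: int,
    weights: Dict[int, float],
    assigned: Set[int],
    params: MCODEParams,
) -> Set[int]:
    """Greedy breadth-first expansion from *seed*: include unassigned
    neighbors whose weight is within (1 − node_score_cutoff) of the seed's."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        next_frontier = []
        for v in frontier:
            for w in g[v]:
                if w in members or w in assigned:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    next_frontier.append(w)
        frontier = next_frontier
        depth += 1
    return members


def _haircut(g: nx.Graph, members: Set[int]) -> Set[int]:
    """Iteratively remove members with fewer than 2 within-cluster neighbors."""
    members = set(members)
    while True:
        sub = g.subgraph(members)
        drop = {v for v in members if sub.degree(v) < 2}
        if not drop or len(members) - len(drop) == 0:
            return members - drop
        members -= drop


def _fluff(g: nx.Graph, members: Set[int], params: MCODEParams) -> Set[int]:
    """Add boundary neighbors whose closed-neighborhood density exceeds the
    fluff cutoff.  Fluffed nodes may overlap other clusters."""
    added = set()
    for v in set(members):
        for w in g[v]:
            if w in members or w in added:
                continue
            closed = g.subgraph(set(g[w]) | {w})
            if graph_density(closed) > params.fluff_density_cutoff:
                added.add(w)
    return members | added


def mcode_find_clusters(
    network: ContactNetwork | nx.Graph, params: MCODEParams | None = None
) -> List[MCODECluster]:
    """Run the MCODE procedure and return retained clusters ranked by score.

    Seeds are visited in order of (weight desc, node id asc); each vertex
    joins at most one cluster core.  Post-processing: clusters lacking a
    ``k_core_filter``-core are dropped, fluff (if enabled) grows the boundary,
    haircut (default) prunes singly-connected members.  Clusters smaller than
    two nodes or scoring below ``min_cluster_score`` are discarded; ranking
    ties break toward the smaller minimum member id.
    """
    params = params or MCODEParams()
    g = network.graph if isinstance(network, ContactNetwork) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")

    weights = {v: mcode_vertex_weight(g, v, params) for v in g}
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: Set[int] = set()
    raw: List[Tuple[int, Set[int]]] = []

    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _expand_cluster(g, seed, weights, assigned, params)
        assigned |= members
        raw.append((seed, members))

    clusters: List[MCODECluster] = []
    for seed, members in raw:
        sub = g.subgraph(members)
        if params.k_core_filter > 0:
            k_max, _ = _highest_k_core(sub)
            if k_max < params.k_core_filter:
                continue
        if params.fluff:
            members = _fluff(g, members, params)
        if params.haircut:
            members = _haircut(g, members)
        if len(members) < params.min_cluster_size:
            continue
        score = cluster_score(g, members)
        if score < params.min_cluster_score:
            continue
        clusters.append(MCODECluster(members=set(members), score=score, rank=0, seed=seed))

    clusters.sort(key=lambda c: (-c.score, min(c.members)))
    for i, c in enumerate(clusters, start=1):
        c.rank = i
    return clusters


def export_gml(network: ContactNetwork) -> str:
    """GML text: 0-based node ids, labels carrying author number and name,
    each undirected edge emitted once."""
    lines = ["graph [", "  directed 0"]
    for v in sorted(network.graph.nodes):
        data = network.graph.nodes[v]
        label = f"{data.get('resname', 'UNK')}{data.get('resnum', v)}"
        lines.append("  node [")
        lines.append(f"    id {v}")
        lines.append(f'    label "{label}"')
        lines.append(f"    resnum {data.get('resnum', v)}")
        lines.append("  ]")
    for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
        lines.append("  edge [")
        lines.append(f"    source {a}")
        lines.append(f"    target {b}")
        lines.append("  ]")
    lines.append("]")
    return "\n".join(lines) + "\n"


@dataclass
class ClusterMatch:
    """A variant cluster matched to its best-overlapping reference cluster."""

    structure_id: str
    variant_rank: int
    reference_rank: Optional[int]
    jaccard: float
    gained: Set[int]  # author residue numbers present in variant, absent in ref match
    lost: Set[int]
    score_delta: Optional[float]


@dataclass
class ClusterComparison:
    """Cross-structure cluster differences against a reference structure."""

    reference_id: str
    matches: List[ClusterMatch]
    consistent_changes: Set[int]  # residues gained/lost in every variant


def compare_clusters(
    per_structure: Dict[str, List[MCODECluster]],
    networks: Dict[str, ContactNetwork],
    reference_id: Optional[str] = None,
) -> ClusterComparison:
    """Compare each variant's clusters to the reference structure's clusters.

    Clusters are matched by maximal Jaccard overlap of author residue
    numbers.  Residues that changed cluster membership (gained or lost
    relative to the matched reference cluster) in *every* variant are
    flagged as consistent changes.
    """
    if len(per_structure) < 2:
        raise ValueError("need a reference and at least one variant")
    if reference_id is None:
        reference_id = next(iter(per_structure))
    ref_clusters = per_structure[reference_id]
    ref_sets = [
        (c, set(c.residue_numbers(networks[reference_id]))) for c in ref_clusters
    ]

    matches: List[ClusterMatch] = []
    per_variant_changes: List[Set[int]] = []
    for sid, clusters in per_structure.items():
        if sid == reference_id:
            continue
        changes: Set[int] = set()
        for c in clusters:
            members = set(c.residue_numbers(networks[sid]))
            best, best_j, best_set = None, 0.0, set()
            for rc, rset in ref_sets:
                j = len(members & rset) / len(members | rset) if members | rset else 0.0
                if j > best_j:
                    best, best_j, best_set = rc, j, rset
            gained = members - best_set
            lost = best_set - members
            matches.append(
                ClusterMatch(
                    structure_id=sid,
                    variant_rank=c.rank,
                    reference_rank=best.rank if best else None,
                    jaccard=best_j,
                    gained=gained,
                    lost=lost,
                    score_delta=(c.score - best.score) if best else None,
                )
            )
            changes |= gained | lost
        per_variant_changes.append(changes)

    consistent = set.intersection(*per_variant_changes) if per_variant_changes else set()
    return ClusterComparison(
        reference_id=reference_id, matches=matches, consistent_changes=consistent
    )


def clusters_tsv(clusters: Sequence[MCODECluster], network: ContactNetwork) -> str:
    """TSV: rank, score, members (author residue numbers), seed."""
    lines = ["rank\tscore\tmembers\tseed"]
    for c in clusters:
        members = ",".join(map(str, c.residue_numbers(network)))
        seed_num = network.graph.nodes[c.seed]["resnum"]
        lines.append(f"{c.rank}\t{c.score:.2f}\t{members}\t{seed_num}")
    return "\n".join(lines) + "\n"
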