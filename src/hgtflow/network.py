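"""Cross-genome cluster comparison and gene flow network assembly.

Final clusters from different genomes are compared under the same JS
significance framework used for gene clustering; a pair whose p-value is
at or above ``alpha_net`` is similar. Similar pairs are typed by the
labels of their endpoints:

* native + alien  -> a directed edge from the native (donor) cluster to
  the alien (recipient) cluster — the alien cluster is inferred to carry
  genes drawn from the donor genome's backbone;
* alien + alien   -> an undirected edge (shared mobilome; direction
  indeterminate);
* native + native -> excluded from the network (high backbone
  similarity, e.g. conspecific strains) but counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from .jscb import GeneCluster, js_test_arrays


@dataclass
class FlowEdge:
    """A typed connection between clusters of two different genomes.

    For ``native_to_alien`` edges ``cluster_a`` is the donor (native)
    side and ``cluster_b`` the recipient (alien) side; for the unordered
    types the endpoints are stored in sorted id order.
    """

    cluster_a: str
    cluster_b: str
    js_bits: float
    p_value: float
    edge_type: str  # 'native_to_alien' | 'alien_alien' | 'native_native_excluded'

    @property
    def directed(self) -> bool:
        return self.edge_type == "native_to_alien"


@dataclass
class FlowNetwork:
    nodes: dict[str, GeneCluster]
    edges: list[FlowEdge]
    excluded_nn_count: int = 0

    def to_networkx(self, taxonomy: dict[str, str] | None = None) -> nx.Graph:
        """Attributed undirected graph; direction is carried as edge data."""
        g = nx.Graph()
        for cid, cluster in self.nodes.items():
            g.add_node(
                cid,
                genome=cluster.genome_id,
                label=cluster.label,
                size=cluster.size,
                phylum=(taxonomy or {}).get(cluster.genome_id, ""),
            )
        for e in self.edges:
            g.add_edge(
                e.cluster_a,
                e.cluster_b,
                edge_type=e.edge_type,
                directed=int(e.directed),
                source=e.cluster_a,
                target=e.cluster_b,
                js_bits=e.js_bits,
                p_value=e.p_value,
            )
        return g


@dataclass(frozen=True)
class SimilarPair:
    cluster_a: str  # lexicographically smaller id
    cluster_b: str
    js_bits: float
    p_value: float


def compare_clusters(
    clusters: list[GeneCluster],
    alpha_net: float = 1e-8,
    species_group: dict[str, str] | None = None,
    exclude_conspecific: bool = True,
) -> list[SimilarPair]:
    """All inter-genome cluster pairs whose JS test p-value is >= alpha_net.

    Same-genome pairs are never compared. When a genome -> species-group
    map is supplied and ``exclude_conspecific`` is set, pairs of genomes
    from the same species group are skipped (backbone similarity between
    conspecific strains reflects homologous recombination, not HGT).
    """
    usable = [c for c in clusters if c.pooled.total > 0]
    pairs = []
    for ca, cb in combinations(sorted(usable, key=lambda c: c.cluster_id), 2):
        if ca.genome_id == cb.genome_id:
            continue
        if (
            exclude_conspecific
            and species_group is not None
            and species_group.get(ca.genome_id) is not None
            and species_group.get(ca.genome_id) == species_group.get(cb.genome_id)
        ):
            continue
        pairs.append((ca, cb))
    if not pairs:
        return []
    m1 = np.stack([p[0].pooled.vector for p in pairs])
    m2 = np.stack([p[1].pooled.vector for p in pairs])
    js, _lam, _dof, pvals = js_test_arrays(m1, m2)
    out = [
        SimilarPair(ca.cluster_id, cb.cluster_id, float(j), float(p))
        for (ca, cb), j, p in zip(pairs, js, pvals)
        if p >= alpha_net
    ]
    return out


def type_edges(pairs: list[SimilarPair], clusters: list[GeneCluster]) -> FlowNetwork:
    """Type similar pairs by endpoint labels and assemble the network.

    native+native pairs are dropped from the edge set but counted, so
    ``len(pairs) == len(edges) + excluded_nn_count`` always holds.
    """
    by_id = {c.cluster_id: c for c in clusters}
    edges: list[FlowEdge] = []
    excluded = 0
    for pair in pairs:
        ca, cb = by_id[pair.cluster_a], by_id[pair.cluster_b]
        for c in (ca, cb):
            if c.label not in ("native", "alien"):
                raise ValueError(f"cluster {c.cluster_id} is unlabelled")
        la, lb = ca.label, cb.label
        if la == "native" and lb == "native":
            excluded += 1
            continue
        if la == "alien" and lb == "alien":
            a, b = sorted((ca.cluster_id, cb.cluster_id))
            edges.append(FlowEdge(a, b, pair.js_bits, pair.p_value, "alien_alien"))
        else:
            donor = ca if la == "native" else cb
            recipient = cb if la == "native" else ca
            edges.append(
                FlowEdge(
                    donor.cluster_id,
                    recipient.cluster_id,
                    pair.js_bits,
                    pair.p_value,
                    "native_to_alien",
                )
            )
    incident = {e.cluster_a for e in edges} | {e.cluster_b for e in edges}
    nodes = {cid: by_id[cid] for cid in sorted(incident)}
    return FlowNetwork(nodes=nodes, edges=edges, excluded_nn_count=excluded)


def build_network(
    clusters: list[GeneCluster],
    alpha_net: float = 1e-8,
    species_group: dict[str, str] | None = None,
    exclude_conspecific: bool = True,
) -> FlowNetwork:
    """Compare labelled clusters across genomes and type the resulting edges."""
    pairs = compare_clusters(clusters, alpha_net, species_group, exclude_conspecific)
    return type_edges(pairs, clusters)


EDGE_TSV_HEADER = [
    "source", "target", "edge_type", "directed",
    "js_bits", "p_value", "source_phylum", "target_phylum",
]


def write_network(
    network: FlowNetwork,
    edge_tsv: str | Path | None = None,
    graphml: str | Path | None = None,
    taxonomy: dict[str, str] | None = None,
) -> None:
    """Write the edge-list TSV and/or GraphML representation."""
    taxonomy = taxonomy or {}
    if edge_tsv is not None:
        with open(edge_tsv, "w") as fh:
            fh.write("\t".join(EDGE_TSV_HEADER) + "\n")
            for e in network.edges:
                pa = taxonomy.get(network.nodes[e.cluster_a].genome_id, "")
                pb = taxonomy.get(network.nodes[e.cluster_b].genome_id, "")
                fh.write(
                    f"{e.cluster_a}\t{e.cluster_b}\t{e.edge_type}\t{int(e.directed)}"
                    f"\t{e.js_bits:.6g}\t{e.p_value:.6g}\t{pa}\t{pb}\n"
                )
    if graphml is not None:
        nx.write_graphml(network.to_networkx(taxonomy), str(graphml))
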