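"""End-to-end orchestration over a directory of per-genome inputs.

The data directory layout is the one ``hgtflow simulate`` writes:
``<genome>.fna`` + ``<genome>.coords.tsv`` per genome, ``markers.tsv``,
``taxonomy.tsv`` and optionally ``truth.json``. Real data in the same
layout runs identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import annotation, genome_io, jscb, network
from .config import RunConfig

logger = logging.getLogger(__name__)


def discover_genomes(data_dir: str | Path) -> list[str]:
    data_dir = Path(data_dir)
    return sorted(p.stem for p in data_dir.glob("*.fna"))


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species_group", "phylum"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxonomy table must carry columns {sorted(required)}")
    return df


def cluster_directory(
    data_dir: str | Path, config: RunConfig
) -> dict[str, list[jscb.GeneCluster]]:
    """JS-CB clustering of every genome in the directory."""
    data_dir = Path(data_dir)
    clusters: dict[str, list[jscb.GeneCluster]] = {}
    for genome_id in discover_genomes(data_dir):
        genes = genome_io.read_genes(
            data_dir / f"{genome_id}.fna", data_dir / f"{genome_id}.coords.tsv", genome_id
        )
        clusters[genome_id] = jscb.cluster_genome(
            genes,
            alphabet_id=config.alphabet_id,
            alpha_contig=config.alpha_contig,
            alpha_global=config.alpha_global,
        )
        logger.info("%s: %d genes -> %d clusters", genome_id, len(genes), len(clusters[genome_id]))
    return clusters


def annotate_clusters(
    clusters: dict[str, list[jscb.GeneCluster]],
    marker_gene_ids: set[str],
    config: RunConfig,
    phyletic: dict[str, annotation.PhyleticCall] | None = None,
    genomes_with_relatives: set[str] | None = None,
) -> None:
    """Marker-enrichment then phyletic annotation, in place, per genome."""
    for genome_id, cls in clusters.items():
        native = next(c for c in cls if c.compositional_class == "typical")
        genome_genes = [g for c in cls for g in c.member_gene_ids]
        genome_markers = len(set(genome_genes) & marker_gene_ids)
        results = {}
        for c in cls:
            if c.compositional_class == "typical":
                continue
            results[c.cluster_id] = annotation.enrichment_test(
                c,
                native,
                marker_gene_ids,
                alpha=config.enrich_alpha,
                fold_cutoff=config.fold_cutoff,
                genome_marker_count=genome_markers,
                genome_size=len(genome_genes),
            )
        has_rel = genomes_with_relatives is None or genome_id in genomes_with_relatives
        annotation.finalize_labels(cls, results, phyletic, has_relatives=has_rel)


def run_pipeline(
    data_dir: str | Path, config: RunConfig
) -> tuple[dict[str, list[jscb.GeneCluster]], network.FlowNetwork, dict[str, str]]:
    """cluster -> annotate -> network over one data directory.

    Returns (clusters per genome, flow network, genome -> phylum map).
    """
    data_dir = Path(data_dir)
    clusters = cluster_directory(data_dir, config)

    marker_path = data_dir / "markers.tsv"
    marker_gene_ids: set[str] = set()
    if marker_path.exists():
        marker_gene_ids = annotation.marker_genes(
            annotation.load_marker_hits(marker_path, e_max=config.e_max)
        )
    annotate_clusters(clusters, marker_gene_ids, config)

    taxonomy_path = data_dir / "taxonomy.tsv"
    species_group: dict[str, str] | None = None
    phylum: dict[str, str] = {}
    if taxonomy_path.exists():
        tax = load_taxonomy(taxonomy_path)
        species_group = dict(zip(tax["genome_id"], tax["species_group"]))
        phylum = dict(zip(tax["genome_id"], tax["phylum"]))

    all_clusters = [c for cls in clusters.values() for c in cls]
    net = network.build_network(
        all_clusters,
        alpha_net=config.alpha_net,
        species_group=species_group,
        exclude_conspecific=config.exclude_conspecific,
    )
    logger.info(
        "network: %d nodes, %d edges, %d native-native pairs excluded",
        len(net.nodes),
        len(net.edges),
        net.excluded_nn_count,
    )
    return clusters, net, phylum


def write_cluster_table(
    clusters: dict[str, list[jscb.GeneCluster]], path: str | Path, config: RunConfig
) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# hgtflow clusters; config={config.digest} "
            f"alpha_contig={config.alpha_contig} alpha_global={config.alpha_global}\n"
        )
        fh.write("cluster_id\tgenome_id\tgene_id\tcompositional_class\tlabel\tevidence_tier\n")
        for genome_id in sorted(clusters):
            for c in clusters[genome_id]:
                tier = "" if c.evidence_tier is None else str(c.evidence_tier)
                for g in c.member_gene_ids:
                    fh.write(
                        f"{c.cluster_id}\t{c.genome_id}\t{g}\t{c.compositional_class}"
                        f"\t{c.label}\t{tier}\n"
                    )


def write_usage_table(
    clusters: dict[str, list[jscb.GeneCluster]], path: str | Path
) -> None:
    """Pooled codon counts per cluster (cluster_id + one column per codon)."""
    from .alphabets import ALPHABETS

    first = next(c for cls in clusters.values() for c in cls)
    codons = ALPHABETS[first.pooled.alphabet_id]
    with open(path, "w") as fh:
        fh.write("cluster_id\t" + "\t".join(codons) + "\n")
        for genome_id in sorted(clusters):
            for c in clusters[genome_id]:
                fh.write(c.cluster_id + "\t" + "\t".join(map(str, c.pooled.vector)) + "\n")


def evaluate_against_truth(
    net: network.FlowNetwork,
    truth_expected_edges: list[dict],
) -> dict[str, float]:
    """Genome-level recovery of the expected edge set, with direction accuracy.

    A recovered cluster-level edge maps to the genome pair of its two
    endpoints with its type; direction of a native_to_alien edge is
    correct when the donor-side genome matches the truth.
    """
    recovered: set[tuple[str, str, str]] = set()
    directed_recovered: dict[tuple[str, str], str] = {}
    for e in net.edges:
        ga = net.nodes[e.cluster_a].genome_id
        gb = net.nodes[e.cluster_b].genome_id
        if e.edge_type == "native_to_alien":
            recovered.add(("native_to_alien", *sorted((ga, gb))))
            directed_recovered[tuple(sorted((ga, gb)))] = ga  # donor side
        else:
            recovered.add(("alien_alien", *sorted((ga, gb))))

    n_expected = len(truth_expected_edges)
    n_found = 0
    n_dir_total = 0
    n_dir_correct = 0
    for exp in truth_expected_edges:
        if exp["edge_type"] == "native_to_alien":
            pair = tuple(sorted((exp["donor_genome"], exp["recipient_genome"])))
            if ("native_to_alien", *pair) in recovered:
                n_found += 1
                n_dir_total += 1
                if directed_recovered.get(pair) == exp["donor_genome"]:
                    n_dir_correct += 1
        else:
            pair = tuple(sorted((exp["genome_a"], exp["genome_b"])))
            if ("alien_alien", *pair) in recovered:
                n_found += 1
    return {
        "expected_edges": n_expected,
        "recovered_edges": n_found,
        "edge_recovery": n_found / n_expected if n_expected else float("nan"),
        "direction_checked": n_dir_total,
        "direction_correct": n_dir_correct,
        "direction_accuracy": n_dir_correct / n_dir_total if n_dir_total else float("nan"),
    }
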