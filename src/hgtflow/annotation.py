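"""Native/alien annotation of compositionally atypical clusters.

Two independent lines of corroborating evidence are evaluated:

1. **Marker-gene enrichment.** Genes hitting a genomic-island marker
   family (transposase, integrase, recombinase, prophage, plasmid) at
   E-value <= 0.01 are marker genes. An atypical cluster is enriched when
   the upper-tail hypergeometric p-value against the native cluster is
   below 0.05 *and* the fold enrichment versus the native cluster is at
   least 1.25.

2. **Phyletic pattern.** A gene sparsely present among close relatives
   (<= 30% of the genomes of its species group) is phyletically
   aberrant; a well-distributed gene (> 80%) is escalated to the genus
   and then the family rank, which catches transfers into the ancestor
   of a species group. A non-enriched atypical cluster in which a strict
   majority of determinable genes are aberrant is annotated alien.

Atypical clusters supported by neither line of evidence default to
native; the compositionally typical (largest) cluster is always native.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .jscb import GeneCluster

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family")
PIDENT_CUTOFFS = {"species": 60.0, "genus": 50.0, "family": 25.0}
QCOV_MIN = 0.70
ABERRANT_MAX = 0.30  # present in at most this fraction -> aberrant
WELL_DISTRIBUTED_MIN = 0.80  # present in more than this fraction -> escalate

GI_MARKER_KEYWORDS = ("transposase", "integrase", "recombinase", "phage", "plasmid")


@dataclass(frozen=True)
class MarkerHit:
    gene_id: str
    marker_family: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass
class EnrichmentResult:
    cluster_id: str
    markers_in_cluster: int
    fold_vs_native: float
    fold_vs_genome: float | None
    p_hypergeom: float
    enriched: bool


@dataclass
class PhyleticCall:
    gene_id: str
    rank_evaluated: str  # 'species' | 'genus' | 'family' | 'none'
    presence_fractions: dict[str, float]
    status: str  # 'aberrant' | 'not_aberrant' | 'undetermined'


def load_marker_hits(path: str | Path, e_max: float = 0.01) -> set[MarkerHit]:
    """Load marker hits from HMMER3 domtblout or a gene/family/e-value TSV.

    Rows with E-value above ``e_max`` are dropped (boundary inclusive: a
    hit at exactly ``e_max`` is retained). Unparseable rows are logged
    and skipped.
    """
    hits: set[MarkerHit] = set()
    n_bad = n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            parts = line.split()
            try:
                if len(parts) >= 22:  # HMMER3 domtblout: target, query at 0/3, E at 6
                    gene_id, family, e_value = parts[3], parts[0], float(parts[6])
                else:
                    cols = line.split("\t") if "\t" in line else parts
                    if cols and cols[0] == "gene_id":
                        n_rows -= 1
                        continue
                    gene_id, family, e_value = cols[0], cols[1], float(cols[2])
            except (IndexError, ValueError):
                n_bad += 1
                logger.warning("skipping unparseable marker row: %r", line)
                continue
            if e_value <= e_max:
                hits.add(MarkerHit(gene_id, family, e_value))
    if n_rows and n_bad == n_rows:
        logger.warning("%s: every row was unparseable", path)
    return hits


def marker_genes(hits: set[MarkerHit]) -> set[str]:
    """A gene is a marker gene iff it has at least one retained hit."""
    return {h.gene_id for h in hits}


def fold_enrichment(markers_c: int, size_c: int, markers_ref: int, size_ref: int) -> float:
    """Ratio of marker rates, cluster vs reference."""
    if size_c <= 0 or size_ref <= 0:
        raise ValueError("cluster and reference sizes must be positive")
    if markers_ref == 0:
        return math.inf if markers_c > 0 else 1.0
    return (markers_c / size_c) / (markers_ref / size_ref)


def hypergeom_upper_tail(population: int, successes: int, draws: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeometric(population, successes, draws)."""
    return float(hypergeom.sf(observed - 1, population, successes, draws))


def enrichment_test(
    cluster: GeneCluster,
    native_cluster: GeneCluster,
    marker_gene_ids: set[str],
    alpha: float = 0.05,
    fold_cutoff: float = 1.25,
    genome_marker_count: int | None = None,
    genome_size: int | None = None,
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of markers in a cluster vs native.

    The sampling population is the union of the cluster's and the native
    cluster's genes; successes are the marker genes therein; the draw is
    the cluster. Enrichment requires both p < alpha and fold_vs_native >=
    fold_cutoff.
    """
    if native_cluster.size == 0:
        raise ValueError("native cluster is empty")
    if cluster.genome_id != native_cluster.genome_id:
        raise ValueError("cluster and native cluster must come from the same genome")
    cluster_genes = set(cluster.member_gene_ids)
    population = cluster_genes | set(native_cluster.member_gene_ids)
    successes = len(population & marker_gene_ids)
    observed = len(cluster_genes & marker_gene_ids)
    # P(X >= observed) drawing |cluster| genes from the population
    p = hypergeom_upper_tail(len(population), successes, len(cluster_genes), observed)
    fold_native = fold_enrichment(
        observed,
        cluster.size,
        len(set(native_cluster.member_gene_ids) & marker_gene_ids),
        native_cluster.size,
    )
    fold_genome = None
    if genome_marker_count is not None and genome_size is not None:
        fold_genome = fold_enrichment(observed, cluster.size, genome_marker_count, genome_size)
    return EnrichmentResult(
        cluster_id=cluster.cluster_id,
        markers_in_cluster=observed,
        fold_vs_native=fold_native,
        fold_vs_genome=fold_genome,
        p_hypergeom=p,
        enriched=(p < alpha and fold_native >= fold_cutoff),
    )


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "qstart", "qend", "qlen", "evalue", "bitscore",
]


def read_blast6(path: str | Path) -> pd.DataFrame:
    """BLAST tabular (outfmt 6 extended with qlen) as a DataFrame."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    df["qcov"] = (df["qend"] - df["qstart"] + 1) / df["qlen"]
    return df


def presence_from_blast(
    blast: pd.DataFrame,
    relatives: set[str],
    rank: str,
    subject_genome: dict[str, str] | None = None,
    qcov_min: float = QCOV_MIN,
    pident_cutoffs: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-gene presence fraction among the relatives of one taxonomic rank.

    A gene is present in a relative genome iff it has >= 1 hit there with
    query coverage >= ``qcov_min`` and percent identity >= the rank's
    cutoff (60/50/25 at species/genus/family). Returns {} if the rank has
    no relatives, signalling a missing fraction.
    """
    cutoffs = pident_cutoffs or PIDENT_CUTOFFS
    if rank not in cutoffs:
        raise ValueError(f"unknown rank {rank!r}")
    if not relatives:
        return {}
    df = blast.copy()
    if "qcov" not in df.columns:
        df["qcov"] = (df["qend"] - df["qstart"] + 1) / df["qlen"]
    if subject_genome is not None:
        df["subject_genome"] = df["sseqid"].map(subject_genome)
    else:
        df["subject_genome"] = df["sseqid"]
    ok = df[(df["qcov"] >= qcov_min) & (df["pident"] >= cutoffs[rank])]
    ok = ok[ok["subject_genome"].isin(relatives)]
    present = ok.groupby("qseqid")["subject_genome"].nunique()
    fractions = (present / len(relatives)).to_dict()
    all_genes = blast["qseqid"].unique()
    return {g: float(fractions.get(g, 0.0)) for g in all_genes}


def app_gene_status(gene_id: str, fractions: dict[str, float | None]) -> PhyleticCall:
    """Species->genus->family cascade deciding phyletic aberrance of one gene.

    At each rank with relatives: fraction <= 0.30 -> aberrant (stop);
    fraction > 0.80 -> escalate; otherwise -> not_aberrant (stop). A gene
    well distributed at every available rank is not aberrant. With no
    relatives at any rank the status is undetermined.
    """
    available = {r: f for r, f in fractions.items() if f is not None}
    if not available:
        return PhyleticCall(gene_id, "none", {}, "undetermined")
    last_rank = "none"
    for rank in RANKS:
        frac = available.get(rank)
        if frac is None:
            continue  # no relatives at this rank; escalate
        last_rank = rank
        if frac <= ABERRANT_MAX:
            return PhyleticCall(gene_id, rank, dict(available), "aberrant")
        if frac > WELL_DISTRIBUTED_MIN:
            continue  # well distributed here; check the next rank up
        return PhyleticCall(gene_id, rank, dict(available), "not_aberrant")
    return PhyleticCall(gene_id, last_rank, dict(available), "not_aberrant")


def finalize_labels(
    clusters: list[GeneCluster],
    enrichment: dict[str, EnrichmentResult],
    phyletic: dict[str, PhyleticCall] | None = None,
    has_relatives: bool = True,
) -> list[GeneCluster]:
    """Assign native/alien labels and evidence tiers (in place).

    Typical cluster -> native. Atypical and enriched -> alien. Atypical,
    not enriched, strict majority of determinable genes aberrant ->
    alien. Otherwise native. Genomes with no sequenced relatives skip the
    phyletic route. Tier 1 = compositional atypicality only, 2 = one
    corroboration, 3 = all three lines of evidence.
    """
    phyletic = phyletic or {}

    def frac_aberrant(cluster: GeneCluster) -> tuple[int, int]:
        calls = [phyletic.get(g) for g in cluster.member_gene_ids]
        determinable = [c for c in calls if c is not None and c.status != "undetermined"]
        aberrant = [c for c in determinable if c.status == "aberrant"]
        return len(aberrant), len(determinable)

    for cluster in clusters:
        if cluster.compositional_class == "typical":
            cluster.label = "native"
            cluster.evidence_tier = None
            continue
        res = enrichment.get(cluster.cluster_id)
        if res is None:
            raise ValueError(f"missing enrichment result for {cluster.cluster_id}")
        n_aber, n_det = frac_aberrant(cluster) if has_relatives else (0, 0)
        majority_aberrant = n_det > 0 and n_aber > n_det / 2
        cluster.evidence["marker_enriched"] = res.enriched
        cluster.evidence["phyletic_aberrant"] = majority_aberrant
        if res.enriched:
            cluster.label = "alien"
            cluster.evidence_tier = 3 if majority_aberrant else 2
        elif majority_aberrant:
            cluster.label = "alien"
            cluster.evidence_tier = 2
        else:
            cluster.label = "native"
            cluster.evidence_tier = 1
    return clusters
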