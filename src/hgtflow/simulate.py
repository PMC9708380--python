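"""Synthetic genomes, communities and evidence tables with known truth.

Codon-usage signatures are modelled as draws from a symmetric Dirichlet
over the codon alphabet. The default concentration (2.5) gives codon
frequencies whose dispersion is comparable to real prokaryotic usage
tables; lower concentrations give more skewed usage and larger expected
inter-model divergence. Genes are i.i.d. multinomial codon draws from
their origin model; horizontally acquired material enters as contiguous
segments of genes drawn from donor models, mirroring the genomic-island
structure the clustering exploits. Marker hits and presence/absence
matrices are Bernoulli draws at origin-dependent rates, and multi-genome
communities carry an explicit donor->recipient transfer truth from which
the expected flow-network edges are derived.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabets import ALPHABETS, STOP_CODONS, reverse_complement
from .genome_io import GeneSeq
from .jscb import js_bits_arrays

DEFAULT_CONCENTRATION = 2.5
DEFAULT_MARKER_RATE_NATIVE = 0.05
DEFAULT_MARKER_RATE_ALIEN = 0.50
DEFAULT_P_PRESENT_NATIVE = 0.95
DEFAULT_P_PRESENT_ALIEN = 0.10

MARKER_FAMILIES = ("transposase", "integrase", "recombinase", "phage", "plasmid")


@dataclass
class CodonModel:
    """A codon-frequency signature standing in for one donor/recipient lineage."""

    probs: np.ndarray
    model_id: str
    alphabet_id: str = "sense61"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("model probabilities must be nonnegative and sum to 1")


@dataclass
class CommunityTruth:
    """Ground truth for a synthetic genome or community."""

    gene_origin: dict[str, str]  # gene_id -> 'native' | 'alien:<model_id>'
    genome_taxon: dict[str, str] = field(default_factory=dict)
    transfers: list[dict] = field(default_factory=list)
    expected_edges: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "gene_origin": self.gene_origin,
                    "genome_taxon": self.genome_taxon,
                    "transfers": self.transfers,
                    "expected_edges": self.expected_edges,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CommunityTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["gene_origin"], d["genome_taxon"], d["transfers"], d["expected_edges"])


def model_js_bits(m1: CodonModel, m2: CodonModel) -> float:
    """Equal-weight JS divergence (bits) between two model frequency vectors."""
    return float(js_bits_arrays(m1.probs[None, :], m2.probs[None, :])[0])


def sample_codon_model(
    rng: np.random.Generator | int,
    concentration: float = DEFAULT_CONCENTRATION,
    model_id: str = "model",
    alphabet_id: str = "sense61",
) -> CodonModel:
    """Symmetric-Dirichlet codon model; lower concentration => more skew."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    k = len(ALPHABETS[alphabet_id])
    probs = rng.dirichlet(np.full(k, concentration))
    return CodonModel(probs, model_id, alphabet_id)


def sample_distinct_models(
    n: int,
    rng: np.random.Generator | int,
    concentration: float = DEFAULT_CONCENTRATION,
    min_js_bits: float = 0.1,
    model_ids: list[str] | None = None,
    alphabet_id: str = "sense61",
    max_tries: int = 10000,
) -> list[CodonModel]:
    """Sample models until every pair is at least ``min_js_bits`` apart."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    ids = model_ids or [f"model{i}" for i in range(n)]
    models: list[CodonModel] = []
    tries = 0
    while len(models) < n:
        cand = sample_codon_model(rng, concentration, ids[len(models)], alphabet_id)
        if all(model_js_bits(cand, m) >= min_js_bits for m in models):
            models.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not find {n} models with pairwise js >= {min_js_bits} "
                f"bits at concentration {concentration}"
            )
    return models


def _synth_gene_sequence(
    model: CodonModel, n_codons: int, rng: np.random.Generator
) -> str:
    codons = ALPHABETS[model.alphabet_id]
    idx = rng.choice(len(codons), size=n_codons, p=model.probs)
    seq = "".join(codons[i] for i in idx)
    if model.alphabet_id == "sense61":
        seq += STOP_CODONS[0]  # terminate the CDS
    return seq


def synth_genome(
    native: CodonModel,
    donors: list[CodonModel],
    n_genes: int,
    alien_segments: list[tuple[int, int]],
    codons_per_gene: int,
    seed: int | np.random.Generator,
    genome_id: str = "G1",
    replicon_id: str = "chr",
    intergenic_gap: int = 10,
) -> tuple[list[GeneSeq], CommunityTruth]:
    """One genome: native genes with contiguous alien segments inserted.

    ``alien_segments`` is a list of (donor_index, length_in_genes);
    segments are placed contiguously at randomised, non-overlapping
    insertion points along a single replicon. Each gene is an i.i.d.
    multinomial draw of ``codons_per_gene`` codons from its origin model.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n_alien = sum(length for _, length in alien_segments)
    if n_alien >= n_genes:
        raise ValueError("alien segments must total fewer genes than the genome")
    for donor_idx, _ in alien_segments:
        if donor_idx >= len(donors):
            raise ValueError(f"segment references donor {donor_idx} but only {len(donors)} given")

    n_native = n_genes - n_alien
    # choose distinct insertion points among the native genes, then build
    # the gene-origin sequence by splicing segments in
    insert_at = sorted(rng.choice(n_native + 1, size=len(alien_segments), replace=False))
    origins: list[str] = []
    cursor = 0
    for (donor_idx, length), pos in zip(alien_segments, insert_at):
        origins.extend(["native"] * (pos - cursor))
        origins.extend([f"alien:{donors[donor_idx].model_id}"] * length)
        cursor = pos
    origins.extend(["native"] * (n_native - cursor))

    models_by_origin = {"native": native, **{f"alien:{d.model_id}": d for d in donors}}
    genes: list[GeneSeq] = []
    gene_origin: dict[str, str] = {}
    pos = 0
    width = len(str(n_genes))
    for i, origin in enumerate(origins):
        seq = _synth_gene_sequence(models_by_origin[origin], codons_per_gene, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"{genome_id}_g{i:0{width}d}"
        genes.append(
            GeneSeq(
                gene_id=gene_id,
                genome_id=genome_id,
                replicon_id=replicon_id,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                sequence=seq,
            )
        )
        gene_origin[gene_id] = origin
        pos += len(seq) + intergenic_gap
    return genes, CommunityTruth(gene_origin=gene_origin)


def synth_marker_hits(
    truth: CommunityTruth,
    rate_native: float = DEFAULT_MARKER_RATE_NATIVE,
    rate_alien: float = DEFAULT_MARKER_RATE_ALIEN,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bernoulli marker assignment per gene at an origin-dependent rate.

    Returns a gene_id/family/e_value table; e-values fall below the 0.01
    retention cutoff. Marker density in alien material is what the
    enrichment test exploits.
    """
    for r in (rate_native, rate_alien):
        if not 0.0 <= r <= 1.0:
            raise ValueError("marker rates must lie in [0, 1]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    rows = []
    for gene_id in sorted(truth.gene_origin):
        origin = truth.gene_origin[gene_id]
        rate = rate_native if origin == "native" else rate_alien
        if rng.random() < rate:
            family = MARKER_FAMILIES[rng.integers(len(MARKER_FAMILIES))]
            e_value = 10.0 ** rng.uniform(-30.0, -2.0)
            rows.append({"gene_id": gene_id, "family": family, "e_value": e_value})
    return pd.DataFrame(rows, columns=["gene_id", "family", "e_value"])


def synth_phyletic_matrix(
    truth: CommunityTruth,
    relatives: dict[str, list[str]],
    p_present_native: float = DEFAULT_P_PRESENT_NATIVE,
    p_present_alien: float = DEFAULT_P_PRESENT_ALIEN,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-gene, per-relative Bernoulli presence table.

    Native genes are near-universally present among relatives; recently
    acquired genes are sporadic. Columns: gene_id, rank, relative_genome,
    present.
    """
    for p in (p_present_native, p_present_alien):
        if not 0.0 <= p <= 1.0:
            raise ValueError("presence probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    rows = []
    for gene_id in sorted(truth.gene_origin):
        p = p_present_native if truth.gene_origin[gene_id] == "native" else p_present_alien
        for rank in ("species", "genus", "family"):
            for rel in relatives.get(rank, []):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "rank": rank,
                        "relative_genome": rel,
                        "present": int(rng.random() < p),
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "rank", "relative_genome", "present"])


def presence_fractions(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """gene_id -> rank -> presence fraction, from a presence table."""
    out: dict[str, dict[str, float]] = {}
    for (gene_id, rank), grp in table.groupby(["gene_id", "rank"]):
        out.setdefault(str(gene_id), {})[str(rank)] = float(grp["present"].mean())
    return out


def synth_community(
    n_taxa: int,
    genomes_per_taxon: int,
    transfer_matrix: np.ndarray,
    seed: int,
    n_genes: int = 500,
    codons_per_gene: int = 300,
    segment_genes: int = 20,
    min_model_js: float = 0.1,
    concentration: float = DEFAULT_CONCENTRATION,
    n_mobilome_models: int = 0,
    mobilome_taxa: int = 3,
) -> tuple[dict[str, list[GeneSeq]], CommunityTruth]:
    """A multi-genome community with a known donor->recipient transfer truth.

    ``transfer_matrix[i, j]`` is the number of contiguous native-gene
    segments of taxon i inserted into genomes of taxon j (recipients
    cycle through taxon j's genomes). One codon model per taxon, all
    pairwise at least ``min_model_js`` bits apart. Optional mobilome
    models are shared across the first ``mobilome_taxa`` taxa (one
    segment per genome) to induce alien<->alien connectivity.

    Expected network edges are recorded genome-to-genome: a transfer from
    taxon i into recipient genome r implies a native_to_alien edge from
    every genome of taxon i to r, and alien_alien edges among recipients
    carrying segments of the same donor model.
    """
    transfer_matrix = np.asarray(transfer_matrix, dtype=int)
    if transfer_matrix.shape != (n_taxa, n_taxa):
        raise ValueError("transfer_matrix must be n_taxa x n_taxa")
    if (transfer_matrix < 0).any() or np.trace(transfer_matrix) != 0:
        raise ValueError("transfer_matrix must be nonnegative with a zero diagonal")
    rng = np.random.default_rng(seed)
    taxa = [f"T{i + 1}" for i in range(n_taxa)]
    models = sample_distinct_models(
        n_taxa + n_mobilome_models,
        rng,
        concentration=concentration,
        min_js_bits=min_model_js,
        model_ids=taxa + [f"MOB{i + 1}" for i in range(n_mobilome_models)],
    )
    taxon_models = dict(zip(taxa, models[:n_taxa]))
    mobilome_models = models[n_taxa:]

    genome_ids = {
        t: [f"{t}g{j + 1}" for j in range(genomes_per_taxon)] for t in taxa
    }
    # assign each transfer to a recipient genome, round-robin within the taxon
    segments_for_genome: dict[str, list[CodonModel]] = {
        g: [] for t in taxa for g in genome_ids[t]
    }
    transfers = []
    for i, donor in enumerate(taxa):
        for j, recipient_taxon in enumerate(taxa):
            for k in range(transfer_matrix[i, j]):
                r = genome_ids[recipient_taxon][k % genomes_per_taxon]
                segments_for_genome[r].append(taxon_models[donor])
                transfers.append(
                    {"donor_taxon": donor, "recipient_genome": r, "model_id": donor}
                )
    for m in mobilome_models:
        for t in taxa[:mobilome_taxa]:
            for g in genome_ids[t]:
                segments_for_genome[g].append(m)
                transfers.append(
                    {"donor_taxon": "mobilome", "recipient_genome": g, "model_id": m.model_id}
                )

    genomes: dict[str, list[GeneSeq]] = {}
    gene_origin: dict[str, str] = {}
    genome_taxon: dict[str, str] = {}
    for t in taxa:
        for g in genome_ids[t]:
            donors = segments_for_genome[g]
            genes, truth_g = synth_genome(
                native=taxon_models[t],
                donors=donors,
                n_genes=n_genes,
                alien_segments=[(idx, segment_genes) for idx in range(len(donors))],
                codons_per_gene=codons_per_gene,
                seed=rng,
                genome_id=g,
            )
            genomes[g] = genes
            gene_origin.update(truth_g.gene_origin)
            genome_taxon[g] = t

    # genome-level expected edges
    carriers: dict[str, set[str]] = {}  # model_id -> genomes carrying it as alien
    for tr in transfers:
        carriers.setdefault(tr["model_id"], set()).add(tr["recipient_genome"])
    expected = []
    seen = set()
    for model_id, recipients in sorted(carriers.items()):
        donor_taxon = model_id if model_id in taxa else None
        for r in sorted(recipients):
            if donor_taxon is not None:
                for dg in genome_ids[donor_taxon]:
                    if dg == r:
                        continue
                    key = ("native_to_alien", dg, r)
                    if key not in seen:
                        seen.add(key)
                        expected.append(
                            {"edge_type": "native_to_alien", "donor_genome": dg, "recipient_genome": r}
                        )
        for a in sorted(recipients):
            for b in sorted(recipients):
                if a < b:
                    key = ("alien_alien", a, b)
                    if key not in seen:
                        seen.add(key)
                        expected.append(
                            {"edge_type": "alien_alien", "genome_a": a, "genome_b": b}
                        )

    truth = CommunityTruth(
        gene_origin=gene_origin,
        genome_taxon=genome_taxon,
        transfers=transfers,
        expected_edges=expected,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# writers for the pipeline's input formats


def write_genome_files(genes: list[GeneSeq], out_dir: str | Path, genome_id: str) -> None:
    """FASTA (genome-strand sequences) + 1-based inclusive coordinate TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{genome_id}.fna", "w") as fa, open(
        out_dir / f"{genome_id}.coords.tsv", "w"
    ) as tsv:
        tsv.write("gene_id\treplicon_id\tstart\tend\tstrand\n")
        for g in genes:
            seq = g.sequence if g.strand == "+" else reverse_complement(g.sequence)
            fa.write(f">{g.gene_id}\n{seq}\n")
            tsv.write(f"{g.gene_id}\t{g.replicon_id}\t{g.start + 1}\t{g.end}\t{g.strand}\n")


def write_community(
    genomes: dict[str, list[GeneSeq]],
    truth: CommunityTruth,
    out_dir: str | Path,
    marker_rate_native: float = DEFAULT_MARKER_RATE_NATIVE,
    marker_rate_alien: float = DEFAULT_MARKER_RATE_ALIEN,
    seed: int = 0,
) -> None:
    """All pipeline inputs for a community: per-genome FASTA/coords, marker
    TSV, taxonomy TSV and the truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for genome_id, genes in genomes.items():
        write_genome_files(genes, out_dir, genome_id)
    markers = synth_marker_hits(truth, marker_rate_native, marker_rate_alien, seed)
    markers.to_csv(out_dir / "markers.tsv", sep="\t", index=False)
    with open(out_dir / "taxonomy.tsv", "w") as fh:
        fh.write("genome_id\tspecies_group\tgenus\tfamily\tphylum\tdomain\n")
        for g in sorted(truth.genome_taxon):
            t = truth.genome_taxon[g]
            fh.write(f"{g}\t{g}\t{t}\t{t}\t{t}\tBacteria\n")
    truth.to_json(out_dir / "truth.json")
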