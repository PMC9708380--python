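"""Reading CDS sequences with genome coordinates, and codon counting.

Gene coordinates are held internally as 0-based half-open intervals on
the replicon. GFF3 input (1-based inclusive) is converted on parse; the
fallback coordinate TSV (``gene_id  replicon_id  start  end  strand``) is
likewise 1-based inclusive. Minus-strand sequences are reverse
complemented on read so that ``GeneSeq.sequence`` is always the coding
strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabets import ALPHABETS, CODON_INDEX, STOP_CODONS, alphabet_size, reverse_complement

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


@dataclass
class GeneSeq:
    """A protein-coding gene: identity, location and coding-strand sequence."""

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != interval "
                f"length {self.end - self.start}"
            )


@dataclass
class CodonUsage:
    """Codon counts over a fixed alphabet; the unit of all divergence computations."""

    vector: np.ndarray
    alphabet_id: str = "sense61"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.int64)
        if self.vector.shape != (alphabet_size(self.alphabet_id),):
            raise ValueError(
                f"count vector length {self.vector.shape} does not match "
                f"alphabet {self.alphabet_id!r}"
            )
        if (self.vector < 0).any():
            raise ValueError("codon counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.vector.sum())

    @property
    def counts(self) -> dict[str, int]:
        """Nonzero counts as a codon→count mapping."""
        codons = ALPHABETS[self.alphabet_id]
        return {codons[i]: int(c) for i, c in enumerate(self.vector) if c}

    @classmethod
    def from_counts(cls, counts: dict[str, int], alphabet_id: str = "sense61") -> "CodonUsage":
        index = CODON_INDEX[alphabet_id]
        vec = np.zeros(alphabet_size(alphabet_id), dtype=np.int64)
        for codon, n in counts.items():
            if codon not in index:
                raise ValueError(f"codon {codon!r} not in alphabet {alphabet_id!r}")
            vec[index[codon]] = n
        return cls(vec, alphabet_id)

    def __add__(self, other: "CodonUsage") -> "CodonUsage":
        if other.alphabet_id != self.alphabet_id:
            raise ValueError(
                f"cannot pool usages over different alphabets "
                f"({self.alphabet_id!r} vs {other.alphabet_id!r})"
            )
        return CodonUsage(self.vector + other.vector, self.alphabet_id)


def codon_counts(gene: GeneSeq | str, alphabet_id: str = "sense61") -> CodonUsage:
    """Count codons in frame 0 from the first base of the coding sequence.

    Codons containing ambiguous bases are skipped; with ``sense61`` the
    stop codons are dropped. A trailing partial codon is dropped with a
    logged warning. An empty sequence yields a usage with total 0.
    """
    seq = gene.sequence if isinstance(gene, GeneSeq) else gene
    seq = seq.upper()
    name = gene.gene_id if isinstance(gene, GeneSeq) else "<seq>"
    index = CODON_INDEX[alphabet_id]
    vec = np.zeros(alphabet_size(alphabet_id), dtype=np.int64)
    if not seq:
        logger.warning("%s: empty sequence; codon usage total is 0", name)
        return CodonUsage(vec, alphabet_id)
    tail = len(seq) % 3
    if tail:
        logger.warning("%s: dropping %d trailing base(s) (partial codon)", name, tail)
    for i in range(0, len(seq) - tail, 3):
        codon = seq[i : i + 3]
        if not VALID_BASES.issuperset(codon):
            continue
        if alphabet_id == "sense61" and codon in STOP_CODONS:
            continue
        vec[index[codon]] += 1
    return CodonUsage(vec, alphabet_id)


def _parse_gff3(path: Path) -> list[tuple[str, str, int, int, str]]:
    """Yield (gene_id, replicon, start0, end, strand) from CDS rows of a GFF3 file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                continue
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attr = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k.strip()] = v.strip()
            gene_id = attr.get("ID") or attr.get("locus_tag")
            if gene_id is None:
                raise ValueError(f"{path}: CDS row lacks ID/locus_tag attribute: {line!r}")
            rows.append((gene_id, seqid, int(start) - 1, int(end), strand))
    return rows


def _parse_coords_tsv(path: Path) -> list[tuple[str, str, int, int, str]]:
    """Coordinate TSV: gene_id, replicon_id, start, end, strand (1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":  # header
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            gene_id, replicon, start, end, strand = parts[:5]
            rows.append((gene_id, replicon, int(start) - 1, int(end), strand))
    return rows


def read_genes(cds_fasta: str | Path, coords: str | Path, genome_id: str) -> list[GeneSeq]:
    """Read CDS sequences and coordinates into an ordered gene list.

    Returns genes sorted by (replicon_id, start); minus-strand records are
    reverse complemented so every stored sequence is the coding strand.
    FASTA records and coordinate rows are joined on the shared identifier;
    any mismatch between the two id sets is a hard error.
    """
    cds_fasta, coords = Path(cds_fasta), Path(coords)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    if coords.suffix.lower() in (".gff", ".gff3"):
        rows = _parse_gff3(coords)
    else:
        rows = _parse_coords_tsv(coords)

    seen: set[str] = set()
    for gene_id, *_ in rows:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {coords}")
        seen.add(gene_id)
    missing_seq = sorted(seen - seqs.keys())
    missing_coord = sorted(seqs.keys() - seen)
    if missing_seq or missing_coord:
        raise ValueError(
            f"FASTA/coordinate identifier mismatch for genome {genome_id!r}: "
            f"no sequence for {missing_seq[:5]}, no coordinates for {missing_coord[:5]}"
        )

    genes = []
    for gene_id, replicon, start0, end, strand in rows:
        seq = seqs[gene_id]
        if strand == "-":
            seq = reverse_complement(seq)
        genes.append(
            GeneSeq(
                gene_id=gene_id,
                genome_id=genome_id,
                replicon_id=replicon,
                start=start0,
                end=end,
                strand=strand,
                sequence=seq,
            )
        )
    genes.sort(key=lambda g: (g.replicon_id, g.start, g.gene_id))
    return genes
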