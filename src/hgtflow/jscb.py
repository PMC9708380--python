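"""Jensen–Shannon codon-bias divergence, its significance test, and
two-phase agglomerative gene clustering.

The divergence between two codon-usage count vectors with totals N1, N2
is the weighted Jensen–Shannon divergence in bits,

    JS = H(pi1*p1 + pi2*p2) - pi1*H(p1) - pi2*H(p2),   pi_i = N_i/(N1+N2),

with H the base-2 Shannon entropy. The statistic

    Lambda = 2*(N1+N2)*ln(2)*JS

is identically the G statistic (likelihood-ratio statistic) of the 2 x K
contingency table formed by the two count vectors, and is referred
asymptotically to a chi-square distribution with K-1 degrees of freedom,
K being the number of codons with nonzero pooled count. A pair of
genes/clusters whose p-value exceeds the significance threshold is
considered compositionally indistinguishable and may be merged.

Clustering is two-phase: contiguous genes along each replicon are merged
first at a stringent threshold (default 1e-4), isolating candidate
genomic islands as segments; the resulting segments are then merged
globally (no adjacency constraint) at a relaxed threshold (default
1e-8). The largest final cluster is the compositionally typical
(native-backbone) cluster; all others are atypical.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2

from .genome_io import CodonUsage, GeneSeq, codon_counts

LN2 = float(np.log(2.0))

__all__ = [
    "JSResult",
    "GeneCluster",
    "js_divergence",
    "js_test",
    "pooled_usage",
    "cluster_contiguous",
    "cluster_global",
    "cluster_genome",
    "js_bits_arrays",
    "js_test_arrays",
]


@dataclass
class JSResult:
    """Weighted JS divergence with its chi-square significance approximation."""

    js_bits: float
    statistic: float
    dof: int
    p_value: float
    n1: int
    n2: int


@dataclass
class GeneCluster:
    """A set of genes of one genome with pooled codon usage and annotation state."""

    cluster_id: str
    genome_id: str
    member_gene_ids: list[str]
    pooled: CodonUsage
    compositional_class: str  # 'typical' | 'atypical'
    label: str = "unassigned"  # 'unassigned' | 'native' | 'alien'
    evidence: dict = field(
        default_factory=lambda: {
            "compositional": False,
            "marker_enriched": False,
            "phyletic_aberrant": False,
        }
    )
    evidence_tier: int | None = None

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def _entropy_bits(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Base-2 entropy of count rows (0*log0 := 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[..., None]
    return -xlogy(p, p).sum(axis=-1) / LN2


def js_bits_arrays(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Row-wise weighted JS divergence (bits) between count matrices.

    ``c1`` and ``c2`` broadcast on the leading axes; the last axis is the
    codon alphabet. Rows must have positive totals.
    """
    c1 = np.asarray(c1, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    n1 = c1.sum(axis=-1)
    n2 = c2.sum(axis=-1)
    tot = n1 + n2
    h_mix = _entropy_bits(c1 + c2, tot)
    h1 = _entropy_bits(c1, n1)
    h2 = _entropy_bits(c2, n2)
    js = h_mix - (n1 / tot) * h1 - (n2 / tot) * h2
    return np.clip(js, 0.0, None)


def js_test_arrays(
    c1: np.ndarray, c2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise (js_bits, statistic, dof, p_value) for count-vector pairs."""
    js = js_bits_arrays(c1, c2)
    n1 = np.asarray(c1).sum(axis=-1)
    n2 = np.asarray(c2).sum(axis=-1)
    lam = 2.0 * (n1 + n2) * LN2 * js
    pooled_support = ((np.asarray(c1) + np.asarray(c2)) > 0).sum(axis=-1)
    dof = np.maximum(pooled_support - 1, 1)
    p = chi2.sf(lam, dof)
    return js, lam, dof, p


def _require_positive(u: CodonUsage, side: str) -> None:
    if u.total <= 0:
        raise ValueError(f"{side} codon usage has zero total; divergence undefined")


def _check_alphabets(u1: CodonUsage, u2: CodonUsage) -> None:
    if u1.alphabet_id != u2.alphabet_id:
        raise ValueError(
            f"mixed alphabets: {u1.alphabet_id!r} vs {u2.alphabet_id!r}"
        )


def js_divergence(u1: CodonUsage, u2: CodonUsage) -> float:
    """Weighted Jensen–Shannon divergence between two codon usages, in bits."""
    _check_alphabets(u1, u2)
    _require_positive(u1, "first")
    _require_positive(u2, "second")
    return float(js_bits_arrays(u1.vector, u2.vector))


def js_test(u1: CodonUsage, u2: CodonUsage) -> JSResult:
    """JS divergence with the chi-square (G-test) significance approximation."""
    _check_alphabets(u1, u2)
    _require_positive(u1, "first")
    _require_positive(u2, "second")
    js, lam, dof, p = js_test_arrays(u1.vector[None, :], u2.vector[None, :])
    return JSResult(
        js_bits=float(js[0]),
        statistic=float(lam[0]),
        dof=int(dof[0]),
        p_value=float(p[0]),
        n1=u1.total,
        n2=u2.total,
    )


def pooled_usage(members: list[CodonUsage] | tuple[CodonUsage, ...]) -> CodonUsage:
    """Element-wise sum of member usages (shared alphabet required)."""
    members = list(members)
    if not members:
        raise ValueError("cannot pool an empty set of usages")
    out = members[0]
    for u in members[1:]:
        out = out + u
    return out


@dataclass
class Segment:
    """A proto-cluster: ordered gene ids with their pooled count vector."""

    seg_id: str
    gene_ids: list[str]
    counts: np.ndarray
    replicon_id: str | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _pair_stats(ca: np.ndarray, cb: np.ndarray) -> tuple[float, float]:
    """(p_value, js_bits) for one count-vector pair; p = -1 if either side empty."""
    if ca.sum() == 0 or cb.sum() == 0:
        return -1.0, float("inf")
    js, _lam, _dof, p = js_test_arrays(ca[None, :], cb[None, :])
    return float(p[0]), float(js[0])


def cluster_contiguous(
    genes: list[tuple[GeneSeq, CodonUsage]],
    alpha1: float = 1e-4,
) -> list[Segment]:
    """Phase 1: merge contiguous compositionally similar genes per replicon.

    Starting from single-gene segments in genome order, the adjacent pair
    with the largest p-value is merged repeatedly, provided p >= alpha1;
    pairs below the threshold are deemed different. Replicons are
    independent. Genes with zero codon total stay singleton segments.
    """
    if not genes:
        return []
    by_replicon: dict[str, list[tuple[GeneSeq, CodonUsage]]] = {}
    for gene, usage in genes:
        by_replicon.setdefault(gene.replicon_id, []).append((gene, usage))

    segments: list[Segment] = []
    seg_counter = itertools.count()
    for replicon_id in sorted(by_replicon):
        items = sorted(by_replicon[replicon_id], key=lambda gu: (gu[0].start, gu[0].gene_id))
        n = len(items)
        ids = list(range(n))
        gene_lists: list[list[str] | None] = [[g.gene_id] for g, _ in items]
        counts = [u.vector.astype(np.int64).copy() for _, u in items]
        nxt: list[int | None] = [i + 1 if i + 1 < n else None for i in ids]
        prv: list[int | None] = [i - 1 if i > 0 else None for i in ids]
        version = [0] * n

        heap: list[tuple[float, float, int, int, int, int]] = []

        def push_pair(a: int, b: int) -> None:
            p, js = _pair_stats(counts[a], counts[b])
            if p < 0:  # zero-total side: never mergeable
                return
            heapq.heappush(heap, (-p, js, a, b, version[a], version[b]))

        for i in range(n - 1):
            push_pair(i, i + 1)

        while heap:
            negp, _js, a, b, va, vb = heapq.heappop(heap)
            if gene_lists[a] is None or gene_lists[b] is None:
                continue
            if version[a] != va or version[b] != vb:
                continue
            if -negp < alpha1:
                break  # best remaining adjacent pair is significantly different
            # merge b into a (a precedes b along the replicon)
            gene_lists[a] = gene_lists[a] + gene_lists[b]  # type: ignore[operator]
            counts[a] = counts[a] + counts[b]
            gene_lists[b] = None
            version[a] += 1
            nxt[a] = nxt[b]
            if nxt[b] is not None:
                prv[nxt[b]] = a
            if prv[a] is not None:
                push_pair(prv[a], a)
            if nxt[a] is not None:
                push_pair(a, nxt[a])

        node = 0 if n else None
        # walk the linked list from the first surviving segment
        first = next((i for i in ids if gene_lists[i] is not None and prv[i] is None), None)
        node = first
        while node is not None:
            segments.append(
                Segment(
                    seg_id=f"s{next(seg_counter):06d}",
                    gene_ids=list(gene_lists[node]),  # type: ignore[arg-type]
                    counts=counts[node],
                    replicon_id=replicon_id,
                )
            )
            node = nxt[node]
    return segments


def cluster_global(segments: list[Segment], alpha2: float = 1e-8) -> list[Segment]:
    """Phase 2: agglomerate segments genome-wide with no adjacency constraint.

    The pair with the largest p-value is merged while p >= alpha2. Ties
    are broken by smaller js_bits, then by the lexicographically smaller
    segment-id pair, making the clustering deterministic.
    """
    if not segments:
        return []
    segs = {s.seg_id: Segment(s.seg_id, list(s.gene_ids), s.counts.copy(), s.replicon_id) for s in segments}
    version: dict[str, int] = {sid: 0 for sid in segs}
    heap: list[tuple[float, float, str, str, int, int]] = []

    def push_batch(pairs: list[tuple[str, str]]) -> None:
        """Vectorized p/js computation for many candidate pairs at once."""
        live = [(a, b) for a, b in pairs if segs[a].total > 0 and segs[b].total > 0]
        if not live:
            return
        ca = np.stack([segs[a].counts for a, _ in live])
        cb = np.stack([segs[b].counts for _, b in live])
        js, _lam, _dof, p = js_test_arrays(ca, cb)
        for (a, b), pj, jj in zip(live, p, js):
            heapq.heappush(heap, (-float(pj), float(jj), a, b, version[a], version[b]))

    sids = sorted(segs)
    push_batch([(a, b) for i, a in enumerate(sids) for b in sids[i + 1 :]])

    while heap:
        negp, _js, a, b, va, vb = heapq.heappop(heap)
        if a not in segs or b not in segs:
            continue
        if version[a] != va or version[b] != vb:
            continue
        if -negp < alpha2:
            break
        # merge into the lexicographically smaller id (a <= b by construction)
        sa, sb = segs[a], segs[b]
        sa.gene_ids = sa.gene_ids + sb.gene_ids
        sa.counts = sa.counts + sb.counts
        sa.replicon_id = sa.replicon_id if sa.replicon_id == sb.replicon_id else None
        del segs[b]
        version[a] += 1
        push_batch([(min(a, o), max(a, o)) for o in segs if o != a])
    return [segs[sid] for sid in sorted(segs)]


def clusters_from_segments(
    segments: list[Segment],
    genome_id: str,
    alphabet_id: str = "sense61",
) -> list[GeneCluster]:
    """Name final clusters G{genome}_Cl_{k} in descending size order.

    The cluster with the most genes is compositional_class 'typical'
    (native backbone); a size tie is broken by larger pooled codon total,
    then by lexicographically smallest member gene id.
    """
    order = sorted(
        segments,
        key=lambda s: (-len(s.gene_ids), -s.total, min(s.gene_ids)),
    )
    clusters = []
    for k, seg in enumerate(order, start=1):
        clusters.append(
            GeneCluster(
                cluster_id=f"G{genome_id}_Cl_{k}",
                genome_id=genome_id,
                member_gene_ids=list(seg.gene_ids),
                pooled=CodonUsage(seg.counts, alphabet_id),
                compositional_class="typical" if k == 1 else "atypical",
            )
        )
    for c in clusters:
        c.evidence["compositional"] = c.compositional_class == "atypical"
    return clusters


def cluster_genome(
    genes: list[GeneSeq],
    alphabet_id: str = "sense61",
    alpha_contig: float = 1e-4,
    alpha_global: float = 1e-8,
) -> list[GeneCluster]:
    """Full two-phase JS-CB clustering of one genome's ordered gene list."""
    with_usage = [(g, codon_counts(g, alphabet_id)) for g in genes]
    segments = cluster_contiguous(with_usage, alpha1=alpha_contig)
    merged = cluster_global(segments, alpha2=alpha_global)
    genome_id = genes[0].genome_id if genes else "NA"
    return clusters_from_segments(merged, genome_id, alphabet_id)
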