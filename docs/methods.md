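# Methods

## Divergence measure and significance approximation

All comparisons — gene vs gene, cluster vs cluster, within and across
genomes — use the weighted Jensen–Shannon (JS) divergence between codon
usage count vectors. With totals $N_1, N_2$, weights
$\pi_i = N_i/(N_1+N_2)$ and frequency vectors $p_i$,

$$\mathrm{JS} = H(\pi_1 p_1 + \pi_2 p_2) - \pi_1 H(p_1) - \pi_2 H(p_2)$$

in bits ($H$ = base-2 entropy, $0\log 0 := 0$). JS is symmetric,
nonnegative, zero exactly when the frequency vectors coincide, and at
most 1 bit. Weighting by sample size makes the statistic

$$\Lambda = 2 (N_1 + N_2) \ln 2 \cdot \mathrm{JS}$$

*identical* to the likelihood-ratio (G) statistic of the $2\times K$
contingency table formed by the two count vectors — an identity the test
suite verifies against an independently coded G computation to $10^{-9}$
relative error. We therefore use the asymptotic $\chi^2$ reference
distribution with $K-1$ degrees of freedom, where $K$ counts codons with
nonzero *pooled* count. Using pooled support rather than the full
alphabet size avoids inflating the degrees of freedom with codons absent
from both sides; for short genes this makes the test mildly conservative,
which is the safer direction when deciding merges.

Empirical size: with 5000 codons per side and mildly skewed usage vectors
(symmetric Dirichlet, concentration 10), the 0.05-level test rejects true
null pairs at 0.051–0.054. Strongly skewed usage (concentration ≤ 1)
creates many near-empty codon cells and pushes the empirical size to
≈0.06 at this sample size; this finite-sample liberality of the
$\chi^2$ approximation is a known property of G-type tests and is the
main caveat when interpreting borderline p-values for short genes. A
refined effective-length-corrected approximation could be slotted in
behind `js_test` but the G form is the default because it is exact in the
large-sample limit and oracle-testable.

## Two-phase agglomerative clustering

Phase 1 (contiguous, default significance $10^{-4}$): each replicon
starts as single-gene segments in genome order. The *adjacent* pair with
the largest p-value is merged repeatedly while that p-value is at or
above the threshold. The stringent setting builds pure segments and
respects gene order, exploiting the fact that acquired DNA arrives as
contiguous genomic islands. Replicons are independent; genes with zero
codon total (empty/ambiguous sequences) stay singletons.

Phase 2 (global, default $10^{-8}$): the segments are agglomerated with
no adjacency constraint under the same rule — merge the pair with the
largest p-value while p ≥ threshold. The relaxed setting reunites
segments of common origin scattered around the genome (including across
replicons).

Merge order is by largest p-value rather than smallest JS because the
acceptance rule is defined on p; under unequal cluster sizes the two
orderings differ. Ties break by smaller JS, then by lexicographic segment
id; the final clusters are named `G{genome}_Cl_{k}` in descending size
order (ties: larger pooled codon total, then smallest member gene id), so
identical input yields byte-identical output. The largest cluster is the
compositionally *typical* (native-backbone) cluster; all others are
*atypical*. Both phases use a max-heap over candidate pairs with lazy
invalidation and vectorised batch p-value computation; the global phase
is $O(C^2 \log C)$ for $C$ segments.

Codon counting reads frame 0 of the annotated CDS (annotation is
trusted; no internal stop scanning), skips codons containing ambiguous
bases, drops a trailing partial codon with a warning, and by default uses
the 61 sense codons (`sense61`; stop codons dropped), the convention of
the codon-usage literature. `all64` is available by configuration. Genes
shorter than 30 codons are retained — the test's sample-size weighting
already discounts them.

## Cluster annotation

**Marker enrichment.** Genes with at least one hit against a
genomic-island marker family (transposase, integrase, recombinase,
prophage, plasmid) at E-value ≤ 0.01 (boundary inclusive) are marker
genes. For each atypical cluster, the sampling population is the union of
that cluster and the genome's native cluster; the upper-tail
hypergeometric p-value asks whether the cluster holds surprisingly many
of the population's marker genes. A cluster is enriched when p < 0.05
*and* the marker-rate ratio versus the native cluster is ≥ 1.25; the
conjunction honours both the significance rule and the fold cutoff
calibrated on native-cluster background rates. Fold enrichment against
the whole genome is computed and reported but does not enter the
decision, which is defined with respect to the native cluster.

**Phyletic pattern.** For genes of non-enriched atypical clusters, the
presence fraction among sequenced relatives is evaluated in a
species → genus → family cascade: fraction ≤ 0.30 ⇒ phyletically
aberrant (stop); fraction > 0.80 ⇒ well distributed, escalate one rank —
this is what detects older transfers into the ancestor of a species
group (universal within the species group, sparse in the genus);
fractions in (0.30, 0.80] stop the cascade as not aberrant, the
conservative reading that minimises false alien calls. Presence in a
relative requires a BLAST hit with query coverage ≥ 0.70 and percent
identity ≥ 60/50/25 at species/genus/family (cutoffs relax with rank to
track expected sequence divergence). A rank with no relatives is skipped;
a gene with no relatives at any rank is undetermined.

**Labels.** Typical cluster → native. Atypical and enriched → alien.
Atypical, not enriched, with a strict majority (> 50% of genes with
determinable status) aberrant → alien. Otherwise native — compositional
atypicality alone (evidence tier 1) is not sufficient, since unusual
codon bias also arises from, e.g., highly expressed ribosomal operons.
Tier 2 = one corroborating line of evidence, tier 3 = all three. Genomes
without sequenced relatives skip the phyletic route and their
non-enriched atypical clusters default to native.

## Flow network

Every cluster pair from different genomes is compared with the same JS
test; p ≥ `alpha_net` (default $10^{-8}$, the relaxed clustering
threshold — the cross-genome comparison deliberately reuses the same
hypothesis-testing framework) makes the pair similar. Similar pairs are
typed by endpoint labels: native+alien becomes a directed edge from the
native (donor) cluster to the alien (recipient) cluster; alien+alien an
undirected edge (shared mobilome, direction indeterminate);
native+native pairs are counted and excluded — backbone similarity
between close relatives reflects vertical proximity or homologous
recombination, not HGT. When a taxonomy is supplied, genome pairs from
the same species group are skipped entirely (configurable). One edge per
cluster pair regardless of supporting gene count; multiplicity lives in
cluster sizes, and a link may represent multiple transfer events. The
typing is a partition: similar pairs = edges + excluded native–native
count, an invariant the tests assert.

## Degree-distribution model comparison

Node degree is incidence count (direction ignored). The discrete power
law $P_k \propto k^{-\alpha}$, $k \ge x_{\min}$, is fitted by maximum
likelihood: $\hat\alpha$ maximises
$-n \ln \zeta(\alpha, x_{\min}) - \alpha \sum \ln x_i$ (Hurwitz zeta),
seeded with the closed form
$1 + n [\sum \ln(x_i/(x_{\min}-\tfrac12))]^{-1}$ and refined by bounded
scalar minimisation ($\alpha \in (1, 12]$, tolerance $10^{-6}$).
$x_{\min}$ is chosen to minimise the KS distance between the fitted and
empirical tail CDFs, scanning unique degree values (quantile-thinned to
≤150 candidates; candidates must leave ≥10 tail points). Goodness of fit
is the Clauset-style semi-parametric bootstrap: synthetic samples draw
the tail from the fitted model and the body by resampling the empirical
values below $x_{\min}$, are refitted from scratch, and the p-value is
the fraction with KS at or above the observed. The replicate count is a
config value (2500 in the headline regime; smaller counts suffice to
resolve p < 0.1). Power-law samples are generated by the standard
rounding transform
$x = \lfloor (x_{\min}-\tfrac12)(1-u)^{-1/(\alpha-1)} + \tfrac12 \rfloor$,
accurate to well under 1% bias for $x_{\min}$ above a few.

Exponential and lognormal alternatives are fitted with and without
$x_{\min}$: shifted-exponential rate by the closed-form tail MLE,
lognormal by log-moments (truncated ML refinement when a cutoff is
used), with the same KS/bootstrap machinery on integer-rounded synthetic
samples. Caveat: when the alternative is given a *free* cutoff on
strongly heavy-tailed data, the KS scan can retreat to a far tail with
few points where almost anything fits, so whole-sample (no-$x_{\min}$)
fits are the informative rejection test at moderate sample sizes; both
variants are reported.

Interaction coefficients: for a taxon pair $(D_1, D_2)$ (analysis level
defaults to phylum), edges are counted by mode —
$N_{D1}\to A_{D2}$, $A_{D1}\leftarrow N_{D2}$, $A_{D1}\leftrightarrow A_{D2}$ —
and each IC is its count over the pair's total interactions, so the
three ICs sum to 1 and the per-pair totals sum to the network's edge
count. Link rates normalise the observed links by possible genome pairs:
$n_1 n_2$ inter-taxon, $\binom{n}{2}$ intra-taxon, expressed per 100
pairs.

## Synthetic data

Codon signatures are symmetric-Dirichlet draws over the 61 sense codons.
The default concentration 2.5 matches the dispersion of real codon
frequency tables (frequency s.d. ≈ 1% around the 1/61 ≈ 1.6% mean);
`sample_distinct_models` rejection-samples until all pairwise model JS
reaches a floor (0.1 bits by default — a realistic inter-lineage codon
divergence and the regime in which the pipeline is expected to resolve
donors). Genes are i.i.d. multinomial draws of (default) 300 codons —
a typical prokaryotic CDS length — with a stop codon appended; alien
material enters as contiguous segments (default 20 genes, a typical
genomic-island scale) at random non-overlapping positions. Marker hits
are per-gene Bernoulli draws at defaults 0.05 (native) and 0.50 (alien),
reflecting the strong concentration of mobility genes inside islands;
presence/absence tables use 0.95 (native) vs 0.10 (alien) per relative.
Communities assign one model per taxon and insert donor-taxon native
segments into recipients per an explicit transfer matrix; expected edges
follow from the construction (every donor-taxon genome's backbone should
link to the recipient's alien cluster; recipients of the same donor model
should interlink alien–alien).

What the generator does *not* emulate: amelioration (acquired genes
drifting toward host composition), within-genome heterogeneity of the
native backbone (strand skew, expression-level codon bias), gene length
variation, annotation errors, and homology-level signal (the phyletic
tables are generated at the presence/absence level, not from sequence).
Passing recovery tests therefore demonstrates correctness of the
machinery under the model's assumptions — clean compositional signal and
contiguous islands — not performance on ameliorated or short-segment
transfers, which the compositional approach inherently misses.

## Problem sizes in tests and the acceptance script

The bundled checks run at desk scale, chosen to keep the full suite in
tens of seconds while leaving comfortable statistical margins: null
calibration uses $10^5$ pairs (tests) / $5\times 10^4$ (script) at 5000
codons per side; clustering recovery one 1100-gene genome; community
recovery 6 taxa × 3 genomes × 500 genes; the degree-distribution regime
uses 5000 tail values at the scale-free exponent α = 2.25, x_min = 101
with 100-replicate bootstraps for the alternatives. Corpus-scale results
(hundreds of genomes, database searches) are outside the package's
scope: marker hits, BLAST tables and taxonomy are consumed as inputs,
never produced.

## Known limitations

- The $\chi^2$ approximation is liberal for strongly skewed usage and
  short genes (see above); thresholds are best interpreted as tuning
  knobs calibrated by the defaults rather than exact error rates.
- Greedy largest-p agglomeration is order-deterministic but not globally
  optimal; pathological interleavings of two sources can leave split
  clusters.
- Direction is only inferred for native→alien edges; alien↔alien flow is
  undirected by construction.
- The free-cutoff alternative fits can under-reject on heavy-tailed data
  (far-tail retreat), so scale-free claims should rest on the
  whole-sample alternative rejections plus the power-law bootstrap.
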