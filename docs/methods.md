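# Methods

## Scope and coordinate system

All synteny work happens in gene-rank space: each gene's position is its
0-based index along its chromosome when genes are sorted by start
coordinate (ties broken by end, then id). Rank space removes
assembly-scale effects and matches how gene-order dot plots are read.
Base-pair-resolution structural variation is out of scope; all
rearrangement classification is at gene-order resolution. Internally all
coordinates are 0-based half-open; GFF3 input is converted at the
boundary and converted back on write.

## Collinear blocks

Homolog pairs (externally produced, e.g. reciprocal best hits) become
anchors `(chr_a, rank_a, chr_b, rank_b)`. Within each chromosome pair
and orientation, chains maximise
`sum(anchor scores) - gap_penalty * sum(rank gaps)` subject to both rank
gaps between consecutive anchors being at most `max_gap`; the dynamic
program is exact and is property-tested against exhaustive enumeration.
Blocks are extracted greedily by descending chain score (an anchor joins
at most one block), extraction stops in a group when the best remaining
chain is shorter than `min_block_size`, and ties break on (score, anchor
count, chromosome names) so output is bit-reproducible.

Defaults: `max_gap 25`, `min_block_size 5`, `gap_penalty 1.0`,
anchor score 1 when the input has no scores. Two stages deliberately
deviate: retention runs use `gap_penalty 0.1` (in fractionated regions
anchors are sparse but still collinear; a harsh per-rank penalty clips
chain ends and biases retention downward), and ancestral-block
partitioning uses `max_gap 0` (exact collinear runs), because with any
positive gap allowance the centre anchor of an odd-length inversion sits
on the main diagonal and gets absorbed by the flanking chain, shifting
inferred breakpoints by one gene. Both choices are plain parameters of
the respective stage.

Classification first computes the dominant chromosome correspondence by
exact maximum-weight one-to-one matching (weights = summed anchors per
chromosome pair), then labels each block: `syntenic` ("+" on a dominant
pair), `inversion` ("-" on a dominant pair), `translocation` (any
orientation elsewhere), `duplication` (over 50% span overlap with a
higher-scoring block on either side). The syntenic depth ratio counts,
for every gene, how many block spans of the other genome cover it; the
modal nonzero coverages are reported as "x:y" with x the modal coverage
of genome-b genes, so (pre-WGT reference, triplicated genome) reads 1:3.

## Ks estimation (NG86)

Coding sequences are translated, globally aligned at the protein level
(BLOSUM62, affine gaps; configurable) and back-translated to codon
columns. Counting follows Nei–Gojobori (1986): per-codon synonymous site
fractions over all single-base neighbours, averaged over the two
sequences; codons differing at several positions are scored by averaging
over all minimal substitution pathways with equal weights. Conventions
that the method leaves open are fixed as: mutations creating a stop
codon count as nonsynonymous (the original convention); pathways through
stop codons are excluded unless every pathway is blocked; codon columns
containing a gap, an N, or a stop are excluded from counting entirely,
so S + N = 3 x (counted codons). Distances use the Jukes–Cantor
correction, `ks = -(3/4) ln(1 - 4 pS / 3)`; `pS >= 3/4` sets a
saturation flag instead of producing a number. The implementation is
tested for exact agreement of S, N, Sd, Nd with an independent
enumeration oracle.

## Peak fitting, rate correction, dating

Ks values inside (0.005, 5.0) — the lower bound excludes allelic/tandem
noise, the upper bound saturation — are log-transformed and fitted with
Gaussian mixtures (scikit-learn EM, k-means++ initialisation, 10 seeded
restarts) for 1..max_components components; BIC picks the component
count. Fewer than 50 usable values or zero variance is refused. The γ
component is the one nearest a prior location (default Ks 1.2); if the
two nearest candidates lie within 15% of each other the choice is
declared ambiguous and must be made explicitly.

Rate correction is a single multiplicative factor per species,
`f = Ks_γ(reference) / Ks_γ(species)`, applied to all of that species'
Ks values; correcting the reference against itself is the identity, and
a refit of corrected values reproduces the reference peak. Dating is
`T = Ks / (2 r)` with the synonymous rate r supplied by the user; the
package infers no absolute rate. For a γ peak at Ks 1.22, dates in the
115–130 Mya range correspond to r between 4.69e-9 and 5.30e-9 per site
per year; the simulation studies use r = 5e-9, which dates Ks 1.22 at
122 Mya.

Whether to fit intra-genomic paralog Ks, inter-genomic ortholog Ks, or
both on real data is left to the caller: both routes
are supported and the pipeline fits whichever pair lists the
configuration provides.

## Retention

A reference gene is retained iff it anchors at least one collinear
block. The denominator is all reference genes (a flag restricts it to
genes inside block spans, since published retention percentages are
ambiguous on this point). Windows are rank-based (default 100 genes,
step 50); with step = window the size-weighted window mean equals the
overall fraction exactly, which is asserted in tests. Under i.i.d.
per-copy survival q in three subgenomes, reference-side retention
approaches 1 - (1-q)^3.

## Ancestral karyotype

Ancestral blocks are the common refinement of all pairwise block
segmentations: every block boundary is expressed as a broken adjacency
between homology families (union-find over anchor pairs) and propagated
across genomes until no genome keeps an adjacency another genome cuts.
Segments are grouped across species by their family signature (up to
reversal); segments supported in fewer than two species, or shorter than
`min_genes`, are dropped with a report. For noisy real data a larger
`min_genes` (order 10) filters micro-blocks; the clean simulation
studies keep every segment (`min_genes 1`) because one-gene segments
between nearby breakpoints are genuine signal there.

Adjacencies between oriented block extremities are counted per species;
with a species tree, a Dollo criterion keeps only adjacencies observed
on at least two sides of the root. Linearisation is greedy
maximum-weight matching on extremities under linearity constraints (each
extremity used once, cycle-closing edges rejected, deterministic
tie-breaks); paths become CARs, isolated blocks singleton CARs, and CAR
orientation is canonicalised since a chromosome has no intrinsic
direction.

Rearrangement classification compares a descendant's ordered oriented
block lists to the CARs. Inversions: within each maximal same-CAR
fragment, count maximal runs of orientation-flipped blocks, taking the
minimum over the fragment read forwards or backwards (reading a whole
chromosome in reverse costs nothing). Fusions/fissions/translocations:
per connected component of the CAR-chromosome incidence graph,
`fission = max(0, chromosomes - CARs)`,
`fusion = max(0, CARs - chromosomes)`; each CAR present on k
chromosomes contributes k-1 inter-chromosomal moves, fissions absorb
their share, and the remaining moves pair into reciprocal translocations
(`ceil(moves/2)`), so an unpaired moved segment still counts once. On a
history of one reciprocal translocation plus one inversion per tip this
reproduces the simulator's event log exactly; compound events sharing
breakpoints can in principle be under- or over-counted, which is why the
recovery study reports per-replicate CAR counts rather than silently
averaging.

## Simulator

The generator emulates the inferred history the pipeline is built to
recover: an 8-chromosome ancestor with uniformly spaced genes; a
whole-genome triplication in which subgenome 0 keeps every gene and each
duplicated copy survives i.i.d. with probability `wgt_retention`
(default 0.3 — heavy fractionation, no subgenome bias; bias would be a
config extension); a star of descendant lineages whose whole root-to-tip
synonymous paths are scaled by per-lineage rate multipliers; and
post-speciation inversions, reciprocal terminal translocations and
optional fusions/fissions, drawn with interior breakpoints and
non-interfering gene sets so each drawn event corresponds to exactly one
recoverable rearrangement. Speciation is treated as recent relative to
the triplication, so paralog and ortholog pairs alike carry γ-depth
divergence — one deep Ks peak per lineage, as observed across such
clades. All stochastic choices are resolved at draw time and stored in
the event log with concrete breakpoints and gene lists; replaying the
log from the ancestor reproduces each tip exactly, and identical
configurations yield byte-identical fixtures.

Sequence divergence is synonymous-only: each codon runs a
continuous-time chain over its amino acid's synonymous codons
(transition:transversion weight kappa, default 2), which can never
create a stop. Because NG86 is mildly non-linear in the substitution
load (twofold-degenerate sites saturate faster than their 1/3-site
weight implies), the chain time is set by inverting the analytically
expected NG86 estimate, computed from the per-amino-acid chain matrices
for a uniform sense-codon root; the realised estimator then matches the
target on average (verified within 5% at 300+ codons in the tests).
Per-gene rate heterogeneity is lognormal with sigma 0.2 on the log-Ks
scale — a free choice, surfaced in the config, in the absence of a
reported empirical dispersion. No indels, no gene-family birth/death
beyond WGT + loss, no composition heterogeneity.

What passing these tests shows — and does not show: the simulator's
genomes have complete, noise-free homology lists, no tandem arrays, no
missing annotation and independent clean events, so recovery here
demonstrates correctness of the algorithms, not robustness to annotation
noise or breakpoint reuse. One confounder is represented honestly:
random breakpoints occasionally collide (the same block adjacency broken
on both sides of the tree root), and such replicates legitimately fail
CAR recovery, which is why the acceptance threshold is 18 of 20 rather
than 20 of 20.

## Problem sizes

The studies run at desk scale by design: genomes of 8 chromosomes x
30–100 genes, coding sequences of 300 codons, ~200–300 Ks pairs per
lineage, 20 replicates for the karyotype recovery study. These sizes
keep every distributional check well-powered (binomial and mixture
tolerances are stated per study) while the full suite runs in well under
a minute per stage.

## Known limitations

- NG86 with JC correction is downward/upward biased in regimes of strong
  transition bias or near saturation; no maximum-likelihood codon model
  (YN00-style) is provided.
- The Gaussian-mixture-on-log-Ks peak model can split a single skewed
  empirical peak into a dominant and a small tail component; the γ
  designation then follows the component nearest the prior, which can
  shift the reported peak a few percent from the distribution centre.
- Rate correction is strictly linear (one factor per species), exactly
  as strong as the shared-event benchmark assumption and no finer.
- The karyotype module assumes an essentially 1:1 homology structure
  (post-fractionation single-copy regions); it does not assign
  subgenomes or compute DCJ distances, and it infers no event order
  along a branch.
- Homolog detection is an input, not a stage: the package never runs
  BLAST/DIAMOND and treats pair lists as given.
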