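# Methods

## Best-hit classification

Each query gene's hits are filtered at an E-value threshold (default
`1e-5`; "significant hit" admits no canonical value, so the threshold is a
parameter and is echoed in every report header), collapsed over subject
isoforms to distinct subject *genes* (per gene, keep the maximum bit score
and, among equal scores, the minimum E-value), ranked, and truncated to the
three best subjects. Ranking ties are broken deterministically: bit score
descending, E-value ascending, subject gene id ascending. Two ordering
decisions deserve note:

* **Collapse before ranking.** Isoform hits are merged into their gene
  before the three best subjects are picked, so a gene with many isoform
  hits cannot crowd out other subjects. The alternative order (rank raw
  hits, then collapse) changes "total" counts when isoform hits dominate; a
  sensitivity analysis only needs a different `protein_to_gene` map.
* **Solo before truncation.** A query is "solo" iff it has exactly one
  distinct significant subject *before* truncation: a query with four weak
  distinct subjects is not solo. This is forced by the definition of a solo
  gene as one whose similarity is confined to a single subject gene.

"Total" counts query genes once per subject chromosome (a query with two
of its three best subjects on one chromosome contributes 1 there, not 2).
Per query chromosome the invariants Σ top = number of queries with hits,
Σ solo = number of solo queries, Σ total ≤ 3 × queries-with-hits are
enforced by `CountMatrix.validate()`.

Monotonicity caveat: tightening the threshold can only shrink top/total
counts when E-values are monotone in bit score (true of real search output
and of the simulator). "Solo" counts are *not* monotone in the threshold in
either direction: a two-subject query becomes solo when its weaker subject
drops out.

## Chromosome association

Given two query chromosomes and the two WGD-derived subject chromosome
groups, one column (top/total/solo) of the count matrix is pooled into a
2×2 table; subject chromosomes outside both groups are ignored. The test is
the Pearson chi-square with one degree of freedom, **without** Yates
continuity correction — on these pooled tables the corrected statistic
differs in the first decimal, and the uncorrected form is the one whose
values this pipeline reproduces and reports (statistics at 2 decimals,
p at 3, percentages at the nearest integer).

`monte_carlo_p` provides a simulation check of the p-value. Two nulls are
offered: the unconditional multinomial independence model (the sampling
model the χ²(1) reference distribution approximates; agreement is within
Monte-Carlo error at the table sizes involved here) and the conditional
both-margins-fixed hypergeometric (label-permutation) null. The conditional
null is exact but discrete: on any fixed table its p differs from the
asymptotic value by more than Monte-Carlo error, which is a property of
conditioning, not an implementation artifact — hence the unconditional
model is the default for approximation checks.

Group fractions (`fraction_on_group`) are percentages of a column falling
on a named chromosome set, with the denominator over *all* subject
chromosomes; `count_group_sum` is the integer numerator.

## Local synteny

Neighborhoods are ±`half_width` genes (default 5) around an anchor, by
coordinate rank; truncation at chromosome ends is recorded, not padded.
Flanking genes map to their single best subject under the classifier's tie
rules. Homology *families* are connected components of the best-hit links
restricted to the compared neighborhoods, so two near-identical subject
genes merge into one family exactly when the hits link them.

Order congruence of two neighborhoods is |Kendall τ| over the shared
families (ordered by first occurrence), so an exactly reversed block — a
chromosomal inversion — scores 1. Orientation consistency is judged in the
frame of the better-aligned direction: when τ < 0 the block is treated as
inverted and *flipped* relative orientations count as consistent, so a
clean inversion scores 1 on both measures.

Conserved blocks are maximal tuples of families occurring as consecutive
family-labelled genes — with at most `gap_budget` (default 2) unlabelled
genes between neighbours, since real blocks are interrupted by genes
without informative hits — forward or reversed, in at least `min_members`
neighborhoods. A block is suppressed when its family tuple is a sub-run of
a longer reported block with at least the same member set. Candidate
generation enumerates windows of each neighborhood's family runs, which is
exhaustive at neighborhood scale (≤ 11 genes); the test suite checks
equivalence against a brute-force subsequence enumeration.

## Loss scenarios and the solo-gene bias

The enumerator models one ancestral gene through WGD1 (copies 0 and 1), the
lineage split, and gnathostome WGD2. The observed query (agnathan) gene
descends from copy 0 without loss of generality — the model is symmetric in
the copy labels. Each loss event strikes a uniformly chosen surviving copy
in its lineage/epoch; branches are conditioned on the query's copy
surviving all shared losses and on exactly one human survivor. This yields
exact rationals: P(ortholog) = 1 under the shared-loss scenario (a), 1/2
under the two lineage-specific scenarios (b, c); scenario (c) needs three
losses, so with per-event loss probability p its relative weight is lower
by a factor p.

`simulate_solo_bias` demonstrates the aggregate bias on full genomes: WGD1,
a shared loss epoch, the split, a query-lineage loss epoch, and a subject
lineage with loss–WGD2–loss (so all three scenario types arise), all at the
same retention rate. Hits are noise-free (score = base − decay·depth, so
ranking is exact) and classified by the production classifier. The solo
fraction is the share of solo queries whose unique match is a true
ortholog; the non-solo fraction is computed over non-solo queries' listed
best matches (per match, not per query), because a *single* match of a
multi-match query carries no information about which copy is the ortholog —
that contrast, not top-hit accuracy, is what makes solo genes useful
markers. With perfect ranking the top hit of a multi-match query finds a
surviving ortholog essentially whenever one exists, so a per-query top-hit
comparison would not measure the marker property at all.

## The simulator

* **Events.** WGD (integer multiplier m ≥ 2; hexaploidization is m = 3),
  chromosome fusion (concatenation of gene orders), loss epochs
  (i.i.d. per-copy survival with retention r, overridable per chromosome —
  preferential retention is expressed as unequal r, and r = 0 on a named
  chromosome gives deterministic copy loss), and transposition epochs (each
  gene moves with probability q to a uniform chromosome and position,
  keeping its strand with probability 1/2).
* **Depth and orthology.** Epochs are numbered globally (shared events,
  then the split, then lineage events). A cross-genome pair is an ortholog
  iff the two genes carry the same copy index at every pre-split WGD;
  divergence depth is `total_epochs + 1 − divergence_epoch`, an ordinal
  quantity — only the ordering of depths matters to best-hit structure, so
  continuous divergence times would add parameters without changing any
  downstream behaviour.
* **Similarity.** Scores are modelled directly in bit-score space
  (base 200, decay 10 per epoch, optional Gaussian noise, significance
  floor 40 bits, E = 10⁹·2^(−score), strictly decreasing); no sequences are
  evolved. Two independent seeds separate history from hit noise, so the
  same history can be re-scored.
* **I.i.d. losses** are the simplest exchangeable loss model; the true
  retention process after WGDs is biased by dosage constraints, and the
  simulator makes no attempt to model that beyond per-chromosome retention
  overrides.

What passing simulation-based tests shows — and what it does not: the
simulator reproduces the *combinatorial* structure of post-WGD genomes
(copy genealogies, losses, order, orientation) under known ground truth, so
it validates the counting, ranking, pooling and testing machinery. It does
not model sequence-level effects (alignment quality, compositional bias,
rate variation among genes, hit E-values correlated between paralogs), so
agreement on simulations does not by itself certify behaviour on real
BLAST output — the packaged real count matrix serves as the regression
anchor for that.

## Problem sizes and test design

The statistical acceptance checks run at the following scales, chosen for
statistical power at interactive runtimes: count-matrix invariants on 100
simulated replicates of a 40-gene two-chromosome ancestor; chi-square
closed form vs the Σ(O−E)²/E oracle on 300 random tables (tolerance 1e-9)
and vs a 100,000-draw Monte-Carlo null within 3 standard errors; parameter
recovery on 100 replicates of a 500-gene ancestor (400 signal + 100
unrelated genes, retention 0.6, score noise 6 bits), requiring null
rejection at α = 0.05 in ≥ 90 replicates; scenario Monte-Carlo at 10⁴
trials within 3 binomial SEs; solo-bias enrichment on a 20,000-gene
ancestor at retention 0.5 (an expected solo-vs-non-solo gap of ~0.07 needs
a combined standard error well under 0.023 for a 3-SE criterion).

## Known limitations

* The agnathan hexaploidization is modelled as a single m = 3 WGD
  (autopolyploid-like); an allopolyploid origin would give the three copies
  unequal divergence depths, which the event model cannot express.
* Fissions are not modelled (only fusions), so a chromosome group larger
  than a WGD multiplier cannot arise within one lineage; the parameter
  recovery experiment emulates the mixed-origin human chromosomes with a
  fusion instead.
* One protein per gene in the simulator; isoform collapse is exercised only
  through explicit protein→gene maps in tests.
* `closest_paralog_counts` attributes each gene to the chromosome of its
  single best non-self hit; it does not attempt synteny-aware paralogon
  assignment.
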