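# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; GFF3 (1-based closed) and
RepeatMasker `.out` are converted at the I/O boundary. A gene belongs wholly
to the chromosome named in its record, and every synteny statistic operates
on per-chromosome gene *ranks* (order by ascending start; ties broken by
end, then gene id), never on base-pair positions — macrosynteny is about
content and order, not physical distance. Strand is stored but ignored by
the assignment statistic. Repeat classes outside DNA/LTR/LINE/SINE are
dropped with a tally rather than raising, since repeat annotations contain
many minor classes the analysis does not count.

## Ortholog pairing and block chaining

`compute_rbh` keeps a hit iff it is the unique best for both its query and
its target and its C-score — score divided by max(best-of-query,
best-of-target) — reaches `c_score_min` (default 0.99, i.e. reciprocal best
hits with ≤1% slack). Ties for best are dropped entirely: arbitrary
orthology is worse than missing orthology. Block chaining works in rank
space: the longest collinear chain (monotone on both genomes, consecutive
rank gaps ≤ `max_gap` on both) is found exactly by O(n²) dynamic
programming, extracted, and the search repeats; display blocks use
`min_pairs=4`, `max_gap=75`, while chromosome-assignment mode uses a single
pair with no window. Tandem duplicates are not collapsed before chaining.

## Chromosome homology assignment

Each chromosome pair is tested with a two-sided Fisher's exact test on its
2×2 ortholog table. The test sums hypergeometric point probabilities
(scipy's pmf) of all tables at least as extreme as observed, with a 10⁻¹²
relative tolerance on the point-probability comparison so float rounding
cannot flip a boundary table. Bonferroni uses m = nA×nB tested pairs.
Direction is enforced by the risk difference a/(a+b) − c/(c+d) > 0; tiers
are strong (p_adj < 1e-10) and weak (1e-10 ≤ p_adj < 1e-2). Unplaced
scaffolds can be excluded from the tested chrom_b candidates while still
counting in the b/c/d margins. Weak-tier edges are never promoted to
fusion/split operands; they are reported as small-scale-rearrangement
annotations only.

## Rearrangement calls and fusion geometry

Strong-tier assignments form a bipartite correspondence graph; degree
patterns give one-to-one, fusion (degree ≥ 2), split (mirror pattern) and
dispersal (degree 0 with orthologs scattered such that no partner holds
≥ `max_frac` = 0.3 of them — the 0.3 keeps a two-way split from being
misread as dispersal). Fusion geometry uses the runs statistic over the
gene-order source labels. Because ortholog noise paints isolated wrong
labels onto an otherwise clean chromosome, single-gene runs are discounted
first, but only while they make up under 10% of anchors — a genuinely
interleaved (mixed) sequence is never smoothed. Then: ≤2 runs ⇒ end-end;
exactly 3 runs with the minority source internal and ≤40% of anchors ⇒
centric insertion; otherwise mixed when the normalized runs index
(runs−1)/(n−1) ≥ `mix_threshold` = 0.2. The 0.2 threshold and the
singleton rule are declared conventions formalizing what is otherwise a
visual dot-plot judgement; synthetic genomes with known geometry are the
calibration, not any real dataset. Polarization follows outgroup logic: if
the outgroup holds a fusion's operands on distinct chromosomes the fusion is
derived in the fused lineage; a fused outgroup leaves the call unresolved,
and polarity is never assigned without outgroup edges.

## ALG event algebra and parsimony

States are sets of chromosomes, each a head-to-tail tuple of units (single
groups, mixed amalgams, or declared split parts). Fusions concatenate units
(end-end, centric) or collapse them into one mixed unit (⊗); fissions take
declared products; dispersal retires a whole composition. Chromosome counts
obey 24 − Σ(k−1 fusions) + Σ(products−1 fissions) − #dispersals, which is
property-tested against replay. Splitting a mixed chromosome (the
hemichordate B2⊗C2 case) necessarily places parts of both source groups in
both products, so split units carry the full label set with a split marker;
label conservation is checked as presence, with multiplicity allowed only
through declared fissions. An ALG is censused *intact* only if it sits alone
on an unfused, unsplit, undispersed chromosome in every leaf.

Ancestral reconstruction treats each unordered ALG pair's co-residency as a
binary character: mixed co-residency under Dollo (fusion-with-mixing cannot
revert — one gain, losses only), unmixed co-residency under Fitch (root
ambiguity resolved toward the outgroup state). Internal states are the
connected components of reconstructed pair relations; non-transitive
co-residency is reported as a conflict, never silently repaired. The
vertebrate B1⊗B2⊗B3 fusion is encoded as a single three-way event (count
change −2), matching how the histories record it.

The shipped history fixtures (`fixtures/*.yaml`) are data, not code: a
rooted newick tree, the 24 root labels, and per-branch event lists for the
deuterostome, sea-urchin and spiralian histories. The sea-urchin fixture
orders the shared E⊗(B2⊗C2) fusion before J1↘B3, reflecting the more
advanced mixing of the former. Where a history is ambiguous the fixture
commits to the documented reading (e.g. the SCO5/SCO17 chromosomes are
encoded as a fusion followed by a split rather than a duplication).

## Synteny characters, distances, and the Mk2 sampler

The category encoder names each chromosome's event composition canonically
(⊗/●/↘ symbols, operands in recorded order); nested earlier fusions are
recorded as their own categories for every species that carries them, so a
doubly fused chromosome contributes both its early and late event. Split
products contribute one split category per source. Binarization makes one
column per category; a fusion joining k groups would otherwise appear k
times, so de-duplication keeps one column per distinct category name.
Distances are the asymmetric binary (Jaccard) form — mismatches over
columns where either species scores 1 — with pairs lacking informative
columns reported as missing. Clustering is agglomerative with complete
linkage (configurable), tie-broken by label order.

The tree sampler is a deliberately minimal Bayesian MCMC over unrooted
topologies and branch lengths: two-state symmetric (Mk2) pruning
likelihood, exponential(10) branch-length prior, uniform topology prior,
alternating branch-length multiplier and NNI proposals, majority-rule
consensus splits after a 25% burn-in, fully seed-reproducible. It is
validated on four taxa against per-topology marginal likelihoods estimated
by prior Monte-Carlo with an independent closed-form likelihood. It makes
no claim to numerical identity with any external phylogenetics program;
the scientific check is clade recovery, not posterior equality.

## TE density

A TE is counted by its start coordinate (counts, not length-weighted) into
10-kb or 50-kb bins; densities are normalized to counts per 10 kb so
regions of different length are comparable. The cluster contrast reports
cluster density, same-chromosome non-cluster density, and the percent
difference (non-cluster − cluster)/non-cluster × 100, positive when the
cluster is TE-poor. Cluster spans default to the first-to-last member gene
with zero flank; assembly gaps are not masked.

## Microsynteny

Two family members are linked when they share a chromosome with at most
3 intervening non-family genes — the operational reading of the
"double-slash" display convention; same-chromosome-but-distant and
cross-chromosome pairs are reported as separate tiers rather than merged.
Family membership is input data (orthology curation is out of scope).
Ancestral block presence uses the same Dollo/Fitch machinery as the ALG
characters.

## Synthetic genomes and what they do (not) show

The simulator evolves a root genome of `n_alg` chromosomes ×
`genes_per_alg` genes (defaults 24 × 150, the scale at which a strong-tier
call survives a fission product's minority share) along a tree.
Fusion-with-mixing applies `mixing_rounds` = 200 random within-chromosome
inversions and reciprocal translocations — local mixing, not genome-wide
shuffling. Centric fission cuts in the central 20–80% span (a centromeric
break yielding two viable chromosomes). Dispersal scatters genes uniformly.
Per-branch gene loss is 5%; ortholog misannotation reassigns 2% of pairs
cyclically (preserving one-to-one), chosen to stress but not break the
strong tier. Gene identifiers encode lineage and ancestral group for truth
auditing, and identical seeds give identical output.

Synthetic genomes have uniform gene spacing, equal chromosome sizes, no
tandem duplication, no missing assembly regions and no annotation-quality
gradients. Passing recovery tests therefore shows the inference chain is
correct under its own model assumptions; it does not certify performance on
real assemblies, where ortholog error is structured rather than uniform.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale instances: six-leaf histories at
12 × 150 genes over 50 seeds for end-to-end recovery, 12 × 200 genes over
100 seeds for pattern classification, exact-test enumeration up to table
total 30, chaining oracles up to 15 anchors, 4-taxon samplers at 4,000
retained samples and the ten-species matrix at 3,000. Exact-test point
probabilities are compared with 1e-12 relative tolerance; MCMC-vs-exact
checks allow Monte-Carlo error of ±0.05–0.06 in posterior frequency.

## Known limitations

Breakpoint positions are not localized in base pairs; partial dispersal and
automatic fission-partition inference are not modeled; Bonferroni is the
only multiplicity correction; the centric-vs-translocated distinction is
heuristic at exactly three runs; and an insertion landing at a host
chromosome's tip is genuinely indistinguishable from an end-end fusion, so
geometry subtypes at tips can swap while the fusion itself is still
recovered.
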