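# Methods

This note documents the statistical models, numerical policies and design
choices behind `mitonuc`, and what its synthetic validation does and does
not establish.

## Allele-sharing distance

For two individuals genotyped at the same sites, divergence is the number
of allele differences divided by the number of alleles compared. For
unphased diploid genotypes the per-site contribution is
`|dosage_a − dosage_b|` — the minimal number of mismatched alleles over all
pairings of the four alleles, so phase never enters. Haploid (mtDNA)
profiles contribute `1[a ≠ b]` per site. Normalization is by `2n` alleles
for diploid and `n` for haploid data; the choice is recorded in the
distance matrix metadata.

Missing genotypes use pairwise-complete deletion: a site missing in either
member of a pair is removed from numerator and denominator for that pair
only. A pair with no shared genotyped site has no defined distance and is
an error, not a silent zero. Because different pairs may use different site
subsets, the dissimilarity need not satisfy the triangle inequality; this
is documented rather than asserted, and nothing downstream assumes
metricity. No minor-allele-frequency or missingness filtering is applied by
default; both would be cohort-level preprocessing outside the distance
definition.

## Classical MDS

Projections use classical/Torgerson scaling, not stress minimization: the
method is deterministic, exact for Euclidean-embeddable inputs, and the
standard tool for visualizing an allele-sharing matrix. The Gram matrix
`B = −½ J D² J` is symmetrized before `eigh` to average numerical
asymmetry. Eigenvalues are reported in descending order; coordinates are
eigenvectors scaled by `√λ`. Negative eigenvalues inside the requested `k`
(allele-sharing matrices are not guaranteed Euclidean) yield zero-filled
axes and set a `negative_axes` flag; eigensolver noise within
`1e-9 · max|λ|` of zero is clipped silently. Axis signs are arbitrary; the
canonicalization helper fixes each axis so its first nonzero coordinate is
positive, keeping plots and regression tests stable. Eigen-ties keep input
order.

## Neighbor joining

Standard Saitou–Nei agglomeration, O(n³) with a warning above 3,000
leaves. Two policies make output byte-deterministic and well-formed:
argmin-Q ties break on the lowest (row, column) pair in the current active
ordering, and negative computed pendant lengths are clamped to zero with
the deficit transferred to the sibling branch so the cherry's total length
is preserved (common practice in distance-tree software). On additive
inputs NJ reconstructs topology and branch lengths exactly; this is the
basis of the oracle tests.

A cherry is an internal node with exactly two leaf neighbours. The
definition is applied to the tree as represented: a rooted Newick parsed
with its degree-2 root retained classifies `(((A,B),C),D)` as having the
single cherry {A,B}, while the 3-leaf star has none (its one internal node
has three leaf neighbours, so no pair is privileged). NJ output contains no
degree-2 nodes, so pipeline behaviour never depends on this subtlety.

## Haplogroup calling

A sample's derived-variant set `O` is scored against every node's
cumulative defining-variant set `E` (union over the root→node path) with
the unweighted Kulczynski similarity `½(|O∩E|/|E| + |O∩E|/|O|)`. The root
has empty `E`; its completeness term is defined as 1, so an empty profile
deterministically calls the root ("reference", rCRS-like). Ties break
toward greater depth (the more derived call), then lexicographically.
Production haplogroup callers weight variants phylogenetically; weighting
is deliberately out of scope — the fidelity target is recovery of planted
truth, not concordance with any specific caller. Back-mutations are not
modelled; an expected-but-absent variant simply lowers the completeness
term. Variants at positions no tree edge uses count as private and lower
the `|O∩E|/|O|` term equally for all candidate nodes.

The bundled tree is an explicit fixture: topology follows the canonical
human mtDNA macro-structure — L0, L1, L5 branching basally; L2 and L3'4
next; M, N and R (with H, U, K, T, J, B, F, A, D, G) under L3 — but every
defining-variant position is invented. Real haplogroup tables in the same
TSV format (parent, child, `pos:alt` list, origin, macro) can be swapped
in. Path distances between haplogroups are edge counts on this tree.

## Concordance statistics

Spearman ρ is computed as the Pearson correlation of average ranks; the
p-value uses the t-approximation, or exact permutation for n ≤ 8. Pairs of
a distance matrix are not independent observations, so the plain
coefficient (matching standard practice for this analysis) is the primary
output and an optional Mantel-style permutation test — permuting the sample
labels of one matrix, seeded — provides a permutation p-value labelled as
such.

Rank distance-differences: both condensed pair vectors are ranked with
average ranks under ties; the per-pair difference is normalized by the pair
count P so cohorts of different sizes are comparable. The raw rank
differences sum to exactly zero (half-integer arithmetic is exact in binary
floats); the normalized sum is zero to ~1e-9 because dividing by P is not
exact.

Outlier pairs standardize the differences by their own mean and SD and
flag |z| above a threshold, default 3 (the reference analysis displays but
does not threshold its outliers, so the cutoff is an explicit, configurable
parameter). Two caveats matter at desk scale: the statistic's support is
bounded (|diff| < 1) and tie-compressed, and heavy contamination inflates
the SD it is standardized by. In 300-sample cohorts with 10% planted
cross-continental lineages the contaminated pairs top out at |z| ≈ 2.9, so
detecting them requires a threshold slightly below the default (2.5 in the
acceptance suite); at cohort scales of thousands the default is
appropriate. A zero-variance difference vector yields a warning and no
outliers.

## Synthetic cohorts

The generator emulates a 1000 Genomes-style cohort. Nuclear sites are
independent bi-allelic SNVs under Balding–Nichols drift: ancestral
frequency `p ~ Uniform(0.05, 0.95)` per site, population frequency
`Beta(p(1−F)/F, (1−p)(1−F)/F)` so that `E = p`, `Var = F·p(1−p)`; `F = 0`
bypasses the degenerate Beta. Unadmixed dosages are `Binomial(2, p_pop)`;
admixed individuals draw ancestry proportions from a Dirichlet and then
each allele from a population chosen by those weights.

Each sample's mtDNA haplogroup is a categorical draw from its population's
frequency vector, except: admixed samples first draw a single maternal
population from their own ancestry proportions (one lineage, not a
mixture), and unadmixed samples defect with probability `cross_mt_rate` to
a uniformly chosen foreign continental group, drawing from that group's
average frequency vector. The haplotype is the exact union of defining
variants on the root→haplogroup path plus Poisson(`private_mut_rate`)
private variants placed only at positions no tree edge uses — so planted
haplogroups remain uniquely recoverable and recovery failures indicate
caller defects, not construction ambiguity. The mismatch flag is true iff
the maternal origin group differs from the group of the majority-ancestry
population (argmax ties resolve to the lexicographically first group, for
determinism). All randomness flows from one integer seed through named
substreams, so nuclear and mtDNA stages are individually reproducible.

Reduced panel mode emulates SNP-array resolution by masking all but a
retained site set; the default retention is the defining variants of the
tree's macro-backbone edges (23 of the fixture's 48 positions — a
scaled-down analogue of array panels that type ~4% of the variants a
sequence-based analysis sees). Calls then collapse to backbone nodes but
preserve macro-level assignment.

Defaults of the bundled demo (6 populations × 50 samples, three
continental groups, `F = 0.1`, 1,000 nuclear sites, two haplogroups per
population, `private_mut_rate = 2`, `cross_mt_rate = 0.1`) are chosen as a
realistic continental-scale miniature: F ≈ 0.1 matches human
between-continent differentiation, and 10% cross-continental maternal
lineages plants enough mismatches to exercise every detector. 1,000
independent sites keep runtime in seconds; real cohorts have millions of
correlated sites, so absolute ρ values here (~0.2–0.4) sit well below
sequence-scale analyses (~0.5) because nuclear distances carry far more
sampling noise per pair.

Not simulated: recombination, linkage disequilibrium, selection,
heteroplasmy, multi-allelic sites, indels, back-mutation. A green test on
synthetic data therefore establishes algorithmic correctness and
end-to-end consistency, not robustness to the full messiness of real
call sets.

## Pipeline and reproducibility

`pipeline.run` executes all stages from a single config (either a
simulation block or input file paths, never both) and writes a manifest
with the config hash, seed and SHA-256 of every output file. Output floats
are formatted with `%.10g`, nothing reads wall-clock state into results,
and identical configs give byte-identical outputs. Stage failures abort
with the stage name attached.

## Known limitations

- The haplogroup scorer is unweighted; real data with recurrent mutations
  and back-mutation would need phylogenetic variant weighting for
  caller-grade accuracy.
- Distances are O(n²·sites) in memory-friendly row chunks but NJ is O(n³):
  cohorts beyond ~3,000 samples need subsampling or population-level trees
  (`gendist.mean_population_distances` aggregates a sample matrix to mean
  between-population distances for that purpose).
- The matched/mismatched rule treats continental group labels as
  authoritative input; for groups that are themselves admixed the
  source-origin declaration must be supplied explicitly rather than
  inferred.
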