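# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Ortholog clustering

Protein pairs are scored by exact Smith–Waterman local alignment with
BLOSUM62 and affine gaps (open 11, extend 1: a gap of length *k* costs
11 + (k−1)). Two interchangeable engines implement the same scoring
contract: Biopython's `PairwiseAligner` behind the public `sw_score`, and a
numba-compiled Gotoh dynamic program behind the graph builder, which also
returns the aligned extent on the shorter sequence in the same pass. The
two routes are cross-checked against each other and against an independent
plain-Python DP oracle in the test suite. When co-optimal alignments
exist, engines may report different (equally optimal) aligned spans; only
the score is unique.

Edge weights are self-score-normalized, *w(a,b) = SW(a,b) /
min(SW(a,a), SW(b,b))*, which is scale-free in sequence length and bounded
by 1; an edge is kept when *w ≥ min_norm_score* (default 0.4) and the
aligned span covers at least *min_coverage* (default 0.5) of the shorter
sequence. The coverage condition stops short local matches (domains,
repeats) from gluing unrelated families together. A seeding prefilter
skips alignment for pairs sharing fewer than max(3, 5% of the shorter
sequence's k-mer count) 4-mers; at the divergences where an edge could
pass the weight threshold, true pairs share far more. Pass
`prefilter_k=None` to force exact all-vs-all scoring.

Markov clustering is implemented from scratch: self-loops at each node's
maximum incident weight (floor 1e-6), column normalization, then repeated
expansion (*M ← M·M*) and inflation (element-wise power *r*, pruning of
entries < 1e-5, renormalization) until the largest entry change falls
below 1e-6 or 100 iterations pass (non-convergence returns the current
partition with a warning). Clusters are the connected components of the
converged matrix's nonzero structure; since MCL can never connect nodes in
different components of the input graph, the algorithm runs per component,
which bounds the dense matrices by component size. Inflation defaults to
1.5, the customary orthology setting; higher values fragment clusters
more. Cluster count is not guaranteed monotone in inflation and is not
asserted anywhere. All tie-breaks (cluster ids, OG ids) are lexicographic
in gene id, so output is deterministic.

A strain's state in an OG is `present` if it has an intact member,
`pseudo` if all its members are pseudogenes, `absent` otherwise.

## Pseudogene calling

A gene is flagged a pseudogene on read when its protein carries an
internal stop, and after clustering when its protein is shorter than
`length_fraction` (default 0.8) times the median length of its OG's intact
members — the operational meaning of "encodes an incomplete protein". OGs
with fewer than 3 members get only the internal-stop rule; a median over
two values says nothing about which one is truncated.

## Pan/core rarefaction

Pan(k) counts OGs carried by at least one of the first k strains of a
random ordering; core(k) counts OGs carried by all k. Pseudogene cells
count as carried: the pangenome is the set of gene families a gene caller
found, independent of whether every copy is still intact. The
`require_intact` switch tightens core membership to intact copies.
Defaults: 500 sampled orderings, explicit seed. Both curves are monotone
along every single ordering, and their endpoints are
permutation-independent; the test suite checks the sampled machinery
against exhaustive enumeration of all N! orderings at small N. The
"levels off" point is reported descriptively as the first k whose mean pan
increment drops below 0.5% of the total, never asserted.

## Core-SNP phylogeny

Single-copy core OGs (exactly one member in every strain, intact or
pseudo) supply the phylogenetic signal. Within each OG the nucleotide
sequences must arrive aligned (equal length; the pipeline never aligns —
simulated data is ungapped by construction, real data needs an external
aligner first). Columns containing gaps or ambiguity codes are dropped
entirely; remaining columns with at least two distinct residues are
concatenated in (sorted OG, column) order into one "artificial sequence"
per strain.

Distances are p-distances (fraction of differing supermatrix columns),
optionally Jukes–Cantor corrected (−3/4 ln(1 − 4p/3); an error above
p = 0.75 where the correction diverges). p-distance matrices can violate
the triangle inequality; nothing downstream assumes it.

Tree inference is Saitou–Nei neighbor joining, written here rather than
borrowed so that the contract is exact: Q-criterion ties break toward the
lexicographically smallest pair of smallest-descendant-leaf labels, and a
negative pendant branch is clamped to zero with the deficit moved to its
sister so the joined pair's path length is preserved. NJ is exact on
additive matrices — verified on noiseless patristic distances (topology by
Robinson–Foulds distance 0, lengths via the induced tree metric to 1e-9) —
and is cross-checked topologically against scikit-bio's independent NJ on
perturbed matrices. Re-rooting requires the outgroup to be one side of an
existing branch (checked; a named error otherwise) and splits that branch
length equally. An approximate maximum-likelihood tree could replace NJ
for real data; at the divergences this package targets, topology recovery
is distance-limited, not model-limited.

## Plasmid calling

A strain's chromosomal baseline is the length-weighted median of its
contig depths — robust both to plasmid contigs (usually a small minority
of the assembly length) and to short repeat-heavy contigs. A contig is
called plasmid when depth/baseline ≥ `min_ratio` (default 1.5, below
typical lactococcal plasmid copy numbers ≥ 2) and its length is ≥
`min_length_bp` (default 2000; shorter contigs are dominated by repeats).
User-supplied repeat flags (rRNA operons, IS elements, prophages) force
`unclassified`, standing in for manual inspection. Calls depend only on
depth ratios, so uniformly rescaling a strain's depths changes nothing.
An OG is plasmid-origin when at least half its member genes lie on
plasmid-called contigs; ties go to plasmid, since a family seen at
elevated coverage anywhere usually is a mobile element.

## Gene-trait matching

For a binary label (A/B, missing allowed), each OG is scored under two
orientations. Under "present → A", errors are presences in B plus
absences in A; pseudogene cells are compatible with both states and
contribute no error under either orientation. The score is
1 − min(e_A, e_B)/n with n the number of labeled strains. Normalizing by
all labeled strains (rather than by non-pseudo strains) keeps pseudogene
neutrality monotone: converting any cell to pseudo can only remove errors,
never shrink the scale, so genome erosion cannot lower a marker's score.
The n_labeled denominator also means a score of 1 is attainable with
pseudo cells present, which is the intended reading of "intermediate
state".

Significance: the label vector is permuted as a whole B times (default
999; at least 99 enforced), preserving the correlation structure across
OGs, and p = (1 + #{permuted score ≥ observed})/(B + 1). The smallest
attainable p is therefore 1/(B+1), reached exactly when no permutation
reproduces the split — with few labeled strains or a very unbalanced
split, an occasional permutation can match it and p rises accordingly.
Benjamini–Hochberg q-values (statsmodels) are computed over all tested
OGs; note that a single perfect marker among m OGs cannot fall below
q = m/(B+1) — the permutation floor times the number of tests.

Leave-one-out prediction: for each held-out labeled strain, each selected
marker refits its orientation on the rest, then votes from the held-out
strain's state (pseudo abstains, absence votes the opposite class);
majority wins, ties and all-abstain default to class A with a warning.
The marker set for heatmaps and prediction is every score-1.0 OG when any
exist, else the top 50 by rank.

Heatmap ordering is complete-linkage agglomerative clustering on Manhattan
or Euclidean distances over the numeric encoding absent 0 / pseudo 0.5 /
present 1 (the 0.5 encoding is used for distances only, never for
scoring). The merge loop is written out so ties break toward the smallest
cluster indices; it is verified against brute-force linkage enumeration
and scipy's implementation.

## Synthetic data generator

The generator emulates a two-subspecies strain collection and is the
package's ground-truth instrument; its defaults are the study conditions
under which the acceptance checks run.

- **Phylogeny**: Yule (pure-birth) topology, ultrametric, normalized to
  unit root-to-tip depth; the first split defines clades A and B
  (the subspecies analogue). Topologies are rejection-sampled
  (deterministically, from seeds derived from the configured seed) until
  both clades have ≥ 2 leaves — a one-strain "subspecies" cannot be scored
  as a trait — and every internal branch is ≥ `min_internal_branch`
  (default 0.01) of the depth. Pure-birth trees routinely contain internal
  branches carrying well under one expected substitution at desk-scale
  sequence lengths; such branches are unresolvable in principle and do not
  represent the well-separated clades being emulated.
- **Core genes**: `n_core_ogs` = 30 unlinked genes of `gene_length_bp` =
  900 (the typical bacterial CDS is ~300 codons), each evolving by
  Jukes–Cantor substitution: on a branch of length d the per-site
  substitution probability is 3/4(1 − e^(−4·d·rate/3)) with uniform
  choice among the three other bases — the exact JC transition kernel, so
  branch composition is exact and the leaf-pair p-distance has the closed
  form the tests and acceptance script check against. Root sequences are
  uniform sense codons; substitutions creating in-frame stops are redrawn.
  `subst_rate` = 0.05 expected substitutions/site over unit depth puts the
  maximum pairwise core divergence near 10%, in line with within-species
  diversity of a broadly sampled bacterial species.
- **Markers**: 3 accessory families per clade present in exactly that
  clade, and 3 niche families present in exactly the dairy strains. The
  dairy niche is clade A plus a fraction (default 0.25) of clade B,
  mimicking dairy-adapted strains of the other subspecies, so niche and
  genotype are correlated but not identical. Accessory sequences are
  random and unrelated to the core, so similarity clustering separates
  them without tuning.
- **Pseudogenization** is concentrated in the larger subclade of clade A
  (the eroded-dairy-genome analogue): each (strain, core OG) pair there is
  independently hit with probability `pseudo_fraction` = 0.3, replacing
  the codon at a uniform 30–70% position with a stop. The nucleotide
  sequence keeps its length (so core alignments stay gap-free); the
  emitted protein is the truncated prefix, which the pipeline's
  length-based pseudogene caller must rediscover.
- **Plasmids**: 5 accessory families carried by the dairy strains on a
  dedicated 50 kb contig at `coverage_multiplier` = 5 times the 50×
  chromosomal base depth; optional Gaussian depth noise (default 0).

Everything derives from one seed; emitted datasets are byte-identical
across runs. What the generator does **not** emulate: gene order and
synteny, recombination, insertion-sequence dynamics, gapped alignments,
annotation error, draft-assembly fragmentation, and copy-number variation
beyond single-copy core genes. Passing tests on this generator therefore
demonstrate correctness of the algorithms under clean, identifiable
conditions — not robustness to the full messiness of draft genomes.

## Problem sizes

The default simulated collection is 12 strains × (30 core + 11 accessory)
families; end-to-end validation runs 20 such collections, and the marker
analysis uses a 20-strain collection with 999 permutations. These sizes
make every stage's behavior checkable against enumeration or closed forms
while keeping a full validation run around a minute on one CPU.

## Known limitations

- The orthology step is one-pass MCL on the normalized similarity graph;
  the ortholog/in-paralog/co-ortholog edge re-weighting of full OrthoMCL
  is not reproduced, so fine paralog resolution is out of scope.
- Heatmap ordering and trait scoring assume binary labels; multi-class
  traits must be one-vs-rest encoded by the caller.
- NJ with p-distances underestimates long-branch lengths; use the JC
  correction flag when divergences approach saturation.
- The plasmid caller sees only mean contig depth; composite contigs
  (chromosome–plasmid misassemblies) and integrated elements are beyond
  its signal.
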