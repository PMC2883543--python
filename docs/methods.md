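# Methods

## The representation

A compound is an explicit-hydrogen molecular graph; its vector counts atom
triplets: for every atom *a* with neighbour set N(a), every unordered pair
{u, w} ⊆ N(a) of distinct atoms contributes one occurrence of the triplet
(element(u), element(a), element(w)). The total count therefore equals
Σₐ C(deg(a), 2). Two canonicalisation rules make keys unambiguous:

* the two end symbols are sorted in **descending** alphabetical order
  (`HCC`, `OCH`, `HOC` — matching the names conventionally printed for
  these triplets; ascending order would produce `CCH`/`HCO`/`COH`);
* keys are rendered as plain concatenation only when all three symbols are
  single letters, otherwise dot-separated (`Cl.C.H`), so multi-letter
  elements cannot collide.

Each neighbour pair is counted **once** regardless of bond multiplicity.
This is the unique counting rule under which the secondary-alcohol →
ketone oxidation loses exactly 2 HCC + 1 OCH + 1 HOC, and it makes the
representation blind to bond orders by construction; saturation differences
still surface through hydrogen counts (unsaturation trades HCH/HCC for
CCC). The representation is not univocal — stereoisomers and some
positional isomers share a vector — which is accepted: the goal is a common
space for compounds and reactions, not a canonical structure code.

The vector space is defined by a frequency-ranked vocabulary built from
the input corpus: triplets ranked by total count, ties broken
lexicographically, truncated to `max_size` (default 60) after dropping
triplets with corpus total below `min_total` (default 5). Rare triplets of
exotic atoms carry little signal and inflate dimensionality. Occurrences
outside the vocabulary are dropped with a counted warning.

Reaction vectors are exact integer differences `p·V_product − s·V_substrate`
for the annotated main substrate/product pair. Non-integer coefficients are
accepted but flagged. Reactions with several main pairs are several rows
sharing a reaction id; EC codes are opaque strings (partial codes like
`2.7.1.-` are legal) and one EC code may label several vectors.

## Structure input

MDL V2000 connection tables are parsed with a dedicated fixed-width reader
whose errors name the offending line; SMILES are parsed with RDKit and
kekulized. Placeholder atoms `R`, `R#`, `*`, `A` — database shorthand for
polymeric "R-" groups — become the pseudo-element `X`, which keeps its
stated bonds and never receives hydrogens. Hydrogen saturation uses a fixed
valence model (C 4; N 3; O 2; S 2/4/6; P 3/5; halogens and H 1; B 3),
choosing the smallest state that accommodates the atom's bond-order sum;
the formal charge is added to the target valence (O⁻ takes one H fewer,
N⁺ one more). The model is deterministic and idempotent, and differs from
a perception-based toolkit only for exotic valences; SMILES hydrogen-count
overrides below the standard valence (e.g. carbenes) are not preserved.
V3000, stereochemistry and 3-D coordinates are out of scope.

## Clustering

Distances between reaction vectors are plain Euclidean. UPGMA
(average-linkage agglomeration, via scipy) produces an ultrametric
dendrogram. Two height conventions are supported: the default draws a merge
at linkage distance d at height d/2 (phylogenetics convention — leaf-to-leaf
path length equals the cophenetic distance); `"full"` uses d itself, as R's
`hclust` does. Newick export writes branch lengths as parent-minus-child
heights, orders children by smallest contained leaf index for determinism,
and quotes reserved characters.

`cut_tree(t, k)` discards the k−1 highest merges (ties broken by merge
order, which is exactly the order of the linkage rows), so successive cuts
are nested refinements and identical vectors are always co-clustered.

The number of clusters is selected by fitting Gaussian mixtures for
k = 1..k_max (default 100, truncated to n−1) and maximising BIC, reported
so that larger is better. Choices: diagonal covariances with variance
floor 1e−6, 5 restarts from k-means++ initialisation, seeded. Full
covariance families are deliberately not searched — with 60-dimensional
integer vectors containing exact duplicates they are ill-conditioned.
Duplicated rows are jittered by N(0, 1e−8) *for the mixture fit only*;
distances and the tree never see jitter. Failed fits are recorded and
excluded from the argmax. Tree-cut membership at the selected k is the
primary labelling; mixture-responsibility labels are available separately
for comparison, and neither is privileged.

## Association and enrichment statistics

A clustering and an annotation source meet in a cluster × keyword
contingency table of frequencies (items with several keywords increment
several cells of their row, so the chi-squared independence assumption is
approximate — documented, not corrected). The statistic applies the Yates
continuity correction per cell, Σ max(|O−E|−0.5, 0)²/E, generalising the
2×2 correction to N×k tables; all-zero rows/columns are dropped with a
warning, degenerate tables are rejected. Because different classifications
have different table shapes, statistics are mapped to a common scale with
Fisher's approximation z = √(2χ²) − √(2·dof−1), dof = (N−1)(k−1). To
compare against a reference classification with N groups, cut the tree at
the same N (`cut_to_match`).

Per-cluster enrichment uses the upper tail P(X ≥ n) (enrichment is the
question being asked; depletion is not scored): hypergeometric for drawing
the cluster from the finite population of clustered items, switching to
the Poisson tail with λ = cluster_size·p in the low-frequency regime
n·p < 5 and p < 0.1, where n is the in-cluster frequency and p the
background probability (feature carriers / clustered items). Raw p-values
are the default output; Bonferroni and Benjamini–Hochberg corrections are
available but off.

## Property regression

One property at a time (logP, MW g/mol, TPSA Å²; missing values drop the
compound for that property only) is fitted by plain OLS on the vector
components plus intercept — no regularisation; rank-deficient designs get
the minimum-norm solution plus a flag. Predictive value is measured by
seeded 10-fold cross-validation: shuffle once, split into contiguous blocks
within ±1 in size, predict each fold from the rest, and report the Pearson
correlation of the pooled predictions against the experimental values
(pooling, rather than averaging per-fold correlations, uses every compound
exactly once).

## Synthetic data

The fixture corpus plants recoverable structure: six local transformation
families (alcohol oxidation, amide hydrolysis, phosphorylation,
sulfonation, aldehyde oxidation, esterification) are implemented as head
fragments grafted onto random valence-respecting scaffold trees of 3–8
heavy atoms via a carbon attachment atom. Every rewritten atom is at least
one bond away from the scaffold, so the scaffold cancels exactly in the
difference vector and all reactions of a family coincide at distance 0 —
the degeneracy the amide example exhibits on real data. Defaults: 120
reactions, 6 families, no keyword noise. Keywords follow the family (two
per family), each independently replaced by a random other family's keyword
with probability `keyword_noise`; an EC-like code `f.f.1.serial` encodes
the family in its first digit. All outputs are bit-reproducible per seed.

The property dataset draws 500 random molecules (3–10 heavy atoms),
computes MW exactly from an embedded average-mass table (2 decimals), a
noise-free TPSA-like column (20 per O, 10 per N), and a logP-like response
that is a fixed linear combination of triplet counts (+0.3 for pure
hydrocarbon triplets, −0.4 for heteroatom triplets) plus Gaussian noise.
With `noise_sd=None` the noise is calibrated to a target population
correlation r (default 0.9) via sd = sd(signal)·√(1/r² − 1), reproducing
the regime reported for real hydrophobicity data. The generator's
vocabulary excludes triplets present in fewer than ~10% of molecules (in
addition to the max-60 cap): rare columns would make training folds
rank-deficient in directions only the held-out fold probes, which is a
property of the synthetic design, not of the method.

Passing tests on this corpus demonstrate exact algebra, oracle-level
agreement of the statistics, and recovery of planted structure; they do
not demonstrate performance on real reactomes, whose vectors are noisier,
whose families are not exactly degenerate, and whose annotations are
correlated across sources.

## Numerical and scale choices

Integer arithmetic end-to-end for vectors with integer stoichiometry;
distances and statistics in float64. UPGMA oracle checks use ≤ 12 items
(exhaustive O(n³) reference); hypergeometric oracles enumerate populations
≤ 12; the BIC demonstration uses 60 points in 3 dimensions; regression
checks use n = 500. These sizes are chosen so the whole suite runs in
seconds while every check remains exact or statistically decisive.

## Known limitations

* The vector map is not injective (stereo/positional isomers collide), and
  bond orders are invisible beyond their effect on hydrogen counts.
* The hydrogen model is a fixed valence table, not a full perception
  algorithm; exotic organometallic valences are left unsaturated with a
  warning.
* The generalised per-cell Yates correction and the upper-tail enrichment
  convention are documented choices among defensible alternatives.
* UPGMA tie-breaking among exactly equal linkage distances follows scipy's
  merge order; ties are measure-zero for continuous inputs but common among
  duplicated integer vectors, where only the (invariant) cophenetic
  structure, not the printed topology, should be relied upon.
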