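# reactvec

Vectorial representation of chemical compounds and biochemical reactions,
with the analysis machinery to classify a reactome bottom-up.

## The problem and the representation

Protein sequences and structures have natural similarity measures, so their
global "spaces" can be clustered and studied as a whole. Chemical reactions
do not: the standard EC classification is an imposed nomenclature hierarchy,
not a quantitative, data-driven one. `reactvec` implements a simple
representation that closes this gap:

* **Compound vector.** A molecule (with explicit hydrogens) is described by
  the frequencies of its *atom triplets* — paths of three bonded atoms,
  enumerated as unordered pairs of distinct neighbours through each centre
  atom. The component for triplet *t* of compound *A* is its count
  `V_A[t]`. Triplet keys are canonicalised with the two end symbols in
  descending alphabetical order (`HCC`, `OCH`, `HOC`, ...). Bond orders are
  deliberately ignored; unknown "R-" groups in database structures become
  opaque `X` pseudo-atoms. The vector space is spanned by the most frequent
  triplets of the input corpus (default: top 60, dropping triplets seen
  fewer than 5 times).

* **Reaction vector.** A reaction transforming main substrate A into main
  product B with stoichiometric coefficients s, p is the signed difference

  `V_{A->B} = p·V_B − s·V_A`   (so for A -> 2B, `V = 2·V_B − V_A`).

  Its components are the triplets gained and lost; the reverse reaction is
  the exact negation (`V_{A->B} = −V_{B->A}`), and a pathway is the sum of
  its steps — a walk through the same space in which compounds are points.

On top of this the package provides: Euclidean distances and UPGMA
hierarchical clustering of reaction vectors (with newick export and tree
cutting), Gaussian-mixture/BIC selection of the cluster number,
chi-squared association between a clustering and annotation keywords with
the Yates continuity correction and Fisher's z-approximation
(`z = √(2χ²) − √(2·dof − 1)`, `dof = (N−1)(k−1)`), per-cluster
hypergeometric/Poisson enrichment of keywords and triplet components, and
OLS regression of physicochemical properties (logP, MW, TPSA) on compound
vectors with 10-fold cross-validation. A fixtures module generates
synthetic molecules, reaction corpora with planted transformation families,
annotations and property tables, so everything is testable offline.

## Worked example

The classic demonstration is the oxidation of a secondary alcohol to a
ketone, instantiated as 2-propanol → acetone:

```python
from reactvec import (fixtures, enumerate_triplets, build_vocabulary,
                      vectorize, reaction_vector)

mols = fixtures.worked_example_molecules()
counts = {n: enumerate_triplets(g) for n, g in mols.items()}
vocab = build_vocabulary(list(counts.values()), max_size=200, min_total=1)
vec = {n: vectorize(c, vocab, n) for n, c in counts.items()}

rv = reaction_vector(vec["2-propanol"], vec["acetone"])
print({k: int(x) for k, x in zip(vocab.keys, rv.values) if x})
```

prints

```
{'HCC': -2, 'HOC': -1, 'OCH': -1}
```

the transformation loses two H–C–C triplets, one O–C–H and one H–O–C —
exactly the local chemistry of removing the hydroxyl hydrogen and the
carbinol hydrogen. Chemically equivalent transformations on different
scaffolds cancel the scaffold entirely: amide → carboxylic acid
(R–CONH₂ → R–COOH) yields the *same* vector for acetamide → acetic acid
and propanamide → propanoic acid, so their Euclidean distance is exactly 0
— a functional similarity invisible to the EC hierarchy, which spreads
these activities over three of its six main classes.

A full pipeline is available from the shell:

```sh
reactvec --seed 7 --out-dir run fixtures          # synthetic corpus
reactvec --out-dir run vectorize run/compounds.sdf
reactvec --out-dir run react run/reactions.tsv run/compound_vectors.tsv
reactvec --out-dir run cluster run/reaction_vectors.tsv   # UPGMA + BIC
reactvec --out-dir run assoc run/assignments.tsv run/annotations.tsv
reactvec --out-dir run enrich run/assignments.tsv run/annotations.tsv
reactvec --out-dir run regress run/property_vectors.tsv run/properties.tsv
```

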