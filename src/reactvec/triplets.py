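"""Atom-triplet enumeration and compound vectors.

A compound is described by counting *atom triplets*: paths of three bonded
atoms, end-centre-end, enumerated as unordered pairs of distinct neighbours
through every atom of the explicit-hydrogen graph.  Each component of the
compound vector is the frequency of one triplet.  Pairs of atoms would miss
most functional-group context (a carbonyl carbon's chemistry depends on its
second-shell neighbours), while quadruplets explode the number of possible
components; triplets are the working compromise.

Canonical form: the two end symbols are sorted in *descending* alphabetical
order, so an H-C-C path is the triplet ``HCC`` (not ``CCH``), an H-centre-C-O
path is ``OCH`` and an H-O-C path is ``HOC``.  Keys are rendered as plain
concatenation when all three symbols are single letters, and dot-separated
otherwise (``Cl.C.H``) so multi-letter elements stay unambiguous.  Bond
orders never enter the key: saturation differences surface only through the
hydrogen counts.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .chem_io import MolecularGraph, MoleculeError

__all__ = [
    "canonical_triplet",
    "enumerate_triplets",
    "build_vocabulary",
    "vectorize",
    "TripletVocabulary",
    "CompoundVector",
    "VocabularyCoverageWarning",
]


class VocabularyCoverageWarning(UserWarning):
    """Emitted when observed triplets fall outside the vocabulary."""


def canonical_triplet(end1: str, center: str, end2: str) -> str:
    """Canonical key for an end-centre-end atom path.

    Ends are ordered descending by element symbol (whole-symbol string
    comparison, so ``Cl`` sorts as a unit, not as ``C`` then ``l``).
    """
    for sym in (end1, center, end2):
        if not sym:
            raise ValueError("empty element symbol in triplet")
    hi, lo = (end1, end2) if end1 >= end2 else (end2, end1)
    if len(hi) == len(center) == len(lo) == 1:
        return hi + center + lo
    return f"{hi}.{center}.{lo}"


def enumerate_triplets(g: MolecularGraph) -> dict[str, int]:
    """Count every canonical triplet of ``g``.

    Requires explicit hydrogens: implicit-H graphs would silently undercount
    the H-containing triplets that dominate organic molecules.  The total
    count equals sum over atoms of C(degree, 2).
    """
    if not g.hydrogens_explicit:
        raise MoleculeError(
            f"{g.id}: triplet enumeration requires explicit hydrogens "
            "(call add_explicit_hydrogens first)"
        )
    counts: Counter[str] = Counter()
    adj = g.neighbors()
    elements = [a.element for a in g.atoms]
    for center, nbrs in enumerate(adj):
        for u, w in itertools.combinations(nbrs, 2):
            counts[canonical_triplet(elements[u], elements[center], elements[w])] += 1
    return dict(counts)


@dataclass(frozen=True)
class TripletVocabulary:
    """Ordered triplet keys defining the dense vector space."""

    keys: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("vocabulary keys must be distinct")

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: str) -> bool:
        return key in self.keys

    def index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.keys)}


@dataclass
class CompoundVector:
    """Dense non-negative triplet-count vector for one compound."""

    compound_id: str
    values: np.ndarray
    vocabulary: TripletVocabulary = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.vocabulary),):
            raise ValueError(
                f"{self.compound_id}: vector length {self.values.shape} does not "
                f"match vocabulary size {len(self.vocabulary)}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"{self.compound_id}: compound vector must be >= 0")


def build_vocabulary(
    counts_collection: list[dict[str, int]],
    max_size: int = 60,
    min_total: int = 5,
) -> TripletVocabulary:
    """Frequency-ranked vocabulary over a corpus of triplet counts.

    Keys are ranked by total frequency across the corpus (ties broken
    lexicographically), keys below ``min_total`` total occurrences are
    dropped (rare triplets of exotic atoms carry little signal and bloat
    the space), and the list is truncated to ``max_size``.
    """
    if not counts_collection:
        raise ValueError("counts_collection must be non-empty")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    totals: Counter[str] = Counter()
    for tc in counts_collection:
        totals.update(tc)
    ranked = sorted(
        (k for k, v in totals.items() if v >= min_total),
        key=lambda k: (-totals[k], k),
    )
    return TripletVocabulary(
        tuple(ranked[:max_size]),
        provenance=(
            f"top {max_size} by corpus frequency, min_total={min_total}, "
            f"{len(counts_collection)} molecules"
        ),
    )


def vectorize(tc: dict[str, int], vocab: TripletVocabulary, compound_id: str = "") -> CompoundVector:
    """Project triplet counts onto a vocabulary.

    Occurrences of triplets outside the vocabulary are dropped; the number
    dropped is reported through a :class:`VocabularyCoverageWarning`.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    idx = vocab.index()
    values = np.zeros(len(vocab), dtype=np.int64)
    dropped = 0
    for key, n in tc.items():
        i = idx.get(key)
        if i is None:
            dropped += n
        else:
            values[i] = n
    if dropped:
        warnings.warn(
            f"{compound_id or 'compound'}: {dropped} triplet occurrence(s) "
            "outside the vocabulary were dropped",
            VocabularyCoverageWarning,
            stacklevel=2,
        )
    return CompoundVector(compound_id, values, vocab)


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------


def write_vectors_tsv(vectors: list[CompoundVector]) -> str:
    """Header row of triplet keys, one row of integer components per compound."""
    if not vectors:
        raise ValueError("no vectors to write")
    vocab = vectors[0].vocabulary
    out = ["compound_id\t" + "\t".join(vocab.keys)]
    for v in vectors:
        if v.vocabulary.keys != vocab.keys:
            raise ValueError("vectors span different vocabularies")
        out.append(v.compound_id + "\t" + "\t".join(str(int(x)) for x in v.values))
    return "\n".join(out) + "\n"


def read_vectors_tsv(text: str) -> list[CompoundVector]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    vocab = TripletVocabulary(tuple(header[1:]), provenance="read from TSV")
    vectors = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        vectors.append(
            CompoundVector(parts[0], np.array([int(x) for x in parts[1:]]), vocab)
        )
    return vectors
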