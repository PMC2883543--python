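"""Reaction difference vectors.

A reaction transforming one "main" substrate into one "main" product is the
difference of their compound vectors, product minus substrate, each scaled
by its stoichiometric coefficient: for A -> 2B, V = 2*V_B - V_A.  The
components of a reaction vector are the triplets gained (positive) and lost
(negative) by the transformation, so the reverse reaction is the exact
negation, and a multi-step pathway is the sum of its step vectors -- a walk
through the same space in which the compounds are points.

Reactions with several main pairs in a source database are represented as
several table rows sharing a reaction id; one EC code may likewise label
several reaction vectors.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .triplets import CompoundVector, TripletVocabulary

__all__ = [
    "ReactionRecord",
    "ReactionVector",
    "reaction_vector",
    "load_reaction_table",
    "build_reaction_vectors",
    "write_reaction_vectors_tsv",
]

REACTION_TABLE_COLUMNS = [
    "reaction_id",
    "ec_codes",
    "substrate_id",
    "product_id",
    "substrate_coeff",
    "product_coeff",
]


class VocabularyMismatchError(ValueError):
    """Substrate and product vectors live in different triplet spaces."""


@dataclass(frozen=True)
class ReactionRecord:
    """One main substrate->product transformation with stoichiometry."""

    reaction_id: str
    ec_codes: tuple[str, ...]
    substrate_id: str
    product_id: str
    substrate_coeff: float = 1.0
    product_coeff: float = 1.0

    def __post_init__(self) -> None:
        if self.substrate_coeff <= 0 or self.product_coeff <= 0:
            raise ValueError(f"{self.reaction_id}: coefficients must be > 0")
        if self.substrate_id == self.product_id:
            raise ValueError(
                f"{self.reaction_id}: substrate and product ids must differ"
            )


@dataclass
class ReactionVector:
    """Signed triplet-change vector for one reaction."""

    reaction_id: str
    values: np.ndarray
    vocabulary: TripletVocabulary = field(repr=False)
    ec_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.vocabulary),):
            raise ValueError(
                f"{self.reaction_id}: vector length does not match vocabulary"
            )


def _as_exact(c: float) -> int | float:
    return int(c) if float(c).is_integer() else float(c)


def reaction_vector(
    sub: CompoundVector,
    prod: CompoundVector,
    s: float = 1,
    p: float = 1,
    reaction_id: str | None = None,
    ec_codes: tuple[str, ...] = (),
) -> ReactionVector:
    """p * V_product - s * V_substrate on a shared vocabulary.

    Integer coefficients keep the arithmetic exact in int64; non-integer
    stoichiometry is accepted but flagged, since curated main pairs almost
    always carry whole-number coefficients.
    """
    if sub.vocabulary.keys != prod.vocabulary.keys:
        raise VocabularyMismatchError(
            f"{sub.compound_id} and {prod.compound_id} use different vocabularies"
        )
    s, p = _as_exact(s), _as_exact(p)
    if isinstance(s, float) or isinstance(p, float):
        warnings.warn(
            f"non-integer stoichiometric coefficients ({s}, {p})", stacklevel=2
        )
        values = p * prod.values.astype(float) - s * sub.values.astype(float)
    else:
        values = p * prod.values.astype(np.int64) - s * sub.values.astype(np.int64)
    rid = reaction_id or f"{sub.compound_id}->{prod.compound_id}"
    return ReactionVector(rid, values, sub.vocabulary, tuple(ec_codes))


def load_reaction_table(
    source: str | io.TextIOBase,
    known_compounds: set[str] | None = None,
) -> list[ReactionRecord]:
    """Read a reaction table TSV into records.

    Expected header: reaction_id, ec_codes (semicolon-separated, may be
    blank), substrate_id, product_id, substrate_coeff, product_coeff
    (blank coefficients default to 1).  When ``known_compounds`` is given,
    rows referencing unknown compound ids are reported and skipped.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str).rename(columns=str.strip)
    missing = [c for c in REACTION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reaction table missing mandatory column(s): {missing}")

    records: list[ReactionRecord] = []
    for _, row in df.iterrows():
        def cell(col: str) -> str:
            v = row[col]
            return "" if pd.isna(v) else str(v).strip()

        sub_id, prod_id = cell("substrate_id"), cell("product_id")
        if known_compounds is not None and (
            sub_id not in known_compounds or prod_id not in known_compounds
        ):
            warnings.warn(
                f"{cell('reaction_id')}: unknown compound id "
                f"({sub_id!r} or {prod_id!r}); row skipped",
                stacklevel=2,
            )
            continue
        ec = tuple(e.strip() for e in cell("ec_codes").split(";") if e.strip())
        records.append(
            ReactionRecord(
                reaction_id=cell("reaction_id"),
                ec_codes=ec,
                substrate_id=sub_id,
                product_id=prod_id,
                substrate_coeff=float(cell("substrate_coeff") or 1),
                product_coeff=float(cell("product_coeff") or 1),
            )
        )
    return records


def write_reaction_table_tsv(records: list[ReactionRecord]) -> str:
    out = ["\t".join(REACTION_TABLE_COLUMNS)]
    for r in records:
        out.append(
            "\t".join(
                [
                    r.reaction_id,
                    ";".join(r.ec_codes),
                    r.substrate_id,
                    r.product_id,
                    str(_as_exact(r.substrate_coeff)),
                    str(_as_exact(r.product_coeff)),
                ]
            )
        )
    return "\n".join(out) + "\n"


def build_reaction_vectors(
    records: list[ReactionRecord],
    vectors: dict[str, CompoundVector],
) -> list[ReactionVector]:
    """One reaction vector per record whose compounds resolve.

    Records referencing unknown compounds are skipped with a warning; an
    EC code may legitimately end up on several vectors when the enzyme
    acts in several reactions.
    """
    out: list[ReactionVector] = []
    for r in records:
        sub = vectors.get(r.substrate_id)
        prod = vectors.get(r.product_id)
        if sub is None or prod is None:
            warnings.warn(
                f"{r.reaction_id}: no vector for "
                f"{r.substrate_id if sub is None else r.product_id}; skipped",
                stacklevel=2,
            )
            continue
        out.append(
            reaction_vector(
                sub,
                prod,
                s=r.substrate_coeff,
                p=r.product_coeff,
                reaction_id=r.reaction_id,
                ec_codes=r.ec_codes,
            )
        )
    return out


def write_reaction_vectors_tsv(vectors: list[ReactionVector]) -> str:
    """Key-header TSV with an ec_codes column."""
    if not vectors:
        raise ValueError("no vectors to write")
    vocab = vectors[0].vocabulary
    out = ["reaction_id\tec_codes\t" + "\t".join(vocab.keys)]
    for v in vectors:
        if v.vocabulary.keys != vocab.keys:
            raise ValueError("vectors span different vocabularies")
        comps = "\t".join(repr(x) if isinstance(x, float) else str(int(x)) for x in v.values.tolist())
        out.append(f"{v.reaction_id}\t{';'.join(v.ec_codes)}\t{comps}")
    return "\n".join(out) + "\n"


def read_reaction_vectors_tsv(text: str) -> list[ReactionVector]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    vocab = TripletVocabulary(tuple(header[2:]), provenance="read from TSV")
    vectors = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        ec = tuple(e for e in parts[1].split(";") if e)
        vals = [float(x) for x in parts[2:]]
        arr = (
            np.array([int(v) for v in vals], dtype=np.int64)
            if all(v.is_integer() for v in vals)
            else np.array(vals)
        )
        vectors.append(ReactionVector(parts[0], arr, vocab, ec))
    return vectors
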