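"""Molecular structure I/O: explicit-hydrogen graphs from MOL/SDF and SMILES.

Compounds enter as MDL MOL/SDF V2000 connection tables or SMILES strings and
are normalised to a plain molecular graph: element-labelled atoms, integer
bond orders, and (after saturation) explicit hydrogens.  Database placeholder
atoms written as ``R``, ``R#``, ``*`` or ``A`` -- metabolic databases use
them for parts of a molecule not resolved to atoms, typically polymeric
"R-groups" (peptides, poly-sugars, DNA fragments) -- are mapped to the
pseudo-element ``X``.  ``X`` atoms are opaque: they keep the bonds the file
states and never receive hydrogens.

Hydrogen saturation uses a fixed valence model (C:4, N:3, O:2, S:2/4/6,
P:3/5, halogens:1), with the formal charge added to the target valence, so
the result is deterministic and independent of any external perception code.
Bond orders are recorded but play no role downstream: the triplet
representation deliberately ignores them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "MoleculeError",
    "ParseError",
    "ValenceError",
    "parse_molfile",
    "parse_sdf",
    "parse_smiles",
    "read_smiles_file",
    "add_explicit_hydrogens",
    "write_molfile",
    "write_sdf",
    "write_graph_tsv",
]


class MoleculeError(ValueError):
    """Base error for structural problems in molecular input."""


class ParseError(MoleculeError):
    """Raised when a structure file cannot be interpreted."""


class ValenceError(MoleculeError):
    """Raised when an atom exceeds every allowed valence."""


#: file symbols standing for an unspecified R-group
PSEUDO_ATOM_SYMBOLS = frozenset({"R", "R#", "*", "A"})

#: allowed valence states, lowest first; elements not listed are opaque
#: (no hydrogens added), like "X"
VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.element:
            raise MoleculeError("atom element symbol must be non-empty")
        if self.index < 0:
            raise MoleculeError("atom index must be >= 0")


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: int = 1

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise MoleculeError(f"self-loop bond on atom {self.a}")
        if self.order < 1:
            raise MoleculeError(f"bond order must be >= 1, got {self.order}")

    @property
    def key(self) -> tuple[int, int]:
        """Unordered endpoint pair."""
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class MolecularGraph:
    """Simple undirected graph of element-labelled atoms."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    hydrogens_explicit: bool = False

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise MoleculeError(
                    f"{self.id}: bond ({b.a},{b.b}) references a missing atom"
                )
            if b.key in seen:
                raise MoleculeError(f"{self.id}: duplicate bond {b.key}")
            seen.add(b.key)

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> list[list[int]]:
        """Adjacency list, atom index -> neighbour indices (file order)."""
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
        return adj

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def formula(self) -> dict[str, int]:
        """Element -> count, e.g. {"C": 3, "H": 8, "O": 1}."""
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts


# --------------------------------------------------------------------------
# MDL V2000
# --------------------------------------------------------------------------

_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


def _normalize_symbol(sym: str) -> str:
    return "X" if sym in PSEUDO_ATOM_SYMBOLS else sym


def parse_molfile(text: str, mol_id: str | None = None) -> MolecularGraph:
    """Parse a single MDL MOL (V2000) connection table.

    Atoms labelled ``R``, ``R#``, ``*`` or ``A`` become ``X`` pseudo-atoms.
    ``hydrogens_explicit`` is set when H atoms appear in the block.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile truncated: fewer than 4 lines (no counts line)")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed counts line (line 4): {counts!r}") from None
    if n_atoms < 0 or n_bonds < 0:
        raise ParseError(f"malformed counts line (line 4): {counts!r}")

    atoms: list[Atom] = []
    charges: dict[int, int] = {}
    for i in range(n_atoms):
        lineno = 5 + i
        try:
            ln = lines[4 + i]
        except IndexError:
            raise ParseError(
                f"truncated atom block: expected {n_atoms} atoms, "
                f"input ends before line {lineno}"
            ) from None
        sym = ln[31:34].strip()
        if not sym:
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom line {lineno}: {ln!r}")
            sym = parts[3]
        try:
            code = int(ln[36:39])
        except (ValueError, IndexError):
            code = 0
        charges[i] = _CHARGE_CODES.get(code, 0)
        atoms.append(Atom(i, _normalize_symbol(sym), charges[i]))

    bonds: list[Bond] = []
    for j in range(n_bonds):
        lineno = 5 + n_atoms + j
        try:
            ln = lines[4 + n_atoms + j]
        except IndexError:
            raise ParseError(
                f"truncated bond block: expected {n_bonds} bonds, "
                f"input ends before line {lineno}"
            ) from None
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except (ValueError, IndexError):
            raise ParseError(f"malformed bond line {lineno}: {ln!r}") from None
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise ParseError(f"bond line {lineno} references atom out of range: {ln!r}")
        bonds.append(Bond(a, b, order))

    # "M  CHG" property lines supersede the atom-block charge column
    chg_lines = [ln for ln in lines[4 + n_atoms + n_bonds :] if ln.startswith("M  CHG")]
    if chg_lines:
        charges = {i: 0 for i in range(n_atoms)}
        for ln in chg_lines:
            fields = ln.split()
            for k in range(3, len(fields) - 1, 2):
                charges[int(fields[k]) - 1] = int(fields[k + 1])
        atoms = [replace(a, charge=charges[a.index]) for a in atoms]

    name = lines[0].strip() or mol_id or "mol"
    has_h = any(a.element == "H" for a in atoms)
    return MolecularGraph(name, atoms, bonds, hydrogens_explicit=has_h)


def parse_sdf(text: str) -> list[MolecularGraph]:
    """Parse an SDF file: V2000 blocks separated by ``$$$$``."""
    graphs = []
    for i, block in enumerate(text.split("$$$$")):
        if block.strip():
            graphs.append(parse_molfile(block.lstrip("\n"), mol_id=f"mol{i + 1}"))
    return graphs


def write_molfile(g: MolecularGraph) -> str:
    """Serialize to a V2000 block; ``X`` atoms are written back as ``R#``."""
    out = [g.id, "  reactvec", ""]
    out.append(f"{len(g.atoms):>3}{len(g.bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for a in g.atoms:
        sym = "R#" if a.element == "X" else a.element
        out.append(f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {sym:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in g.bonds:
        out.append(f"{b.a + 1:>3}{b.b + 1:>3}{b.order:>3}  0")
    charged = [a for a in g.atoms if a.charge]
    for i in range(0, len(charged), 8):
        chunk = charged[i : i + 8]
        ln = f"M  CHG{len(chunk):>3}"
        for a in chunk:
            ln += f"{a.index + 1:>4}{a.charge:>4}"
        out.append(ln)
    out.append("M  END")
    return "\n".join(out) + "\n"


def write_sdf(graphs: list[MolecularGraph]) -> str:
    return "$$$$\n".join(write_molfile(g) for g in graphs) + "$$$$\n"


def write_graph_tsv(g: MolecularGraph) -> str:
    """Debug dump: atom table then bond table, tab-separated."""
    out = [f"# molecule\t{g.id}\thydrogens_explicit={g.hydrogens_explicit}"]
    out.append("atom\telement\tcharge")
    out.extend(f"{a.index}\t{a.element}\t{a.charge}" for a in g.atoms)
    out.append("bond_a\tbond_b\torder")
    out.extend(f"{b.a}\t{b.b}\t{b.order}" for b in g.bonds)
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# SMILES (via RDKit)
# --------------------------------------------------------------------------


def parse_smiles(s: str, mol_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string; the wildcard atom ``*`` becomes ``X``.

    Hydrogens stay implicit (``hydrogens_explicit`` false) unless written
    explicitly as ``[H]`` atoms.  Aromatic rings are kekulized; bond orders
    are irrelevant to the triplet representation, so only the hydrogen
    counts implied by the kekule structure matter.
    """
    from rdkit import Chem

    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(s, params)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {s!r}")
    mol = Chem.Mol(mol)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Exception as exc:  # pragma: no cover - exotic aromatic systems
        raise ParseError(f"cannot kekulize SMILES {s!r}: {exc}") from exc

    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        atoms.append(Atom(a.GetIdx(), _normalize_symbol(sym), a.GetFormalCharge()))
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    has_h = any(a.element == "H" for a in atoms)
    return MolecularGraph(mol_id or s, atoms, bonds, hydrogens_explicit=has_h)


def read_smiles_file(text: str) -> list[MolecularGraph]:
    """Read one SMILES per line, optionally ``SMILES<TAB>id``."""
    graphs = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        smiles = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        graphs.append(parse_smiles(smiles, mol_id=mol_id))
    return graphs


# --------------------------------------------------------------------------
# hydrogen saturation
# --------------------------------------------------------------------------


def add_explicit_hydrogens(g: MolecularGraph) -> MolecularGraph:
    """Saturate every atom of known valence with explicit hydrogens.

    The target valence is the smallest allowed state (see ``VALENCES``)
    that accommodates the atom's current bond-order sum, shifted by the
    formal charge (so O(-1) takes one H fewer, N(+1) one more).  ``X``
    atoms and elements outside the table are left untouched.  Idempotent:
    already-saturated atoms need zero additional hydrogens.
    """
    order_sum = [0] * len(g.atoms)
    for b in g.bonds:
        order_sum[b.a] += b.order
        order_sum[b.b] += b.order

    atoms = list(g.atoms)
    bonds = list(g.bonds)
    next_idx = len(atoms)
    for a in g.atoms:
        if a.element in ("H", "X"):
            continue
        allowed = VALENCES.get(a.element)
        if allowed is None:
            warnings.warn(
                f"{g.id}: no valence model for element {a.element!r}; "
                "no hydrogens added",
                stacklevel=2,
            )
            continue
        targets = [v + a.charge for v in allowed if v + a.charge >= 0]
        fitting = [t for t in targets if t >= order_sum[a.index]]
        if not fitting:
            raise ValenceError(
                f"{g.id}: atom {a.index} ({a.element}, charge {a.charge:+d}) has "
                f"bond-order sum {order_sum[a.index]}, exceeding every allowed "
                f"valence {targets}"
            )
        for _ in range(min(fitting) - order_sum[a.index]):
            atoms.append(Atom(next_idx, "H"))
            bonds.append(Bond(a.index, next_idx, 1))
            next_idx += 1

    return MolecularGraph(g.id, atoms, bonds, hydrogens_explicit=True)
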