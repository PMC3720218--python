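"""Molecular graphs for topological bond-descriptor computation.

This module turns SMILES strings or MDL molfile (V2000) records into
explicit-hydrogen :class:`MolecularGraph` objects restricted to net-neutral
CHONS chemistry, and assigns the two atom-type systems every descriptor
depends on:

* the *element* system — one label per element (C, H, N, O, S);
* the *connection-number* system — element plus the number of bonded
  neighbours, hydrogens included (the methane carbon is ``C4``, the
  acetylene carbon ``C2``).  The connection-number system is a closed set
  of 14 labels; any molecule that would produce a label outside it (e.g.
  the ``C1`` of carbon monoxide) is rejected.

Aromatic input is kekulized to a single canonical Kekulé form before any
descriptor is computed, so mesomers of the same aromatic system are
indistinguishable downstream.  Aromaticity is perceived with a pinned
Hückel 4n+2 electron-count model on simple rings; π-system membership
covers every atom of a multiple (or aromatic) bond plus atoms bridging two
conjugated bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from rdkit import Chem
from rdkit import RDLogger

from .errors import ChemistryError, FormatError, TypingError

RDLogger.DisableLog("rdApp.*")

#: Elements admitted anywhere in the pipeline.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")

#: The closed connection-number atom-type set (element + neighbour count).
CN_TYPES: tuple[str, ...] = (
    "C2", "C3", "C4",
    "H1",
    "N1", "N2", "N3", "N4",
    "O1", "O2",
    "S1", "S2", "S3", "S4",
)

#: Unordered element pairs, in canonical (sorted) order — the label space of
#: element-typed pair descriptors.
ELEMENT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b)
    for idx, a in enumerate(ELEMENTS)
    for b in ELEMENTS[idx:]
)

#: Unordered connection-number pairs.
CN_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b)
    for idx, a in enumerate(CN_TYPES)
    for b in CN_TYPES[idx:]
)


class Bond(NamedTuple):
    """A covalent bond between atom indices ``i < j``."""

    i: int
    j: int
    order: int       # 1, 2 or 3 (Kekulé-resolved)
    in_ring: bool


@dataclass(frozen=True)
class Verdict:
    """Admission verdict for a parsed molecule."""

    accepted: bool
    reason: str | None = None


@dataclass
class MolecularGraph:
    """Explicit-hydrogen molecular graph.

    Atom identity is the 0-based index into the parallel per-atom tuples.
    ``bonds`` are unordered pairs stored with ``i < j``; orders are
    Kekulé-resolved integers.  The per-atom flags (``in_ring``,
    ``aromatic``, ``in_pi``) come from the pinned perception models
    described in the module docstring.
    """

    elements: tuple[str, ...]
    formal_charges: tuple[int, ...]
    bonds: tuple[Bond, ...]
    in_ring: tuple[bool, ...]
    aromatic: tuple[bool, ...]
    in_pi: tuple[bool, ...]
    title: str = ""
    _rdkit: Chem.Mol | None = field(default=None, repr=False, compare=False)
    _neighbors: tuple[tuple[int, ...], ...] = field(
        default=(), repr=False, compare=False
    )

    def __post_init__(self) -> None:
        n = len(self.elements)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemistryError(f"bond {b} references a missing atom")
        nbrs: list[list[int]] = [[] for _ in range(n)]
        for b in self.bonds:
            nbrs[b.i].append(b.j)
            nbrs[b.j].append(b.i)
        object.__setattr__(
            self, "_neighbors", tuple(tuple(sorted(x)) for x in nbrs)
        )

    # -- basic accessors ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def net_charge(self) -> int:
        return sum(self.formal_charges)

    def neighbors(self, i: int) -> tuple[int, ...]:
        return self._neighbors[i]

    def degree(self, i: int) -> int:
        return len(self._neighbors[i])

    def bond_between(self, i: int, j: int) -> Bond | None:
        a, b = min(i, j), max(i, j)
        for bond in self.bonds:
            if bond.i == a and bond.j == b:
                return bond
        return None

    def to_smiles(self) -> str:
        if self._rdkit is None:
            raise ChemistryError("graph carries no structure record")
        return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(self._rdkit)))

    def to_molblock(self) -> str:
        if self._rdkit is None:
            raise ChemistryError("graph carries no structure record")
        return Chem.MolToMolBlock(self._rdkit, kekulize=True)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _looks_like_molblock(text: str) -> bool:
    return "V2000" in text or "V3000" in text or text.count("\n") >= 3


def _raw_mol(text: str) -> Chem.Mol:
    if _looks_like_molblock(text):
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text.strip(), sanitize=False)
    if mol is None:
        raise FormatError("input is not a valid V2000 molfile record or SMILES")
    return mol


def prepare_rdkit_mol(mol: Chem.Mol) -> Chem.Mol:
    """Sanitize, re-perceive aromaticity under the pinned model, add explicit
    hydrogens and kekulize.  Raises :class:`ChemistryError` for valence
    violations, disallowed elements, or disconnected structures."""
    mol = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise ChemistryError(f"sanitization failed: {exc}") from exc
    bad = sorted({a.GetSymbol() for a in mol.GetAtoms()} - set(ELEMENTS))
    if bad:
        raise ChemistryError(
            f"element(s) outside the admitted C/H/N/O/S set: {', '.join(bad)}"
        )
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ChemistryError("structure is disconnected")
    # Pinned Hückel 4n+2 aromaticity on simple rings.
    Chem.SetAromaticity(mol, Chem.AromaticityModel.AROMATICITY_SIMPLE)
    mol = Chem.AddHs(mol)
    Chem.Kekulize(mol, clearAromaticFlags=False)
    return mol


def _pi_flags(mol: Chem.Mol) -> list[bool]:
    """π-system membership: multiple-bond (or aromatic) atoms, plus atoms
    bridging at least two conjugated bonds."""
    n = mol.GetNumAtoms()
    flags = [False] * n
    conj_count = [0] * n
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bond.GetBondTypeAsDouble() >= 2.0 or bond.GetIsAromatic():
            flags[i] = flags[j] = True
        if bond.GetIsConjugated():
            conj_count[i] += 1
            conj_count[j] += 1
    for i in range(n):
        if conj_count[i] >= 2:
            flags[i] = True
    return flags


def from_rdkit(mol: Chem.Mol, title: str = "") -> MolecularGraph:
    """Build a :class:`MolecularGraph` from a *prepared* RDKit mol
    (see :func:`prepare_rdkit_mol`)."""
    ring_info = mol.GetRingInfo()
    bonds = []
    for bond in mol.GetBonds():
        i, j = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        order = int(round(bond.GetBondTypeAsDouble()))
        if order not in (1, 2, 3):
            raise ChemistryError(f"unsupported bond order {order} on bond {i}-{j}")
        bonds.append(Bond(i, j, order, ring_info.NumBondRings(bond.GetIdx()) > 0))
    g = MolecularGraph(
        elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
        formal_charges=tuple(a.GetFormalCharge() for a in mol.GetAtoms()),
        bonds=tuple(bonds),
        in_ring=tuple(a.IsInRing() for a in mol.GetAtoms()),
        aromatic=tuple(a.GetIsAromatic() for a in mol.GetAtoms()),
        in_pi=tuple(_pi_flags(mol)),
        title=title or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
        _rdkit=mol,
    )
    return g


def parse_structure(text: str) -> MolecularGraph:
    """Parse a V2000 molfile record or a SMILES string.

    Implicit hydrogens are materialized, aromatic bonds are resolved to one
    canonical Kekulé form, and the pinned aromaticity/π models are applied.

    Raises
    ------
    FormatError
        If the text cannot be parsed at all.
    ChemistryError
        For valence violations, elements outside C/H/N/O/S, or
        disconnected structures.
    """
    raw = _raw_mol(text)
    return from_rdkit(prepare_rdkit_mol(raw))


# ---------------------------------------------------------------------------
# Admission and typing
# ---------------------------------------------------------------------------


def validate_molecule(g: MolecularGraph) -> Verdict:
    """Admission rule: net charge zero and elements within C/H/N/O/S.

    Zwitterions (non-zero formal charges summing to zero) are accepted.
    Returns a verdict rather than raising, so dataset builders can report
    skip reasons.
    """
    bad = sorted(set(g.elements) - set(ELEMENTS))
    if bad:
        return Verdict(False, f"disallowed element(s): {', '.join(bad)}")
    if g.net_charge != 0:
        return Verdict(False, f"net charge {g.net_charge:+d}")
    try:
        for i in range(g.n_atoms):
            atom_type(g, i, "cn")
    except TypingError as exc:
        return Verdict(False, str(exc))
    return Verdict(True)


def atom_type(g: MolecularGraph, index: int, system: str) -> str:
    """Atom-type label under ``system`` ∈ {"element", "cn"}.

    The connection-number label is the element symbol followed by the count
    of bonded neighbours (hydrogens included); labels outside the closed
    14-type set raise :class:`TypingError`.
    """
    element = g.elements[index]
    if system == "element":
        return element
    if system == "cn":
        label = f"{element}{g.degree(index)}"
        if label not in CN_TYPES:
            raise TypingError(
                f"atom {index} ({element}, {g.degree(index)} neighbours) has "
                f"no label in the closed connection-number type set"
            )
        return label
    raise ValueError(f"unknown atom-type system {system!r}")


def atom_types(g: MolecularGraph, system: str) -> tuple[str, ...]:
    """Labels for every atom of the graph under one type system."""
    return tuple(atom_type(g, i, system) for i in range(g.n_atoms))


def perceive_features(g: MolecularGraph) -> dict[str, tuple[bool, ...]]:
    """Per-atom structural flags under the pinned perception models.

    Recomputed from the stored structure record; equals the flags stored on
    the graph at construction.
    """
    if g._rdkit is None:
        return {"in_ring": g.in_ring, "aromatic": g.aromatic, "in_pi": g.in_pi}
    mol = g._rdkit
    return {
        "in_ring": tuple(a.IsInRing() for a in mol.GetAtoms()),
        "aromatic": tuple(a.GetIsAromatic() for a in mol.GetAtoms()),
        "in_pi": tuple(_pi_flags(mol)),
    }


def subset_flags(g: MolecularGraph, subset: str) -> tuple[bool, ...]:
    """Boolean mask for an atom-subset restriction."""
    if subset == "all":
        return tuple([True] * g.n_atoms)
    if subset == "ring":
        return g.in_ring
    if subset == "aromatic":
        return g.aromatic
    if subset == "pi":
        return g.in_pi
    raise ValueError(f"unknown atom subset {subset!r}")


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read one SMILES per line (blank lines and ``#`` comments ignored)."""
    graphs = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            graphs.append(parse_structure(line.split()[0]))
    return graphs


def iter_sdf_blocks(path) -> Iterable[str]:
    """Yield raw record blocks (without the ``$$$$`` terminator) of an SDF."""
    buffer: list[str] = []
    with open(path) as handle:
        for line in handle:
            if line.strip() == "$$$$":
                yield "".join(buffer)
                buffer = []
            else:
                buffer.append(line)
    if any(line.strip() for line in buffer):
        yield "".join(buffer)
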