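"""Hydrogen-filled molecular graphs and CORAL-style structural attributes.

A molecule is represented as its hydrogen-filled labelled graph: every
hydrogen implied by the SMILES valence model is an explicit vertex.  Three
classes of local/global structural attributes are extracted from this graph:

* ``EC0`` — zeroth-order Morgan extended connectivity: the element symbol
  together with the vertex degree, one attribute per atom.
* ``NNC`` — nearest-neighbouring code: the element symbol together with a
  three-digit canonical code of the atom's first-shell environment, one
  attribute per atom.
* ``NOSP`` — a single whole-molecule key recording the presence of
  nitrogen, oxygen, sulfur and phosphorus.

Attribute keys use a fixed-width textual format (``EC0-C...3...``,
``NNC-O...101.``, ``NOSP01000000``) so that learned weight tables are
plain, diffable CSV.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

ATTR_CLASSES = ("NNC", "EC0", "NOSP")

# RDKit logs parse errors on its own channel; we raise Python errors instead.
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a molecular graph."""


class AttributeOverflowError(ValueError):
    """Raised when a code digit of a structural attribute would exceed 9."""


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-filled labelled graph of a single-fragment, non-ionic molecule.

    Attributes
    ----------
    atoms:
        Element symbols in canonical parser order, explicit hydrogens included.
    bonds:
        ``(i, j, order)`` triples with ``i < j``; ``order`` is 1, 2, 3 or 1.5
        for aromatic bonds.
    source_smiles:
        The SMILES string the graph was parsed from.
    ring_bond_flags:
        Parallel to ``bonds``; True where the bond is in a ring.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, float], ...]
    source_smiles: str
    ring_bond_flags: tuple[bool, ...] = field(default=(), compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degrees(self) -> list[int]:
        """Vertex degree of every atom in the hydrogen-filled graph."""
        deg = [0] * len(self.atoms)
        for i, j, _ in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def ring_bond_counts(self) -> list[int]:
        """Number of ring bonds incident to every atom."""
        cnt = [0] * len(self.atoms)
        for (i, j, _), in_ring in zip(self.bonds, self.ring_bond_flags):
            if in_ring:
                cnt[i] += 1
                cnt[j] += 1
        return cnt

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out


@dataclass(frozen=True)
class StructuralAttribute:
    """A single structural-attribute key, e.g. ``NNC-C...303.``."""

    key: str

    @property
    def attr_class(self) -> str:
        if self.key.startswith("NOSP"):
            return "NOSP"
        return self.key.split("-", 1)[0]


@dataclass
class AttributeProfile:
    """Multiset of structural-attribute keys for one molecule."""

    molecule_id: str
    counts: Counter

    def total(self) -> int:
        return sum(self.counts.values())

    def union(self, other: "AttributeProfile") -> "AttributeProfile":
        return AttributeProfile(self.molecule_id, self.counts + other.counts)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-filled molecular graph.

    Multi-fragment (salt) SMILES and formally charged species are rejected:
    the sorption models target single-fragment, non-ionic organics.

    Raises
    ------
    SmilesParseError
        On empty input, syntactically invalid SMILES, multiple fragments or
        formal charges.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise SmilesParseError(
            f"multi-fragment SMILES not supported (salt?): {smiles!r}"
        )
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        raise SmilesParseError(f"charged species not supported: {smiles!r}")
    mol = Chem.AddHs(mol)
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = []
    ring_flags = []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds.append((i, j, b.GetBondTypeAsDouble()))
        ring_flags.append(b.IsInRing())
    order = sorted(range(len(bonds)), key=lambda k: bonds[k][:2])
    return MolecularGraph(
        atoms=atoms,
        bonds=tuple(bonds[k] for k in order),
        source_smiles=smiles,
        ring_bond_flags=tuple(ring_flags[k] for k in order),
    )


def _check_digit(value: int, what: str, graph: MolecularGraph) -> int:
    if value > 9:
        raise AttributeOverflowError(
            f"{what} = {value} exceeds one code digit "
            f"(molecule {graph.source_smiles!r})"
        )
    return value


def ec0_attributes(g: MolecularGraph) -> list[str]:
    """Zeroth-order extended-connectivity keys, one per atom.

    The key encodes the element symbol and the vertex degree of the atom in
    the hydrogen-filled graph, e.g. carbonyl carbon -> ``EC0-C...3...``.
    """
    keys = []
    for sym, deg in zip(g.atoms, g.degrees()):
        _check_digit(deg, f"degree of {sym}", g)
        keys.append(f"EC0-{sym}...{deg}...")
    return keys


def nnc_attributes(g: MolecularGraph) -> list[str]:
    """Nearest-neighbouring-code keys, one per atom.

    The three code digits are (vertex degree, number of incident ring
    bonds, number of neighbours), computed on the hydrogen-filled graph.
    For formaldehyde this yields O -> 101, C -> 303, H -> 101.
    """
    degs = g.degrees()
    rings = g.ring_bond_counts()
    keys = []
    for idx, sym in enumerate(g.atoms):
        d1 = _check_digit(degs[idx], f"degree of {sym}", g)
        d2 = _check_digit(rings[idx], f"ring bonds at {sym}", g)
        d3 = _check_digit(len(g.neighbors(idx)), f"neighbour count of {sym}", g)
        keys.append(f"NNC-{sym}...{d1}{d2}{d3}.")
    return keys


def nosp_attribute(g: MolecularGraph) -> str:
    """Whole-molecule heteroatom-presence key.

    Four 0/1 flags for N, O, S, P in that order, then four zero-padding
    characters: formaldehyde -> ``NOSP01000000``.
    """
    flags = "".join(
        "1" if el in g.atoms else "0" for el in ("N", "O", "S", "P")
    )
    return f"NOSP{flags}0000"


_EXTRACTORS = {
    "EC0": ec0_attributes,
    "NNC": nnc_attributes,
    "NOSP": lambda g: [nosp_attribute(g)],
}


def attribute_profile(
    g: MolecularGraph,
    classes: Iterable[str] = ATTR_CLASSES,
    molecule_id: str | None = None,
) -> AttributeProfile:
    """Multiset of attribute keys over the requested classes.

    EC0 and NNC contribute one key per atom (so their multiplicities each
    sum to the atom count); NOSP contributes exactly one key per molecule.
    """
    classes = tuple(classes)
    if not classes:
        raise ValueError("at least one attribute class is required")
    unknown = set(classes) - set(ATTR_CLASSES)
    if unknown:
        raise ValueError(f"unknown attribute class(es): {sorted(unknown)}")
    counts: Counter = Counter()
    for cls in classes:
        counts.update(_EXTRACTORS[cls](g))
    return AttributeProfile(
        molecule_id=molecule_id if molecule_id is not None else g.source_smiles,
        counts=counts,
    )


def profiles_from_smiles(
    smiles_list: Sequence[str],
    classes: Iterable[str] = ATTR_CLASSES,
    ids: Sequence[str] | None = None,
) -> list[AttributeProfile]:
    """Parse many SMILES and build one profile per molecule."""
    if ids is None:
        ids = [f"mol{i}" for i in range(len(smiles_list))]
    return [
        attribute_profile(parse_smiles(s), classes, molecule_id=i)
        for s, i in zip(smiles_list, ids)
    ]
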