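"""Molecular topology: heavy-atom graphs, atom labels, and atom-pair classification.

The flexible atom-pair encoding rests on a purely topological heuristic: an
unordered pair of heavy atoms is *flexible* when the shortest bond path
between them contains at least one internal rotatable bond, and *rigid*
otherwise.  A bond is rotatable when it is a non-ring, non-aromatic single
bond; rotatable bonds incident to either endpoint of the pair are *terminal*
and do not count, because rotating them leaves the pair distance unchanged.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

BondOrder = str  # "single" | "double" | "triple" | "aromatic"

_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element, ring membership and neighbor counts.

    ``n_hydrogens`` counts implicit plus explicit hydrogens as recorded on the
    hydrogen-complete structure, before hydrogen suppression.
    """

    element: str
    in_ring: bool
    n_heavy_neighbors: int
    n_hydrogens: int


@dataclass(frozen=True)
class BondRecord:
    """An undirected bond between heavy atoms ``i < j``."""

    i: int
    j: int
    order: BondOrder
    in_ring: bool


@dataclass(frozen=True, order=True)
class AtomLabel:
    """Atom typing used throughout the similarity function.

    Three ingredients: element symbol, a ring flag, and the neighbor score
    (number of neighboring heavy atoms minus number of neighboring hydrogens;
    may be negative, e.g. a terminal methyl carbon scores 1 - 3 = -2).
    Two labels are equal iff all three fields are equal.
    """

    element: str
    ring_flag: bool
    neighbor_score: int


@dataclass(frozen=True)
class PairClass:
    """Classification of one unordered atom pair.

    ``kind`` is ``"flexible"`` iff ``n_internal_rotatable >= 1``.  Rigid pairs
    carry the topological distance (bond count of the shortest path); flexible
    pairs carry the internal rotatable-bond count, which later also sets the
    number of Gaussian components of the pair's distance model.
    """

    kind: str  # "rigid" | "flexible"
    topo_distance: int
    n_internal_rotatable: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "flexible"):
            raise ValueError(f"unknown pair kind {self.kind!r}")
        if (self.kind == "flexible") != (self.n_internal_rotatable >= 1):
            raise ValueError("kind=flexible iff n_internal_rotatable >= 1")


@dataclass
class MoleculeGraph:
    """Connected simple graph over the heavy atoms of one molecule."""

    name: str
    atoms: List[AtomRecord]
    bonds: List[BondRecord]
    _adj: Dict[int, List[int]] = field(default_factory=dict, repr=False)
    _bond_index: Dict[Tuple[int, int], BondRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._adj = {i: [] for i in range(len(self.atoms))}
        self._bond_index = {}
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError(f"self-loop on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in self._bond_index:
                raise ValueError(f"duplicate bond {key}")
            self._bond_index[key] = b
            self._adj[b.i].append(b.j)
            self._adj[b.j].append(b.i)
        for nbrs in self._adj.values():
            nbrs.sort()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> List[int]:
        """Neighbor indices of atom ``i`` in ascending order."""
        return self._adj[i]

    def bond(self, i: int, j: int) -> BondRecord:
        return self._bond_index[(min(i, j), max(i, j))]


class MoleculeParseError(ValueError):
    """Raised when an input record cannot be turned into a MoleculeGraph."""


def _looks_like_molblock(record: str) -> bool:
    return "V2000" in record or record.count("\n") > 2


def parse_molecule(record: str, name: Optional[str] = None) -> MoleculeGraph:
    """Parse an SDF V2000 mol block or a SMILES string into a MoleculeGraph.

    Hydrogen counts are captured from the hydrogen-complete structure, then
    hydrogens are suppressed; all downstream topology is heavy-atom only, with
    the heavy-atom order of the input preserved.  Multi-fragment inputs are
    rejected rather than silently split.
    """
    record = record if isinstance(record, str) else str(record)
    if _looks_like_molblock(record):
        mol = Chem.MolFromMolBlock(record, removeHs=True)
        kind = "mol block"
    else:
        mol = Chem.MolFromSmiles(record.strip())
        kind = "SMILES"
    if mol is None:
        head = record.strip().splitlines()[0][:60] if record.strip() else "<empty>"
        raise MoleculeParseError(f"could not parse {kind} record {head!r}")
    return mol_to_graph(mol, name=name)


def mol_to_graph(mol: "Chem.Mol", name: Optional[str] = None) -> MoleculeGraph:
    """Convert an RDKit molecule (hydrogens already suppressed) to a MoleculeGraph."""
    mol = Chem.RemoveHs(mol)
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MoleculeParseError(
            f"disconnected input ({len(frags)} fragments); multi-fragment records are rejected"
        )
    if name is None:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            in_ring=a.IsInRing(),
            n_heavy_neighbors=a.GetDegree(),
            n_hydrogens=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _ORDER_FROM_RDKIT.get(b.GetBondType())
        if order is None:
            raise MoleculeParseError(f"unsupported bond type {b.GetBondType()} in {name!r}")
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append(BondRecord(min(i, j), max(i, j), order, b.IsInRing()))
    return MoleculeGraph(name=name, atoms=atoms, bonds=bonds)


def atom_label(graph: MoleculeGraph, i: int) -> AtomLabel:
    """Label of atom ``i``: (element, ring flag, heavy neighbors - hydrogens)."""
    a = graph.atoms[i]
    return AtomLabel(a.element, a.in_ring, a.n_heavy_neighbors - a.n_hydrogens)


def molecule_labels(graph: MoleculeGraph) -> List[AtomLabel]:
    return [atom_label(graph, i) for i in range(graph.n_atoms)]


def shortest_path(graph: MoleculeGraph, i: int, j: int) -> List[BondRecord]:
    """One shortest bond path between atoms ``i`` and ``j``.

    Ties between equally short paths are broken deterministically: BFS starts
    from min(i, j) and visits neighbors in ascending index order, so equal
    inputs always yield the same path.
    """
    if i == j:
        raise ValueError("shortest_path requires two distinct atoms")
    start, goal = min(i, j), max(i, j)
    parent: Dict[int, int] = {start: -1}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        if u == goal:
            break
        for v in graph.neighbors(u):
            if v not in parent:
                parent[v] = u
                queue.append(v)
    if goal not in parent:
        raise ValueError(f"atoms {i} and {j} are not connected")
    path_atoms = [goal]
    while path_atoms[-1] != start:
        path_atoms.append(parent[path_atoms[-1]])
    path_atoms.reverse()
    return [graph.bond(a, b) for a, b in zip(path_atoms, path_atoms[1:])]


def is_rotatable(graph: MoleculeGraph, bond: BondRecord) -> bool:
    """A bond is rotatable iff it is a single (non-aromatic) bond outside any ring."""
    return bond.order == "single" and not bond.in_ring


def classify_pair(graph: MoleculeGraph, i: int, j: int) -> PairClass:
    """Classify the unordered pair (i, j) as rigid or flexible.

    Counts rotatable bonds on the deterministic shortest path, excluding any
    bond incident to atom i or atom j (terminal rotatable bonds leave the pair
    distance invariant).  Flexible iff the internal count is >= 1.
    """
    path = shortest_path(graph, i, j)
    endpoints = {i, j}
    n_internal = sum(
        1
        for b in path
        if is_rotatable(graph, b) and not (b.i in endpoints or b.j in endpoints)
    )
    if n_internal >= 1:
        return PairClass("flexible", topo_distance=len(path), n_internal_rotatable=n_internal)
    return PairClass("rigid", topo_distance=len(path))


def classify_all_pairs(graph: MoleculeGraph) -> Dict[Tuple[int, int], PairClass]:
    """Classification of all n(n-1)/2 unordered heavy-atom pairs.

    A single-atom molecule yields an empty mapping.
    """
    out: Dict[Tuple[int, int], PairClass] = {}
    for i in range(graph.n_atoms):
        for j in range(i + 1, graph.n_atoms):
            out[(i, j)] = classify_pair(graph, i, j)
    return out
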