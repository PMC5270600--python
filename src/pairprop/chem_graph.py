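"""Annotated molecular graphs and the graph queries the descriptor needs.

Molecules are parsed with RDKit into a light-weight, hydrogen-suppressed
graph representation that carries exactly the information the atom-pair
descriptor consumes: element period/family, bond orders between heavy
atoms, ring membership, 2D coordinates and an optional per-atom shifted
pKa supplied by a pluggable provider.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: offset subtracted from provider pKa values to centre them at neutrality
PKA_SHIFT = 7.0

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

# (first atomic number of period, last) per period
_PERIOD_RANGES = [
    (1, 2),
    (3, 10),
    (11, 18),
    (19, 36),
    (37, 54),
    (55, 86),
    (87, 118),
]


class MoleculeError(ValueError):
    """Raised when a molecule cannot be represented by the descriptor."""


class TransitionElementError(MoleculeError):
    """Raised for atoms outside the main groups (d/f block)."""


class DisconnectedMoleculeError(MoleculeError):
    """Raised when a multi-fragment molecule is encountered."""


def period_and_family(atomic_number: int) -> tuple[int, int]:
    """Return (periodic period, main-group family 1-8) for an element.

    Transition elements (d/f block) raise :class:`TransitionElementError`.
    """
    z = atomic_number
    for period, (lo, hi) in enumerate(_PERIOD_RANGES, start=1):
        if lo <= z <= hi:
            break
    else:
        raise TransitionElementError(f"atomic number {z} out of range")
    if period == 1:
        return 1, (1 if z == 1 else 8)
    if period in (2, 3):
        return period, z - (2 if period == 2 else 10)
    lo, hi = _PERIOD_RANGES[period - 1]
    if z in (lo, lo + 1):
        return period, z - lo + 1
    if z > hi - 6:
        return period, z - (hi - 8)
    raise TransitionElementError(
        f"element with atomic number {z} is a transition element"
    )


@dataclass(frozen=True)
class AtomInfo:
    symbol: str
    period: int
    family: int
    coords: Optional[tuple[float, float]] = None


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    ``bonds`` hold heavy-atom bonds only, each as ``(i, j, order)`` with
    ``i < j`` and ``order`` one of :data:`BOND_ORDERS`.  ``pka_shifted``
    defaults to all zeros and is filled by :func:`apply_pka`.
    """

    mol_id: str
    atoms: list[AtomInfo]
    bonds: list[tuple[int, int, str]]
    pka_shifted: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise MoleculeError(f"invalid bond ({i}, {j}) in {self.mol_id}")
            if (i, j) in seen:
                raise MoleculeError(f"duplicate bond ({i}, {j}) in {self.mol_id}")
            seen.add((i, j))
            if order not in BOND_ORDERS:
                raise MoleculeError(f"unknown bond order {order!r}")
        if not self.pka_shifted:
            self.pka_shifted = [0.0] * n

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        return nx.is_connected(self.to_networkx())


class PkaProvider:
    """Table of calculated pKa values keyed by (molecule id, atom index).

    The default instance is empty: every atom falls back to a shifted
    feature value of 0.  Tables are loaded from CSV rows of
    ``mol_id,atom_index,pka`` with 0-based atom indices in input order.
    """

    def __init__(self, table: Optional[dict[str, dict[int, float]]] = None):
        self._table = table or {}

    @classmethod
    def from_csv(cls, path: str) -> "PkaProvider":
        table: dict[str, dict[int, float]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "mol_id":
                    continue
                mol_id, idx, pka = row[0], int(row[1]), float(row[2])
                table.setdefault(mol_id, {})[idx] = pka
        return cls(table)

    def get(self, mol_id: str, atom_index: int) -> Optional[float]:
        return self._table.get(mol_id, {}).get(atom_index)


def shifted_pka(graph: MolecularGraph, provider: PkaProvider) -> list[float]:
    """Per-atom pKa feature: provider value minus 7.0, or 0 when absent."""
    out = []
    for idx in range(graph.n_atoms):
        pka = provider.get(graph.mol_id, idx)
        out.append(0.0 if pka is None else pka - PKA_SHIFT)
    return out


def apply_pka(graph: MolecularGraph, provider: PkaProvider) -> MolecularGraph:
    """Fill ``graph.pka_shifted`` in place from the provider and return it."""
    graph.pka_shifted = shifted_pka(graph, provider)
    return graph


def ring_flags(graph: MolecularGraph) -> tuple[list[int], "CommonRingPredicate"]:
    """Per-atom cycle membership flags and a common-cycle pair predicate.

    An atom is flagged 1 iff it lies on some cycle; a pair (i, j) satisfies
    the predicate iff the two atoms lie on a common cycle.  Both reduce to
    membership in a biconnected component with at least three vertices.
    """
    g = graph.to_networkx()
    cyclic_components = [c for c in nx.biconnected_components(g) if len(c) >= 3]
    flags = [0] * graph.n_atoms
    membership: list[set[int]] = [set() for _ in range(graph.n_atoms)]
    for comp_id, comp in enumerate(cyclic_components):
        for node in comp:
            flags[node] = 1
            membership[node].add(comp_id)
    return flags, CommonRingPredicate(membership)


class CommonRingPredicate:
    def __init__(self, membership: list[set[int]]):
        self._membership = membership

    def __call__(self, i: int, j: int) -> int:
        return int(bool(self._membership[i] & self._membership[j]))


def shortest_path(graph: MolecularGraph, i: int, j: int) -> list[int]:
    """Minimum-bond path from i to j, lexicographically smallest on ties.

    The path is grown from ``i`` by always stepping to the lowest-index
    neighbour that still lies on some shortest path, which yields the
    lexicographically smallest atom-index sequence deterministically.
    """
    if i == j:
        raise ValueError("shortest_path requires two distinct atoms")
    g = graph.to_networkx()
    try:
        dist_to_j = nx.single_source_shortest_path_length(g, j)
    except nx.NodeNotFound:
        raise MoleculeError(f"atom index out of range in {graph.mol_id}")
    if i not in dist_to_j:
        raise DisconnectedMoleculeError(
            f"atoms {i} and {j} are in different fragments of {graph.mol_id}"
        )
    path = [i]
    current = i
    while current != j:
        step = min(
            n for n in g.neighbors(current) if dist_to_j[n] == dist_to_j[current] - 1
        )
        path.append(step)
        current = step
    return path


def _graph_from_rdkit(mol: Chem.Mol, mol_id: str) -> MolecularGraph:
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for atom in mol.GetAtoms():
        period, family = period_and_family(atom.GetAtomicNum())
        coords = None
        if conf is not None:
            pos = conf.GetAtomPosition(atom.GetIdx())
            coords = (pos.x, pos.y)
        atoms.append(AtomInfo(atom.GetSymbol(), period, family, coords))
    bonds = []
    for bond in mol.GetBonds():
        order = _RDKIT_BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise MoleculeError(
                f"unsupported bond type {bond.GetBondType()} in {mol_id}"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), order))
    graph = MolecularGraph(mol_id, atoms, sorted(bonds))
    if not graph.is_connected():
        raise DisconnectedMoleculeError(f"{mol_id} has multiple fragments")
    return graph


def from_smiles(smiles: str, mol_id: str = "mol") -> MolecularGraph:
    """Parse a SMILES string; a deterministic 2D layout is generated."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES: {smiles!r}")
    AllChem.Compute2DCoords(mol)
    return _graph_from_rdkit(mol, mol_id)


def _iter_smiles_records(path: str) -> Iterable[tuple[str, str, Optional[int]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 and parts[1] else f"mol{lineno}"
            label = int(parts[2]) if len(parts) > 2 and parts[2] else None
            yield smiles, mol_id, label


def read_molecules(path: str, fmt: str = "smiles") -> list[MolecularGraph]:
    """Read molecules from an SDF (V2000) or SMILES file.

    Unparseable, multi-fragment or transition-element records are skipped
    with a log message carrying their record index.  An unreadable file or
    a file with zero parseable records is fatal.
    """
    graphs: list[MolecularGraph] = []
    if fmt == "smiles":
        for index, (smiles, mol_id, _label) in enumerate(_iter_smiles_records(path)):
            try:
                graphs.append(from_smiles(smiles, mol_id))
            except MoleculeError as exc:
                logger.warning("skipping record %d (%s): %s", index, mol_id, exc)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(path, removeHs=True)
        for index, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping record %d: unparseable SDF record", index)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            mol_id = mol_id or f"mol{index}"
            try:
                graphs.append(_graph_from_rdkit(mol, mol_id))
            except MoleculeError as exc:
                logger.warning("skipping record %d (%s): %s", index, mol_id, exc)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'sdf' or 'smiles'")
    if not graphs:
        raise MoleculeError(f"no parseable molecules in {path}")
    return graphs
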