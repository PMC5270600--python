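"""The 19-feature atom-pair descriptor with frequency grouping.

Every ordered pair of heavy atoms contributes one candidate row of 19
features: eight atom-type features for each end atom, two relationship
features (common-ring flag, bond count of the shortest path) and one
cis/trans flag.  Identical rows are merged and their multiplicity kept as
a frequency column that is never itself treated as a feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TextIO

import numpy as np

from .chem_graph import (
    DisconnectedMoleculeError,
    MolecularGraph,
    ring_flags,
    shortest_path,
)

N_FEATURES = 19
#: decimals used when comparing the continuous pKa feature during grouping
PKA_DECIMALS = 2

CROSS_EPS = 1e-6


@dataclass(frozen=True)
class AtomTypeFeatures:
    """The eight per-atom features."""

    period: int
    family: int
    n_single: int
    n_double: int
    n_triple: int
    n_aromatic: int
    ring_flag: int
    pka_shifted: float

    def as_tuple(self) -> tuple:
        return (
            self.period,
            self.family,
            self.n_single,
            self.n_double,
            self.n_triple,
            self.n_aromatic,
            self.ring_flag,
            round(self.pka_shifted, PKA_DECIMALS),
        )


@dataclass(frozen=True)
class AtomPairFeatureSet:
    """One grouped descriptor row: 19 features plus a frequency."""

    features_i: AtomTypeFeatures
    features_j: AtomTypeFeatures
    ring_pair_flag: int
    path_bonds: int
    isomerism: int
    frequency: int = 1

    def feature_tuple(self) -> tuple:
        return (
            self.features_i.as_tuple()
            + self.features_j.as_tuple()
            + (self.ring_pair_flag, self.path_bonds, self.isomerism)
        )


@dataclass
class MoleculeDescriptor:
    """A molecule as its canonically ordered grouped atom-pair rows."""

    mol_id: str
    rows: list[AtomPairFeatureSet]
    n_pairs: int

    def feature_matrix(self) -> np.ndarray:
        """(n_rows, 19) float matrix in canonical row order."""
        if not self.rows:
            return np.empty((0, N_FEATURES))
        return np.array([row.feature_tuple() for row in self.rows], dtype=float)

    def frequencies(self) -> np.ndarray:
        return np.array([row.frequency for row in self.rows], dtype=float)

    def expanded(self) -> "MoleculeDescriptor":
        """Equivalent descriptor with every row at frequency 1 (ungrouped)."""
        rows = []
        for row in self.rows:
            for _ in range(row.frequency):
                rows.append(
                    AtomPairFeatureSet(
                        row.features_i,
                        row.features_j,
                        row.ring_pair_flag,
                        row.path_bonds,
                        row.isomerism,
                        frequency=1,
                    )
                )
        return MoleculeDescriptor(self.mol_id, rows, self.n_pairs)


def atom_type_features(graph: MolecularGraph, atom: int) -> AtomTypeFeatures:
    """The 8 atom-type features of one heavy atom.

    Bond counts refer to heavy-atom neighbours only; the pKa feature is
    the shifted value stored on the graph (0 when no provider entry).
    """
    if not 0 <= atom < graph.n_atoms:
        raise IndexError(f"atom index {atom} out of range")
    counts = {"single": 0, "double": 0, "triple": 0, "aromatic": 0}
    for i, j, order in graph.bonds:
        if atom in (i, j):
            counts[order] += 1
    flags, _ = ring_flags(graph)
    info = graph.atoms[atom]
    return AtomTypeFeatures(
        period=info.period,
        family=info.family,
        n_single=counts["single"],
        n_double=counts["double"],
        n_triple=counts["triple"],
        n_aromatic=counts["aromatic"],
        ring_flag=flags[atom],
        pka_shifted=graph.pka_shifted[atom],
    )


def _bond_order_map(graph: MolecularGraph) -> dict[tuple[int, int], str]:
    orders = {}
    for i, j, order in graph.bonds:
        orders[(i, j)] = order
        orders[(j, i)] = order
    return orders


def _aromatic_atoms(graph: MolecularGraph) -> set[int]:
    out = set()
    for i, j, order in graph.bonds:
        if order == "aromatic":
            out.update((i, j))
    return out


def isomerism_feature(graph: MolecularGraph, path: Sequence[int]) -> int:
    """cis/trans flag for the pair whose shortest path is ``path``.

    Returns -1 (cis) or 1 (trans) only when the path has at least three
    bonds, its first three bonds are single, double, single, and none of
    the first four atoms is aromatic; the geometry is judged from 2D
    coordinates as the side of each terminal atom relative to the line
    through the double bond.  Everything else returns 0.
    """
    if len(path) < 4:
        return 0
    orders = _bond_order_map(graph)
    window = path[:4]
    kinds = [orders[(window[k], window[k + 1])] for k in range(3)]
    if kinds != ["single", "double", "single"]:
        return 0
    aromatic = _aromatic_atoms(graph)
    if any(a in aromatic for a in window):
        return 0
    coords = [graph.atoms[a].coords for a in window]
    if any(c is None for c in coords):
        raise ValueError(
            f"cis/trans geometry for {graph.mol_id} requires 2D coordinates; "
            "generate a layout first"
        )
    p0, p1, p2, p3 = (np.asarray(c, dtype=float) for c in coords)
    axis = p2 - p1
    cross0 = axis[0] * (p0 - p1)[1] - axis[1] * (p0 - p1)[0]
    cross3 = axis[0] * (p3 - p1)[1] - axis[1] * (p3 - p1)[0]
    if abs(cross0) < CROSS_EPS or abs(cross3) < CROSS_EPS:
        return 0
    return -1 if (cross0 > 0) == (cross3 > 0) else 1


def build_descriptor(graph: MolecularGraph) -> MoleculeDescriptor:
    """Enumerate all ordered heavy-atom pairs, group identical rows.

    Rows are compared on their 19-feature vector (pKa rounded to
    :data:`PKA_DECIMALS`), merged with summed frequencies, and sorted
    lexicographically so serialized descriptors are bit-stable.
    """
    if not graph.is_connected():
        raise DisconnectedMoleculeError(f"{graph.mol_id} has multiple fragments")
    n = graph.n_atoms
    if n < 2:
        return MoleculeDescriptor(graph.mol_id, [], 0)

    flags, common_ring = ring_flags(graph)
    counts = [dict.fromkeys(("single", "double", "triple", "aromatic"), 0) for _ in range(n)]
    for i, j, order in graph.bonds:
        counts[i][order] += 1
        counts[j][order] += 1
    per_atom = [
        AtomTypeFeatures(
            period=graph.atoms[a].period,
            family=graph.atoms[a].family,
            n_single=counts[a]["single"],
            n_double=counts[a]["double"],
            n_triple=counts[a]["triple"],
            n_aromatic=counts[a]["aromatic"],
            ring_flag=flags[a],
            pka_shifted=graph.pka_shifted[a],
        )
        for a in range(n)
    ]

    grouped: dict[tuple, AtomPairFeatureSet] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            path = shortest_path(graph, i, j)
            row = AtomPairFeatureSet(
                features_i=per_atom[i],
                features_j=per_atom[j],
                ring_pair_flag=common_ring(i, j),
                path_bonds=len(path) - 1,
                isomerism=isomerism_feature(graph, path),
            )
            key = row.feature_tuple()
            if key in grouped:
                prev = grouped[key]
                grouped[key] = AtomPairFeatureSet(
                    prev.features_i,
                    prev.features_j,
                    prev.ring_pair_flag,
                    prev.path_bonds,
                    prev.isomerism,
                    frequency=prev.frequency + 1,
                )
            else:
                grouped[key] = row
    rows = [grouped[key] for key in sorted(grouped)]
    return MoleculeDescriptor(graph.mol_id, rows, n * (n - 1))


def write_descriptors(descriptors: Iterable[MoleculeDescriptor], fh: TextIO) -> None:
    """Serialize descriptors as TSV: 19 feature columns + frequency."""
    for desc in descriptors:
        fh.write(f"#mol {desc.mol_id} {desc.n_pairs}\n")
        for row in desc.rows:
            values = list(row.feature_tuple()) + [row.frequency]
            fh.write("\t".join(_fmt(v) for v in values) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(int(v)) if v == int(v) else repr(v)
    return repr(v)


def read_descriptors(fh: TextIO) -> list[MoleculeDescriptor]:
    """Inverse of :func:`write_descriptors`."""
    descriptors: list[MoleculeDescriptor] = []
    current: Optional[MoleculeDescriptor] = None
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#mol "):
            _, mol_id, n_pairs = line.split(" ")
            current = MoleculeDescriptor(mol_id, [], int(n_pairs))
            descriptors.append(current)
            continue
        if current is None:
            raise ValueError("descriptor row before any #mol header")
        parts = line.split("\t")
        if len(parts) != N_FEATURES + 1:
            raise ValueError(f"expected {N_FEATURES + 1} columns, got {len(parts)}")
        vals = [float(p) for p in parts]
        fi = AtomTypeFeatures(*(int(v) for v in vals[:7]), vals[7])
        fj = AtomTypeFeatures(*(int(v) for v in vals[8:15]), vals[15])
        current.rows.append(
            AtomPairFeatureSet(
                fi, fj, int(vals[16]), int(vals[17]), int(vals[18]), int(vals[19])
            )
        )
    return descriptors
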