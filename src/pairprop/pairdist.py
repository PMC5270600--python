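"""Weighted frequency-matched pseudo-distance between molecule descriptors.

The distance between two molecules is built bottom-up: a weighted
Euclidean distance between 19-feature rows, a greedy frequency-matching
step that consumes the nearest rows of the target molecule until the
source row's frequency is spent, a directed root-mean-square aggregate,
and finally a symmetrization over both directions.  The result is a
pseudo-distance: non-negative, symmetric and zero on identity, but not
guaranteed to satisfy the triangle inequality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Iterable, Sequence, TextIO

import numpy as np

from .descriptor import MoleculeDescriptor, N_FEATURES

#: order of the 11 named weights; the first 8 are the atom-type weights
WEIGHT_NAMES = (
    "period",
    "family",
    "single_bonds",
    "double_bonds",
    "triple_bonds",
    "aromatic_bonds",
    "atom_ring_flag",
    "pka",
    "pair_ring_flag",
    "path_bonds",
    "cis_trans",
)


@dataclass(frozen=True)
class WeightVector:
    """11 independent feature weights expanded to 19 feature columns.

    The same atom-type weights apply to both atoms of a pair, which is
    what reduces the 19 per-column weights to 11 free parameters.
    """

    period: float = 0.927
    family: float = 0.400
    single_bonds: float = 0.370
    double_bonds: float = 0.013
    triple_bonds: float = 0.504
    aromatic_bonds: float = 0.931
    atom_ring_flag: float = 0.340
    pka: float = 0.688
    pair_ring_flag: float = 0.264
    path_bonds: float = 0.013
    cis_trans: float = 0.925

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ValueError(f"weight {f.name} is not finite")
            if value < 0:
                raise ValueError(f"weight {f.name} is negative")

    def as_array(self) -> np.ndarray:
        """The 11 weights in canonical order."""
        return np.array([getattr(self, name) for name in WEIGHT_NAMES])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "WeightVector":
        values = list(values)
        if len(values) != len(WEIGHT_NAMES):
            raise ValueError(f"expected {len(WEIGHT_NAMES)} weights")
        return cls(**dict(zip(WEIGHT_NAMES, map(float, values))))

    @classmethod
    def from_json(cls, fh: TextIO) -> "WeightVector":
        data = json.load(fh)
        unknown = set(data) - set(WEIGHT_NAMES)
        if unknown:
            raise ValueError(f"unknown weight names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_json(self, fh: TextIO) -> None:
        json.dump({name: getattr(self, name) for name in WEIGHT_NAMES}, fh, indent=1)
        fh.write("\n")


def expand_weights(w: WeightVector) -> np.ndarray:
    """Expand the 11 weights to the 19 feature columns.

    Columns 1-8 and 9-16 carry the atom-type weights (identically for both
    atoms), 17-18 the relationship weights and 19 the cis/trans weight.
    """
    atom = w.as_array()[:8]
    return np.concatenate(
        [atom, atom, [w.pair_ring_flag, w.path_bonds, w.cis_trans]]
    )


def feature_distance(a: Sequence[float], b: Sequence[float], w19: Sequence[float]) -> float:
    """Euclidean norm of the component-wise weighted feature difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w19 = np.asarray(w19, dtype=float)
    if a.shape != (N_FEATURES,) or b.shape != (N_FEATURES,):
        raise ValueError(f"feature rows must have length {N_FEATURES}")
    return float(np.sqrt(np.sum((w19 * (a - b)) ** 2)))


def _row_distances(a_features: np.ndarray, B: MoleculeDescriptor, w19: np.ndarray) -> np.ndarray:
    diff = w19 * (B.feature_matrix() - a_features)
    return np.sqrt(np.sum(diff * diff, axis=1))


def _match_frequency(n_a: float, dists: np.ndarray, freqs: np.ndarray) -> float:
    """Greedy frequency-consuming match of one source row against B.

    ``dists`` are the row distances to B in canonical row order; ties in
    nearness resolve to the earlier canonical row via a stable sort.
    """
    order = np.argsort(dists, kind="stable")
    d = 0.0
    remaining = n_a
    for m in order:
        f_m = freqs[m]
        if remaining <= f_m:
            d += remaining * dists[m]
            return d
        d += f_m * dists[m]
        remaining -= f_m
    # B exhausted before the frequency was spent: ratio correction
    n_b = float(freqs.sum())
    return d * (n_a / n_b)


def frequency_matched_distance(
    a_row, B: MoleculeDescriptor, w19: Sequence[float]
) -> float:
    """The frequency-weighted minimum-distance term f(a_i, B).

    Starting from the source row's frequency n', repeatedly consume the
    nearest remaining row b_m of B: if n' fits in freq(b_m) add n'*dist
    and stop, else add freq(b_m)*dist, deduct and drop b_m.  If B runs out
    first the accumulated distance is rescaled by n_a / n_B.
    """
    if not B.rows:
        raise ValueError("cannot match against an empty descriptor")
    w19 = np.asarray(w19, dtype=float)
    a_features = np.array(a_row.feature_tuple(), dtype=float)
    dists = _row_distances(a_features, B, w19)
    return _match_frequency(float(a_row.frequency), dists, B.frequencies())


def directed_distance(
    A: MoleculeDescriptor, B: MoleculeDescriptor, w19: Sequence[float]
) -> float:
    """Root mean square of f(a_i, B) over all rows of A, normalized by n_A."""
    if not A.rows or not B.rows:
        raise ValueError("directed_distance requires nonempty descriptors")
    w19 = np.asarray(w19, dtype=float)
    a_mat = A.feature_matrix()
    b_mat = B.feature_matrix()
    b_freqs = B.frequencies()
    # all pairwise row distances at once, then the greedy match per row
    diff = a_mat[:, None, :] - b_mat[None, :, :]
    dmat = np.sqrt(np.einsum("ijk,ijk->ij", diff * w19, diff * w19))
    total = 0.0
    for idx, row in enumerate(A.rows):
        f = _match_frequency(float(row.frequency), dmat[idx], b_freqs)
        total += f * f
    return float(np.sqrt(total / A.n_pairs))


def pseudo_distance(
    A: MoleculeDescriptor,
    B: MoleculeDescriptor,
    w: WeightVector,
    rms_symmetrization: bool = False,
) -> float:
    """Symmetrized pseudo-distance between two molecules.

    By default the two directed distances combine as sqrt(d_AB^2 + d_BA^2);
    ``rms_symmetrization`` divides the sum by 2 (root-mean-square variant).
    """
    w19 = expand_weights(w)
    d_ab = directed_distance(A, B, w19)
    d_ba = directed_distance(B, A, w19)
    s = d_ab * d_ab + d_ba * d_ba
    if rms_symmetrization:
        s /= 2.0
    return float(np.sqrt(s))


@dataclass
class PseudoDistanceMatrix:
    """Symmetric molecule-by-molecule pseudo-distance matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def submatrix(self, indices: Sequence[int]) -> "PseudoDistanceMatrix":
        idx = np.asarray(indices, dtype=int)
        return PseudoDistanceMatrix(
            [self.ids[i] for i in idx], self.values[np.ix_(idx, idx)]
        )

    def write_tsv(self, fh: TextIO) -> None:
        fh.write("id\t" + "\t".join(self.ids) + "\n")
        for mol_id, row in zip(self.ids, self.values):
            fh.write(mol_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, fh: TextIO) -> "PseudoDistanceMatrix":
        header = fh.readline().rstrip("\n").split("\t")
        ids = header[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            rows.append([float(v) for v in parts[1:]])
        return cls(ids, np.array(rows))


def cross_distances(
    left: Sequence[MoleculeDescriptor],
    right: Sequence[MoleculeDescriptor],
    w: WeightVector,
    rms_symmetrization: bool = False,
) -> np.ndarray:
    """Rectangular block of pseudo-distances between two descriptor lists."""
    values = np.zeros((len(left), len(right)))
    for i, A in enumerate(left):
        for j, B in enumerate(right):
            values[i, j] = pseudo_distance(A, B, w, rms_symmetrization)
    return values


def pairwise_matrix(
    descriptors: Sequence[MoleculeDescriptor],
    w: WeightVector,
    rms_symmetrization: bool = False,
) -> PseudoDistanceMatrix:
    """All-pairs pseudo-distance matrix (upper triangle computed, mirrored)."""
    ids = [d.mol_id for d in descriptors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids in descriptor list")
    n = len(descriptors)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pseudo_distance(
                descriptors[i], descriptors[j], w, rms_symmetrization
            )
            values[i, j] = values[j, i] = d
    return PseudoDistanceMatrix(ids, values)
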