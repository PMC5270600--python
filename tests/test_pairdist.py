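import math

import numpy as np
import pytest

import pairprop as pp
from pairprop.descriptor import AtomPairFeatureSet, AtomTypeFeatures, MoleculeDescriptor
from pairprop.pairdist import (
    WEIGHT_NAMES,
    WeightVector,
    cross_distances,
    directed_distance,
    expand_weights,
    feature_distance,
    frequency_matched_distance,
    pairwise_matrix,
    pseudo_distance,
)

TABLE_INITIAL = {
    "period": 0.927,
    "family": 0.400,
    "single_bonds": 0.370,
    "double_bonds": 0.013,
    "triple_bonds": 0.504,
    "aromatic_bonds": 0.931,
    "atom_ring_flag": 0.340,
    "pka": 0.688,
    "pair_ring_flag": 0.264,
    "path_bonds": 0.013,
    "cis_trans": 0.925,
}


def make_atom(period=2, family=4):
    return AtomTypeFeatures(period, family, 1, 0, 0, 0, 0, 0.0)


def make_row(path_bonds=1, frequency=1, isomerism=0):
    a = make_atom()
    return AtomPairFeatureSet(a, a, 0, path_bonds, isomerism, frequency)


def make_desc(rows, mol_id="synthetic"):
    n_pairs = sum(r.frequency for r in rows)
    return MoleculeDescriptor(mol_id, list(rows), n_pairs)


def step_through_match(n_a, rows):
    """Oracle: literal 4-step frequency-consuming procedure.

    ``rows`` is a list of (distance, frequency) working copies.
    """
    pool = sorted(rows, key=lambda r: r[0])
    n_b = sum(f for _, f in rows)
    d = 0.0
    remaining = n_a
    while pool:
        dist, freq = pool.pop(0)
        if remaining <= freq:
            return d + remaining * dist
        d += freq * dist
        remaining -= freq
    return d * (n_a / n_b)


class TestWeightVector:
    def test_defaults_match_initial_column(self):
        w = WeightVector()
        for name, value in TABLE_INITIAL.items():
            assert getattr(w, name) == value

    def test_eleven_free_parameters(self):
        assert len(WEIGHT_NAMES) == 11
        assert len(WeightVector().as_array()) == 11

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(period=-0.1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(pka=float("nan"))

    def test_json_round_trip(self, tmp_path):
        w = WeightVector(period=0.5, path_bonds=0.2)
        path = tmp_path / "w.json"
        with open(path, "w") as fh:
            w.to_json(fh)
        with open(path) as fh:
            assert WeightVector.from_json(fh) == w


class TestExpandWeights:
    def test_all_ones(self):
        assert expand_weights(WeightVector.from_array([1.0] * 11)).tolist() == [1.0] * 19

    def test_period_only(self):
        w = WeightVector.from_array([0.927] + [0.0] * 10)
        w19 = expand_weights(w)
        assert w19[0] == 0.927 and w19[8] == 0.927
        assert np.count_nonzero(w19) == 2

    def test_zero_vector(self):
        assert not np.any(expand_weights(WeightVector.from_array([0.0] * 11)))

    def test_layout(self):
        w = WeightVector.from_array(np.arange(1.0, 12.0))
        w19 = expand_weights(w)
        assert w19[:8].tolist() == w19[8:16].tolist() == list(np.arange(1.0, 9.0))
        assert w19[16:].tolist() == [9.0, 10.0, 11.0]


class TestFeatureDistance:
    def test_identity(self):
        row = make_row().feature_tuple()
        assert feature_distance(row, row, np.ones(19)) == 0.0

    def test_weighted_path_difference(self):
        a = make_row(path_bonds=1).feature_tuple()
        b = make_row(path_bonds=3).feature_tuple()
        w19 = np.zeros(19)
        w19[17] = 0.5  # the path-bonds column
        assert feature_distance(a, b, w19) == pytest.approx(1.0)

    def test_all_zero_weights(self):
        a = make_row(path_bonds=1).feature_tuple()
        b = make_row(path_bonds=9).feature_tuple()
        assert feature_distance(a, b, np.zeros(19)) == 0.0

    def test_frequency_never_participates(self):
        a = make_row(frequency=1)
        b = make_row(frequency=50)
        assert feature_distance(
            a.feature_tuple(), b.feature_tuple(), np.ones(19)
        ) == 0.0


def path_weight_only():
    """w19 whose only nonzero column is path_bonds with weight 1."""
    w19 = np.zeros(19)
    w19[17] = 1.0
    return w19


class TestFrequencyMatchedDistance:
    def test_identical_row_with_enough_frequency(self):
        a = make_row(path_bonds=2, frequency=3)
        B = make_desc([make_row(path_bonds=2, frequency=5)])
        assert frequency_matched_distance(a, B, np.ones(19)) == 0.0

    def test_spec_micro_case_partial_consumption(self):
        # freq(a)=3; b1 at distance 1 with freq 2, b2 at distance 2 with
        # freq 5 -> d = 2*1 + 1*2 = 4
        a = make_row(path_bonds=1, frequency=3)
        B = make_desc(
            [make_row(path_bonds=2, frequency=2), make_row(path_bonds=3, frequency=5)]
        )
        d = frequency_matched_distance(a, B, path_weight_only())
        assert d == pytest.approx(4.0)
        assert d == pytest.approx(step_through_match(3, [(1.0, 2), (2.0, 5)]))

    def test_spec_micro_case_ratio_correction(self):
        # freq(a)=5 against a single row at distance 1 with freq 3:
        # d = 3*1 scaled by 5/3 = 5
        a = make_row(path_bonds=1, frequency=5)
        B = make_desc([make_row(path_bonds=2, frequency=3)])
        d = frequency_matched_distance(a, B, path_weight_only())
        assert d == pytest.approx(5.0)
        assert d == pytest.approx(step_through_match(5, [(1.0, 3)]))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_cases_match_step_through_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_rows = int(rng.integers(1, 6))
        path_values = rng.choice(np.arange(2, 12), size=n_rows, replace=False)
        freqs = rng.integers(1, 6, size=n_rows)
        B = make_desc(
            [make_row(path_bonds=int(p), frequency=int(f)) for p, f in zip(path_values, freqs)]
        )
        n_a = int(rng.integers(1, 20))
        a = make_row(path_bonds=1, frequency=n_a)
        expected = step_through_match(
            n_a, [(float(p - 1), int(f)) for p, f in zip(path_values, freqs)]
        )
        assert frequency_matched_distance(a, B, path_weight_only()) == pytest.approx(expected)

    def test_empty_B_rejected(self):
        with pytest.raises(ValueError):
            frequency_matched_distance(make_row(), make_desc([]), np.ones(19))


class TestDirectedDistance:
    def test_self_distance_zero(self, toy_descriptors):
        w19 = expand_weights(WeightVector())
        for d in toy_descriptors.values():
            if d.rows:
                assert directed_distance(d, d, w19) == 0.0

    def test_hand_case(self):
        # one row freq 2 vs one row freq 2 at weighted distance 1:
        # f = 2*1, result sqrt(4/2) = sqrt(2)
        A = make_desc([make_row(path_bonds=1, frequency=2)], "A")
        B = make_desc([make_row(path_bonds=2, frequency=2)], "B")
        assert directed_distance(A, B, path_weight_only()) == pytest.approx(math.sqrt(2))

    def test_homogeneity(self, toy_descriptors):
        A = toy_descriptors["pyridine"]
        B = toy_descriptors["acetic_acid"]
        w19 = expand_weights(WeightVector())
        assert directed_distance(A, B, 3.0 * w19) == pytest.approx(
            3.0 * directed_distance(A, B, w19)
        )

    def test_empty_rejected(self, toy_descriptors):
        with pytest.raises(ValueError):
            directed_distance(make_desc([]), toy_descriptors["ethane"], np.ones(19))


class TestPseudoDistance:
    def test_identity(self, toy_descriptors, default_weights):
        for d in toy_descriptors.values():
            if d.rows:
                assert pseudo_distance(d, d, default_weights) == 0.0

    def test_hand_symmetrization(self):
        # both directed distances sqrt(2) -> sqrt(2 + 2) = 2
        A = make_desc([make_row(path_bonds=1, frequency=2)], "A")
        B = make_desc([make_row(path_bonds=2, frequency=2)], "B")
        w = WeightVector.from_array([0.0] * 9 + [1.0, 0.0])
        assert pseudo_distance(A, B, w) == pytest.approx(2.0)

    def test_rms_variant(self):
        A = make_desc([make_row(path_bonds=1, frequency=2)], "A")
        B = make_desc([make_row(path_bonds=2, frequency=2)], "B")
        w = WeightVector.from_array([0.0] * 9 + [1.0, 0.0])
        assert pseudo_distance(A, B, w, rms_symmetrization=True) == pytest.approx(
            math.sqrt(2)
        )

    def test_symmetry(self, toy_descriptors, default_weights):
        descs = [d for d in toy_descriptors.values() if d.rows]
        for A in descs:
            for B in descs:
                assert pseudo_distance(A, B, default_weights) == pseudo_distance(
                    B, A, default_weights
                )

    def test_grouped_equals_target_expanded(self, toy_descriptors, default_weights):
        # grouping the *target* descriptor is pure compression: the greedy
        # match consumes expanded frequency-1 copies exactly like one
        # grouped row.  (Source-side expansion is NOT value-preserving:
        # the directed distance weights each source row's frequency
        # quadratically and the match pool resets per source row.)
        w19 = expand_weights(default_weights)
        descs = [d for d in toy_descriptors.values() if d.rows]
        for A in descs[:4]:
            for B in descs[:4]:
                grouped = directed_distance(A, B, w19)
                expanded = directed_distance(A, B.expanded(), w19)
                assert abs(grouped - expanded) < 1e-9
                for row in A.rows:
                    assert abs(
                        frequency_matched_distance(row, B, w19)
                        - frequency_matched_distance(row, B.expanded(), w19)
                    ) < 1e-9

    def test_homogeneity(self, toy_descriptors):
        A = toy_descriptors["pyridine"]
        B = toy_descriptors["ethane"]
        w = WeightVector()
        scaled = WeightVector.from_array(2.5 * w.as_array())
        assert pseudo_distance(A, B, scaled) == pytest.approx(
            2.5 * pseudo_distance(A, B, w)
        )


class TestPairwiseMatrix:
    def test_identical_molecules_zero_matrix(self, default_weights):
        descs = [
            make_desc([make_row(frequency=2)], mol_id=f"m{i}") for i in range(3)
        ]
        matrix = pairwise_matrix(descs, default_weights)
        assert not np.any(matrix.values)

    def test_consistency_with_elementwise(self, toy_descriptors, default_weights):
        descs = [d for d in toy_descriptors.values() if d.rows][:4]
        matrix = pairwise_matrix(descs, default_weights)
        for i, A in enumerate(descs):
            for j, B in enumerate(descs):
                assert matrix.values[i, j] == pytest.approx(
                    pseudo_distance(A, B, default_weights) if i != j else 0.0
                )

    def test_zero_diagonal_nonnegative(self, toy_descriptors, default_weights):
        descs = [d for d in toy_descriptors.values() if d.rows]
        matrix = pairwise_matrix(descs, default_weights)
        assert np.all(np.diag(matrix.values) == 0)
        assert np.all(matrix.values >= 0)
        assert np.array_equal(matrix.values, matrix.values.T)

    def test_duplicate_ids_rejected(self, default_weights):
        descs = [make_desc([make_row()], "same"), make_desc([make_row()], "same")]
        with pytest.raises(ValueError):
            pairwise_matrix(descs, default_weights)

    def test_tsv_round_trip(self, toy_descriptors, default_weights, tmp_path):
        descs = [d for d in toy_descriptors.values() if d.rows][:3]
        matrix = pairwise_matrix(descs, default_weights)
        path = tmp_path / "dmat.tsv"
        with open(path, "w") as fh:
            matrix.write_tsv(fh)
        with open(path) as fh:
            restored = pp.PseudoDistanceMatrix.read_tsv(fh)
        assert restored.ids == matrix.ids
        assert np.array_equal(restored.values, matrix.values)

    def test_cross_distances_match(self, toy_descriptors, default_weights):
        descs = [d for d in toy_descriptors.values() if d.rows]
        left, right = descs[:2], descs[2:5]
        block = cross_distances(left, right, default_weights)
        for i, A in enumerate(left):
            for j, B in enumerate(right):
                assert block[i, j] == pseudo_distance(A, B, default_weights)
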