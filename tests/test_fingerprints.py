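"""Circular fingerprints and per-bit selectivity statistics."""

import numpy as np
import pytest
from rdkit import Chem

from maosel.dataset import NON_SELECTIVE, SELECTIVE
from maosel.fingerprints import (
    BitStatTable,
    FingerprintMatrix,
    assign_zones,
    attach_substructures,
    binary_score_auc,
    bit_statistics,
    compute_fingerprints,
    fragment_mol,
    mean_bits_per_molecule,
    prevalence_filter,
    rank_auc,
    substructure_for_bit,
)


def brute_force_auc(scores, labels):
    """Independent O(n_pos * n_neg) pairwise oracle for the ROC AUC."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def table_from_matrix(matrix, classes, si=None):
    n_bits = matrix.shape[1]
    fm = FingerprintMatrix(
        matrix=matrix.astype(np.uint8), ids=[f"m{i}" for i in range(matrix.shape[0])], n_bits=n_bits
    )
    return bit_statistics(fm, classes, si)


class TestComputeFingerprints:
    def test_deterministic_and_equal_for_equal_structures(self):
        fps = compute_fingerprints(["c1ccccc1", "C1=CC=CC=C1"])
        assert np.array_equal(fps.matrix[0], fps.matrix[1])
        assert fps.matrix[0].sum() >= 1

    def test_aromatic_and_saturated_rings_differ(self):
        fps = compute_fingerprints(["c1ccccc1", "C1CCCCC1"])
        assert not np.array_equal(fps.matrix[0], fps.matrix[1])

    def test_n_bits_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            FingerprintMatrix(matrix=np.zeros((1, 100), dtype=np.uint8), ids=["a"], n_bits=100)


class TestBitStatistics:
    def test_printed_class_frequencies(self):
        # a bit carried by 9 of 34 selective and 5 of 92 non-selective
        classes = [SELECTIVE] * 34 + [NON_SELECTIVE] * 92
        col = np.array([1] * 9 + [0] * 25 + [1] * 5 + [0] * 87)
        matrix = np.column_stack([col, np.zeros(126, dtype=int)])
        stat = table_from_matrix(matrix, classes).stats[0]
        assert stat.freq_sel == pytest.approx(9 / 34)  # prints as 0.264
        assert stat.freq_nonsel == pytest.approx(5 / 92)  # prints as 0.054
        assert round(stat.freq_sel, 3) == 0.265 or round(stat.freq_sel, 2) == 0.26
        # closed-form AUC for those frequencies, cross-checked pairwise
        assert stat.auc_bit == pytest.approx(0.6052, abs=5e-5)
        assert stat.auc_bit == pytest.approx(brute_force_auc(col, [c == SELECTIVE for c in classes]), abs=1e-12)

    def test_nondiscriminative_bit_has_auc_half(self):
        assert binary_score_auc(0.4, 0.4) == pytest.approx(0.5)

    def test_label_swap_mirrors_auc(self, rng):
        matrix = (rng.random((40, 8)) < 0.4).astype(int)
        classes = [SELECTIVE] * 15 + [NON_SELECTIVE] * 25
        swapped = [NON_SELECTIVE] * 15 + [SELECTIVE] * 25
        for s, t in zip(table_from_matrix(matrix, classes).stats, table_from_matrix(matrix, swapped).stats):
            assert s.auc_bit == pytest.approx(1.0 - t.auc_bit, abs=1e-12)

    def test_both_auc_modes_match_pairwise_oracle(self, rng):
        """Closed-form bit AUC and rank-based SI AUC both equal the
        brute-force pairwise comparison on matrices up to 50x50."""
        for n, bits in ((20, 16), (50, 32)):
            matrix = (rng.random((n, bits)) < rng.uniform(0.1, 0.9, bits)).astype(int)
            n_sel = n // 3
            classes = [SELECTIVE] * n_sel + [NON_SELECTIVE] * (n - n_sel)
            si = 10.0 ** rng.normal(1.5, 1.0, n)
            table = table_from_matrix(matrix, classes, si)
            labels = [c == SELECTIVE for c in classes]
            for stat in table.stats:
                expected = brute_force_auc(matrix[:, stat.bit], labels)
                assert stat.auc_bit == pytest.approx(expected, abs=1e-12)
                carried = matrix[:, stat.bit].astype(bool)
                if 0 < carried.sum() < n:
                    expected_si = brute_force_auc(si, carried)
                    assert stat.auc_sirank == pytest.approx(expected_si, abs=1e-12)

    def test_sirank_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        if 0 < labels.sum() < 60:
            assert rank_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_row_order_invariance(self, rng):
        matrix = (rng.random((30, 8)) < 0.5).astype(int)
        classes = np.array([SELECTIVE] * 10 + [NON_SELECTIVE] * 20)
        perm = rng.permutation(30)
        a = table_from_matrix(matrix, list(classes))
        b = table_from_matrix(matrix[perm], list(classes[perm]))
        for s, t in zip(a.stats, b.stats):
            assert (s.freq_sel, s.freq_nonsel, s.auc_bit) == (t.freq_sel, t.freq_nonsel, t.auc_bit)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            table_from_matrix(np.ones((4, 2), dtype=int), [SELECTIVE] * 4)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("carriers,kept", [(13, True), (12, False)])
    def test_ten_percent_boundary_of_126(self, carriers, kept):
        classes = [SELECTIVE] * 34 + [NON_SELECTIVE] * 92
        col = np.array([1] * carriers + [0] * (126 - carriers))
        table = table_from_matrix(np.column_stack([col, col ^ 1]), classes)
        filtered = prevalence_filter(table, 0.10)
        assert (0 in [s.bit for s in filtered.stats]) == kept

    def test_zero_threshold_is_identity(self, rng):
        matrix = (rng.random((20, 8)) < 0.3).astype(int)
        table = table_from_matrix(matrix, [SELECTIVE] * 8 + [NON_SELECTIVE] * 12)
        assert len(prevalence_filter(table, 0.0)) == len(table)


class TestMeanBitsPerMolecule:
    def test_hand_built_matrix(self):
        matrix = np.array([[1, 1, 0], [0, 1, 0], [1, 1, 1], [0, 0, 0]])
        fm = FingerprintMatrix(matrix=np.column_stack([matrix, np.zeros((4, 1), int)]).astype(np.uint8),
                               ids=list("abcd"), n_bits=4)
        classes = [SELECTIVE, SELECTIVE, NON_SELECTIVE, NON_SELECTIVE]
        means = mean_bits_per_molecule(fm, [0, 1, 2], classes)
        assert means[SELECTIVE] == pytest.approx((2 + 1) / 2)
        assert means[NON_SELECTIVE] == pytest.approx((3 + 0) / 2)

    def test_all_zero_matrix_gives_zero(self):
        fm = FingerprintMatrix(matrix=np.zeros((4, 4), np.uint8), ids=list("abcd"), n_bits=4)
        means = mean_bits_per_molecule(fm, [0, 1], [SELECTIVE] * 2 + [NON_SELECTIVE] * 2)
        assert means == {SELECTIVE: 0.0, NON_SELECTIVE: 0.0}

    def test_empty_bit_subset_rejected(self):
        fm = FingerprintMatrix(matrix=np.zeros((2, 4), np.uint8), ids=list("ab"), n_bits=4)
        with pytest.raises(ValueError):
            mean_bits_per_molecule(fm, [], [SELECTIVE, NON_SELECTIVE])


class TestSubstructures:
    def test_single_environment_molecule_returns_itself(self):
        fps = compute_fingerprints(["C"])
        bit = int(np.flatnonzero(fps.matrix[0])[0])
        assert substructure_for_bit("C", bit) == "C"

    def test_absent_bit_raises(self):
        fps = compute_fingerprints(["C"])
        absent = int(np.flatnonzero(fps.matrix[0] == 0)[0])
        with pytest.raises(ValueError, match="does not carry"):
            substructure_for_bit("C", absent)

    def test_fragments_from_two_carriers_are_consistent(self):
        smiles = ["Oc1ccccc1C", "Oc1ccccc1CC"]
        fps = compute_fingerprints(smiles)
        shared = np.flatnonzero(fps.matrix[0] & fps.matrix[1])
        consistent = 0
        for bit in shared:
            a = fragment_mol(substructure_for_bit(smiles[0], int(bit)))
            b = fragment_mol(substructure_for_bit(smiles[1], int(bit)))
            assert a is not None and b is not None
            qa = Chem.MolFromSmarts(Chem.MolToSmiles(a))
            qb = Chem.MolFromSmarts(Chem.MolToSmiles(b))
            if b.HasSubstructMatch(qa) or a.HasSubstructMatch(qb):
                consistent += 1
        assert consistent >= len(shared) // 2  # folding collisions are possible but rare


class TestZones:
    def test_empty_zone_map_leaves_all_unlabelled(self, rng):
        matrix = (rng.random((10, 4)) < 0.5).astype(int)
        table = table_from_matrix(matrix, [SELECTIVE] * 4 + [NON_SELECTIVE] * 6)
        assert all(s.zone is None for s in assign_zones(table, {}).stats)

    def test_planted_fragment_bit_labelled_zone_a(self, synthetic_126):
        records, gt = synthetic_126
        fps = compute_fingerprints(records)
        classes = [r.selectivity_class for r in records]
        table = prevalence_filter(bit_statistics(fps, classes), 0.10)
        table = attach_substructures(table, records, fps)
        zoned = assign_zones(table, {"[I]": "A"})
        iodine_zones = [s.zone for s in zoned.stats if s.substructure_smiles and "I" in s.substructure_smiles]
        assert iodine_zones and all(z == "A" for z in iodine_zones)
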