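import numpy as np
import pytest

from tracenet.info import (
    ResponseMatrix,
    binomial_exact_test,
    confusion_matrix_information,
    measure_responses,
    multiple_cell_information,
    select_best_cells,
    single_cell_information,
)


def brute_force_mutual_information(confusion):
    """Independent oracle: I(S;D) = H(S) + H(D) - H(S,D) over the joint
    count table."""
    p = np.asarray(confusion, float) / np.sum(confusion)

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log2(q))

    return entropy(p.sum(axis=1)) + entropy(p.sum(axis=0)) - entropy(p.ravel())


class TestResponseMatrix:
    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            ResponseMatrix(rates=np.full((2, 2, 2), 1.5), grouping="identity")
        with pytest.raises(ValueError):
            ResponseMatrix(rates=np.full((2, 2, 2), -0.1), grouping="identity")

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        resp = ResponseMatrix(rates=rng.random((3, 2, 4)), grouping="identity")
        p = tmp_path / "r.csv"
        resp.to_csv(p)
        back = ResponseMatrix.from_csv(p)
        assert np.allclose(back.rates, resp.rates)


class TestSingleCellInformation:
    def test_perfectly_selective_binary_cell_carries_one_bit(self):
        # fires 1 for every transform of class 0, 0 for class 1
        rates = np.zeros((1, 2, 4))
        rates[0, 0, :] = 1.0
        info, best = single_cell_information(ResponseMatrix(rates, "identity"))
        assert info[0] == pytest.approx(1.0)
        assert best[0] == 0

    def test_half_fire_cell_hand_computed(self):
        # class 0 transforms (0, 1); class 1 transforms (0, 0).
        # I(s=1) = log2(1/0.75) ~ 0.415 bits, the cell's best class is 1
        rates = np.zeros((1, 2, 2))
        rates[0, 0] = [0.0, 1.0]
        info, best = single_cell_information(ResponseMatrix(rates, "identity"))
        assert best[0] == 1
        assert info[0] == pytest.approx(np.log2(4.0 / 3.0))

    def test_constant_cell_carries_zero_bits(self):
        rates = np.full((1, 3, 5), 0.4)
        info, _ = single_cell_information(ResponseMatrix(rates, "identity"))
        assert info[0] == 0.0

    def test_class_permutation_invariance(self):
        rng = np.random.default_rng(1)
        rates = rng.random((6, 4, 5))
        info, _ = single_cell_information(ResponseMatrix(rates, "identity"))
        perm = [2, 0, 3, 1]
        info_p, _ = single_cell_information(
            ResponseMatrix(rates[:, perm, :], "identity"))
        assert np.allclose(np.sort(info), np.sort(info_p))

    def test_information_bounded_by_log_bins(self):
        rng = np.random.default_rng(2)
        rates = rng.random((20, 3, 7))
        info, _ = single_cell_information(ResponseMatrix(rates, "identity"),
                                          n_bins=8)
        assert np.all(info >= 0)
        assert np.all(info <= np.log2(8) + 1e-9)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            single_cell_information(
                ResponseMatrix(np.zeros((1, 2, 2)), "identity"), n_bins=1)


class TestSelectBestCells:
    def test_top_k_per_class_ranked_by_information(self):
        info = np.array([0.9, 0.1, 0.5, 0.8, 0.3, 0.7])
        best = np.array([0, 0, 0, 1, 1, 1])
        sel = select_best_cells(info, best, k=2, n_classes=2)
        assert sel.per_class[0] == [0, 2]
        assert sel.per_class[1] == [3, 5]
        assert sel.shortfall == {0: 0, 1: 0}
        assert sel.cells == [0, 2, 3, 5]

    def test_tie_breaks_to_lower_cell_index(self):
        info = np.array([0.5, 0.5, 0.5])
        best = np.zeros(3, dtype=int)
        sel = select_best_cells(info, best, k=2, n_classes=1)
        assert sel.per_class[0] == [0, 1]

    def test_shortfall_reported_when_class_lacks_cells(self):
        info = np.array([0.9, 0.8])
        best = np.array([0, 0])
        sel = select_best_cells(info, best, k=3, n_classes=2)
        assert sel.shortfall == {0: 1, 1: 3}
        assert sel.per_class[1] == []


class TestMultipleCellInformation:
    def test_orthogonal_population_decodes_perfectly(self):
        # one indicator cell per class, constant across transforms
        n_classes, n_transforms = 4, 6
        rates = np.zeros((n_classes, n_classes, n_transforms))
        for s in range(n_classes):
            rates[s, s, :] = 1.0
        resp = ResponseMatrix(rates, "identity")
        bits, pc, conf = multiple_cell_information(resp, list(range(n_classes)))
        assert pc == pytest.approx(100.0)
        assert bits == pytest.approx(np.log2(n_classes))
        assert np.array_equal(conf, np.eye(n_classes, dtype=int) * n_transforms)

    def test_uninformative_population_near_chance(self):
        rates = np.full((3, 4, 8), 0.5)
        resp = ResponseMatrix(rates, "identity")
        bits, pc, _ = multiple_cell_information(resp, [0, 1, 2])
        # all similarities tie -> always decodes class 0
        assert bits == pytest.approx(0.0)
        assert pc == pytest.approx(25.0)

    def test_single_transform_rejected(self):
        resp = ResponseMatrix(np.zeros((2, 2, 1)), "identity")
        with pytest.raises(ValueError):
            multiple_cell_information(resp, [0, 1])

    def test_empty_cell_list_rejected(self):
        resp = ResponseMatrix(np.zeros((2, 2, 2)), "identity")
        with pytest.raises(ValueError):
            multiple_cell_information(resp, [])

    def test_decoding_is_scale_invariant(self):
        rng = np.random.default_rng(3)
        rates = rng.random((5, 3, 4))
        a = multiple_cell_information(ResponseMatrix(rates, "identity"),
                                      list(range(5)))
        b = multiple_cell_information(ResponseMatrix(rates * 0.5, "identity"),
                                      list(range(5)))
        assert a[0] == pytest.approx(b[0])
        assert a[1] == pytest.approx(b[1])


class TestConfusionInformation:
    def test_identity_confusion_gives_log2_classes(self):
        for n in (2, 3, 5):
            conf = np.eye(n, dtype=int) * 7
            assert confusion_matrix_information(conf) == pytest.approx(np.log2(n))

    def test_uniform_confusion_gives_zero(self):
        assert confusion_matrix_information(np.full((4, 4), 3)) == pytest.approx(0.0)

    def test_matches_entropy_decomposition_oracle(self):
        rng = np.random.default_rng(4)
        conf = rng.integers(0, 20, size=(5, 5))
        conf[0, 0] += 1  # ensure non-empty
        assert confusion_matrix_information(conf) == pytest.approx(
            brute_force_mutual_information(conf))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix_information(np.zeros((3, 3)))


class TestBinomialTest:
    def test_three_of_three_at_even_chance(self):
        assert binomial_exact_test(3, 3, 0.5) == pytest.approx(0.125)

    def test_zero_successes_gives_one(self):
        assert binomial_exact_test(0, 10, 0.3) == pytest.approx(1.0)

    def test_matches_exact_tail_sum(self):
        from math import comb
        k, n, p = 14, 20, 0.25
        tail = sum(comb(n, j) * p**j * (1 - p)**(n - j) for j in range(k, n + 1))
        assert binomial_exact_test(k, n, p) == pytest.approx(tail)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            binomial_exact_test(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_exact_test(1, 3, 1.0)


class TestMeasureResponses:
    def test_groupings_are_transposes_of_the_same_rates(self, tiny_bank,
                                                        small_network):
        from tracenet import gabor, stimuli
        s = stimuli.generate_flag_set(2, wind_levels=[0.0, 200.0],
                                      image_size=32, seed=6)
        enc = gabor.encode_set(s, tiny_bank)
        enc = enc / np.linalg.norm(enc, axis=1, keepdims=True)
        by_id = measure_responses(small_network, enc, s.labels(), "identity")
        by_def = measure_responses(small_network, enc, s.labels(), "deformation")
        assert by_id.rates.shape == (64, 2, 4)
        assert by_def.rates.shape == (64, 2, 4)
        # the same multiset of measured rates, rearranged
        assert np.allclose(np.sort(by_id.rates.reshape(64, -1), axis=1),
                           np.sort(by_def.rates.reshape(64, -1), axis=1))

    def test_incomplete_factorial_rejected(self, tiny_bank, small_network):
        from tracenet import gabor, stimuli
        s = stimuli.generate_flag_set(2, wind_levels=[0.0, 200.0],
                                      image_size=32, seed=6)
        enc = gabor.encode_set(s, tiny_bank)
        with pytest.raises(ValueError):
            measure_responses(small_network, enc[:-1], s.labels()[:-1],
                              "identity")

    def test_unknown_grouping_rejected(self, tiny_bank, small_network):
        with pytest.raises(ValueError):
            measure_responses(small_network, np.zeros((0, 1)), [], "pose")
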