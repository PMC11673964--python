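"""Wavelet-packet tree: structure, Parseval, zeroing identity, compression."""

import numpy as np
import pytest

from ecgkit import (SynthConfig, compression_summary, daubechies_filters,
                    dwt_step, generate_ecg, wpt_decompose, wpt_reconstruct,
                    zero_overlap)
from ecgkit.errors import (IncompatibleTreesError, InvalidLevelError,
                           TooShortError)


@pytest.fixture(scope="module")
def random_tree():
    x = np.random.default_rng(0).standard_normal(1024)
    return x, wpt_decompose(x, daubechies_filters(4), levels=4)


class TestDecompose:
    def test_length16_four_levels_gives_unit_leaves(self):
        tree = wpt_decompose(np.arange(16.0), daubechies_filters(1), levels=4)
        assert len(tree.leaves()) == 16
        for key in tree.leaves():
            assert tree.nodes[key].size == 1

    def test_single_level_equals_dwt_step(self):
        x = np.random.default_rng(1).standard_normal(64)
        bank = daubechies_filters(3)
        tree = wpt_decompose(x, bank, levels=1)
        a, d = dwt_step(x, bank)
        assert np.array_equal(tree.nodes[(1, 0)], a)
        assert np.array_equal(tree.nodes[(1, 1)], d)

    def test_energy_conserved_at_every_level(self, random_tree):
        x, tree = random_tree
        e = np.sum(x**2)
        for level in range(1, 5):
            assert tree.level_energy(level) == pytest.approx(e, rel=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            wpt_decompose(np.ones(15), daubechies_filters(1), levels=4)


class TestZeroOverlap:
    def test_empty_set_is_identity(self, random_tree):
        _, tree = random_tree
        out, report = zero_overlap(tree, ())
        for key, arr in tree.nodes.items():
            assert np.array_equal(out.nodes[key], arr)
        assert report.n_zeroed == 0
        assert report.energy_zeroed == 0.0

    def test_constant_signal_detail_nodes_carry_no_energy(self):
        tree = wpt_decompose(np.ones(256), daubechies_filters(4), levels=4)
        _, report = zero_overlap(tree, (3, 4))
        assert report.energy_zeroed == pytest.approx(0.0, abs=1e-16)

    def test_rmse_identity(self, random_tree):
        x, tree = random_tree
        zeroed, report = zero_overlap(tree, (3, 4))
        recon = wpt_reconstruct(zeroed)
        sq_err = np.sum((recon.samples - x) ** 2)
        assert sq_err == pytest.approx(report.leaf_energy_zeroed, rel=1e-8)

    def test_rmse_monotone_in_zero_levels(self, random_tree):
        x, tree = random_tree
        rmses = []
        for levels in [(), (4,), (3, 4), (2, 3, 4)]:
            zeroed, _ = zero_overlap(tree, levels)
            recon = wpt_reconstruct(zeroed)
            rmses.append(float(np.sqrt(np.mean((recon.samples - x) ** 2))))
        assert all(a <= b + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_clean_ecg_correlation_after_default_zeroing(self):
        # at 1 kHz the retained pure-approximation band (0 - fs/32) covers
        # virtually all template energy
        rec = generate_ecg(SynthConfig(heart_rate=75.0, duration=10.0,
                                       sampling_rate=1000.0, seed=0))
        tree = wpt_decompose(rec, daubechies_filters(4), levels=4)
        zeroed, _ = zero_overlap(tree, (3, 4))
        recon = wpt_reconstruct(zeroed)
        corr = np.corrcoef(rec.samples, recon.samples)[0, 1]
        assert corr >= 0.99

    def test_level_out_of_range(self, random_tree):
        _, tree = random_tree
        with pytest.raises(InvalidLevelError):
            zero_overlap(tree, (5,))

    def test_magnitude_policy_zeros_about_half(self, random_tree):
        _, tree = random_tree
        zeroed, _ = zero_overlap(tree, (3,), policy="magnitude", quantile=0.5)
        for pos in range(8):
            arr = zeroed.nodes[(3, pos)]
            frac = np.count_nonzero(arr == 0) / arr.size
            assert 0.4 <= frac <= 0.6


class TestReconstruct:
    @pytest.mark.parametrize("n", [64, 100, 255, 1024])
    @pytest.mark.parametrize("order", [1, 4, 10])
    def test_perfect_reconstruction(self, n, order):
        x = np.random.default_rng(n + order).standard_normal(n)
        bank = daubechies_filters(order)
        tree = wpt_decompose(x, bank, levels=4)
        recon = wpt_reconstruct(tree, bank)
        assert recon.samples.size == n
        assert np.max(np.abs(recon.samples - x)) < 1e-8

    def test_all_zero_tree_reconstructs_zero(self):
        tree = wpt_decompose(np.zeros(128), daubechies_filters(2), levels=4)
        assert np.allclose(wpt_reconstruct(tree).samples, 0.0)


class TestCompressionSummary:
    def test_identical_trees(self, random_tree):
        _, tree = random_tree
        s = compression_summary(tree, tree)
        assert s.fraction_removed == 0.0
        assert s.energy_retained == 1.0

    def test_counting_identity_after_full_zeroing(self, random_tree):
        _, tree = random_tree
        zeroed, _ = zero_overlap(tree, (3, 4))
        s = compression_summary(tree, zeroed)
        nz_before = sum(int(np.count_nonzero(tree.nodes[(lvl, p)]))
                        for lvl in (1, 2, 3, 4) for p in range(2**lvl))
        nz_removed = nz_before - sum(
            int(np.count_nonzero(zeroed.nodes[(lvl, p)]))
            for lvl in (1, 2, 3, 4) for p in range(2**lvl))
        assert s.fraction_removed == pytest.approx(nz_removed / nz_before)
        assert 0.0 < s.energy_retained < 1.0

    def test_median_threshold_removes_half_of_targeted(self, random_tree):
        _, tree = random_tree
        zeroed, _ = zero_overlap(tree, (3,), policy="magnitude", quantile=0.5)
        removed = sum(int(np.count_nonzero(tree.nodes[(3, p)]))
                      - int(np.count_nonzero(zeroed.nodes[(3, p)]))
                      for p in range(8))
        targeted = sum(tree.nodes[(3, p)].size for p in range(8))
        assert removed / targeted == pytest.approx(0.5, abs=0.05)

    def test_structure_mismatch_rejected(self, random_tree):
        _, tree = random_tree
        other = wpt_decompose(np.ones(512), daubechies_filters(4), levels=4)
        with pytest.raises(IncompatibleTreesError):
            compression_summary(tree, other)
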