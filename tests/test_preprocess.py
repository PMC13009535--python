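"""Censoring, global-signal regression, RSFC, gradients, and label-map ops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connvar import preprocess as pp
from connvar.synthdata import RunTimeSeries


def make_run(data, rms=None, censored=None):
    n = len(data)
    return RunTimeSeries(
        data=np.asarray(data, dtype=float),
        rms=np.asarray(rms if rms is not None else np.full(n, 0.05), dtype=float),
        censored=np.asarray(
            censored if censored is not None else np.zeros(n, bool), dtype=bool
        ),
        run_id="test",
    )


class TestCensorFrames:
    def test_single_spike_marks_neighbors_and_short_head_segment(self):
        rms = [0.1, 0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        mask, valid = pp.censor_frames(rms)
        assert np.flatnonzero(mask).tolist() == [0, 1, 2, 3]
        assert valid

    def test_clean_run_untouched(self):
        mask, valid = pp.censor_frames(np.full(20, 0.1))
        assert not mask.any()
        assert valid

    def test_two_spikes_shred_run_into_invalidity(self):
        rms = np.full(10, 0.1)
        rms[[3, 8]] = 0.3
        mask, valid = pp.censor_frames(rms)
        # surviving segments {0,1} and {6} are shorter than 5 frames
        assert mask.all()
        assert not valid

    def test_idempotent_on_surviving_frames(self, rng):
        rms = rng.uniform(0.02, 0.3, 60)
        mask, _ = pp.censor_frames(rms)
        mask2, valid2 = pp.censor_frames(rms[~mask])
        assert not mask2.any()
        assert valid2

    def test_empty_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            pp.censor_frames([])
        with pytest.raises(ValueError):
            pp.censor_frames([-0.1, 0.1, 0.1, 0.1, 0.1])


class TestGlobalSignalRegression:
    def test_common_series_removed_entirely(self, rng):
        series = rng.standard_normal(30)
        run = make_run(np.tile(series[:, None], (1, 4)))
        out = pp.regress_global_signal(run)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_data_only_demeaned(self, rng):
        n = 200
        g = rng.standard_normal(n)
        x = rng.standard_normal(n)
        x -= x @ g / (g @ g) * g  # orthogonal to the shared series
        data = np.column_stack([g + x, g - x])  # global = g exactly
        out = pp.regress_global_signal(make_run(data))
        resid = data - data.mean(axis=0)
        # projection removes the g-component; the x-component survives
        assert abs(np.corrcoef(out.data[:, 0], x)[0, 1]) > 0.99

    def test_matches_normal_equations_oracle(self, rng):
        data = rng.standard_normal((6, 3))
        censored = np.array([False, False, True, False, False, False])
        run = make_run(data, censored=censored)
        out = pp.regress_global_signal(run)
        g = data.mean(axis=1)
        d = np.r_[0.0, np.diff(g)]
        x = np.column_stack([g, d, np.ones(6)])
        keep = ~censored
        beta = np.linalg.inv(x[keep].T @ x[keep]) @ x[keep].T @ data[keep]
        np.testing.assert_allclose(out.data[keep], data[keep] - x[keep] @ beta,
                                   atol=1e-10)
        # censored frames pass through untouched
        np.testing.assert_array_equal(out.data[censored], data[censored])


class TestComputeRsfc:
    def test_identical_parcels_hit_clipped_fisher_z(self, rng):
        base = rng.standard_normal(50)
        data = np.column_stack([base, base, rng.standard_normal(50)])
        z = pp.compute_rsfc([make_run(data)]).values
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_anticorrelated_pair(self, rng):
        base = rng.standard_normal(50)
        data = np.column_stack([base, -base, rng.standard_normal(50)])
        z = pp.compute_rsfc([make_run(data)]).values
        assert z[0, 1] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_matches_bruteforce_correlation_oracle(self):
        data = np.array(
            [
                [1.0, 2.0, 0.5],
                [2.0, 1.5, 1.0],
                [3.0, 3.5, 0.0],
                [4.0, 3.0, 2.0],
                [5.0, 5.5, 1.0],
                [6.0, 5.0, 3.0],
                [7.0, 7.5, 2.0],
                [8.0, 7.0, 4.0],
            ]
        )
        z = pp.compute_rsfc([make_run(data)]).values
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(data[:, i], data[:, j])[0, 1]
                assert z[i, j] == pytest.approx(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))

    def test_zero_variance_parcel_named_in_error(self, rng):
        data = rng.standard_normal((20, 3))
        data[:, 1] = 2.5
        with pytest.raises(ValueError, match=r"\[1\]"):
            pp.compute_rsfc([make_run(data)])

    def test_all_runs_invalid_rejected(self, rng):
        run = make_run(rng.standard_normal((10, 3)),
                       censored=np.ones(10, bool))
        with pytest.raises(ValueError):
            pp.compute_rsfc([run])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_output_symmetric_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((15, 5))
        z = pp.compute_rsfc([make_run(data)]).values
        np.testing.assert_allclose(z, z.T)
        np.testing.assert_array_equal(np.diag(z), 0.0)


class TestPrincipalGradient:
    def test_matches_eigendecomposition_oracle(self, rng):
        m = rng.standard_normal((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        grad = pp.principal_gradient(pp.ConnMatrix(m))
        xc = m - m.mean(axis=0)
        cov = xc.T @ xc / 4
        w, v = np.linalg.eigh(cov)
        oracle = xc @ v[:, -1]
        sign = np.sign(oracle @ grad.values)
        np.testing.assert_allclose(grad.values, sign * oracle, atol=1e-10)
        assert grad.variance_explained == pytest.approx(w[-1] / np.trace(cov))

    def test_two_block_structure_separates_blocks(self):
        n = 10
        block = np.repeat([1.0, -1.0], n // 2)
        m = 0.6 * np.outer(block, block)
        np.fill_diagonal(m, 0)
        grad = pp.principal_gradient(pp.ConnMatrix(m))
        assert len(set(np.sign(grad.values[: n // 2]))) == 1
        assert set(np.sign(grad.values)) == {-1.0, 1.0}

    def test_reference_alignment_fixes_sign(self, rng):
        m = rng.standard_normal((8, 8))
        m = (m + m.T) / 2
        ref = pp.principal_gradient(pp.ConnMatrix(m)).values
        flipped = pp.principal_gradient(pp.ConnMatrix(m), reference=-ref)
        assert np.corrcoef(flipped.values, -ref)[0, 1] > 0

    def test_thresholded_variant_stays_symmetric_input(self, rng):
        m = np.abs(rng.standard_normal((12, 12)))
        m = (m + m.T) / 2
        out = pp._threshold_top(m, 0.1)
        np.testing.assert_allclose(out, out.T)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pp.principal_gradient(pp.ConnMatrix(np.zeros((4, 4))))


class TestLabelMaps:
    def test_dice_identical_and_disjoint(self):
        a = np.array([1, 1, 2, 2])
        assert pp.dice_overlap(a, a) == 1.0
        assert pp.dice_overlap(np.array([1, 1]), np.array([2, 2])) == 0.0

    def test_dice_half_overlap_toy(self):
        # 6 vertices, 2 labels: each label overlaps in half its vertices
        a = np.array([1, 1, 1, 2, 2, 2])
        b = np.array([1, 2, 2, 2, 1, 1])
        # label 1: |A|=3,|B|=3, inter=1 -> 2/6; label 2: same -> mean = 1/3
        assert pp.dice_overlap(a, b) == pytest.approx(1 / 3)

    def test_dice_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.dice_overlap(np.array([1, 2]), np.array([1]))

    def test_fusion_majority_and_tie_rule(self):
        maps = [np.array([1, 1]), np.array([1, 2]), np.array([2, 2])]
        np.testing.assert_array_equal(pp.fuse_parcellations(maps), [1, 2])
        # 2 maps, labels {1,2}: tie resolved to the lowest label id
        np.testing.assert_array_equal(
            pp.fuse_parcellations([np.array([1]), np.array([2])]), [1]
        )

    def test_fusion_of_identical_maps_is_identity(self, rng):
        m = rng.integers(1, 5, 20)
        np.testing.assert_array_equal(pp.fuse_parcellations([m, m, m]), m)

    def test_agreement_identical_and_half_cases(self):
        a = [np.array([1, 2, 3])] * 2
        b = [np.array([1, 2, 3])] * 3
        np.testing.assert_allclose(pp.pairwise_parcellation_agreement(a, b), 1.0)
        # one vertex differs in half of B's maps -> 0.5 there
        b2 = [np.array([1, 2, 3]), np.array([9, 2, 3])]
        out = pp.pairwise_parcellation_agreement([np.array([1, 2, 3])], b2)
        np.testing.assert_allclose(out, [0.5, 1.0, 1.0])

    def test_agreement_matches_analytic_expectation_for_uniform_labels(self, rng):
        n_labels, n_maps, n_vertices = 4, 40, 50
        a = [rng.integers(1, n_labels + 1, n_vertices) for _ in range(n_maps)]
        b = [rng.integers(1, n_labels + 1, n_vertices) for _ in range(n_maps)]
        out = pp.pairwise_parcellation_agreement(a, b)
        assert abs(out.mean() - 1 / n_labels) < 0.02
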