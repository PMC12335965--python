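import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gfcpm.connectivity import (
    DegenerateDataError,
    ShapeError,
    build_confounds,
    build_design_regressors,
    build_gfc,
    compcor_components,
    compute_fd,
    edge_count,
    edge_pairs,
    extract_condition_segments,
    handwriting_speed_score,
    nodes_to_edge,
    regress_confounds,
    subject_gfc,
    temporal_filter,
)
from gfcpm.synthetic_cohort import Block, TaskDesign, make_task_design


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        fd, avg = compute_fd(np.zeros((20, 6)))
        assert np.all(fd == 0) and avg == 0.0

    def test_single_translation_step(self):
        mot = np.zeros((10, 6))
        mot[5:, 0] = 1.0  # 1-mm x step between frames 4 and 5
        fd, _ = compute_fd(mot)
        assert fd[5] == pytest.approx(1.0)
        assert fd[4] == 0.0 and fd[6] == 0.0

    def test_rotation_steps_scaled_by_sphere_radius(self):
        mot = np.zeros((10, 6))
        mot[3:, 3:] = 0.01  # 0.01 rad on all three rotations
        fd, _ = compute_fd(mot)
        assert fd[3] == pytest.approx(50 * 0.03)

    def test_first_frame_is_zero_and_average_includes_it(self):
        mot = np.zeros((4, 6))
        mot[1:, 1] = 2.0
        fd, avg = compute_fd(mot)
        assert fd[0] == 0.0
        assert avg == pytest.approx(fd.sum() / 4)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ShapeError):
            compute_fd(np.zeros((10, 5)))


class TestDesignRegressors:
    def test_all_fixation_design_has_no_regressors(self):
        d = TaskDesign(1.0, (Block("fixation", 0.0, 20.0),), 20.0)
        X, names = build_design_regressors(d)
        assert X.shape == (20, 0) and names == []

    def test_three_conditions_give_six_columns(self):
        X, names = build_design_regressors(make_task_design())
        assert X.shape == (318, 6)
        assert sum(n.endswith("_derivative") for n in names) == 3

    def test_single_block_peaks_with_hemodynamic_lag(self):
        """Oracle: explicit discrete convolution of the boxcar with the HRF."""
        from nilearn.glm.first_level import spm_hrf

        d = TaskDesign(
            1.0,
            (Block("fixation", 0, 10), Block("HFC-copy", 10, 30), Block("fixation", 40, 60)),
            100.0,
        )
        X, _ = build_design_regressors(d)
        box = np.zeros(100)
        box[10:40] = 1.0
        hrf = spm_hrf(1.0, oversampling=1)
        expected = np.array(
            [sum(box[t - k] * hrf[k] for k in range(min(t + 1, len(hrf)))) for t in range(100)]
        )
        assert np.allclose(X[:, 0], expected, atol=1e-10)
        peak = int(np.argmax(X[:, 0]))
        assert 10 + 4 <= peak <= 40 + 8  # peak lags block onset hemodynamically
        assert X[:10, 0] == pytest.approx(0.0)


class TestConfoundRegression:
    def test_intercept_only_demeans(self, rng):
        ts = rng.standard_normal((50, 3)) + 5.0
        resid = regress_confounds(ts, None)
        assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(resid, ts - ts.mean(axis=0), atol=1e-12)

    def test_perfect_fit_leaves_zero_residual(self, rng):
        c = rng.standard_normal(60)
        resid = regress_confounds(np.column_stack([c, 2 * c + 1]), c[:, None])
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_confounds(self, rng):
        ts = rng.standard_normal((80, 4))
        C = rng.standard_normal((80, 3))
        resid = regress_confounds(ts, C)
        dots = np.abs(C.T @ resid)
        norms = np.linalg.norm(C, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert np.all(dots <= 1e-8 * norms)

    def test_known_mixing_recovers_signal(self, rng):
        signal = rng.standard_normal(500)
        motion = rng.standard_normal(500)
        ts = (signal + 2.0 * motion)[:, None]
        resid = regress_confounds(ts, motion[:, None])
        r = np.corrcoef(resid[:, 0], signal)[0, 1]
        assert r > 0.99

    def test_collinear_columns_dropped_deterministically(self, rng, caplog):
        ts = rng.standard_normal((40, 2))
        c = rng.standard_normal(40)
        with caplog.at_level("WARNING", logger="gfcpm.connectivity"):
            resid = regress_confounds(ts, np.column_stack([c, 3 * c]))
        assert "collinear" in caplog.text
        assert np.allclose(resid, regress_confounds(ts, c[:, None]), atol=1e-10)


class TestTemporalFilter:
    def test_highpass_removes_constant(self):
        out = temporal_filter(np.full((200, 2), 7.0), tr=1.0, low_cut=0.008)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_passband_sinusoid_retained(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = temporal_filter(x, 1.0, 0.008, 0.09)
        amp_in = np.abs(np.fft.rfft(x[:, 0]))[50]
        amp_out = np.abs(np.fft.rfft(out[:, 0]))[50]
        assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 0.2 * t)[:, None]
        out = temporal_filter(x, 1.0, 0.008, 0.09)
        assert np.abs(np.fft.rfft(out[:, 0]))[200] <= 0.1 * np.abs(np.fft.rfft(x[:, 0]))[200]

    def test_output_length_and_zero_mean_after_highpass(self, rng):
        x = rng.standard_normal((317, 3))  # odd length exercises irfft n=
        out = temporal_filter(x, 1.0, low_cut=0.01)
        assert out.shape == x.shape
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            temporal_filter(np.zeros((50, 1)), tr=1.0, low_cut=0.008, high_cut=0.6)


class TestConditionExtraction:
    def make_design(self):
        blocks = (
            Block("fixation", 0, 10),
            Block("A", 10, 30),
            Block("fixation", 40, 10),
            Block("A", 50, 30),
            Block("B", 80, 20),
        )
        return TaskDesign(1.0, blocks, 100.0)

    def test_single_block_frame_count(self):
        d = self.make_design()
        ts = np.arange(100)[:, None].astype(float)
        seg = extract_condition_segments(ts, d, "B")
        assert seg.shape[0] == 20
        assert seg[0, 0] == 80

    def test_two_blocks_concatenated_in_order(self):
        d = self.make_design()
        ts = np.arange(100)[:, None].astype(float)
        seg = extract_condition_segments(ts, d, "A")
        assert seg.shape[0] == 60
        assert np.all(np.diff(seg[:, 0]) > 0)

    def test_shift_displaces_and_clips(self):
        d = self.make_design()
        ts = np.arange(100)[:, None].astype(float)
        seg = extract_condition_segments(ts, d, "B", shift_s=5.0)
        # window [85, 105) clipped at run end -> 15 frames
        assert seg.shape[0] == 15
        assert seg[0, 0] == 85

    def test_absent_condition_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            extract_condition_segments(np.zeros((100, 1)), self.make_design(), "C")


class TestGFC:
    def test_identical_series_hit_clamp(self, rng):
        x = rng.standard_normal(50)
        gfc = build_gfc([np.column_stack([x, x])])
        assert gfc.matrix[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        assert gfc.provenance["n_clamped_edges"] == 1

    def test_independent_noise_has_small_z(self, rng):
        X = rng.standard_normal((10000, 4))
        gfc = build_gfc([X])
        off = gfc.edge_vector
        assert np.all(np.abs(off) < 0.05)  # ~ few / sqrt(n-3)

    def test_264_nodes_give_34716_edges(self, rng):
        X = rng.standard_normal((30, 264))
        gfc = build_gfc([X])
        assert len(gfc.edge_vector) == 34716

    def test_symmetric_finite_zero_diagonal(self, small_cohort):
        gfc = subject_gfc(small_cohort.subjects[0])
        assert np.allclose(gfc.matrix, gfc.matrix.T)
        assert np.all(np.isfinite(gfc.matrix))
        assert np.all(np.diag(gfc.matrix) == 0)

    def test_zero_variance_node_named(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 1] = 2.5
        with pytest.raises(DegenerateDataError, match="1"):
            build_gfc([X])

    def test_pipeline_order_reproduces_latent_connectome(self, rng):
        """Regression + filtering + correlation on pure multivariate-normal
        data recovers the generating matrix within sampling error."""
        C = np.array(
            [
                [1.0, 0.5, 0.2, 0.0],
                [0.5, 1.0, 0.3, 0.1],
                [0.2, 0.3, 1.0, 0.4],
                [0.0, 0.1, 0.4, 1.0],
            ]
        )
        L = np.linalg.cholesky(C)
        X = rng.standard_normal((10000, 4)) @ L.T
        resid = regress_confounds(X, None)
        filt = temporal_filter(resid, 1.0, low_cut=0.008)
        gfc = build_gfc([filt])
        emp = np.tanh(gfc.matrix) + np.eye(4)
        assert np.linalg.norm(emp - C) / np.linalg.norm(C) < 0.05


class TestEdgeIndexing:
    def test_edge_count_matches_enumeration(self):
        for n in range(2, 301):
            assert edge_count(n) == len(list(itertools.combinations(range(n), 2)))

    def test_edge_count_examples(self):
        assert edge_count(264) == 34716
        assert edge_count(200) == 19900
        assert edge_count(2) == 1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            edge_count(1)

    def test_nodes_to_edge_roundtrip_264(self):
        i, j = edge_pairs(264)
        assert np.array_equal(nodes_to_edge(i, j, 264), np.arange(34716))


class TestCompCor:
    def test_components_capture_shared_noise(self, rng):
        shared = rng.standard_normal(300)
        noise_src = shared[:, None] + 0.1 * rng.standard_normal((300, 8))
        comps = compcor_components(noise_src, n_components=2)
        assert comps.shape == (300, 2)
        assert abs(np.corrcoef(comps[:, 0], shared)[0, 1]) > 0.95

    def test_confound_set_concatenates_components(self, rng):
        d = make_task_design()
        cs = build_confounds(
            motion=rng.standard_normal((318, 6)) * 0.01,
            design=d,
            noise_signals=rng.standard_normal((318, 10)),
        )
        assert cs.matrix.shape == (318, 6 + 6 + 5)
        assert len(cs.names) == 17


class TestHandwritingScore:
    def test_equal_times_give_zero_composite(self):
        with pytest.warns(UserWarning):
            score = handwriting_speed_score(
                np.array([30.0, 30.0, 30.0]), np.array([40.0, 40.0, 40.0])
            )
        assert np.all(score == 0)

    def test_fastest_subject_has_largest_composite(self):
        score = handwriting_speed_score(
            np.array([25.0, 30.0, 35.0, 40.0]), np.array([30.0, 36.0, 41.0, 44.0])
        )
        assert np.argmax(score) == 0
        assert np.all(np.diff(score) < 0)

    def test_three_subject_worked_example(self):
        """Hand-computed z(1/t) sums for HFC 30/35/40 s, LFC 35/40/45 s."""
        t_h = np.array([30.0, 35.0, 40.0])
        t_l = np.array([35.0, 40.0, 45.0])
        def z(v):
            return (v - v.mean()) / v.std(ddof=1)
        expected = z(1 / t_h) + z(1 / t_l)
        got = handwriting_speed_score(t_h, t_l)
        assert np.allclose(got, expected, atol=1e-12)
        assert np.all(np.argsort(got)[::-1] == [0, 1, 2])

    def test_invariant_to_relabeling(self, rng):
        t_h = rng.uniform(25, 45, 6)
        t_l = rng.uniform(30, 50, 6)
        perm = rng.permutation(6)
        assert np.allclose(
            handwriting_speed_score(t_h, t_l)[perm],
            handwriting_speed_score(t_h[perm], t_l[perm]),
        )

    @given(st.floats(0.1, 5.0))
    def test_antimonotone_in_each_copy_time(self, delta):
        t_h = np.array([30.0, 35.0, 40.0])
        t_l = np.array([35.0, 40.0, 45.0])
        base = handwriting_speed_score(t_h, t_l)[1]
        slower = t_h.copy()
        slower[1] += delta
        assert handwriting_speed_score(slower, t_l)[1] < base

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            handwriting_speed_score(np.array([30.0, -1.0]), np.array([40.0, 41.0]))
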