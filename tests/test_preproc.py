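import numpy as np
import pytest

from connmvpa import (
    FDSeries,
    MotionTrace,
    RoiTimeSeries,
    bandpass,
    discard_initial,
    framewise_displacement,
    parcellate,
    regress_nuisance,
    scrub,
)


def _ts(data, tr=2.0):
    data = np.asarray(data, dtype=float)
    return RoiTimeSeries(data=data, tr=tr, region_ids=np.arange(1, data.shape[1] + 1))


class TestDiscardInitial:
    def test_180_minus_5_gives_175(self, rng):
        ts = _ts(rng.standard_normal((180, 3)))
        out = discard_initial(ts)  # default k=5
        assert out.n_frames == 175
        assert np.array_equal(out.data, ts.data[5:])

    def test_identity_and_boundary(self, rng):
        ts = _ts(rng.standard_normal((180, 2)))
        assert discard_initial(ts, 0).n_frames == 180
        assert discard_initial(ts, 179).n_frames == 1

    def test_discarding_everything_errors(self, rng):
        ts = _ts(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError):
            discard_initial(ts, 10)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(MotionTrace(params=np.ones((20, 6))))
        assert np.all(fd.fd == 0) and not fd.flags.any()

    def test_one_degree_rotation_arc_length(self):
        # 1 deg on one axis: FD = 50 * pi/180 ~ 0.8727 mm
        p = np.zeros((5, 6))
        p[3:, 3] = 1.0
        fd = framewise_displacement(MotionTrace(params=p, unit="deg"))
        assert fd.fd[3] == pytest.approx(50 * np.pi / 180, abs=1e-9)
        assert fd.fd[3] == pytest.approx(0.8727, abs=5e-4)
        assert list(fd.flags) == [False, False, False, True, False]

    def test_sum_of_translation_deltas(self):
        p = np.zeros((4, 6))
        p[2:, :3] = 0.2  # 0.2 mm step on each translation axis
        fd = framewise_displacement(MotionTrace(params=p))
        assert fd.fd[2] == pytest.approx(0.6)
        assert fd.flags[2]  # 0.6 > 0.5 mm threshold

    def test_first_frame_zero_and_shift_invariance(self, rng):
        p = rng.standard_normal((30, 6)) * 0.1
        fd1 = framewise_displacement(MotionTrace(params=p))
        fd2 = framewise_displacement(MotionTrace(params=p + rng.standard_normal(6)))
        assert fd1.fd[0] == 0.0
        assert np.allclose(fd1.fd, fd2.fd)

    def test_radians_vs_degrees_consistency(self):
        p_deg = np.zeros((3, 6))
        p_deg[1:, 4] = 2.0
        p_rad = p_deg.copy()
        p_rad[:, 4] = np.deg2rad(p_deg[:, 4])
        fd_deg = framewise_displacement(MotionTrace(params=p_deg, unit="deg"))
        fd_rad = framewise_displacement(MotionTrace(params=p_rad, unit="rad"))
        assert np.allclose(fd_deg.fd, fd_rad.fd)

    def test_undeclared_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            MotionTrace(params=np.zeros((5, 6)), unit="furlongs")


class TestScrub:
    def _fd(self, flags):
        flags = np.asarray(flags, dtype=bool)
        fd = np.where(flags, 1.0, 0.0)
        return FDSeries(fd=fd, flags=flags, threshold_mm=0.5)

    def test_no_flags_is_identity(self, small_series):
        out, mask = scrub(small_series, self._fd(np.zeros(40)))
        assert out is small_series and not mask.any()

    def test_interior_flag_is_neighbor_mean(self):
        data = np.array([[0.0, 10.0], [99.0, 99.0], [2.0, 30.0]])
        ts = _ts(data)
        out, mask = scrub(ts, self._fd([0, 1, 0]))
        assert np.allclose(out.data[1], [1.0, 20.0])
        assert list(mask) == [False, True, False]

    def test_linear_fixture_recovered_exactly(self):
        t = np.arange(10.0)
        clean = np.column_stack([2 * t + 1, -t])
        data = clean.copy()
        flags = np.zeros(10, bool)
        flags[[3, 4, 7]] = True
        data[flags] = 999.0
        out, _ = scrub(_ts(data), self._fd(flags))
        assert np.allclose(out.data, clean)

    def test_boundary_run_takes_nearest_value(self):
        data = np.arange(5.0)[:, None]
        out, _ = scrub(_ts(data), self._fd([1, 1, 0, 0, 1]))
        assert np.allclose(out.data[:, 0], [2.0, 2.0, 2.0, 3.0, 3.0])

    def test_idempotent(self, rng):
        ts = _ts(rng.standard_normal((30, 3)))
        fd = self._fd(rng.random(30) < 0.2)
        once, mask1 = scrub(ts, fd)
        twice, mask2 = scrub(once, fd)
        assert np.array_equal(mask1, mask2)
        assert np.allclose(once.data, twice.data)

    def test_all_flagged_errors(self, small_series):
        with pytest.raises(ValueError, match="all frames"):
            scrub(small_series, self._fd(np.ones(40)))


class TestRegressNuisance:
    def test_empty_covariates_demeans(self, small_series):
        out = regress_nuisance(small_series, None)
        assert np.allclose(out.data, small_series.data - small_series.data.mean(0))

    def test_perfect_covariate_leaves_zero(self, rng):
        cov = rng.standard_normal((40, 1))
        ts = _ts(np.column_stack([cov[:, 0], 2 * cov[:, 0] + 5]))
        out = regress_nuisance(ts, cov)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_residuals_orthogonal_to_design(self, rng, small_series):
        cov = rng.standard_normal((40, 4))
        out = regress_nuisance(small_series, cov)
        inner = cov.T @ out.data
        norms = np.linalg.norm(cov, axis=0)[:, None] * np.linalg.norm(out.data, axis=0)
        assert np.all(np.abs(inner) < 1e-8 * norms)

    def test_orthogonal_covariate_changes_nothing(self, rng, small_series):
        cov = rng.standard_normal((40, 2))
        base = regress_nuisance(small_series, cov)
        # a covariate orthogonal to the design AND to every data column
        span = np.column_stack([np.ones(40), cov, small_series.data])
        q, _ = np.linalg.qr(span)
        extra = rng.standard_normal(40)
        extra -= q @ (q.T @ extra)
        again = regress_nuisance(small_series, np.column_stack([cov, extra]))
        assert np.allclose(again.data, base.data, atol=1e-10)

    def test_collinear_design_rejected_with_columns(self, rng):
        cov = rng.standard_normal((40, 2))
        cov = np.column_stack([cov, cov[:, 0] + cov[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(_ts(rng.standard_normal((40, 2))), cov)


class TestBandpass:
    @staticmethod
    def _sinusoid(freq_hz, tr=2.0, n=400):
        t = np.arange(n) * tr
        return _ts(np.sin(2 * np.pi * freq_hz * t)[:, None], tr=tr)

    def test_in_band_passes(self):
        ts = self._sinusoid(0.04)
        out = bandpass(ts)
        core = slice(60, -60)  # trim filter transients
        ratio = np.abs(out.data[core]).max() / np.abs(ts.data[core]).max()
        assert 0.9 < ratio < 1.1

    def test_out_of_band_attenuated(self):
        ts = self._sinusoid(0.2)
        out = bandpass(ts)
        core = slice(60, -60)
        assert np.abs(out.data[core]).max() < 0.1 * np.abs(ts.data[core]).max()

    def test_dc_removed(self):
        ts = _ts(np.full((200, 1), 7.0))
        out = bandpass(ts)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_cutoff_above_nyquist_rejected(self):
        ts = self._sinusoid(0.04)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, 0.01, 0.3)  # Nyquist = 0.25 at TR=2


class TestParcellate:
    def test_single_label_is_global_mean(self, rng):
        vol = rng.standard_normal((4, 4, 2, 10))
        atlas = np.ones((4, 4, 2), dtype=int)
        ts = parcellate(vol, atlas, tr=2.0)
        assert ts.n_regions == 1
        assert np.allclose(ts.data[:, 0], vol.reshape(-1, 10).mean(0))

    def test_constructed_label_values_exact(self):
        # voxels of label k carry value k*t at frame t
        atlas = np.array([[[1, 1], [2, 3]]])
        n_frames = 6
        vol = np.zeros(atlas.shape + (n_frames,))
        for t in range(n_frames):
            vol[..., t] = atlas * t
        ts = parcellate(vol, atlas, tr=2.0)
        assert np.array_equal(ts.region_ids, [1, 2, 3])
        for col, k in enumerate([1, 2, 3]):
            assert np.allclose(ts.data[:, col], k * np.arange(n_frames))

    def test_116_labels_give_116_columns(self, rng):
        atlas = np.arange(1, 117).reshape(4, 29, 1)
        vol = rng.standard_normal(atlas.shape + (5,))
        ts = parcellate(vol, atlas, tr=2.0)
        assert ts.n_regions == 116

    def test_missing_requested_label_errors(self, rng):
        atlas = np.ones((2, 2, 2), dtype=int)
        vol = rng.standard_normal((2, 2, 2, 4))
        with pytest.raises(ValueError, match=r"\[9\]"):
            parcellate(vol, atlas, tr=2.0, region_ids=[1, 9])

    def test_nibabel_images_accepted(self, rng):
        import nibabel as nib

        atlas = np.array([[[1, 2]]], dtype=np.int16)
        vol = rng.standard_normal((1, 1, 2, 7)).astype(np.float32)
        ts = parcellate(
            nib.Nifti1Image(vol, np.eye(4)),
            nib.Nifti1Image(atlas, np.eye(4)),
            tr=2.0,
        )
        assert ts.data.shape == (7, 2)
        assert np.allclose(ts.data[:, 0], vol[0, 0, 0])
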