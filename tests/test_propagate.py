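"""Diffeomorphic registration and 3D/4D label propagation."""

import numpy as np
import pytest

from cardiac4d import cardiometrics as cm
from cardiac4d import phantom, propagate as pr
from cardiac4d.io_core import Cine4D, centered_affine


def _blob_pair(shift=2.0, size=96):
    x, y = np.mgrid[0:size, 0:size].astype(float)
    fixed = np.exp(-(((x - 48) / 12) ** 2 + ((y - 48) / 12) ** 2))
    moving = np.exp(-(((x - 48 + shift) / 12) ** 2 + ((y - 48) / 12) ** 2))
    return fixed, moving


class TestRegistration:
    def test_identity_input_gives_near_zero_field(self):
        fixed, _ = _blob_pair()
        f = pr.register_diffeomorphic(fixed, fixed, spacing_mm=1.0)
        assert np.abs(f.displacement_vox()).max() < 0.1

    def test_translation_recovered_inside_blob(self):
        fixed, moving = _blob_pair(shift=2.0)
        cfg = pr.RegistrationConfig(iters_per_level=(300, 150, 50))
        f = pr.register_diffeomorphic(fixed, moving, cfg, spacing_mm=1.0)
        inside = fixed > 0.3
        mean_dx = f.displacement_vox()[..., 0][inside].mean()
        assert mean_dx == pytest.approx(-2.0, abs=0.3)
        assert abs(f.displacement_vox()[..., 1][inside].mean()) < 0.1

    def test_jacobian_positive_everywhere(self):
        fixed, moving = _blob_pair(shift=3.0)
        f = pr.register_diffeomorphic(fixed, moving, spacing_mm=1.0)
        assert f.jacobian_determinant().min() > 0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pr.register_diffeomorphic(np.zeros((8, 8)), np.zeros((9, 9)))

    def test_non_finite_rejected(self):
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pr.register_diffeomorphic(bad, np.zeros((8, 8)))

    def test_local_cc_metric_handles_intensity_scaling(self):
        """Locally normalised forces recover motion despite a contrast change."""
        fixed, moving = _blob_pair(shift=2.0)
        moving = 0.3 * moving + 0.2  # different brightness/contrast
        cfg = pr.RegistrationConfig(metric="local_cc", iters_per_level=(300, 150, 50))
        f = pr.register_diffeomorphic(fixed, moving, cfg, spacing_mm=1.0)
        moving_mask = (moving > 0.3 * 0.5 + 0.2).astype(np.uint8)
        warped = pr.warp_labels(moving_mask, f)
        assert cm.dice(warped == 1, fixed > 0.5) >= 0.9

    def test_agrees_with_independent_demons_implementation(self):
        """Cross-check translation recovery against SimpleITK's diffeomorphic demons."""
        import SimpleITK as sitk

        fixed, moving = _blob_pair(shift=2.0)
        inside = fixed > 0.3

        cfg = pr.RegistrationConfig(iters_per_level=(300, 150, 50))
        mine = pr.register_diffeomorphic(fixed, moving, cfg, spacing_mm=1.0)
        mean_mine = mine.displacement_vox()[..., 0][inside].mean()

        f_itk = sitk.GetImageFromArray(fixed.astype(np.float32))
        m_itk = sitk.GetImageFromArray(moving.astype(np.float32))
        demons = sitk.DiffeomorphicDemonsRegistrationFilter()
        demons.SetNumberOfIterations(300)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(1.0)
        field = sitk.GetArrayFromImage(demons.Execute(f_itk, m_itk))
        mean_itk = field[..., 1][inside].mean()  # ITK orders components (x=col, y=row)

        # regularisation differs, so compare behaviour: same direction, same
        # magnitude to within a voxel, and both fields transfer the mask
        assert np.sign(mean_mine) == np.sign(mean_itk)
        assert mean_mine == pytest.approx(mean_itk, abs=1.0)
        itk_field = pr.DeformationField(field[..., ::-1].astype(float), np.ones(2))
        moving_mask = (moving > 0.5).astype(np.uint8)
        for f in (mine, itk_field):
            warped = pr.warp_labels(moving_mask, f)
            assert cm.dice(warped == 1, fixed > 0.5) >= 0.95

    def test_deterministic(self):
        fixed, moving = _blob_pair(shift=1.5, size=48)
        f1 = pr.register_diffeomorphic(fixed, moving, spacing_mm=1.0)
        f2 = pr.register_diffeomorphic(fixed, moving, spacing_mm=1.0)
        np.testing.assert_array_equal(f1.displacement, f2.displacement)


class TestWarpLabels:
    def test_zero_field_identity(self):
        labels = np.zeros((10, 10), np.uint8)
        labels[3:7, 3:7] = 2
        field = pr.DeformationField(np.zeros((10, 10, 2)), np.ones(2))
        np.testing.assert_array_equal(pr.warp_labels(labels, field), labels)

    def test_one_voxel_lattice_translation(self):
        labels = np.zeros((10, 10), np.uint8)
        labels[3:7, 3:7] = 1
        disp = np.zeros((10, 10, 2))
        disp[..., 0] = -1.0  # sample from x-1: content shifts +x
        field = pr.DeformationField(disp, np.ones(2))
        out = pr.warp_labels(labels, field)
        np.testing.assert_array_equal(out[1:, :], labels[:-1, :])

    def test_registration_field_transfers_mask(self):
        fixed, moving = _blob_pair(shift=2.0)
        cfg = pr.RegistrationConfig(iters_per_level=(300, 150, 50))
        f = pr.register_diffeomorphic(fixed, moving, cfg, spacing_mm=1.0)
        moving_mask = (moving > 0.5).astype(np.uint8)
        fixed_mask = fixed > 0.5
        warped = pr.warp_labels(moving_mask, f)
        assert cm.dice(warped == 1, fixed_mask) >= 0.95

    def test_tie_break_prefers_lvb(self):
        # construct exact 2-class probability tie through symmetric half-shift
        labels = np.zeros((4, 4), np.uint8)
        labels[0] = 1  # LVB row
        labels[2] = 2  # LVM row
        disp = np.zeros((4, 4, 2))
        disp[1, :, 0] = -0.5  # row 1 samples halfway to row 0: p(LVB) = p(background) = 0.5
        field = pr.DeformationField(disp, np.ones(2))
        out = pr.warp_labels(labels, field)
        assert (out[1] == 1).all()  # LVB beats background on the tie


class TestPropagate3D:
    def test_every_slice_key_returns_stack(self, small_phantom):
        _, cine, truth = small_phantom
        keys = phantom.simulate_key_slice_annotations(truth.labels, 0, step=1)
        out = pr.propagate_labels_3d(cine.phase(0), keys, spacing_mm=cine.spacing_mm)
        span = slice(min(keys.slice_indices), max(keys.slice_indices) + 1)
        np.testing.assert_array_equal(out[:, :, span], truth.labels.voxels[:, :, span, 0])

    def test_outside_span_is_background(self, small_phantom):
        _, cine, truth = small_phantom
        full = phantom.simulate_key_slice_annotations(truth.labels, 0, step=1)
        lo, hi = 30, 50
        keys = phantom.KeySliceAnnotation(
            phase=0, slice_axis=2, slice_indices=[lo, hi],
            slices={lo: full.slices.get(lo, truth.labels.voxels[:, :, lo, 0]),
                    hi: truth.labels.voxels[:, :, hi, 0]},
        )
        out = pr.propagate_labels_3d(cine.phase(0), keys, spacing_mm=cine.spacing_mm)
        assert not out[:, :, :lo].any()
        assert not out[:, :, hi + 1:].any()

    def test_single_key_slice_rejected(self, small_phantom):
        _, cine, truth = small_phantom
        keys = phantom.KeySliceAnnotation(
            phase=0, slice_axis=2, slice_indices=[40],
            slices={40: truth.labels.voxels[:, :, 40, 0]},
        )
        with pytest.raises(ValueError, match="at least 2"):
            pr.propagate_labels_3d(cine.phase(0), keys, spacing_mm=cine.spacing_mm)

    def test_interior_empty_key_rejected(self, small_phantom):
        _, cine, truth = small_phantom
        shape2d = cine.grid_shape[:2]
        keys = phantom.KeySliceAnnotation(
            phase=0, slice_axis=2, slice_indices=[30, 40, 50],
            slices={30: truth.labels.voxels[:, :, 30, 0],
                    40: np.zeros(shape2d, np.uint8),
                    50: truth.labels.voxels[:, :, 50, 0]},
        )
        with pytest.raises(ValueError, match="interior"):
            pr.propagate_labels_3d(cine.phase(0), keys, spacing_mm=cine.spacing_mm)


class TestPropagate4D:
    def _tiny_cine(self, n_phases, constant=True):
        rng = np.random.default_rng(0)
        base = rng.random((24, 24, 24)).astype(np.float32)
        base = np.asarray(base)
        vox = np.stack([base] * n_phases, axis=-1)
        return Cine4D(vox, np.ones(3), centered_affine((24, 24, 24), np.ones(3)))

    def _labels(self):
        lab = np.zeros((24, 24, 24), np.uint8)
        lab[8:16, 8:16, 8:16] = 1
        lab[6:8, 8:16, 8:16] = 2
        return lab

    def test_single_phase_returns_ed_labels(self):
        cine = self._tiny_cine(1)
        lab = self._labels()
        out = pr.propagate_labels_4d(cine, lab, lab, 0, 0)
        np.testing.assert_array_equal(out.voxels[..., 0], lab)

    def test_identical_phases_keep_labels_exactly(self):
        cine = self._tiny_cine(5)
        lab = self._labels()
        out = pr.propagate_labels_4d(cine, lab, lab, 0, 2)
        for p in range(5):
            np.testing.assert_array_equal(out.voxels[..., p], lab)

    def test_sources_keep_their_input_labels(self, small_phantom):
        _, cine, truth = small_phantom
        ed, es = truth.ed_phase, truth.es_phase
        out = pr.propagate_labels_4d(
            cine, truth.labels.voxels[..., ed], truth.labels.voxels[..., es], ed, es
        )
        np.testing.assert_array_equal(out.voxels[..., ed], truth.labels.voxels[..., ed])
        np.testing.assert_array_equal(out.voxels[..., es], truth.labels.voxels[..., es])
        assert set(np.unique(out.voxels)) <= {0, 1, 2, 3}

    def test_same_phase_sources_rejected(self):
        cine = self._tiny_cine(3)
        lab = self._labels()
        with pytest.raises(ValueError, match="distinct"):
            pr.propagate_labels_4d(cine, lab, lab, 1, 1)

    def test_geometry_mismatch_rejected(self):
        cine = self._tiny_cine(3)
        with pytest.raises(ValueError, match="shape"):
            pr.propagate_labels_4d(cine, np.zeros((8, 8, 8), np.uint8), self._labels(), 0, 1)


def test_3d_propagation_stable_under_key_density(default_phantom):
    """Halving key-slice density changes the result by at most 0.02 Dice."""
    _, cine, truth = default_phantom
    ed = truth.ed_phase
    results = {}
    for step in (5, 10):
        keys = phantom.simulate_key_slice_annotations(truth.labels, ed, step=step)
        results[step] = pr.propagate_labels_3d(cine.phase(ed), keys, spacing_mm=cine.spacing_mm)
    for code in (1, 2, 3):
        d = cm.dice(results[5] == code, results[10] == code)
        assert d >= 0.98


def test_cyclic_path_shortest_arc():
    assert pr._cyclic_path(0, 3, 20) == [1, 2, 3]
    assert pr._cyclic_path(0, 18, 20) == [19, 18]
    assert pr._cyclic_path(8, 5, 20) == [7, 6, 5]
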