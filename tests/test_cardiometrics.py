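"""Metric correctness against constructed cases and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiac4d import cardiometrics as cm
from cardiac4d.io_core import LabelMap4D, centered_affine


def _labels4d(vox):
    vox = np.asarray(vox, dtype=np.uint8)
    return LabelMap4D(vox, np.ones(3), centered_affine(vox.shape[:3], np.ones(3)))


class TestVolumes:
    def test_empty_is_zero(self):
        assert cm.label_volume_ml(np.zeros((4, 4, 4)), 1, 1.4) == 0.0

    def test_thousand_voxels_at_1p4(self):
        lab = np.zeros((12, 12, 12))
        lab.ravel()[:1000] = 1
        assert cm.label_volume_ml(lab, 1, 1.4) == pytest.approx(2.744)

    def test_single_voxel_at_1mm(self):
        lab = np.zeros((3, 3, 3))
        lab[1, 1, 1] = 3
        assert cm.label_volume_ml(lab, 3, 1.0) == pytest.approx(0.001)


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert cm.dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert cm.dice(a, b) == 0.0

    def test_counting_formula(self):
        a = np.zeros(12, bool)
        b = np.zeros(12, bool)
        a[:4] = True          # |A| = 4
        b[1:7] = True         # |B| = 6, overlap 3
        assert cm.dice(a, b) == pytest.approx(0.6)

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert cm.dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cm.dice(np.zeros((3, 3)), np.zeros((4, 4)))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) > 0.6
        b = rng.random((6, 6, 6)) > 0.6
        if not (a.any() or b.any()):
            return
        d = cm.dice(a, b)
        assert d == cm.dice(b, a)
        assert 0.0 <= d <= 1.0


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert cm.surface_distances(m, m, 1.4) == (0.0, 0.0)

    def test_single_voxels_three_slices_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2] = True
        b[2, 2, 5] = True
        hd, assd = cm.surface_distances(a, b, 1.4)
        assert hd == pytest.approx(4.2)
        assert assd == pytest.approx(4.2)

    def test_asymmetric_pooling(self):
        # A = {v0}, B = {v0, v0+5}: minima are {5} one way, {0, 5} the other
        a = np.zeros((10, 3, 3), bool)
        b = np.zeros((10, 3, 3), bool)
        a[1, 1, 1] = True
        b[1, 1, 1] = True
        b[6, 1, 1] = True
        hd, assd = cm.surface_distances(a, b, 1.0)
        assert hd == pytest.approx(5.0)
        assert assd == pytest.approx(5.0 / 3.0)

    def test_empty_mask_raises_missing_structure(self):
        m = np.zeros((4, 4, 4), bool)
        full = ~m
        with pytest.raises(ValueError, match="missing structure"):
            cm.surface_distances(m, full, 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_hd_dominates_assd(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((7, 7, 7)) > 0.7
        b = rng.random((7, 7, 7)) > 0.7
        if not (a.any() and b.any()):
            return
        hd, assd = cm.surface_distances(a, b, 1.3)
        assert hd >= assd >= 0.0


class TestRVD:
    def test_equal_volumes(self):
        assert cm.relative_volume_difference(100, 100) == 0.0

    def test_overestimate(self):
        assert cm.relative_volume_difference(103, 100) == pytest.approx(3.0)

    def test_underestimate_absolute_convention(self):
        assert cm.relative_volume_difference(95, 100) == pytest.approx(5.0)
        assert cm.relative_volume_difference(95, 100, signed=True) == pytest.approx(-5.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            cm.relative_volume_difference(10, 0)


class TestPooledMetrics:
    def _masks(self, shape=(10, 10, 10)):
        ed = np.zeros(shape, np.uint8)
        ed[2:6, 2:6, 2:6] = 1
        ed[6:8, 2:6, 2:6] = 2
        ed[2:6, 6:8, 2:6] = 3
        return ed

    def test_perfect_agreement(self):
        ed = self._masks()
        es = self._masks()
        g = cm.pooled_geometric_metrics(ed, ed, es, es, 1.0)
        for code in (1, 2, 3):
            geo = g.per_structure[code]
            assert geo.dsc == 1.0
            assert geo.hd_mm == 0.0
            assert geo.rvd_pct == 0.0

    def test_pooled_dice_from_summed_components(self):
        # ED: |A∩B| = 30, |A|+|B| = 80; ES: 10 and 40 -> pooled 2*40/120
        ed_ref = np.zeros((20, 20, 4), np.uint8)
        ed_auto = np.zeros_like(ed_ref)
        ed_ref.ravel()[:50] = 1   # |B| = 50
        ed_auto.ravel()[20:50] = 1  # |A| = 30, overlap 30
        es_ref = np.zeros_like(ed_ref)
        es_auto = np.zeros_like(ed_ref)
        es_ref.ravel()[:30] = 1   # |B| = 30
        es_auto.ravel()[20:30] = 1  # |A| = 10, overlap 10
        # add the other structures so the reference is never empty
        for arr in (ed_ref, ed_auto, es_ref, es_auto):
            arr.ravel()[-2] = 2
            arr.ravel()[-1] = 3
        g = cm.pooled_geometric_metrics(ed_auto, ed_ref, es_auto, es_ref, 1.0)
        assert g.per_structure[1].dsc == pytest.approx(2 * (30 + 10) / (80 + 40))

    def test_pooled_hd_is_max_of_phases(self):
        base = np.zeros((12, 5, 5), np.uint8)
        base[1, 1, 1] = 1
        ed_auto = base.copy()
        ed_auto[1, 1, 1] = 0
        ed_auto[4, 1, 1] = 1   # 3 mm off at ED
        es_auto = base.copy()
        es_auto[1, 1, 1] = 0
        es_auto[8, 1, 1] = 1   # 7 mm off at ES
        for arr in (base, ed_auto, es_auto):
            arr[0, 0, 0] = 2
            arr[0, 0, 1] = 3
        g = cm.pooled_geometric_metrics(ed_auto, base, es_auto, base, 1.0)
        assert g.per_structure[1].hd_mm == pytest.approx(7.0)

    def test_reference_empty_both_phases_raises(self):
        ed = self._masks()
        empty = np.zeros_like(ed)
        empty[0, 0, 0] = 1  # LVB present, LVM/RVB absent in reference
        with pytest.raises(ValueError, match="empty in reference"):
            cm.pooled_geometric_metrics(ed, empty, ed, empty, 1.0)


class TestEdEsDetection:
    def _from_volumes(self, vols):
        shape = (20, 20, 1)
        vox = np.zeros((*shape, len(vols)), np.uint8)
        for p, v in enumerate(vols):
            vox.reshape(-1, len(vols))[:v, p] = 1
        return _labels4d(vox)

    def test_argmax_argmin(self):
        assert cm.detect_ed_es(self._from_volumes([150, 120, 70, 90, 140])) == (0, 2)

    def test_constant_volumes_tie_warns(self):
        with pytest.warns(UserWarning, match="tie"):
            assert cm.detect_ed_es(self._from_volumes([50, 50, 50])) == (0, 0)

    def test_empty_lvb_everywhere_raises(self):
        with pytest.raises(ValueError, match="empty"):
            cm.detect_ed_es(_labels4d(np.zeros((4, 4, 4, 2))))

    def test_matches_phantom_truth(self, default_phantom):
        _, _, truth = default_phantom
        assert cm.detect_ed_es(truth.labels) == (truth.ed_phase, truth.es_phase)


class TestClinicalMetrics:
    def _two_phase(self, edv_vox, esv_vox, code=1, extra=None):
        vox = np.zeros((30, 30, 30, 2), np.uint8)
        flat = vox.reshape(-1, 2)
        flat[:edv_vox, 0] = code
        flat[:esv_vox, 1] = code
        if extra:
            for (c, n0, n1) in extra:
                flat[27000 - 3000 : 27000 - 3000 + n0, 0] = c
                flat[27000 - 3000 : 27000 - 3000 + n1, 1] = c
        return _labels4d(vox)

    def test_ef_and_sv_formulas(self):
        # 160000 / 60000 voxels at 1 mm -> EDV 160 mL... scaled: use 16000/6000 -> 16/6 mL
        lab = self._two_phase(16000, 6000)
        met = cm.clinical_metrics(lab, 0, 1)
        assert met.lv.ef_pct == pytest.approx(62.5)
        assert met.lv.sv_ml == pytest.approx(10.0)

    def test_edv_equals_esv_gives_zero_ef(self):
        met = cm.clinical_metrics(self._two_phase(5000, 5000), 0, 1)
        assert met.lv.ef_pct == pytest.approx(0.0)

    def test_sixty_percent_ef(self):
        met = cm.clinical_metrics(self._two_phase(12000, 4800), 0, 1)
        assert met.lv.ef_pct == pytest.approx(60.0)

    def test_zero_edv_yields_error_record_not_number(self):
        met = cm.clinical_metrics(self._two_phase(5000, 2000), 0, 1)  # RV absent
        assert met.rv.ef_pct is None
        assert any("EF undefined" in e for e in met.errors)


class TestLVMMismatch:
    def test_equal(self):
        assert cm.lvm_mismatch(100, 100) == 0.0

    def test_twenty_percent(self):
        assert cm.lvm_mismatch(110, 90) == pytest.approx(20.0)

    def test_ten_percent(self):
        assert cm.lvm_mismatch(105, 95) == pytest.approx(10.0)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            cm.lvm_mismatch(0, 50)

    def test_grows_with_es_myocardial_dilation(self, small_phantom):
        from scipy import ndimage

        _, _, truth = small_phantom
        ed, es = truth.ed_phase, truth.es_phase
        ed_lvm = cm.label_volume_ml(truth.labels.voxels[..., ed], 2, 1.4)
        mismatches = []
        for r in (0, 1, 2):
            es_mask = truth.labels.voxels[..., es] == 2
            if r:
                es_mask = ndimage.binary_dilation(es_mask, iterations=r)
            es_lvm = es_mask.sum() * 1.4**3 / 1000.0
            mismatches.append(cm.lvm_mismatch(ed_lvm, es_lvm))
        assert mismatches[0] < mismatches[1] < mismatches[2]


class TestConsistencyChecks:
    def _metrics(self, lvsv, rvsv, eps=2.0):
        vm = cm.VentricleMetrics
        return cm.ClinicalMetrics(
            lv=vm(150, 150 - lvsv, lvsv, 60.0),
            rv=vm(140, 140 - rvsv, rvsv, 55.0),
            edv_lvm_ml=160, esv_lvm_ml=160, eps_lvm_pct=eps,
        )

    @pytest.mark.parametrize("rvsv,expected", [(100, True), (95, True), (85, False)])
    def test_sv_tolerance_10ml(self, rvsv, expected):
        flags = cm.consistency_checks(self._metrics(100, rvsv))
        assert flags.sv_consistent is expected

    def test_sv_check_skippable_for_patients(self):
        flags = cm.consistency_checks(self._metrics(100, 70), check_sv=False)
        assert flags.sv_consistent is None

    def test_lvm_flag_uses_tolerance(self):
        assert cm.consistency_checks(self._metrics(100, 100, eps=9.0)).lvm_consistent
        assert not cm.consistency_checks(self._metrics(100, 100, eps=11.0)).lvm_consistent
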