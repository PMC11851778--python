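"""Geometry, label map, ROI and tissue-table behavior."""

import itertools

import numpy as np
import pytest

from dvcqmri import (
    GeometrySpec,
    build_label_map,
    make_roi_set,
    tissue_params_for,
)
from dvcqmri.phantom import EmptyROIError, GeometryOverflowError
from dvcqmri.tissues import LABEL_LEGEND, TissueParamTable


class TestLabelMap:
    def test_all_compartments_present(self, small_label):
        assert set(np.unique(small_label.labels)) == {0, 1, 2, 3, 4, 5, 6}

    def test_immature_endplate_thicker_than_mature(self):
        """Immature animals carry thicker GP and CEP slabs."""
        mat = build_label_map(GeometrySpec.for_maturity("mature"))
        imm = build_label_map(GeometrySpec.for_maturity("immature"))
        for lab in (3, 4):  # CEP, GP
            assert (imm.labels == lab).sum() > (mat.labels == lab).sum()

    def test_axial_slab_order_within_unit(self, small_geom, small_label):
        """Along the tail axis: disc -> CEP -> GP -> SB -> body, mirrored."""
        nx, ny, _ = small_geom.matrix_size
        profile = small_label.labels[nx // 2, ny // 2, :]
        profile = profile[profile > 0]
        # collapse runs to the slab sequence
        seq = [k for k, _ in itertools.groupby(profile)]
        unit = [1, 3, 4, 5, 6, 5, 4, 3]
        assert seq == unit * small_geom.n_vertebrae

    def test_np_laterally_enclosed_by_af(self, small_label):
        lab = small_label.labels
        np_mask = lab == 1
        for z in range(lab.shape[2]):
            if not np_mask[:, :, z].any():
                continue
            sl = lab[:, :, z]
            core = np_mask[:, :, z]
            # every in-plane neighbor of an NP voxel is NP or AF
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                shifted = np.roll(core, (dx, dy), axis=(0, 1))
                touched = shifted & ~core
                assert set(np.unique(sl[touched])) <= {1, 2}

    def test_deterministic(self, small_geom):
        a = build_label_map(small_geom)
        b = build_label_map(small_geom)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("kwargs", [
        dict(gp_thickness_vox=0),
        dict(n_vertebrae=1),
        dict(voxel_size_mm=(0.15, 0.15, -1.0)),
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeometrySpec.for_maturity("mature", **kwargs)

    def test_too_many_units_overflow(self):
        geom = GeometrySpec.for_maturity("mature", n_vertebrae=5)
        with pytest.raises(GeometryOverflowError):
            build_label_map(geom)

    def test_in_plane_overflow(self):
        geom = GeometrySpec.for_maturity("mature", matrix_size=(16, 16, 32))
        with pytest.raises(GeometryOverflowError):
            build_label_map(geom)


class TestROISet:
    def test_zero_erosion_equals_label_regions(self, small_label, small_rois):
        for structure, mask in small_rois:
            assert np.array_equal(mask, small_label.mask(structure))

    def test_erosion_empties_thin_endplate(self, small_label):
        # mature CEP/GP slabs are one voxel thick: one erosion removes them,
        # and the error names the structure
        with pytest.raises(EmptyROIError, match="CEP|GP"):
            make_roi_set(small_label, erosion_vox=1)

    def test_masks_pairwise_disjoint(self, small_rois):
        names = list(small_rois.masks)
        for a, b in itertools.combinations(names, 2):
            assert not (small_rois[a] & small_rois[b]).any()
        for name in names:
            assert not (small_rois[name] & small_rois.background).any()

    def test_background_only_label_zero(self, small_label, small_rois):
        assert small_rois.background.any()
        assert (small_label.labels[small_rois.background] == 0).all()


class TestTissueTables:
    @pytest.mark.parametrize("arm, structure, column, expected", [
        (("mature", "healthy", "D0"), "NP", "t2_ms", 105.0),
        (("mature", "healthy", "D0"), "AF", "t2_ms", 6.0),
        (("mature", "healthy", "D0"), "CEP", "t2_ms", 28.2),
        (("mature", "healthy", "D0"), "SB", "t2_ms", 96.1),
        (("mature", "healthy", "D0"), "AF", "t1_ms", 803.0),
        (("mature", "healthy", "D0"), "NP", "t1_ms", 1810.0),
        (("mature", "healthy", "D0"), "SB", "t1_ms", 568.0),
        (("mature", "ddd", "W1"), "AF", "t2_ms", 20.7),
        (("mature", "ddd", "W1"), "NP", "t2_ms", 51.8),
        (("immature", "ddd", "W2"), "NP", "t1_ms", 1268.0),
        (("mature", "healthy", "D0"), "AF", "ute_snr", 16.8),
    ])
    def test_study_values(self, arm, structure, column, expected):
        table = tissue_params_for(*arm)
        assert table.value(structure, column) == pytest.approx(expected)

    def test_healthy_constant_over_time(self):
        frames = [tissue_params_for("mature", "healthy", tp).frame for tp in ("D0", "W1", "W2")]
        assert frames[0].equals(frames[1]) and frames[0].equals(frames[2])

    def test_ddd_changes_np_af_only(self):
        for maturity in ("mature", "immature"):
            for tp in ("W1", "W2"):
                healthy = tissue_params_for(maturity, "healthy", tp).frame
                ddd = tissue_params_for(maturity, "ddd", tp).frame
                assert not healthy.loc[[1, 2]].equals(ddd.loc[[1, 2]])
                assert healthy.loc[3:6].equals(ddd.loc[3:6])

    def test_ddd_baseline_equals_healthy(self):
        h = tissue_params_for("mature", "healthy", "D0").frame
        d = tissue_params_for("mature", "ddd", "D0").frame
        assert h.equals(d)

    def test_t2_below_t1_everywhere(self):
        for maturity in ("mature", "immature"):
            for state in ("healthy", "ddd"):
                for tp in ("D0", "W1", "W2"):
                    f = tissue_params_for(maturity, state, tp).frame
                    assert (f["t2_ms"] < f["t1_ms"]).all()
                    assert (f["t2_ms"] > 0).all()

    @pytest.mark.parametrize("arm", [
        ("adult", "healthy", "D0"),
        ("mature", "sick", "D0"),
        ("mature", "healthy", "W9"),
    ])
    def test_unknown_arm_rejected(self, arm):
        with pytest.raises(ValueError):
            tissue_params_for(*arm)

    def test_inconsistent_relaxation_rejected(self, healthy_table):
        frame = healthy_table.frame.copy()
        frame.loc[1, "t2_ms"] = frame.loc[1, "t1_ms"] + 1
        with pytest.raises(ValueError, match="T2 must be shorter"):
            TissueParamTable("mature", "healthy", "D0", frame)

    def test_ute_amplitude_calibration(self, healthy_table):
        amp = healthy_table.ute_amplitude(sigma=2.0)
        assert amp[2] == pytest.approx(16.8 * 2.0)  # AF
        assert amp[0] == 0.0  # background

    def test_label_legend_consistency(self, healthy_table):
        assert list(healthy_table.frame["name"]) == [LABEL_LEGEND[i] for i in range(1, 7)]
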