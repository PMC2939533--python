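import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from fuzzywater.phantom import PhantomSpec, generate_phantom
from fuzzywater.volume_io import (
    BrainVolume,
    ROIBox,
    boxes_overlap,
    default_parietal_rois,
    read_manifest,
    read_volume,
    rois_from_config,
    write_manifest,
    write_volume,
)


class TestBrainVolume:
    def test_rejects_invalid_grids(self):
        with pytest.raises(ValueError, match="3D"):
            BrainVolume(np.ones((4, 4)))
        with pytest.raises(ValueError, match="negative"):
            BrainVolume(np.full((3, 3, 3), -1.0))
        with pytest.raises(ValueError, match="finite"):
            BrainVolume(np.full((3, 3, 3), np.nan))
        with pytest.raises(ValueError, match="at least 3"):
            BrainVolume(np.ones((2, 4, 4)))


class TestVolumeRoundTrip:
    def test_write_read_identity(self, tmp_path):
        vol = BrainVolume(np.ones((4, 4, 4)))
        path = tmp_path / "ones.nii"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, vol.data)

    def test_2d_image_rejected(self, tmp_path):
        path = tmp_path / "flat.nii"
        nib.save(nib.Nifti1Image(np.ones((5, 5)), np.eye(4)), str(path))
        with pytest.raises(ValueError, match="volume must be 3D"):
            read_volume(path)

    def test_negative_voxels_rejected_not_clamped(self, tmp_path):
        arr = np.ones((3, 3, 3))
        arr[1, 1, 1] = -2.0
        path = tmp_path / "neg.nii"
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
        with pytest.raises(ValueError, match="negative"):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii")

    def test_full_scale_phantom_roundtrip(self, tmp_path):
        vol, _ = generate_phantom(PhantomSpec(seed=3))
        assert vol.shape == (128, 128, 128)
        path = tmp_path / "phantom.nii"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, vol.data)


class TestParietalROIs:
    def test_default_boxes_have_documented_size(self):
        left, right = default_parietal_rois((128, 128, 128))
        assert left.extents == (22, 29, 3) == right.extents
        assert left.n_voxels == right.n_voxels == 22 * 29 * 3 == 1914

    def test_defaults_disjoint_and_mirror_symmetric(self):
        for shape in ((128, 128, 128), (64, 64, 64), (96, 80, 70)):
            left, right = default_parietal_rois(shape)
            assert not boxes_overlap(left, right)
            # mirror about the mid-sagittal plane: x intervals reflect
            assert right.start[0] == shape[0] - left.stop[0]
            assert right.stop[0] == shape[0] - left.start[0]
            assert right.start[1:] == left.start[1:]

    def test_too_small_volume_is_an_error_not_a_clip(self):
        with pytest.raises(ValueError, match="ROI exceeds volume bounds"):
            default_parietal_rois((10, 10, 10))

    def test_explicit_center_override(self):
        left, right = default_parietal_rois(
            (128, 128, 128), centers=((32, 80, 64), (96, 80, 64))
        )
        assert left.center == (32, 80, 64)
        assert right.center == (96, 80, 64)

    def test_overlapping_override_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            default_parietal_rois(
                (128, 128, 128), centers=((60, 64, 64), (64, 64, 64))
            )

    def test_box_geometry_half_open(self):
        box = ROIBox("left", (10, 10, 10), (4, 3, 1))
        assert box.start == (8, 9, 10)
        assert box.stop == (12, 12, 11)
        assert box.contains_point((11.9, 9.0, 10.0))
        assert not box.contains_point((12.0, 9.0, 10.0))
        with pytest.raises(ValueError, match=">= 1"):
            ROIBox("left", (5, 5, 5), (0, 3, 3))


class TestManifest:
    def _write(self, tmp_path, rows):
        for sid, _, p in rows:
            write_volume(BrainVolume(np.ones((3, 3, 3))), tmp_path / p)
        df = pd.DataFrame(rows, columns=["subject_id", "group", "volume_path"])
        path = tmp_path / "manifest.csv"
        write_manifest(df, path)
        return path

    def test_roundtrip_resolves_relative_paths(self, tmp_path):
        path = self._write(
            tmp_path, [("s1", "AD", "s1.nii"), ("s2", "control", "s2.nii")]
        )
        df = read_manifest(path)
        assert list(df["subject_id"]) == ["s1", "s2"]
        assert all(p.startswith(str(tmp_path)) for p in df["volume_path"])

    def test_duplicate_ids_rejected(self, tmp_path):
        path = self._write(
            tmp_path, [("s1", "AD", "s1.nii"), ("s1", "control", "s1b.nii")]
        )
        with pytest.raises(ValueError, match="unique"):
            read_manifest(path)

    def test_unknown_group_rejected(self, tmp_path):
        path = self._write(tmp_path, [("s1", "AD", "s1.nii")])
        pd.DataFrame(
            [("s1", "patient", "s1.nii")],
            columns=["subject_id", "group", "volume_path"],
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="group"):
            read_manifest(path)

    def test_unresolvable_path_rejected(self, tmp_path):
        path = tmp_path / "manifest.csv"
        pd.DataFrame(
            [("s1", "AD", "missing.nii")],
            columns=["subject_id", "group", "volume_path"],
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="does not exist"):
            read_manifest(path)


def test_rois_from_config_overrides():
    cfg = {
        "roi": {
            "left": {"center": [20, 40, 35]},
            "right": {"center": [44, 40, 35]},
            "extents": [8, 10, 3],
        }
    }
    left, right = rois_from_config((64, 64, 64), cfg)
    assert left.center == (20, 40, 35)
    assert right.extents == (8, 10, 3)
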