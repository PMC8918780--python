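import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from pancshell import VoxelGrid
from pancshell import spots as sp
from pancshell._raster import paint_ball


def blob_image(positions_xyz, shape=(40, 100, 100), spacing=(2, 1, 1), amplitude=100.0, sigma=2.2):
    img = np.zeros(shape, dtype=np.float32)
    spv = np.asarray(spacing)
    for p in np.atleast_2d(positions_xyz):
        idx = np.round(np.asarray(p)[::-1] / spv).astype(int)
        img[tuple(idx)] = 1.0
    img = ndi.gaussian_filter(img, sigma / spv)
    img *= amplitude / img.max()
    return VoxelGrid(img, spacing, "blobs")


class TestDetectSpots:
    def test_single_blob_recovered_within_one_voxel(self):
        img = blob_image([(50, 50, 50)])
        det = sp.detect_spots(img)
        assert len(det) == 1
        assert np.linalg.norm(det.positions()[0] - (50, 50, 50)) <= 2.0

    def test_empty_image_no_spots(self):
        det = sp.detect_spots(VoxelGrid(np.zeros((20, 40, 40), np.float32), (2, 1, 1)))
        assert len(det) == 0

    def test_translation_equivariance(self):
        pos = np.array([(30.0, 40.0, 30.0), (60.0, 70.0, 50.0)])
        shift_vox = np.array([3, 5, 2])  # (z, y, x) voxels
        shift_um = shift_vox[::-1] * np.array([1, 1, 2])  # -> (x, y, z) µm
        a = sp.detect_spots(blob_image(pos))
        b = sp.detect_spots(blob_image(pos + shift_um))
        pa = a.positions()[np.lexsort(a.positions().T)]
        pb = b.positions()[np.lexsort(b.positions().T)]
        assert np.allclose(pb - pa, shift_um, atol=1e-6)

    def test_noise_only_image_nearly_spotless(self):
        """The 5-sigma noise floor admits at most stray single detections."""
        rng = np.random.default_rng(0)
        img = VoxelGrid(rng.normal(5, 10, (40, 80, 80)).astype(np.float32), (2, 1, 1))
        assert len(sp.detect_spots(img)) <= 2


class TestDeduplicate:
    def _spotset(self, rows):
        return sp.SpotSet(pd.DataFrame(rows))

    def test_close_pair_keeps_brighter(self):
        s = self._spotset(
            [
                {"id": 0, "x": 10.0, "y": 0.0, "z": 0.0, "peak_intensity": 5.0},
                {"id": 1, "x": 12.0, "y": 0.0, "z": 0.0, "peak_intensity": 9.0},
            ]
        )
        out = sp.deduplicate_spots(s, 4.0)
        assert list(out.df["id"]) == [1]

    def test_far_spots_untouched(self):
        s = self._spotset(
            [{"id": i, "x": 10.0 * i, "y": 0.0, "z": 0.0, "peak_intensity": 1.0} for i in range(4)]
        )
        assert len(sp.deduplicate_spots(s, 4.0)) == 4

    def test_equal_intensity_chain_tie_rule(self):
        """Colinear spots 3 µm apart, equal intensity: greedy keeps ids 0 and 2."""
        s = self._spotset(
            [{"id": i, "x": 3.0 * i, "y": 0.0, "z": 0.0, "peak_intensity": 7.0} for i in range(3)]
        )
        out = sp.deduplicate_spots(s, 4.0)
        assert list(out.df["id"]) == [0, 2]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        s = self._spotset(
            [
                {"id": i, "x": x, "y": y, "z": z, "peak_intensity": w}
                for i, (x, y, z, w) in enumerate(rng.random((50, 4)) * 40)
            ]
        )
        once = sp.deduplicate_spots(s, 5.0)
        twice = sp.deduplicate_spots(once, 5.0)
        assert once.df.reset_index(drop=True).equals(twice.df.reset_index(drop=True))


class TestPreprocessing:
    def test_zero_membrane_is_identity(self):
        rng = np.random.default_rng(0)
        nuc = VoxelGrid(rng.random((10, 20, 20)).astype(np.float32) * 50, (1, 1, 1))
        mem = nuc.like(np.zeros_like(nuc.data))
        out = sp.subtract_membrane(nuc, mem)
        assert np.allclose(out.data, nuc.data)

    def test_identical_channels_cancel(self):
        rng = np.random.default_rng(0)
        nuc = VoxelGrid(rng.random((10, 20, 20)).astype(np.float32) * 50, (1, 1, 1))
        out = sp.subtract_membrane(nuc, nuc)
        assert np.allclose(out.data, 0, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        a = VoxelGrid(np.zeros((5, 5, 5), np.float32), (1, 1, 1))
        b = VoxelGrid(np.zeros((6, 5, 5), np.float32), (1, 1, 1))
        with pytest.raises(ValueError):
            sp.subtract_membrane(a, b)

    def test_subtraction_improves_recall_near_membrane(self):
        """Nuclei whose rims touch a bright membrane detect better after
        percentile-matched subtraction."""
        shape, spacing = (30, 80, 80), (2, 1, 1)
        rng = np.random.default_rng(11)
        truth = np.array([[x, 40.0, 30.0] for x in np.arange(8, 76, 9.0)])
        nuc = blob_image(truth, shape, spacing).data
        membrane = np.zeros(shape, dtype=np.float32)
        membrane[:, 43:46, :] = 1.0  # slab membrane clipping every rim
        membrane = ndi.gaussian_filter(membrane, (0.5, 1, 1)) * 160
        noisy = lambda img: img + rng.normal(0, 8, shape).astype(np.float32)
        raw = VoxelGrid(noisy(nuc + membrane), spacing)
        mem = VoxelGrid(noisy(membrane), spacing)
        f1_raw = sp.match_spots(sp.detect_spots(raw), truth)["f1"]
        f1_sub = sp.match_spots(sp.detect_spots(sp.subtract_membrane(raw, mem)), truth)["f1"]
        assert f1_sub >= f1_raw

    def test_invert_constant_stays_constant(self):
        g = VoxelGrid(np.full((8, 8, 8), 7.0, np.float32), (1, 1, 1))
        out = sp.invert_cellbody(g, sigma=1.0)
        assert np.allclose(out.data, out.data.flat[0])

    def test_invert_puts_minimum_on_membrane_plane(self):
        img = np.zeros((10, 20, 20), np.float32)
        img[5] = 100.0
        out = sp.invert_cellbody(VoxelGrid(img, (1, 1, 1)), sigma=1.0)
        assert out.data[5].mean() == pytest.approx(out.data.min(), abs=1e-3)

    def test_honeycomb_maxima_count_cells(self):
        """Inverted membrane lattice has one local maximum per cell."""
        from skimage.feature import peak_local_max

        img = np.zeros((24, 60, 60), np.float32)
        img[::8, :, :] = 1.0
        img[:, ::10, :] = 1.0
        img[:, :, ::10] = 1.0
        inv = sp.invert_cellbody(VoxelGrid(img * 100, (1, 1, 1)), sigma=1.5)
        peaks = peak_local_max(inv.data, min_distance=3, exclude_border=False)
        n_cells = 3 * 6 * 6  # 24/8 x 60/10 x 60/10
        assert abs(len(peaks) - n_cells) / n_cells <= 0.05


class TestClassify:
    @pytest.fixture
    def epi_mask(self):
        mask = np.zeros((30, 60, 60), dtype=bool)
        paint_ball(mask, (2, 1, 1), (30, 30, 30), 15)
        return VoxelGrid(mask, (2, 1, 1))

    def _nuclei(self, rows):
        return sp.SpotSet(pd.DataFrame(rows))

    def test_inside_mask_is_epithelial(self, epi_mask):
        nuclei = self._nuclei([{"id": 0, "x": 30.0, "y": 30.0, "z": 30.0}])
        erg = sp.SpotSet(pd.DataFrame(columns=["id", "x", "y", "z"]))
        out = sp.classify_spots(nuclei, epi_mask, erg)
        assert out.df["class"].iloc[0] == "epithelial"

    def test_near_marker_spot_is_endothelial(self, epi_mask):
        nuclei = self._nuclei([{"id": 0, "x": 55.0, "y": 30.0, "z": 30.0}])
        erg = self._nuclei([{"id": 0, "x": 53.0, "y": 30.0, "z": 30.0}])
        out = sp.classify_spots(nuclei, epi_mask, erg)
        assert out.df["class"].iloc[0] == "endothelial"

    def test_neither_is_mesenchymal_and_partition_holds(self, epi_mask):
        rng = np.random.default_rng(2)
        rows = [
            {"id": i, "x": x, "y": y, "z": z}
            for i, (x, y, z) in enumerate(rng.uniform(5, 55, (40, 3)))
        ]
        nuclei = self._nuclei(rows)
        erg = self._nuclei([{"id": 0, "x": 5.0, "y": 5.0, "z": 5.0}])
        out = sp.classify_spots(nuclei, epi_mask, erg)
        counts = out.class_counts()
        assert sum(counts.values()) == len(nuclei)
        assert set(counts) <= {"epithelial", "endothelial", "mesenchymal"}

    def test_intensity_mode_with_marker_channel(self, epi_mask):
        marker = np.zeros((30, 60, 60), np.float32)
        marker[25:28, 50:56, 50:56] = 100.0
        nuclei = self._nuclei(
            [{"id": 0, "x": 52.0, "y": 52.0, "z": 52.0}, {"id": 1, "x": 10.0, "y": 10.0, "z": 10.0}]
        )
        out = sp.classify_spots(nuclei, epi_mask, VoxelGrid(marker, (2, 1, 1)))
        assert list(out.df["class"]) == ["endothelial", "mesenchymal"]
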