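import numpy as np
import pandas as pd
import pytest

from pancshell import VoxelGrid
from pancshell import proximity as prox

from conftest import ANISO, sphere_mask


def slab_mask(shape=(40, 30, 30), spacing=ANISO, z_to=10.0):
    mask = np.zeros(shape, dtype=bool)
    nz = int(np.ceil(z_to / spacing[0]))
    mask[:nz] = True
    return VoxelGrid(mask, spacing)


def records_from(distances, classes=None):
    classes = classes or ["endothelial"] * len(distances)
    df = pd.DataFrame(
        {"id": range(len(distances)), "x": 0.0, "y": 0.0, "z": 0.0, "class": classes}
    )
    rec = pd.DataFrame(
        {
            "spot_id": df["id"],
            "class": classes,
            "distance": np.asarray(distances, dtype=float),
        }
    )
    rec["layer"] = prox._layer_of(rec["distance"].to_numpy(), 7.5, 15.0)
    return rec


class TestDistanceMap:
    def test_slab_analytic_with_anisotropy(self):
        g = slab_mask()
        dmap = prox.distance_map(g)
        # analytic distance from a voxel center to the slab surface plane,
        # tolerance one voxel (criterion for the EDT oracle)
        zs = np.arange(g.shape[0]) * g.spacing[0]
        surface = 8.0  # last in-slab voxel center
        for zi in range(5, g.shape[0]):
            analytic = zs[zi] - surface
            assert abs(dmap.data[zi, 15, 15] - analytic) <= max(g.spacing)

    def test_inside_voxels_exactly_zero(self):
        dmap = prox.distance_map(slab_mask())
        assert (dmap.data[:5] == 0).all()

    def test_sphere_analytic_with_anisotropy(self):
        g = sphere_mask(20, (40, 40, 40), (40, 80, 80), spacing=ANISO)
        dmap = prox.distance_map(g)
        zz, yy, xx = np.meshgrid(
            np.arange(40) * 2.0, np.arange(80) * 1.0, np.arange(80) * 1.0, indexing="ij"
        )
        r = np.sqrt((xx - 40) ** 2 + (yy - 40) ** 2 + (zz - 40) ** 2)
        shell = (r > 28) & (r < 32)
        assert np.abs(dmap.data[shell] - (r[shell] - 20)).max() <= max(ANISO)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            prox.distance_map(VoxelGrid(np.zeros((5, 5, 5), bool), ANISO))


class TestRecords:
    def test_layers_and_half_open_boundary(self):
        dmap = prox.distance_map(slab_mask())
        spots = pd.DataFrame(
            {
                "id": [0, 1, 2],
                "x": [15.0, 15.0, 15.0],
                "y": [15.0, 15.0, 15.0],
                "z": [11.0, 16.0, 30.0],  # ~3, ~7.5(+), far
                "class": "endothelial",
            }
        )
        rec = prox.record_distances(spots, dmap)
        assert list(rec["layer"]) == ["first", "second", "excluded"]

    def test_exact_boundary_is_second_layer(self):
        rec = records_from([7.5])
        assert rec["layer"].iloc[0] == "second"
        rec15 = records_from([15.0])
        assert rec15["layer"].iloc[0] == "excluded"

    def test_spot_outside_volume_lists_ids(self):
        dmap = prox.distance_map(slab_mask())
        spots = pd.DataFrame({"id": [7], "x": [500.0], "y": [0.0], "z": [0.0], "class": "x"})
        with pytest.raises(ValueError, match="7"):
            prox.record_distances(spots, dmap)


class TestLayerFractions:
    def test_all_first(self):
        fr = prox.layer_fractions(records_from([1, 2, 3.0]))
        assert fr == {"first": 100.0, "second": 0.0}

    def test_even_split(self):
        fr = prox.layer_fractions(records_from([3.0, 12.0]))
        assert fr["first"] == 50.0 and fr["second"] == 50.0

    def test_excluded_only_is_error(self):
        with pytest.raises(ValueError):
            prox.layer_fractions(records_from([20.0, 30.0]))


class TestCumulative:
    def test_single_record_step(self):
        curve = prox.cumulative_distribution(records_from([5.0]), grid_step=1.0)
        assert curve.loc[curve["distance"] < 5, "cumulative_pct"].eq(0).all()
        assert curve.loc[curve["distance"] >= 5, "cumulative_pct"].eq(100).all()

    def test_uniform_close_to_straight_line(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 15, 3000)
        curve = prox.cumulative_distribution(records_from(d), grid_step=0.5)
        expect = 100 * curve["distance"] / 15.0
        assert (curve["cumulative_pct"] - expect).abs().max() < 3.0

    def test_nondecreasing_and_ends_at_100(self):
        rng = np.random.default_rng(1)
        curve = prox.cumulative_distribution(records_from(rng.uniform(0, 14.9, 200)))
        assert (np.diff(curve["cumulative_pct"]) >= 0).all()
        assert curve["cumulative_pct"].iloc[-1] == 100.0


class TestShellRegion:
    def test_slab_shell_volume_analytic(self):
        g = slab_mask(shape=(40, 30, 30))
        dmap = prox.distance_map(g)
        sh = prox.shell_region(dmap, 0, 15, g)
        area = 30 * 30  # one exposed face (other face is at the volume border)
        expected = area * 15
        assert abs(sh.volume - expected) <= area * max(ANISO)

    def test_shells_disjoint_and_exclude_reference(self):
        g = sphere_mask(12, (30, 30, 30), (30, 60, 60))
        dmap = prox.distance_map(g)
        near = prox.shell_region(dmap, 0, 15, g)
        far = prox.shell_region(dmap, 15, 50, g)
        assert not (near.mask.data & far.mask.data).any()
        assert not (near.mask.data & (g.data > 0)).any()

    def test_bad_bounds_rejected(self):
        g = slab_mask()
        dmap = prox.distance_map(g)
        with pytest.raises(ValueError):
            prox.shell_region(dmap, 15, 15, g)


class TestComposition:
    def test_arithmetic(self):
        rec = records_from(
            [0] * 6 + [3] + [5] * 3, classes=["epithelial"] * 6 + ["endothelial"] + ["mesenchymal"] * 3
        )
        comp = prox.composition_in_shell(rec)
        assert comp.percentages == {"epithelial": 60.0, "endothelial": 10.0, "mesenchymal": 30.0}
        assert sum(comp.percentages.values()) == 100.0

    def test_empty_shell_is_error(self):
        with pytest.raises(ValueError):
            prox.composition_in_shell(records_from([20.0, 30.0]))

    def test_epithelial_always_counted(self):
        rec = records_from([0.0, 14.9, 15.0], classes=["epithelial", "mesenchymal", "endothelial"])
        comp = prox.composition_in_shell(rec)
        assert comp.total == 2  # the 15.0 µm spot is outside the half-open shell


class TestAnisotropyInvariance:
    def test_resampled_distances_agree(self, small_phantom):
        """Dropping z-resolution changes recorded distances by < 2 voxels."""
        spec, _, truth = small_phantom
        fine = truth.epithelium_mask  # (2,1,1)
        coarse = VoxelGrid(fine.data[::2], (4.0, 1.0, 1.0))
        pos = truth.spots[["x", "y", "z"]].to_numpy()
        d_fine = prox.distance_map(fine).sample_nearest(pos)
        d_coarse = prox.distance_map(coarse).sample_nearest(pos)
        assert np.abs(d_fine - d_coarse).max() < 2 * 4.0
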