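import numpy as np
import pytest
from scipy import ndimage as ndi

from pancshell import PhantomSpec, VoxelGrid
from pancshell import phantom as ph
from pancshell import proximity as prox
from pancshell.vessels import build_vessel_graph

SMALL_EPI = ph.EpitheliumParams(
    n_branches=2, branch_length=60, branch_radius=12, trunk_length=90, trunk_radius=16
)


def small_spec(**kw):
    defaults = dict(
        volume_shape=(60, 120, 120),
        spacing=(2.0, 1.0, 1.0),
        seed=5,
        epithelium=SMALL_EPI,
        vessels=ph.VesselParams(n_tubes=0, n_free_tubes=0),
        nuclei=ph.NucleiParams(counts={"epithelial": 0, "endothelial": 0, "mesenchymal": 0}),
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestEpithelium:
    def test_trunk_only_is_one_cylinder(self):
        spec = small_spec(epithelium=ph.EpitheliumParams(n_branches=0, trunk_length=100, trunk_radius=10))
        mask = ph.make_epithelium(spec)
        _, n = ndi.label(mask.data)
        assert n == 1
        # voxel volume ~ pi r^2 L + spherical caps of the capsule
        expected = np.pi * 10**2 * 100 + 4 / 3 * np.pi * 10**3
        assert abs(mask.data.sum() * mask.voxel_volume - expected) / expected < 0.10

    def test_same_seed_identical(self):
        a = ph.make_epithelium(small_spec(seed=9))
        b = ph.make_epithelium(small_spec(seed=9))
        assert np.array_equal(a.data, b.data)

    def test_branches_create_skeleton_endpoints(self):
        spec = small_spec(
            epithelium=ph.EpitheliumParams(
                n_branches=4, branch_length=50, branch_radius=8, trunk_length=90, trunk_radius=10
            )
        )
        mask = ph.make_epithelium(spec)
        graph = build_vessel_graph(mask, prune_length=10.0)  # thinning oracle
        assert graph.n_endpoints >= 4

    def test_subvoxel_radius_rejected(self):
        spec = small_spec(epithelium=ph.EpitheliumParams(branch_radius=1.0, trunk_radius=1.0))
        with pytest.raises(ValueError, match="radius"):
            ph.make_epithelium(spec)


class TestVessels:
    def test_straight_tube_volume_matches_cylinder(self):
        # one straight free tube in empty space: volume ~ pi r^2 L
        from pancshell._raster import paint_polyline_tube

        mask = np.zeros((60, 120, 120), dtype=bool)
        path = np.array([[10.0, 60.0, 60.0], [110.0, 60.0, 60.0]])
        paint_polyline_tube(mask, (2, 1, 1), path, 4.0)
        vol = mask.sum() * 2.0
        expected = np.pi * 16 * 100 + 4 / 3 * np.pi * 64  # capsule caps included
        assert abs(vol - expected) / expected < 0.10

    def test_tubes_never_intersect_epithelium(self):
        spec = small_spec(vessels=ph.VesselParams(n_tubes=3, radii=(3, 4, 5), n_free_tubes=1, path_length=120))
        epi = ph.make_epithelium(spec)
        vmask, segs = ph.make_vessels(spec, epi)
        assert not (vmask.data & epi.data.astype(bool)).any()
        assert len(segs) == 4

    def test_same_seed_identical_truth(self):
        spec = small_spec(vessels=ph.VesselParams(n_tubes=2, radii=(3, 5), n_free_tubes=0, path_length=100))
        epi = ph.make_epithelium(spec)
        m1, s1 = ph.make_vessels(spec, epi)
        m2, s2 = ph.make_vessels(spec, epi)
        assert np.array_equal(m1.data, m2.data)
        assert all(np.allclose(a[0], b[0]) and a[1] == b[1] for a, b in zip(s1, s2))


class TestPlaceNuclei:
    def test_pure_first_shell_weights(self):
        spec = small_spec(
            nuclei=ph.NucleiParams(
                counts={"mesenchymal": 50}, shell_weights={"mesenchymal": (1.0, 0.0, 0.0)}
            )
        )
        epi = ph.make_epithelium(spec)
        spots = ph.place_nuclei(spec, epi)
        assert len(spots) == 50
        assert (spots["true_distance"] < 7.5).all()

    def test_zero_counts_empty_truth(self):
        spec = small_spec()
        epi = ph.make_epithelium(spec)
        assert len(ph.place_nuclei(spec, epi)) == 0

    def test_shell_split_recovery(self):
        spec = small_spec(
            volume_shape=(80, 160, 160),
            epithelium=ph.EpitheliumParams(
                n_branches=3, branch_length=70, branch_radius=16, trunk_length=120, trunk_radius=22
            ),
            nuclei=ph.NucleiParams(
                counts={"mesenchymal": 1000}, shell_weights={"mesenchymal": (0.5, 0.5, 0.0)}
            ),
            seed=3,
        )
        epi = ph.make_epithelium(spec)
        spots = ph.place_nuclei(spec, epi)
        first = (spots["true_distance"] < 7.5).mean() * 100
        assert abs(first - 50.0) < 4.0  # binomial bound at the fixed draw

    def test_impossible_count_reports_achievable(self):
        spec = small_spec(
            volume_shape=(20, 40, 40),
            epithelium=ph.EpitheliumParams(
                n_branches=0, trunk_length=20, trunk_radius=8, branch_radius=8
            ),
            nuclei=ph.NucleiParams(counts={"epithelial": 5000}),
        )
        epi = ph.make_epithelium(spec)
        with pytest.raises(ValueError, match=r"\d+/5000"):
            ph.place_nuclei(spec, epi)

    def test_separation_respected(self, small_phantom):
        from scipy.spatial import cKDTree

        spec, _, truth = small_phantom
        pos = truth.spots[["x", "y", "z"]].to_numpy()
        d, _ = cKDTree(pos).query(pos, k=2)
        min_sep = spec.nuclei.min_separation_factor * spec.nuclei.nuclear_radius
        assert d[:, 1].min() >= min_sep - 1e-6

    def test_truth_self_consistency(self, small_phantom):
        """Re-deriving distances with the proximity EDT reproduces the truth."""
        spec, _, truth = small_phantom
        dmap = prox.distance_map(truth.epithelium_mask)
        rec = prox.record_distances(truth.spots.rename(columns={"true_distance": "td"}), dmap)
        err = np.abs(rec["distance"].to_numpy() - truth.spots["true_distance"].to_numpy())
        assert err.max() < max(spec.spacing)


class TestRender:
    def test_identity_limit_without_blur_or_noise(self):
        spec = small_spec(
            render=ph.RenderParams(
                psf_sigma=(1e-6, 1e-6, 1e-6),
                poisson_scale=0.0,
                gaussian_sd=0.0,
                background=0.0,
                membrane_interior_fraction=1.0,
            )
        )
        epi = ph.make_epithelium(spec)
        truth = ph.PhantomTruth(
            epithelium_mask=epi,
            vessel_mask=VoxelGrid(np.zeros(spec.volume_shape, bool), spec.spacing),
            vessel_segments=[],
            spots=ph.place_nuclei(spec, epi),
        )
        vol = ph.render_volume(spec, truth)
        scaled = vol["ecad"].data / spec.render.amplitude
        assert np.allclose(scaled, epi.data.astype(float), atol=1e-3)

    def test_noiseless_signal_seed_independent(self):
        quiet = ph.RenderParams(poisson_scale=0.0, gaussian_sd=0.0)
        base = dict(
            nuclei=ph.NucleiParams(counts={"epithelial": 20, "mesenchymal": 10}),
            render=quiet,
        )
        va, ta = ph.make_phantom(small_spec(seed=1, **base))
        # same truth, different render seed -> identical noiseless channels
        vb = ph.render_volume(small_spec(seed=99, **base), ta)
        assert np.array_equal(va["draq5"].data, vb["draq5"].data)

    def test_noise_differs_between_seeds_on_same_truth(self, small_phantom):
        spec, vol, truth = small_phantom
        import dataclasses

        other = dataclasses.replace(spec, seed=spec.seed + 1)
        vol2 = ph.render_volume(other, truth)
        assert not np.array_equal(vol["draq5"].data, vol2["draq5"].data)

    def test_peak_snr_near_target(self, small_phantom):
        """Blob peak over background s.d. ~ 10 under the default render model."""
        spec, vol, truth = small_phantom
        img = vol["draq5"].data
        pos = truth.spots[["x", "y", "z"]].to_numpy()
        peaks = vol["draq5"].sample_nearest(pos)
        dmap = prox.distance_map(truth.epithelium_mask)
        bg = img[(dmap.data > 25)]  # far from everything
        snr = (np.median(peaks) - np.median(bg)) / bg.std()
        assert snr > 5.0

    def test_full_phantom_determinism(self):
        base = dict(
            seed=4,
            nuclei=ph.NucleiParams(counts={"epithelial": 15, "mesenchymal": 10}),
            vessels=ph.VesselParams(n_tubes=1, radii=(4.0,), n_free_tubes=0, path_length=80),
        )
        va, ta = ph.make_phantom(small_spec(**base))
        vb, tb = ph.make_phantom(small_spec(**base))
        assert np.array_equal(va["draq5"].data, vb["draq5"].data)
        assert ta.spots.equals(tb.spots)


class TestSections:
    def test_section_count_arithmetic(self, small_phantom):
        spec, _, truth = small_phantom
        secs, _ = ph.make_sections(spec, truth, 30.0)
        assert len(secs) == int(spec.extent[0] // 30)  # 120 µm deep / 30 -> 4

    def test_spacing_below_dz_rejected(self, small_phantom):
        spec, _, truth = small_phantom
        with pytest.raises(ValueError):
            ph.make_sections(spec, truth, 1.0)

    def test_midpoint_tie_goes_to_lower_slice(self):
        z = np.array([15.0]) / 30.0
        nearest = np.floor(z + 0.5).astype(int)
        nearest = np.where(np.isclose(z + 0.5, np.rint(z + 0.5)) & (nearest > 0), nearest - 1, nearest)
        assert nearest[0] == 0

    def test_cavalieri_volume_estimate(self, small_phantom):
        """Summed slice areas x spacing approximate the 3D mask volume."""
        spec, _, truth = small_phantom
        dz_sections = 10.0
        secs, _ = ph.make_sections(spec, truth, dz_sections)
        area_sum = 0.0
        pix_area = spec.spacing[1] * spec.spacing[2]
        for s in secs:
            zi = min(int(round(s.z_position / spec.spacing[0])), spec.volume_shape[0] - 1)
            area_sum += truth.epithelium_mask.data[zi].sum() * pix_area
        vol_est = area_sum * dz_sections
        vol_true = truth.epithelium_mask.data.sum() * truth.epithelium_mask.voxel_volume
        assert abs(vol_est - vol_true) / vol_true < 0.10
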