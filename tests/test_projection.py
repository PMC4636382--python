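import numpy as np
import pytest

from voxelrad.materials import hu_to_mu
from voxelrad.phantom import make_edge_phantom, make_slab
from voxelrad.projection import Geometry, attenuate_ray, project
from voxelrad.spectrum import Spectrum, kramers_spectrum


class TestGeometry:
    def test_validation(self):
        with pytest.raises(ValueError):
            Geometry(rows=0, cols=4, pitch_mm=1.0)
        with pytest.raises(ValueError):
            Geometry(rows=4, cols=4, pitch_mm=-1.0)
        with pytest.raises(ValueError):
            Geometry(rows=4, cols=4, pitch_mm=1.0, sid_cm=0.0)

    def test_field_size(self):
        g = Geometry(rows=10, cols=20, pitch_mm=0.5)
        assert g.field_size_mm == (10.0, 5.0)

    def test_distances_invariant_under_rotation(self):
        a = Geometry(rows=5, cols=5, pitch_mm=2.0, sid_cm=100.0)
        b = Geometry(
            rows=5, cols=5, pitch_mm=2.0, sid_cm=100.0, projection_angle_deg=37.0
        )
        np.testing.assert_allclose(
            a.source_pixel_distances_mm(), b.source_pixel_distances_mm()
        )

    def test_on_axis_distance_equals_sid(self):
        g = Geometry(rows=3, cols=3, pitch_mm=1.0, sid_cm=150.0)
        assert g.source_pixel_distances_mm()[1, 1] == pytest.approx(1500.0)


class TestAttenuateRay:
    def test_empty_volume_transmits_one(self, tables, mono60):
        ph = make_slab(material_hu=-1000.0, thickness_mm=50, lateral_mm=50, voxel_size_mm=1)
        t = attenuate_ray(
            ph, tables, [0.0, 500.0, 0.0], [0.0, -500.0, 0.0], 100, mono60
        )
        assert t[0] == 1.0

    def test_perpendicular_slab_matches_beer_lambert(self, tables, mono60):
        """Closed-form oracle: T = exp(-mu t) within 0.5% at dx = voxel/2."""
        vox = 0.62
        ph = make_slab(material_hu=0.0, thickness_mm=100.0, lateral_mm=60.0, voxel_size_mm=vox)
        t_slab = np.ceil(100.0 / vox) * vox  # world thickness of the built slab
        mu = hu_to_mu(0.0, 57.5, tables)
        exact = np.exp(-mu * t_slab)
        n = int(np.ceil(1000.0 / (vox / 2)))
        t = attenuate_ray(ph, tables, [0.0, 500.0, 0.0], [0.0, -500.0, 0.0], n, mono60)
        assert abs(t[0] - exact) / exact < 5e-3

    def test_oblique_45deg_matches_path_length_oracle(self, tables, mono60):
        ph = make_slab(material_hu=0.0, thickness_mm=100.0, lateral_mm=300.0, voxel_size_mm=1.0)
        src, pix = np.array([-500.0, 500.0, 0.0]), np.array([500.0, -500.0, 0.0])
        n = int(np.ceil(np.linalg.norm(pix - src) / 0.5))
        t = attenuate_ray(ph, tables, src, pix, n, mono60)
        mu = hu_to_mu(0.0, 57.5, tables)
        exact = np.exp(-mu * 100.0 * np.sqrt(2.0))
        assert t[0] == pytest.approx(exact, rel=5e-3)

    def test_worst_case_error_decreases_with_step_refinement(self, tables, mono60):
        """Worst-case transmission error over sampling phases falls with n."""
        vox = 0.62
        ph = make_slab(material_hu=0.0, thickness_mm=100.0, lateral_mm=300.0, voxel_size_mm=vox)
        t_slab = np.ceil(100.0 / vox) * vox
        mu = hu_to_mu(0.0, 57.5, tables)
        worst = []
        for fac in (4.0, 2.0, 1.0, 0.5):
            errs = []
            for d in np.linspace(0.0, 3.0, 25):
                src = np.array([0.0, 500.0 + d, 0.0])
                pix = np.array([137.3, -500.0, 0.0])
                L = np.linalg.norm(pix - src)
                exact = np.exp(-mu * t_slab * L / (1000.0 + d))
                n = int(np.ceil(L / (vox * fac)))
                t = attenuate_ray(ph, tables, src, pix, n, mono60)[0]
                errs.append(abs(t - exact) / exact)
            worst.append(max(errs))
        assert all(b < a for a, b in zip(worst, worst[1:]))

    def test_monotone_in_added_material(self, tables, mono60):
        """More material along the ray never increases any bin's transmission."""
        thin = make_slab(material_hu=0.0, thickness_mm=20, lateral_mm=60, voxel_size_mm=1)
        thick = make_slab(material_hu=0.0, thickness_mm=80, lateral_mm=60, voxel_size_mm=1)
        args = (tables, [0.0, 500.0, 0.0], [0.0, -500.0, 0.0], 2000, mono60)
        assert attenuate_ray(thick, *args)[0] < attenuate_ray(thin, *args)[0]


class TestProject:
    def test_zero_attenuation_gives_flat_unattenuated_fluence(self, tables):
        ph = make_slab(material_hu=-1000.0, thickness_mm=40, lateral_mm=40, voxel_size_mm=1)
        spec = kramers_spectrum(70)
        g = Geometry(rows=8, cols=8, pitch_mm=4.0, sid_cm=100.0, n_steps=64)
        img = project(ph, g, spec, tables)
        for i in range(spec.n_bins):
            np.testing.assert_allclose(img.phi[i], spec.fluence[i], rtol=1e-12)

    def test_half_field_slab_plateau_ratio(self, tables, mono60):
        """Edge phantom: two plateaus; covered/uncovered ratio = exp(-mu t)."""
        ph = make_edge_phantom(material_hu=0.0, thickness_mm=20.0, lateral_mm=400.0, voxel_size_mm=1.0)
        g = Geometry(rows=4, cols=64, pitch_mm=2.0, sid_cm=100.0, n_steps=4000)
        img = project(ph, g, mono60, tables)
        row = img.phi[0][2]
        covered, uncovered = row[5:25].mean(), row[40:60].mean()
        mu = hu_to_mu(0.0, 57.5, tables)
        # perpendicular-equivalent: small obliquity correction < 1%
        assert covered / uncovered == pytest.approx(np.exp(-mu * 20.0), rel=2e-2)

    def test_edge_position_matches_magnification(self, tables, mono60):
        """Similar triangles: an edge 20 mm off-axis at the phantom midplane
        projects to 40 mm off-axis at the detector (magnification 2)."""
        ph = make_edge_phantom(material_hu=0.0, thickness_mm=10.0, lateral_mm=200.0, voxel_size_mm=1.0)
        ph = ph.centred_at([20.0, 0.0, 0.0])
        g = Geometry(rows=4, cols=64, pitch_mm=2.0, sid_cm=180.0, n_steps=4000)
        img = project(ph, g, mono60, tables)
        row = img.phi[0][2]
        # transition column: largest jump
        jump = np.argmax(np.diff(row)) + 0.5
        x_mm = (jump - (64 - 1) / 2.0) * 2.0
        assert x_mm == pytest.approx(40.0, abs=2.0)
        # point source, no blur: transition confined to <= 1 pixel
        plateau_lo, plateau_hi = row[:15].mean(), row[-15:].mean()
        interior = (row > plateau_lo * 1.05) & (row < plateau_hi * 0.95)
        assert interior.sum() <= 1

    def test_doubling_steps_changes_pixels_below_discretisation_scale(
        self, tables, mono60, torso
    ):
        """At the default half-voxel step the residual discretisation error
        is first-order in dx (nearest-voxel sampling of material
        boundaries), so doubling n shifts pixels by at most ~mu*dx < 1%."""
        n = int(np.ceil(1800.0 / 1.0))  # half the torso's 2 mm voxel
        g1 = Geometry(rows=16, cols=16, pitch_mm=16.0, sid_cm=180.0, n_steps=n)
        g2 = Geometry(rows=16, cols=16, pitch_mm=16.0, sid_cm=180.0, n_steps=2 * n)
        a = project(torso, g1, mono60, tables).phi[0]
        b = project(torso, g2, mono60, tables).phi[0]
        assert np.max(np.abs(a - b) / b) < 1e-2

    def test_mirror_symmetry_at_180_degrees(self, tables, mono60):
        """Assembly rotated by 180 deg sees a y-symmetric phantom mirrored."""
        ph = make_edge_phantom(material_hu=0.0, thickness_mm=20.0, lateral_mm=300.0, voxel_size_mm=1.0)
        kw = dict(rows=4, cols=32, pitch_mm=4.0, sid_cm=120.0, n_steps=2400)
        img0 = project(ph, Geometry(**kw), mono60, tables).phi[0]
        img180 = project(
            ph, Geometry(projection_angle_deg=180.0, **kw), mono60, tables
        ).phi[0]
        np.testing.assert_allclose(img180, img0[:, ::-1], rtol=1e-3)

    def test_source_inside_phantom_rejected(self, tables, mono60):
        ph = make_slab(material_hu=0.0, thickness_mm=3000.0, lateral_mm=3000.0, voxel_size_mm=50.0)
        g = Geometry(rows=2, cols=2, pitch_mm=1.0, sid_cm=100.0, n_steps=10)
        with pytest.raises(ValueError, match="inside"):
            project(ph, g, mono60, tables)
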