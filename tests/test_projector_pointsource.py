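import numpy as np
import pytest

from drrforge.attenuation import AttenuationModel, material_decompose
from drrforge.core import (
    CTVolume,
    DomainError,
    DRRImage,
    GeometryError,
    ProjectionGeometry,
    validate_volume,
)
from drrforge.phantom import PhantomSpec, generate_chest_phantom
from drrforge.projector_parallel import beer_lambert_project
from drrforge.projector_pointsource import (
    apply_noise,
    cast_ray,
    default_pointsource_geometry,
    point_source_project,
)

# attenuation model with inactive decomposition: identical mu field for both
# the parallel and the point-source projector
NEUTRAL = AttenuationModel(bone_factor=1.0, air_below=-2000.0, bone_above=4000.0)


class TestCastRay:
    def test_vacuum_ray_is_zero(self):
        vol = validate_volume(CTVolume(data=np.full((8, 8, 8), -1000.0)))
        assert cast_ray(vol, None, (4.0, -50.0, 4.0), (0, 1, 0)) == 0.0

    def test_water_cube_closed_form(self):
        # 50 mm water cube, axis-aligned central ray: integral = 0.02 * 50 = 1
        vol = validate_volume(CTVolume(data=np.zeros((50, 50, 50)), spacing=(1.0, 1.0, 1.0)))
        got = cast_ray(vol, AttenuationModel(mu_water=0.02), (24.5, -100.0, 24.5), (0, 1, 0))
        assert got == pytest.approx(1.0, rel=1e-6)

    def test_missing_ray_is_zero(self):
        vol = validate_volume(CTVolume(data=np.zeros((8, 8, 8))))
        assert cast_ray(vol, None, (100.0, -50.0, 100.0), (0, 1, 0)) == 0.0

    def test_zero_direction_rejected(self):
        vol = validate_volume(CTVolume(data=np.zeros((4, 4, 4))))
        with pytest.raises(GeometryError):
            cast_ray(vol, None, (0, 0, 0), (0, 0, 0))

    def test_agrees_with_refined_step_quadrature(self, rng):
        """Default-step integrals match a 10x finer quadrature within 1%."""
        data = rng.uniform(-1000, 1500, size=(8, 8, 8))
        vol = validate_volume(CTVolume(data=data))
        mu = material_decompose(vol, NEUTRAL).mu
        for _ in range(10):
            origin = np.array([4.0, 4.0, 4.0]) + rng.normal(0, 1, 3) - np.array([0, 30.0, 0])
            direction = np.array([0, 1, 0]) + rng.normal(0, 0.15, 3)
            direction /= np.linalg.norm(direction)
            coarse = cast_ray(vol, NEUTRAL, origin, direction, step=0.5, mu=mu)
            fine = cast_ray(vol, NEUTRAL, origin, direction, step=0.05, mu=mu)
            assert coarse == pytest.approx(fine, rel=0.01, abs=1e-4)


class TestPointSourceProject:
    def test_empty_volume_gives_i0_everywhere(self):
        vol = validate_volume(CTVolume(data=np.full((16, 16, 16), -1000.0)))
        out = point_source_project(vol, i0=3.0)
        assert out.domain == "intensity"
        assert np.allclose(out.data, 3.0)

    def test_source_inside_volume_rejected(self):
        vol = validate_volume(CTVolume(data=np.zeros((16, 16, 16))))
        geo = ProjectionGeometry(
            mode="point_source",
            source_position=(8.0, 8.0, 8.0),
            source_detector_distance=100.0,
            source_object_distance=50.0,
        )
        with pytest.raises(GeometryError):
            point_source_project(vol, geo)

    def test_magnified_disc_radius_follows_similar_triangles(self):
        # water sphere, radius 12 mm, centered in a 48 mm air cube
        n, sp = 32, 1.5
        idx = (np.arange(n) - (n - 1) / 2) * sp
        zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij")
        data = np.where(zz**2 + yy**2 + xx**2 <= 12.0**2, 0.0, -1000.0)
        vol = validate_volume(CTVolume(data=data, spacing=(sp, sp, sp)))
        geo = default_pointsource_geometry(vol, 1800.0, 1500.0)
        out = point_source_project(vol, geo, NEUTRAL)
        row = out.data[n // 2]
        dark = np.flatnonzero(row < 0.97)
        measured_halfwidth_px = (dark[-1] - dark[0] + 1) / 2.0
        expected_px = 12.0 / sp  # detector pitch = voxel spacing * magnification
        assert measured_halfwidth_px == pytest.approx(expected_px, abs=1.0)

    def test_parallel_limit_recovers_parallel_projection(self):
        vol = generate_chest_phantom(PhantomSpec(shape=(32, 32, 32)))
        par = beer_lambert_project(vol, NEUTRAL)
        geo = default_pointsource_geometry(vol, 1.2e6, 1.0e6)
        ps = point_source_project(vol, geo, NEUTRAL)
        assert np.abs(ps.data - par.data).max() < 1e-3

    def test_edge_rows_integrate_different_voxels_than_parallel(self):
        """Cranial content over-projects into point-source edge rows only."""
        base = np.full((32, 32, 32), -1000.0)
        vol = validate_volume(CTVolume(data=base, spacing=(1.5, 1.5, 1.5)))
        bumped = base.copy()
        bumped[2, 4, 10:22] = 2000.0  # near-cranial, near-anterior content
        vol2 = validate_volume(CTVolume(data=bumped, spacing=(1.5, 1.5, 1.5)))

        par_diff = beer_lambert_project(vol2).data - beer_lambert_project(vol).data
        assert np.all(par_diff[0] == 0.0)  # parallel edge row sees only slice z=0

        geo = default_pointsource_geometry(vol, 240.0, 200.0)  # strong divergence
        ps_diff = point_source_project(vol2, geo, NEUTRAL).data - point_source_project(
            vol, geo, NEUTRAL
        ).data
        assert np.abs(ps_diff[0]).max() > 0.0


class TestApplyNoise:
    def _image(self, value=0.5, shape=(32, 32)):
        return DRRImage(data=np.full(shape, value), domain="intensity", technique="point_source")

    def test_disabled_noise_is_identity(self):
        img = self._image()
        out = apply_noise(img, photons_per_pixel=None, scatter_fraction=0.0)
        assert np.array_equal(out.data, img.data)

    def test_fixed_seed_is_bit_deterministic(self):
        img = self._image()
        a = apply_noise(img, photons_per_pixel=1e4, scatter_fraction=0.1, seed=7)
        b = apply_noise(img, photons_per_pixel=1e4, scatter_fraction=0.1, seed=7)
        assert np.array_equal(a.data, b.data)
        c = apply_noise(img, photons_per_pixel=1e4, scatter_fraction=0.1, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_display_domain_rejected(self):
        img = DRRImage(data=np.zeros((4, 4)), domain="display")
        with pytest.raises(DomainError):
            apply_noise(img)

    def test_scatter_only_preserves_mean_and_blurs(self):
        rng = np.random.default_rng(0)
        img = DRRImage(data=rng.uniform(0.2, 0.9, (64, 64)), domain="intensity")
        out = apply_noise(img, photons_per_pixel=None, scatter_fraction=0.3, scatter_sigma=5.0)
        assert out.data.mean() == pytest.approx(img.data.mean(), rel=1e-3)
        assert out.data.std() < img.data.std()

    def test_poisson_stage_is_mean_preserving(self):
        img = self._image(value=0.4, shape=(100, 100))
        out = apply_noise(img, photons_per_pixel=1e4, scatter_fraction=0.0, seed=3)
        sigma = np.sqrt(0.4 / 1e4)
        assert out.data.mean() == pytest.approx(0.4, abs=3 * sigma / 100)
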