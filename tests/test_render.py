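import math

import numpy as np
import pytest

import ellipsomol as em
from ellipsomol import Camera, Ellipsoid, RenderSettings, Sphere
from ellipsomol.render import screen_bound
from oracles import brute_force_depth


def _rotation_z(angle):
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


SETTINGS_PLAIN = RenderSettings(contours=False, ssao=False)


class TestGenerateRay:
    def test_center_pixel_is_principal_ray(self):
        cam = Camera(position=[0, 0, 10], target=[0, 0, 0], width=65, height=65)
        ray = em.generate_ray(cam, 32, 32)
        np.testing.assert_allclose(ray.direction, [0, 0, -1], atol=1e-12)

    def test_directions_are_unit(self):
        cam = Camera(position=[3, 1, 10], target=[0, 0, 0], width=64, height=48)
        for px, py in [(0, 0), (63, 47), (10, 20)]:
            ray = em.generate_ray(cam, px, py)
            assert abs(np.linalg.norm(ray.direction) - 1.0) <= 1e-12

    def test_adjacent_center_row_pixels_differ_in_right_only(self):
        cam = Camera(position=[0, 0, 10], target=[0, 0, 0], width=65, height=65)
        _, r, u = cam.basis()
        d1 = em.generate_ray(cam, 31, 32).direction
        d2 = em.generate_ray(cam, 32, 32).direction
        delta = d1 / abs(d1 @ np.array([0, 0, -1])) - d2 / abs(d2 @ np.array([0, 0, -1]))
        assert abs(delta @ u) <= 1e-12
        assert abs(delta @ r) > 0

    def test_out_of_range_pixel_rejected(self):
        cam = Camera(position=[0, 0, 10], target=[0, 0, 0], width=8, height=8)
        with pytest.raises(ValueError):
            em.generate_ray(cam, 8, 0)


class TestRaySphere:
    def test_axial_hit(self):
        ray = em.Ray(origin=np.array([0.0, 0, 10]), direction=np.array([0.0, 0, -1]))
        hit = em.ray_sphere_intersect(ray, Sphere(np.zeros(3), 1.0))
        assert hit.t == pytest.approx(9.0)
        np.testing.assert_allclose(hit.point, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(hit.normal, [0, 0, 1], atol=1e-12)

    def test_parallel_offset_miss(self):
        ray = em.Ray(origin=np.array([2.0, 0, 10]), direction=np.array([0.0, 0, -1]))
        assert em.ray_sphere_intersect(ray, Sphere(np.zeros(3), 1.0)) is None

    def test_origin_inside_hits_back_face(self):
        ray = em.Ray(origin=np.zeros(3), direction=np.array([1.0, 0, 0]))
        hit = em.ray_sphere_intersect(ray, Sphere(np.zeros(3), 1.0))
        assert hit.t == pytest.approx(1.0)
        np.testing.assert_allclose(hit.normal, [1, 0, 0])


class TestRayEllipsoid:
    def test_axial_hit_on_canonical_quadric(self):
        e = Ellipsoid(center=np.zeros(3), axes=np.eye(3), semi_axes=[2.0, 1.0, 1.0])
        ray = em.Ray(origin=np.array([-10.0, 0, 0]), direction=np.array([1.0, 0, 0]))
        hit = em.ray_ellipsoid_intersect(ray, e)
        assert hit.t == pytest.approx(8.0)
        np.testing.assert_allclose(hit.point, [-2, 0, 0], atol=1e-12)
        np.testing.assert_allclose(hit.normal, [-1, 0, 0], atol=1e-12)

    def test_sphere_degeneracy_random_rays(self):
        """Equal semi-axes reproduce the sphere intersector, |dt| <= 1e-9."""
        rng = np.random.default_rng(0)
        s = Sphere([0.5, -0.3, 0.2], 1.3)
        e = Ellipsoid(center=s.center, axes=np.eye(3), semi_axes=np.full(3, s.radius))
        n_hits = 0
        for _ in range(1000):
            origin = rng.normal(size=3) * 5
            # aim near the sphere so a good share of rays hit
            d = s.center + rng.normal(size=3) * 1.5 - origin
            d /= np.linalg.norm(d)
            ray = em.Ray(origin=origin, direction=d)
            hs = em.ray_sphere_intersect(ray, s)
            he = em.ray_ellipsoid_intersect(ray, e)
            assert (hs is None) == (he is None)
            if hs is not None:
                n_hits += 1
                assert abs(hs.t - he.t) <= 1e-9
                np.testing.assert_allclose(he.normal, hs.normal, atol=1e-9)
        assert n_hits > 50  # the fixture actually exercises hits

    def test_rotated_ellipsoid_matches_world_space_quadric(self):
        """Glyph-space solve equals solving (x-c)^T A (x-c) = 1 directly."""
        R = _rotation_z(math.pi / 4)
        e = Ellipsoid(center=np.array([1.0, 0.5, -0.2]), axes=R,
                      semi_axes=[2.0, 1.0, 0.5])
        A = e.quadric
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(200):
            origin = rng.normal(size=3) * 4
            d = e.center + rng.normal(size=3) * 1.5 - origin
            d /= np.linalg.norm(d)
            # world-space quadratic oracle
            oc = origin - e.center
            a = d @ A @ d
            b = 2 * oc @ A @ d
            c = oc @ A @ oc - 1.0
            disc = b * b - 4 * a * c
            hit = em.ray_ellipsoid_intersect(em.Ray(origin=origin, direction=d), e)
            if disc < 0:
                assert hit is None
                continue
            roots = [t for t in ((-b - math.sqrt(disc)) / (2 * a),
                                 (-b + math.sqrt(disc)) / (2 * a)) if t > 1e-12]
            if not roots:
                assert hit is None
                continue
            checked += 1
            assert hit is not None
            assert abs(hit.t - min(roots)) <= 1e-9
        assert checked > 30


class TestScreenBound:
    def test_centered_glyph_rect_is_centered(self):
        cam = Camera(position=[0, 0, 20], target=[0, 0, 0], width=65, height=65)
        rect = screen_bound(np.zeros(3), 2.0, cam)
        x0, y0, x1, y1 = rect
        assert x0 < 32 < x1 and y0 < 32 < y1
        assert abs((x0 + x1) / 2 - 32.5) <= 1.5 and abs((y0 + y1) / 2 - 32.5) <= 1.5

    def test_glyph_behind_camera_is_empty(self):
        cam = Camera(position=[0, 0, 20], target=[0, 0, 0], width=64, height=64)
        assert screen_bound(np.array([0.0, 0, 40.0]), 1.0, cam) is None

    def test_rect_is_conservative_against_brute_force(self):
        """Every pixel whose ray hits the ellipsoid lies inside the rect."""
        cam = Camera(position=[6.0, -4.0, 18.0], target=[0.5, 0.2, 0.0],
                     width=64, height=64)
        e = Ellipsoid(center=np.array([1.0, 1.5, -2.0]), axes=_rotation_z(0.6),
                      semi_axes=[3.0, 1.2, 0.8])
        rect = screen_bound(e.center, float(e.semi_axes[0]), cam)
        assert rect is not None
        x0, y0, x1, y1 = rect
        for py in range(64):
            for px in range(64):
                hit = em.ray_ellipsoid_intersect(em.generate_ray(cam, px, py), e)
                if hit is not None:
                    assert x0 <= px < x1 and y0 <= py < y1


class TestRenderFrame:
    def test_empty_display_list_is_background(self):
        cam = Camera(position=[0, 0, 10], target=[0, 0, 0], width=16, height=16)
        fb = em.render_frame([], cam, SETTINGS_PLAIN)
        assert np.all(np.isinf(fb.depth))
        assert np.all(fb.color == 1.0)

    def test_axial_sphere_center_depth(self, unit_sphere_scene):
        sphere, cam = unit_sphere_scene
        fb = em.render_frame([(0, "sphere", sphere, (1.0, 0, 0))], cam, SETTINGS_PLAIN)
        assert fb.depth[32, 32] == pytest.approx(9.0, abs=1e-9)

    def test_depth_test_prefers_near_sphere(self):
        cam = Camera(position=[0, 0, 10], target=[0, 0, 0], width=33, height=33)
        geometry = [
            (0, "sphere", Sphere([0.0, 0, 0], 1.0), (1.0, 0.0, 0.0)),
            (1, "sphere", Sphere([0.0, 0, 3.0], 1.0), (0.0, 1.0, 0.0)),
        ]
        fb = em.render_frame(geometry, cam, RenderSettings(shading="constant",
                                                           contours=False, ssao=False))
        assert fb.node_id[16, 16] == 1  # nearer sphere wins
        np.testing.assert_allclose(fb.color[16, 16], [0.0, 1.0, 0.0])

    def test_depth_matches_brute_force(self):
        """Renderer depth equals per-pixel brute force over all glyphs."""
        cam = Camera(position=[4.0, 3.0, 14.0], target=[0.0, 0.0, 0.0],
                     width=64, height=64)
        geometry = [
            (0, "sphere", Sphere([0.0, 0.0, 0.0], 1.4), (1.0, 0, 0)),
            (1, "ellipsoid", Ellipsoid(center=np.array([2.5, 0.5, -1.0]),
                                       axes=_rotation_z(0.7),
                                       semi_axes=[2.0, 1.0, 0.6]), (0, 1.0, 0)),
            (2, "sphere", Sphere([-2.0, 1.0, 1.0], 1.0), (0, 0, 1.0)),
        ]
        fb = em.render_frame(geometry, cam, SETTINGS_PLAIN)
        ref = brute_force_depth(geometry, cam)
        both = np.isfinite(fb.depth) & np.isfinite(ref)
        assert np.array_equal(np.isfinite(fb.depth), np.isfinite(ref))
        assert np.max(np.abs(fb.depth[both] - ref[both])) <= 1e-9

    def test_equal_axis_ellipsoids_match_spheres_pixelwise(self):
        cam = Camera(position=[1.0, 2.0, 12.0], target=[0, 0, 0], width=48, height=48)
        spheres = [Sphere([0.0, 0, 0], 1.2), Sphere([2.0, -1.0, 1.0], 0.8)]
        as_spheres = [(i, "sphere", s, (0.5, 0.5, 0.5)) for i, s in enumerate(spheres)]
        as_ellipsoids = [
            (i, "ellipsoid", Ellipsoid(center=s.center, axes=np.eye(3),
                                       semi_axes=np.full(3, s.radius)),
             (0.5, 0.5, 0.5))
            for i, s in enumerate(spheres)
        ]
        fb1 = em.render_frame(as_spheres, cam, SETTINGS_PLAIN)
        fb2 = em.render_frame(as_ellipsoids, cam, SETTINGS_PLAIN)
        assert np.array_equal(np.isfinite(fb1.depth), np.isfinite(fb2.depth))
        both = np.isfinite(fb1.depth)
        assert np.max(np.abs(fb1.depth[both] - fb2.depth[both])) <= 1e-6
        np.testing.assert_allclose(fb1.color, fb2.color, atol=1e-6)

    def test_resolution_equivariance_of_silhouette_radius(self):
        def projected_radius(width, height):
            cam = Camera(position=[0, 0, 10], target=[0, 0, 0],
                         width=width, height=height, vertical_fov=30.0)
            fb = em.render_frame([(0, "sphere", Sphere(np.zeros(3), 1.0), (1, 0, 0))],
                                 cam, SETTINGS_PLAIN)
            ys, xs = np.nonzero(fb.foreground)
            return 0.5 * (xs.max() - xs.min() + 1)

        r1 = projected_radius(64, 64)
        r2 = projected_radius(128, 128)
        assert abs(r2 - 2 * r1) <= 1.0


class TestShading:
    def test_aligned_full_intensity(self):
        n = np.array([0.0, 0, 1.0])
        out = em.shade_diffuse(n, n, np.array([1.0, 0.5, 0.25]))
        np.testing.assert_allclose(out, [1.0, 0.5, 0.25])

    def test_grazing_and_backfacing_hit_ambient_floor(self):
        n = np.array([0.0, 0, 1.0])
        albedo = np.array([1.0, 1.0, 1.0])
        for light in ([1.0, 0, 0], [0.0, 0, -1.0]):
            out = em.shade_diffuse(n, np.array(light), albedo, ambient=0.2)
            np.testing.assert_allclose(out, 0.2)

    def test_constant_mode_returns_albedo(self):
        out = em.shade_diffuse(np.array([0.0, 0, 1.0]), np.array([0.0, 0, 1.0]),
                               np.array([0.3, 0.6, 0.9]), constant=True)
        np.testing.assert_allclose(out, [0.3, 0.6, 0.9])


class TestSilhouette:
    def test_uniform_depth_plane_has_no_interior_edges(self):
        fb = em.FrameBuffer.empty(32, 32)
        fb.depth[:] = 5.0
        mask = em.silhouette_pass(fb, RenderSettings())
        assert not mask[1:-1, 1:-1].any()  # frame border touches "background"

    def test_sphere_silhouette_lies_on_analytic_circle(self, unit_sphere_scene):
        """Marked pixels sit within 2 px of the projected circle."""
        sphere, cam = unit_sphere_scene
        fb = em.render_frame([(0, "sphere", sphere, (1.0, 0, 0))], cam,
                             SETTINGS_PLAIN)
        mask = em.silhouette_pass(fb, RenderSettings())
        assert mask.any()
        # analytic projection: silhouette circle of a sphere under pinhole
        d = np.linalg.norm(cam.position - sphere.center)
        sin_a = sphere.radius / d
        tan_a = sin_a / math.sqrt(1 - sin_a**2)
        pix_per_tan = (cam.height / 2) / cam.tan_half_fov
        r_pix = tan_a * pix_per_tan
        cx = (cam.width - 1) / 2
        cy = (cam.height - 1) / 2
        ys, xs = np.nonzero(mask)
        dist = np.abs(np.hypot(xs - cx, ys - cy) - r_pix)
        assert dist.max() <= 2.0

    def test_two_isolated_spheres_give_two_components(self):
        from scipy.ndimage import label

        cam = Camera(position=[0, 0, 15], target=[0, 0, 0], width=96, height=96,
                     vertical_fov=40.0)
        geometry = [(0, "sphere", Sphere([-3.0, 0, 0], 1.0), (1, 0, 0)),
                    (1, "sphere", Sphere([3.0, 0, 0], 1.0), (0, 1, 0))]
        fb = em.render_frame(geometry, cam, SETTINGS_PLAIN)
        mask = em.silhouette_pass(fb, RenderSettings())
        _, n_components = label(mask, structure=np.ones((3, 3)))
        assert n_components == 2


class TestSSAO:
    def _scene(self, spheres, width=96, height=96):
        cam = Camera(position=[0, 0, 12], target=[0, 0, 0], width=width,
                     height=height, vertical_fov=40.0)
        geometry = [(i, "sphere", s, (1.0, 1.0, 1.0)) for i, s in enumerate(spheres)]
        fb = em.render_frame(geometry, cam, SETTINGS_PLAIN)
        return fb, cam

    def test_background_occlusion_is_zero(self):
        fb, cam = self._scene([Sphere(np.zeros(3), 1.0)])
        occ = em.ssao_pass(fb, cam, RenderSettings())
        assert np.all(occ[~fb.foreground] == 0.0)
        assert np.all((occ >= 0.0) & (occ <= 1.0))

    def test_deterministic_under_fixed_seed(self):
        fb, cam = self._scene([Sphere(np.zeros(3), 1.0), Sphere([1.8, 0, 0], 1.0)])
        s = RenderSettings(ssao_seed=42)
        occ1 = em.ssao_pass(fb, cam, s)
        occ2 = em.ssao_pass(fb, cam, s)
        assert np.array_equal(occ1, occ2)

    def test_crevice_darker_than_isolated_pole(self):
        """Contact crevice of touching spheres occludes more than a free pole."""
        fb_pair, cam = self._scene([Sphere([-1.0, 0, 0], 1.0), Sphere([1.0, 0, 0], 1.0)])
        fb_iso, _ = self._scene([Sphere(np.zeros(3), 1.0)])
        settings = RenderSettings(ssao_seed=0)
        occ_pair = em.ssao_pass(fb_pair, cam, settings)
        occ_iso = em.ssao_pass(fb_iso, cam, settings)
        cx, cy = 48, 48  # crevice pixel: between the spheres, at image center
        # pole of the isolated sphere: the pixel nearest the camera
        pole = np.unravel_index(np.argmin(np.where(fb_iso.foreground,
                                                   fb_iso.depth, np.inf)),
                                fb_iso.depth.shape)
        crevice_region = occ_pair[cy - 2:cy + 3, cx - 2:cx + 3]
        crevice = crevice_region[fb_pair.foreground[cy - 2:cy + 3, cx - 2:cx + 3]].max()
        assert crevice > occ_iso[pole]


class TestWriteImage:
    def test_ppm_bytes_for_white_2x2(self, tmp_path):
        path = tmp_path / "white.ppm"
        em.write_image(np.ones((2, 2, 3)), path, format="PPM")
        data = path.read_bytes()
        header = b"P6\n2 2\n255\n"
        assert data.startswith(header)
        payload = data[len(header):]
        assert len(payload) == 12 and set(payload) == {255}

    def test_byte_identical_across_runs(self, tmp_path):
        rng = np.random.default_rng(5)
        img = rng.random((16, 16, 3))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        em.write_image(img, p1)
        em.write_image(img, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_half_up_quantisation(self, tmp_path):
        img = np.full((1, 1, 3), 0.5)  # 127.5 -> 128
        path = tmp_path / "gray.ppm"
        em.write_image(img, path, format="PPM")
        assert path.read_bytes()[-3:] == bytes([128, 128, 128])

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            em.write_image(np.ones((2, 2, 3)), tmp_path / "x.tiff", format="TIFF")
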