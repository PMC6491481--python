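"""Crown geometry: hull volumes, alpha selection, STAR."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from orchard_phenomics import geometry as g
from orchard_phenomics.synthdata import CrownSpec, generate_crown

UNIT_CUBE = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
)
# regular tetrahedron with edge length 1
TETRA = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0.5, np.sqrt(3) / 2, 0],
        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
    ]
)


class TestConvexHull:
    def test_unit_cube_volume_is_one(self):
        assert g.convex_hull_volume(UNIT_CUBE) == pytest.approx(1.0)

    def test_regular_tetrahedron_closed_form(self):
        assert g.convex_hull_volume(TETRA) == pytest.approx(np.sqrt(2) / 12)

    def test_uniform_ball_converges_to_sphere_volume(self, rng):
        # hull deficit of n uniform points in a ball shrinks ~ n^(-1/2);
        # 3e4 points bring it within the 3% band
        n = 30_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * rng.uniform(size=(n, 1)) ** (1 / 3)
        vol = g.convex_hull_volume(pts)
        assert vol == pytest.approx(4 * np.pi / 3, rel=0.03)

    @pytest.mark.parametrize(
        "bad",
        [
            UNIT_CUBE[:3],  # too few points
            np.column_stack([np.arange(6.0), np.arange(6.0) * 2, np.zeros(6)]),  # coplanar
            np.tile(np.arange(5.0), (3, 1)).T,  # collinear
        ],
    )
    def test_degenerate_clouds_raise(self, bad):
        with pytest.raises(g.DegenerateCloudError):
            g.convex_hull_volume(bad)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(size=(400, 3))
        rot = special_ortho_group.rvs(3, random_state=5)
        moved = pts @ rot.T + np.array([12.0, -7.0, 3.0])
        assert g.convex_hull_volume(moved) == pytest.approx(
            g.convex_hull_volume(pts), rel=1e-9
        )
        assert g.alpha_hull_volume(moved, 0.3) == pytest.approx(
            g.alpha_hull_volume(pts, 0.3), rel=1e-6
        )


class TestAlphaHull:
    def test_large_alpha_equals_convex_hull(self, rng):
        pts = rng.uniform(size=(600, 3))
        assert g.alpha_hull_volume(pts, 1e6) == pytest.approx(
            g.convex_hull_volume(pts), rel=1e-9
        )

    def test_alpha_below_point_spacing_gives_zero_with_warning(self):
        pts = np.array([[i, j, k] for i in range(3) for j in range(3) for k in range(3)], float)
        with pytest.warns(RuntimeWarning):
            assert g.alpha_hull_volume(pts, 0.01) == 0.0

    def test_disconnected_components_are_summed(self, rng):
        cube = rng.uniform(size=(4000, 3))
        far = cube + np.array([6.0, 0.0, 0.0])  # 5 m gap between the two cubes
        single = g.alpha_hull_volume(cube, 0.5)
        both = g.alpha_hull_volume(np.vstack([cube, far]), 0.5)
        assert both == pytest.approx(2 * single, rel=1e-9)
        assert both == pytest.approx(2.0, abs=0.25)  # boundary shrinkage only

    def test_monotone_in_alpha_and_bounded_by_convex_hull(self, rng):
        grid = np.array([0.08, 0.15, 0.3, 0.6, 1.2])
        for seed in range(10):
            cloud, _ = generate_crown(CrownSpec(n_leaves=300, seed=seed))
            prof = g.alpha_volume_profile(cloud.points, grid)
            assert np.all(np.diff(prof) >= -1e-12)
            assert prof[-1] <= g.convex_hull_volume(cloud.points) * (1 + 1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            g.alpha_hull_volume(UNIT_CUBE, 0.0)


class TestConvexityIndex:
    @pytest.mark.parametrize("a,c,expect", [(2.0, 2.0, 1.0), (0.5, 2.0, 0.25)])
    def test_ratio(self, a, c, expect):
        assert g.convexity_index(a, c) == expect

    def test_alpha_exceeding_convex_hull_is_inconsistent(self):
        with pytest.raises(ValueError):
            g.convexity_index(2.5, 2.0)

    def test_descriptor_bundle_matches_definitions(self):
        cloud, _ = generate_crown(CrownSpec(n_leaves=800, seed=3))
        res = g.hull_descriptors(cloud, alpha=0.4)
        assert res.c_i == pytest.approx(res.a_volume / res.c_volume, rel=1e-12)
        assert 0 < res.c_i <= 1
        assert 0 < res.a_volume <= res.c_volume


class TestAlphaSelection:
    def test_single_candidate_grid(self):
        clouds = [generate_crown(CrownSpec(n_leaves=200, seed=s))[0] for s in range(3)]
        sel = g.select_alpha(clouds, [1.0, 2.0, 3.0], alpha_grid=[0.15])
        assert sel.alpha == 0.15

    def test_default_without_calibration_data(self):
        sel = g.select_alpha()
        assert sel.alpha == 0.15
        assert not sel.calibrated

    def test_constant_tla_rejected(self):
        clouds = [generate_crown(CrownSpec(n_leaves=200, seed=s))[0] for s in range(3)]
        with pytest.raises(ValueError, match="constant TLA"):
            g.select_alpha(clouds, [2.0, 2.0, 2.0], alpha_grid=[0.15, 0.3])

    def test_planted_optimum_is_recovered(self):
        # Heterogeneous two-lobe crowns whose alpha-volume profiles are not
        # collinear across trees; defining TLA as the alpha-0.3 volume plants
        # the correlation optimum exactly there.
        grid = [0.15, 0.3, 0.6, 1.2]
        clouds = []
        for s in range(6):
            spec = CrownSpec(
                n_leaves=400,
                semi_axes=(0.5 + 0.2 * s, 0.6, 0.8),
                lobes=2 + s % 3,
                clumping=0.3 * (s % 2),
                seed=100 + s,
            )
            clouds.append(generate_crown(spec)[0])
        tla = [g.alpha_hull_volume(c.points, 0.3) for c in clouds]
        sel = g.select_alpha(clouds, tla, alpha_grid=grid)
        assert sel.alpha == 0.3
        assert sel.profile.shape == (len(grid), 2)


class TestStar:
    def test_single_disk_is_one(self):
        res = g.compute_star(
            np.array([[0.0, 0.0, 0.0]]),
            directions=[[0, 0, 1]],
            leaf_radius=0.05,
            grid_resolution=0.004,
        )
        assert res.star == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_coincident_disks_follow_one_over_n(self, n):
        res = g.compute_star(
            np.zeros((n, 3)),
            directions=[[0, 0, 1]],
            leaf_radius=0.05,
            grid_resolution=0.004,
        )
        assert res.star * n == pytest.approx(1.0, rel=0.02)

    def test_well_separated_disks_reach_one(self, rng):
        # 50 disks on a wide grid: no overlap, silhouette = total area
        xy = np.array([[i, j] for i in range(10) for j in range(5)], float) * 0.5
        pts = np.column_stack([xy, np.zeros(50)])
        res = g.compute_star(
            pts, directions=[[0, 0, 1]], leaf_radius=0.05, grid_resolution=0.004
        )
        assert res.star == pytest.approx(1.0, rel=0.02)

    def test_silhouette_matches_union_of_circles_oracle(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point
        from shapely.ops import unary_union

        r = 0.06
        for _ in range(3):
            pts = np.column_stack([rng.uniform(0, 1, size=(50, 2)), np.zeros(50)])
            exact = unary_union(
                [Point(p[0], p[1]).buffer(r, quad_segs=256) for p in pts]
            ).area
            approx = g.silhouette_area(pts, [0, 0, 1], r, r / 20)
            assert approx == pytest.approx(exact, rel=0.02)

    def test_resolution_must_be_finer_than_leaf(self):
        with pytest.raises(ValueError, match="grid_resolution"):
            g.compute_star(
                np.zeros((1, 3)), directions=[[0, 0, 1]], leaf_radius=0.01,
                grid_resolution=0.02,
            )

    def test_clumping_weakly_decreases_star_at_fixed_tla(self):
        dirs = g.upper_hemisphere_directions(6)
        stars = {}
        for clump in (0.0, 0.9):
            vals = []
            for seed in range(4):
                spec = CrownSpec(n_leaves=300, leaf_radius=0.05, clumping=clump, seed=seed)
                cloud, truth = generate_crown(spec)
                res = g.compute_star(
                    cloud.points,
                    directions=dirs,
                    leaf_radius=spec.leaf_radius,
                    grid_resolution=0.01,
                    total_leaf_area=truth["TLA"],
                )
                vals.append(res.star)
            stars[clump] = np.mean(vals)
        assert stars[0.9] <= stars[0.0] + 1e-6

    def test_hemisphere_directions_are_unit_and_upward(self):
        dirs = g.upper_hemisphere_directions(46)
        assert dirs.shape == (46, 3)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        assert np.all(dirs[:, 2] > 0)
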