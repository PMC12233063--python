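import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from hexeye.classify import ProbabilityMaps
from hexeye.hexgrid import (
    HEX_NEIGHBOR_OFFSETS,
    ExpansionConfig,
    HexGrid,
    Ommatidium,
    add_manual,
    affine_from_anchors,
    auto_seed,
    build_mickey_template,
    expand_grid,
    fit_candidate,
    grid_edge_length,
    mirror_predict,
    remove,
    seed_grid,
)
# pairs of neighbor offsets that are themselves adjacent (valid triplet shapes)
ADJACENT_OFFSET_PAIRS = [
    (a, b)
    for a, b in itertools.combinations(HEX_NEIGHBOR_OFFSETS, 2)
    if (a[0] - b[0], a[1] - b[1]) in HEX_NEIGHBOR_OFFSETS
]


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def random_triplet(rng):
    h1 = tuple(rng.integers(-50, 50, 2))
    d2, d3 = ADJACENT_OFFSET_PAIRS[rng.integers(len(ADJACENT_OFFSET_PAIRS))]
    h2 = (h1[0] + d2[0], h1[1] + d2[1])
    h3 = (h1[0] + d3[0], h1[1] + d3[1])
    p1, p2, p3 = rng.normal(0, 100, (3, 2))
    return (
        Ommatidium(h1, p1),
        Ommatidium(h2, p2),
        Ommatidium(h3, p3),
    )


class TestMirrorProperty:
    """Lattice-algebra invariants over arbitrary valid triplets."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    coord = st.integers(min_value=-1000, max_value=1000)
    pos_val = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)

    @given(
        hex1=st.tuples(coord, coord),
        pair_idx=st.integers(min_value=0, max_value=len(ADJACENT_OFFSET_PAIRS) - 1),
        coords=st.lists(pos_val, min_size=6, max_size=6),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mirror_is_an_involution(self, hex1, pair_idx, coords):
        d2, d3 = ADJACENT_OFFSET_PAIRS[pair_idx]
        o1 = Ommatidium(hex1, coords[0:2])
        o2 = Ommatidium((hex1[0] + d2[0], hex1[1] + d2[1]), coords[2:4])
        o3 = Ommatidium((hex1[0] + d3[0], hex1[1] + d3[1]), coords[4:6])
        hex4, pos4 = mirror_predict(o1, o2, o3)
        hex1b, pos1b = mirror_predict(Ommatidium(hex4, pos4), o2, o3)
        assert hex1b == o1.hex
        assert np.allclose(pos1b, o1.pos, rtol=1e-12, atol=1e-6)


class TestSeedGrid:
    def test_equilateral_seed(self):
        g = seed_grid((0, 0), (10, 0), (5, 8.66))
        assert len(g) == 3
        assert {o.hex for o in g} == {(0, 0), (1, 0), (0, 1)}
        assert grid_edge_length(g) == pytest.approx(10.0, rel=0.01)

    def test_collinear_triplet_rejected(self):
        with pytest.raises(ValueError, match="degenerate|collinear"):
            seed_grid((0, 0), (10, 0), (5, 0))

    def test_distant_points_rejected(self):
        with pytest.raises(ValueError, match="close"):
            seed_grid((0, 0), (10, 0), (200, 300))


class TestMirrorPredict:
    def test_hex_and_pos_arithmetic(self):
        o1 = Ommatidium((0, 0), (0.0, 0.0))
        o2 = Ommatidium((1, 0), (2.0, 0.0))
        o3 = Ommatidium((0, 1), (0.0, 2.0))
        hex4, pos4 = mirror_predict(o1, o2, o3)
        assert hex4 == (1, 1)
        assert pos4.tolist() == [2.0, 2.0]

    def test_involution_on_random_triplets(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            o1, o2, o3 = random_triplet(rng)
            hex4, pos4 = mirror_predict(o1, o2, o3)
            assert hex4 == (
                o2.hex[0] + o3.hex[0] - o1.hex[0],
                o2.hex[1] + o3.hex[1] - o1.hex[1],
            )
            assert np.array_equal(pos4, o2.pos + o3.pos - o1.pos)
            o4 = Ommatidium(hex4, pos4)
            hex1b, pos1b = mirror_predict(o4, o2, o3)
            assert hex1b == o1.hex  # integer arithmetic: exact
            assert np.allclose(pos1b, o1.pos, rtol=0, atol=1e-9)

    def test_non_adjacent_triplet_rejected(self):
        o1 = Ommatidium((0, 0), (0.0, 0.0))
        o2 = Ommatidium((2, 0), (2.0, 0.0))
        o3 = Ommatidium((0, 1), (0.0, 2.0))
        with pytest.raises(ValueError, match="adjacent"):
            mirror_predict(o1, o2, o3)


class TestGridEdgeLength:
    def test_uniform_lattice(self):
        g = HexGrid()
        d = 12.0
        basis = d * np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        for i in range(-2, 3):
            for j in range(-2, 3):
                g.add(Ommatidium((i, j), np.array([i, j]) @ basis))
        assert grid_edge_length(g) == pytest.approx(d)

    def test_single_pair(self):
        g = HexGrid()
        g.add(Ommatidium((0, 0), (0.0, 0.0)))
        g.add(Ommatidium((1, 0), (12.0, 0.0)))
        assert grid_edge_length(g) == 12.0

    def test_jittered_lattice_matches_pair_enumeration(self):
        rng = np.random.default_rng(1)
        g = HexGrid()
        basis = 10 * np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        coords = {}
        for i in range(-3, 4):
            for j in range(-3, 4):
                p = np.array([i, j]) @ basis + rng.normal(0, 1, 2)
                g.add(Ommatidium((i, j), p))
                coords[(i, j)] = p
        dists = []
        for (i, j), p in coords.items():
            for dx, dy in HEX_NEIGHBOR_OFFSETS:
                q = coords.get((i + dx, j + dy))
                if q is not None:
                    dists.append(np.linalg.norm(p - q))
        assert grid_edge_length(g) == pytest.approx(np.mean(dists))

    def test_no_pairs_errors(self):
        g = HexGrid()
        g.add(Ommatidium((0, 0), (0.0, 0.0)))
        g.add(Ommatidium((5, 5), (50.0, 50.0)))
        with pytest.raises(ValueError):
            grid_edge_length(g)


class TestMickeyTemplate:
    def test_geometry_at_m40(self):
        t = build_mickey_template(40)
        a = t.anchors
        for i, j in ((0, 1), (0, 2), (1, 2)):
            assert np.linalg.norm(a[i] - a[j]) == pytest.approx(20.0, abs=1e-9)
        # circle radius 0.225*m = 9: values near an anchor are high
        assert t.image[int(a[2][1]), int(a[2][0])] > 0.8

    def test_symmetric_under_ear_swap(self):
        t = build_mickey_template(36)
        img = np.nan_to_num(t.image, nan=-1.0)
        # ears are mirror images about the vertical axis through the face
        assert np.allclose(img, img[:, ::-1], atol=1e-12)

    def test_smoothing_keeps_max_below_one(self):
        for m in (20, 33, 50):
            t = build_mickey_template(m)
            assert np.nanmax(t.image) < 1.0

    def test_nan_region_present_and_excluded(self):
        t = build_mickey_template(30)
        assert np.isnan(t.image).any()
        assert not np.isnan(t.values).any()

    def test_m_below_20_rejected(self):
        with pytest.raises(ValueError):
            build_mickey_template(19)


class TestAffine:
    def test_identity_when_targets_are_anchors(self):
        t = build_mickey_template(40)
        A = affine_from_anchors(t, *t.anchors)
        assert np.allclose(A, np.array([[1, 0, 0], [0, 1, 0]]), atol=1e-9)

    def test_pure_scaling(self):
        t = build_mickey_template(40)
        A = affine_from_anchors(t, *(2.0 * t.anchors))
        assert np.allclose(A[:, :2], 2.0 * np.eye(2), atol=1e-9)

    def test_random_targets_mapped_exactly(self):
        t = build_mickey_template(28)
        rng = np.random.default_rng(2)
        for _ in range(20)        :
            targets = rng.normal(0, 50, (3, 2))
            if abs(_cross2(targets[1] - targets[0], targets[2] - targets[0])) < 1.0:
                continue
            A = affine_from_anchors(t, *targets)
            for anchor, target in zip(t.anchors, targets):
                got = A @ np.array([anchor[0], anchor[1], 1.0])
                assert np.allclose(got, target, atol=1e-9)

    def test_collinear_targets_rejected(self):
        t = build_mickey_template(28)
        with pytest.raises(ValueError, match="collinear"):
            affine_from_anchors(t, (0, 0), (10, 10), (20, 20))


def render_template_image(template, A, shape):
    """Paint the (NaN-free) smoothed template into an image through affine A."""
    h, w = shape
    img = np.zeros((h, w))
    Ainv_lin = np.linalg.inv(A[:, :2])
    for yy in range(h):
        for xx in range(w):
            src = Ainv_lin @ (np.array([xx, yy], float) - A[:, 2])
            i, j = int(round(src[0])), int(round(src[1]))
            if 0 <= i < template.m and 0 <= j < template.m:
                v = template.image[j, i]
                img[yy, xx] = 0.0 if np.isnan(v) else v
    return img


class TestFitCandidate:
    def test_recovers_rendered_template(self):
        m = 24
        template = build_mickey_template(m)
        theta0 = 0.8
        shift = np.array([30.0, 25.0])
        A = np.column_stack([np.eye(2), shift])  # pure translation
        img = theta0 * render_template_image(template, A, (80, 80))
        ears = [template.anchors[0] + shift, template.anchors[1] + shift]
        true_face = template.anchors[2] + shift
        L = m / 2.0
        omtd1 = Ommatidium((0, 0), ears[0] + ears[1] - true_face)
        predicted = true_face + np.array([1.0, -1.0])
        fit = fit_candidate(
            img, Ommatidium((1, 0), ears[0]), Ommatidium((0, 1), ears[1]),
            predicted, omtd1, L, ExpansionConfig(template_m=m),
        )
        assert np.isfinite(fit.delta)
        assert np.linalg.norm(fit.pos - true_face) < 1.0
        assert fit.theta == pytest.approx(theta0, abs=0.05)
        assert fit.delta < 1e-3 * len(template.values)

    def test_displaced_prediction_rejected(self):
        """A fit cannot wander farther than 0.3*L_grid from its prediction."""
        m = 24
        template = build_mickey_template(m)
        shift = np.array([30.0, 25.0])
        A = np.column_stack([np.eye(2), shift])
        img = render_template_image(template, A, (80, 80))
        ears = [template.anchors[0] + shift, template.anchors[1] + shift]
        true_face = template.anchors[2] + shift
        L = m / 2.0
        omtd1 = Ommatidium((0, 0), ears[0] + ears[1] - true_face)
        predicted = true_face + np.array([0.7 * L, 0.0])
        fit = fit_candidate(
            img, Ommatidium((1, 0), ears[0]), Ommatidium((0, 1), ears[1]),
            predicted, omtd1, L, ExpansionConfig(template_m=m),
        )
        # the only plausible facet is beyond the hard 0.3*L_grid search
        # radius: the fit must be rejected or pinned far from that facet
        assert fit.delta == np.inf or np.linalg.norm(fit.pos - true_face) > 0.3 * L

    def test_delta_invariant_under_ear_swap(self, flat_patch):
        _, gt, maps = flat_patch
        g = auto_seed(maps)
        omtds = list(g)
        L = grid_edge_length(g)
        hex4, pos4 = mirror_predict(omtds[0], omtds[1], omtds[2])
        f_ab = fit_candidate(maps.facet_prob, omtds[1], omtds[2], pos4, omtds[0], L)
        f_ba = fit_candidate(maps.facet_prob, omtds[2], omtds[1], pos4, omtds[0], L)
        assert f_ab.delta == pytest.approx(f_ba.delta, rel=1e-9, abs=1e-9)
        assert np.allclose(f_ab.pos, f_ba.pos, atol=1e-6)

    def test_theta_closed_form_matches_brute_force_scan(self):
        """Closed-form brightness factor vs a 1-D scan of the objective."""
        rng = np.random.default_rng(3)
        from scipy.interpolate import RegularGridInterpolator
        from scipy.ndimage import gaussian_filter

        for trial in range(100):
            m = int(rng.integers(20, 36))
            template = build_mickey_template(m)
            img = gaussian_filter(rng.random((60, 60)), 2.0)
            ear1 = rng.uniform(15, 45, 2)
            ear2 = ear1 + rng.uniform(-12, 12, 2)
            face = ear1 + rng.uniform(-12, 12, 2)
            if abs(_cross2(ear2 - ear1, face - ear1)) < 5.0:
                continue
            omtd1 = Ommatidium((0, 0), ear1 + ear2 - face)
            fit = fit_candidate(
                img, Ommatidium((1, 0), ear1), Ommatidium((0, 1), ear2),
                face, omtd1, m / 2.0,
                ExpansionConfig(template_m=m, search_radius_frac=1e-9,
                                slant_max=180, face_mass_ratio=0.0),
            )
            # independent evaluation: own affine solve + own interpolator
            src = np.vstack([template.anchors.T, np.ones(3)])
            A = np.array([ear1, ear2, fit.pos]).T @ np.linalg.inv(src)
            pts = (A @ np.vstack([template.pixels.T, np.ones(len(template.pixels))])).T
            interp = RegularGridInterpolator(
                (np.arange(60), np.arange(60)), img,
                bounds_error=False, fill_value=0.0,
            )
            p = interp(pts[:, ::-1])  # (y, x) order
            t = template.values
            thetas = np.linspace(0.0, 2.0, 4001)
            deltas = [((p - th * t) ** 2).sum() for th in thetas]
            theta_scan = thetas[int(np.argmin(deltas))]
            assert fit.theta == pytest.approx(theta_scan, abs=1e-3)


class TestExpandGrid:
    def test_flat_patch_fully_registered_with_matching_hexes(self, flat_patch):
        _, gt, maps = flat_patch
        g = auto_seed(maps)
        expand_grid(g, maps)
        assert len(g) == gt.n == 61
        pos = g.positions()
        d, idx = cKDTree(gt.centers).query(pos)
        assert d.max() < 0.3 * grid_edge_length(g)
        assert len(set(idx)) == gt.n
        # hex coordinates agree with ground truth up to the lattice map
        # fixed by the seed (an integer affine transform)
        rec = np.array([o.hex for o in g], dtype=float)
        M = np.linalg.solve(
            np.hstack([rec[:3], np.ones((3, 1))]), gt.hex_coords[idx[:3]].astype(float)
        )
        mapped = np.hstack([rec, np.ones((len(rec), 1))]) @ M
        assert np.allclose(mapped, gt.hex_coords[idx], atol=1e-6)

    def test_mask_limited_to_seeds_blocks_growth(self, flat_patch):
        _, gt, maps = flat_patch
        g = auto_seed(maps)
        tiny_mask = np.zeros_like(maps.eye_mask)
        for o in g:
            tiny_mask[int(round(o.pos[1])), int(round(o.pos[0]))] = True
        maps2 = ProbabilityMaps(maps.eye_prob, maps.facet_prob, tiny_mask)
        expand_grid(g, maps2)
        assert len(g) == 3

    def test_deterministic_across_reruns(self, flat_patch):
        _, gt, maps = flat_patch
        outs = []
        for _ in range(2):
            g = auto_seed(maps)
            expand_grid(g, maps)
            outs.append(sorted((o.hex, tuple(o.pos)) for o in g))
        assert outs[0] == outs[1]

    def test_no_two_registrations_closer_than_half_spacing(self, ideal_eye):
        _, gt, maps = ideal_eye
        g = auto_seed(maps)
        expand_grid(g, maps)
        pos = g.positions()
        d, _ = cKDTree(pos).query(pos, k=2)
        assert d[:, 1].min() >= 0.5 * grid_edge_length(g) * 0.99

    def test_hex_uniqueness_is_structural(self):
        g = HexGrid()
        g.add(Ommatidium((0, 0), (0.0, 0.0)))
        with pytest.raises(ValueError, match="occupied"):
            g.add(Ommatidium((0, 0), (5.0, 5.0)))


class TestManualCorrection:
    @pytest.fixture()
    def segmented(self, flat_patch):
        _, gt, maps = flat_patch
        g = auto_seed(maps)
        expand_grid(g, maps)
        return g

    def test_remove_then_readd_recovers_hex(self, segmented):
        g = segmented
        interior = next(o for o in g if len(g.neighbors(o.hex)) == 6)
        hex0, pos0 = interior.hex, interior.pos.copy()
        remove(g, hex0)
        assert hex0 not in g
        add_manual(g, pos0)
        assert hex0 in g
        assert np.allclose(g[hex0].pos, pos0)
        assert g[hex0].origin == "manual"

    def test_duplicate_position_rejected(self, segmented):
        g = segmented
        existing = next(iter(g))
        with pytest.raises(ValueError, match="duplicates"):
            add_manual(g, existing.pos)

    def test_perimeter_addition_follows_mirror_rule(self):
        g = seed_grid((0.0, 0.0), (10.0, 0.0), (5.0, 8.66))
        pos4 = np.array([15.0, 8.66])  # mirror of (0,0) through the others
        add_manual(g, pos4)
        assert (1, 1) in g

    def test_remove_unknown_hex_errors(self, segmented):
        with pytest.raises(ValueError, match="no ommatidium"):
            remove(segmented, (99, 99))

    def test_remove_seed_leaves_two(self):
        g = seed_grid((0.0, 0.0), (10.0, 0.0), (5.0, 8.66))
        remove(g, (0, 0))
        assert len(g) == 2


class TestAutoSeed:
    def test_seeds_land_on_adjacent_true_centers(self, ideal_eye):
        _, gt, maps = ideal_eye
        g = auto_seed(maps)
        d, idx = cKDTree(gt.centers).query(g.positions())
        assert d.max() < 2.0
        hexes = gt.hex_coords[idx]
        for a, b in itertools.combinations(range(3), 2):
            diff = tuple(hexes[a] - hexes[b])
            assert diff in HEX_NEIGHBOR_OFFSETS
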