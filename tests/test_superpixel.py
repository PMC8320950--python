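"""Boruvka forest, region distances, merge hierarchy and extraction."""

import numpy as np
import pytest

from fdagseg import (
    NoiseModel,
    SegConfig,
    anisotropic_edge_strength,
    asa,
    boruvka_round,
    boundary_edge_strength,
    build_hierarchy,
    build_pixel_graph,
    chi_squared_distance,
    extract_superpixels,
    min_arc_distance,
    piecewise_constant_scene,
    preliminary_grouping,
    tree_distance,
    undersegmentation_error,
)


def forest_partition(forest):
    """Current partition as a set of frozensets of pixel indices."""
    roots = forest.roots()
    out = {}
    for pix, r in enumerate(roots):
        out.setdefault(int(r), set()).add(pix)
    return {frozenset(v) for v in out.values()}


def bruteforce_boruvka_round(partition, arcs, weights):
    """All-pairs reference for one Boruvka round with min-arc distance.

    partition: list of sets of pixel ids.  Every tree (id = min pixel)
    selects its nearest neighboring tree (ties toward the lower partner
    id); unique selected pairs merge in ascending (distance, lower id,
    higher id) order.
    """
    trees = {min(s): set(s) for s in partition}
    owner = {p: t for t, s in trees.items() for p in s}
    dist: dict[tuple[int, int], float] = {}
    for (u, v), w in zip(arcs, weights):
        a, b = owner[u], owner[v]
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        dist[key] = min(dist.get(key, np.inf), w)
    selected = {}
    for t in trees:
        cands = [(d, (b if a == t else a)) for (a, b), d in dist.items()
                 if t in (a, b)]
        if not cands:
            raise ValueError("disconnected")
        selected[t] = min(cands)
    pairs = {}
    for t, (d, partner) in selected.items():
        key = (min(t, partner), max(t, partner))
        pairs.setdefault(key, d)
    for (a, b), d in sorted(pairs.items(), key=lambda kv: (kv[1], kv[0])):
        ra = min(t for t, s in trees.items() if a in s)
        rb = min(t for t, s in trees.items() if b in s)
        if ra == rb:
            continue
        keep, drop = min(ra, rb), max(ra, rb)
        trees[keep] |= trees.pop(drop)
    return [s for s in trees.values()]


class TestPixelGraph:
    def test_grid_combinatorics(self):
        f = build_pixel_graph(np.zeros((3, 3)))
        assert f.n_trees == 9
        assert len(f.arc_u) == 12

    def test_constant_image_zero_weights(self):
        f = build_pixel_graph(np.full((4, 4, 3), 0.3))
        assert np.all(f.arc_weight == 0.0)

    def test_hand_computed_weights_2x2(self):
        img = np.array(
            [[[0.0, 0.0, 0.0], [0.3, 0.4, 0.0]],
             [[0.0, 0.0, 0.5], [1.0, 0.0, 0.0]]]
        )
        f = build_pixel_graph(img)
        # arcs: horizontal (0,1), (2,3); vertical (0,2), (1,3)
        expected = {
            (0, 1): 0.5,
            (2, 3): np.sqrt(1.0 + 0.25),
            (0, 2): 0.5,
            (1, 3): np.sqrt(0.49 + 0.16 + 0.0),
        }
        for u, v, w in zip(f.arc_u, f.arc_v, f.arc_weight):
            assert w == pytest.approx(expected[(int(u), int(v))])


class TestBoruvkaRound:
    def test_two_trees_merge_to_one(self):
        f = build_pixel_graph(np.array([[0.0, 1.0]]))
        boruvka_round(f, min_arc_distance)
        assert f.n_trees == 1

    def test_path_graph_hand_trace(self):
        # path with weights 0.1, 0.2, 0.3: every vertex joins its
        # cheapest arc; the selected arcs chain the whole path into one
        # tree, as the all-pairs trace confirms
        img = np.array([[0.0, 0.1, 0.3, 0.6]])
        f = build_pixel_graph(img)
        boruvka_round(f, min_arc_distance)
        arcs = list(zip(f.arc_u.tolist(), f.arc_v.tolist()))
        oracle = bruteforce_boruvka_round(
            [{0}, {1}, {2}, {3}], arcs, f.arc_weight.tolist()
        )
        assert forest_partition(f) == {frozenset(s) for s in oracle}
        assert f.n_trees == 1

    def test_tie_resolved_toward_lower_id(self):
        f = build_pixel_graph(np.array([[0.0, 0.5, 1.0]]))
        boruvka_round(f, min_arc_distance)
        first = f.records[0]
        assert (first.id_a, first.id_b) == (0, 1)

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(10):
            h, w = rng.integers(2, 6, size=2)
            img = rng.random((h, w, 3)).round(2)
            f = build_pixel_graph(img)
            partition = [{i} for i in range(h * w)]
            arcs = list(zip(f.arc_u.tolist(), f.arc_v.tolist()))
            weights = f.arc_weight.tolist()
            while f.n_trees > 1:
                boruvka_round(f, min_arc_distance)
                partition = bruteforce_boruvka_round(partition, arcs, weights)
                assert forest_partition(f) == {frozenset(s) for s in partition}

    def test_single_tree_rejected(self):
        f = build_pixel_graph(np.array([[0.0]]))
        with pytest.raises(ValueError):
            boruvka_round(f, min_arc_distance)


class TestPreliminaryGrouping:
    def test_tau_zero_is_identity(self):
        f = build_pixel_graph(np.zeros((4, 4)))
        preliminary_grouping(f, 0)
        assert f.n_trees == 16 and not f.records

    def test_constant_image_collapses(self):
        f = build_pixel_graph(np.full((4, 8), 0.5))
        preliminary_grouping(f, 4)
        assert f.n_trees == 1

    def test_min_trees_floor(self):
        f = build_pixel_graph(np.full((4, 8), 0.5))
        preliminary_grouping(f, 4, min_trees=2)
        assert f.n_trees == 2


class TestChiSquaredDistance:
    def test_identical_histograms(self):
        h = np.array([0.2, 0.3, 0.5])
        assert chi_squared_distance(h, h) == 0.0

    def test_disjoint_support(self):
        assert chi_squared_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        h1 = np.array([0.5, 0.5, 0.0])
        h2 = np.array([0.25, 0.25, 0.5])
        assert chi_squared_distance(h1, h2) == pytest.approx(1.0 / 3.0)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a = rng.random(10)
            b = rng.random(10)
            a, b = a / a.sum(), b / b.sum()
            d = chi_squared_distance(a, b)
            assert d == pytest.approx(chi_squared_distance(b, a))
            assert 0.0 <= d <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chi_squared_distance(np.ones(3) / 3, np.ones(4) / 4)


class TestBoundaryEdgeStrength:
    def _split_1x4(self):
        f = build_pixel_graph(np.array([[0.0, 0.0, 1.0, 1.0]]))
        f._merge(0, 1, 0.0)
        f._merge(2, 3, 0.0)
        return f

    def test_border_set_enumeration(self):
        f = self._split_1x4()
        ie = np.array([[0.0, 0.4, 0.8, 0.0]])
        assert boundary_edge_strength(f, 0, 2, ie) == pytest.approx(0.6)

    def test_constant_edge_strength(self):
        f = self._split_1x4()
        ie = np.full((1, 4), 0.7)
        assert boundary_edge_strength(f, 0, 2, ie) == pytest.approx(0.7)

    def test_symmetric_in_arguments(self):
        f = self._split_1x4()
        ie = np.array([[0.1, 0.2, 0.9, 0.3]])
        assert boundary_edge_strength(f, 0, 2, ie) == boundary_edge_strength(
            f, 2, 0, ie
        )

    def test_no_shared_border_raises(self):
        f = build_pixel_graph(np.array([[0.0, 0.5, 1.0]]))
        with pytest.raises(ValueError):
            boundary_edge_strength(f, 0, 2, np.zeros((1, 3)))


class TestTreeDistance:
    def test_zero_edge_strength_forces_zero_distance(self):
        f = TestBoundaryEdgeStrength()._split_1x4()
        ie = np.zeros((1, 4))
        cfg = SegConfig(compactness=0.0)
        assert tree_distance(f, 0, 2, ie, cfg) == 0.0

    def test_product_form_at_lambda_zero(self):
        f = TestBoundaryEdgeStrength()._split_1x4()
        ie = np.full((1, 4), 0.5)
        cfg = SegConfig(compactness=0.0)
        de = boundary_edge_strength(f, 0, 2, ie)
        dc = chi_squared_distance(
            f.normalized_histogram(0), f.normalized_histogram(2)
        )
        assert tree_distance(f, 0, 2, ie, cfg) == pytest.approx(de * dc)

    def test_compactness_adds_size_term(self):
        f = TestBoundaryEdgeStrength()._split_1x4()
        ie = np.full((1, 4), 0.5)
        d0 = tree_distance(f, 0, 2, ie, SegConfig(compactness=0.0))
        lam = 0.53
        d1 = tree_distance(f, 0, 2, ie, SegConfig(compactness=lam))
        assert d1 == pytest.approx((1 - lam) * d0 + lam * 1.0)


@pytest.fixture(scope="module")
def scene():
    return piecewise_constant_scene(
        (24, 24), 3, blur_scale=0.8, noise=NoiseModel(0.02, seed=11), seed=11
    )


@pytest.fixture(scope="module")
def hierarchy(scene):
    img = np.clip(scene.image, 0, 1)
    ie = anisotropic_edge_strength(img).Ie
    return build_hierarchy(img, ie)


class TestHierarchy:
    def test_record_count_is_n_minus_two(self, hierarchy):
        assert len(hierarchy.records) == hierarchy.n_leaves - 2
        assert hierarchy.final_count == 2

    def test_every_count_in_range_extractable(self, hierarchy):
        for n in range(2, hierarchy.leaves_after_preliminary + 1):
            labels = extract_superpixels(hierarchy, n)
            assert np.unique(labels).size == n

    def test_out_of_range_rejected(self, hierarchy):
        with pytest.raises(ValueError):
            extract_superpixels(hierarchy, hierarchy.leaves_after_preliminary + 1)
        with pytest.raises(ValueError):
            extract_superpixels(hierarchy, 1)

    def test_nesting(self, hierarchy):
        n2 = hierarchy.leaves_after_preliminary
        n1 = max(2, n2 // 3)
        fine = extract_superpixels(hierarchy, n2)
        coarse = extract_superpixels(hierarchy, n1)
        for v in np.unique(fine):
            assert np.unique(coarse[fine == v]).size == 1

    def test_deterministic(self, scene):
        img = np.clip(scene.image, 0, 1)
        ie = anisotropic_edge_strength(img).Ie
        h1 = build_hierarchy(img, ie)
        h2 = build_hierarchy(img, ie)
        assert [(r.id_a, r.id_b, r.distance) for r in h1.records] == [
            (r.id_a, r.id_b, r.distance) for r in h2.records
        ]

    def test_histogram_conservation_through_rounds(self, scene):
        img = np.clip(scene.image, 0, 1)
        ie = anisotropic_edge_strength(img).Ie
        from fdagseg.superpixel import make_region_distance

        f = build_pixel_graph(img)
        q = f.n_channels
        preliminary_grouping(f, 4, min_trees=2)
        dfn = make_region_distance(ie, SegConfig())
        while f.n_trees > 2:
            boruvka_round(f, dfn, min_trees=2)
            roots = np.unique(f.roots())
            for r in roots:
                assert f.hist[r].sum() == f.size[r] * q
            assert f.size[roots].sum() == f.n_pixels

    def test_two_region_scene_recovered_at_n_two(self):
        sc = piecewise_constant_scene((16, 32), 2, seed=3)
        img = np.clip(sc.image, 0, 1)
        h = build_hierarchy(img, anisotropic_edge_strength(img).Ie)
        labels = extract_superpixels(h, 2)
        assert asa(labels, sc.gt) == 1.0
        assert undersegmentation_error(labels, sc.gt) == 0.0

    def test_misregistered_edge_map_rejected(self):
        with pytest.raises(ValueError):
            build_hierarchy(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_merge_table_roundtrip(self, hierarchy):
        df = hierarchy.to_frame()
        assert list(df.columns) == ["step", "idA", "idB", "idNew", "distance"]
        assert len(df) == len(hierarchy.records)
        assert (df["idNew"] == np.minimum(df["idA"], df["idB"])).all()
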