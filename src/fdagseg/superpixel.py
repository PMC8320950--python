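"""Edge-aware superpixel hierarchies via Boruvka region merging.

The image is a 4-connected pixel graph: one singleton tree per pixel,
arcs between 4-adjacent pixels weighted by the Euclidean color distance.
Each Boruvka round lets every tree select its nearest neighboring tree
and merges all selections at once, so the tree count roughly halves per
round.  The first ``tau`` rounds (preliminary grouping) use the
pixel-level minimum arc weight between trees,

    D(T1, T2) = min over cross arcs (vi in T1, vj in T2) of d(vi, vj),

which is reliable while trees are small.  Later rounds switch to a
region-level distance combining the mean anisotropic edge strength on
the shared border (De) with the chi-squared distance between the trees'
color histograms (Dc):

    D(T1, T2) = De(T1, T2) * Dc(T1, T2),

optionally blended with a size regularizer controlled by a compactness
weight (see :func:`tree_distance`).  Every merge is recorded, so the
resulting hierarchy can be replayed to a partition with any number of
superpixels between 2 and the preliminary tree count.

All tie-breaks are deterministic (lower tree id wins); there is no
randomness anywhere in the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SegConfig",
    "Forest",
    "AdjacencyPairs",
    "MergeRecord",
    "MergeHierarchy",
    "build_pixel_graph",
    "min_arc_distance",
    "make_region_distance",
    "boruvka_round",
    "preliminary_grouping",
    "chi_squared_distance",
    "boundary_edge_strength",
    "tree_distance",
    "build_hierarchy",
    "extract_superpixels",
]


@dataclass(frozen=True)
class SegConfig:
    """Segmentation parameters.

    tau         : number of preliminary pixel-grouping rounds (default 4)
    n_bins      : histogram bins per color channel (default 20)
    compactness : weight of the size regularizer in the region distance,
                  in [0, 1] (default 0.53; 0 recovers the pure
                  edge-times-histogram distance)
    """

    tau: int = 4
    n_bins: int = 20
    compactness: float = 0.53

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not (0.0 <= self.compactness <= 1.0):
            raise ValueError("compactness must lie in [0, 1]")


@dataclass(frozen=True)
class MergeRecord:
    """One merge: trees ``id_a`` and ``id_b`` became ``id_new``."""

    step: int
    id_a: int
    id_b: int
    id_new: int
    distance: float


@dataclass
class AdjacencyPairs:
    """Current tree adjacency, with the cross arcs backing each pair.

    lo/hi are the canonical (lower, higher) root ids of each neighboring
    tree pair; ``arc_pair`` maps every cross-boundary pixel arc to its
    pair index, with pixel endpoints ``arc_u``/``arc_v`` and color-space
    weights ``arc_weight``.
    """

    lo: np.ndarray
    hi: np.ndarray
    arc_pair: np.ndarray
    arc_u: np.ndarray
    arc_v: np.ndarray
    arc_weight: np.ndarray


class Forest:
    """Disjoint-set forest over the pixels of an image.

    Each tree carries its size, per-channel color histogram (counts over
    ``n_bins`` equal-width bins on [0, 1], concatenated across channels)
    and color sum; merges accumulate them.  Tree ids are pixel indices
    (row-major); the surviving id of a merge is the smaller root.
    """

    def __init__(self, image: np.ndarray, n_bins: int = 20):
        image = np.asarray(image, dtype=float)
        if image.ndim == 2:
            image = image[..., None]
        if image.ndim != 3:
            raise ValueError("expected an H x W or H x W x Q image")
        h, w, q = image.shape
        n = h * w
        self.shape = (h, w)
        self.n_channels = q
        self.n_bins = n_bins
        self.n_pixels = n
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)
        self.n_trees = n
        self.records: list[MergeRecord] = []

        colors = image.reshape(n, q)
        bins = np.minimum((np.clip(colors, 0.0, 1.0) * n_bins).astype(np.int64),
                          n_bins - 1)
        self.hist = np.zeros((n, q * n_bins), dtype=np.float64)
        rows = np.repeat(np.arange(n), q)
        cols = (bins + n_bins * np.arange(q)).ravel()
        self.hist[rows, cols] = 1.0
        self.color_sum = colors.copy()

        # 4-adjacency arcs, horizontal then vertical, row-major pixel ids
        idx = np.arange(n).reshape(h, w)
        hu, hv = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        vu, vv = idx[:-1, :].ravel(), idx[1:, :].ravel()
        self.arc_u = np.concatenate([hu, vu])
        self.arc_v = np.concatenate([hv, vv])
        diff = colors[self.arc_u] - colors[self.arc_v]
        self.arc_weight = np.sqrt((diff**2).sum(axis=1))

    # -- disjoint-set -----------------------------------------------------
    def roots(self) -> np.ndarray:
        """Root id of every pixel (path-compressing pointer jumping)."""
        p = self.parent
        while True:
            pp = p[p]
            if np.array_equal(pp, p):
                break
            p = pp
        self.parent = p
        return p

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            i = p[i]
        return int(i)

    def mean_color(self, root: int) -> np.ndarray:
        return self.color_sum[root] / self.size[root]

    def normalized_histogram(self, root: int) -> np.ndarray:
        h = self.hist[root]
        return h / h.sum()

    def label_map(self) -> np.ndarray:
        """Current partition as contiguous labels 1..n_trees (row-major
        order of first appearance)."""
        r = self.roots()
        _, labels = np.unique(r, return_inverse=True)
        # np.unique sorts by root id == first pixel index, which is also
        # row-major first-appearance order
        return (labels + 1).reshape(self.shape).astype(np.int32)

    # -- adjacency --------------------------------------------------------
    def adjacency(self) -> AdjacencyPairs:
        """Unique neighboring tree pairs and their cross arcs."""
        r = self.roots()
        ru, rv = r[self.arc_u], r[self.arc_v]
        cross = ru != rv
        ru, rv = ru[cross], rv[cross]
        lo, hi = np.minimum(ru, rv), np.maximum(ru, rv)
        key = lo * self.n_pixels + hi
        uniq, arc_pair = np.unique(key, return_inverse=True)
        return AdjacencyPairs(
            lo=(uniq // self.n_pixels),
            hi=(uniq % self.n_pixels),
            arc_pair=arc_pair,
            arc_u=self.arc_u[cross],
            arc_v=self.arc_v[cross],
            arc_weight=self.arc_weight[cross],
        )

    def _merge(self, root_a: int, root_b: int, distance: float) -> int:
        new = min(root_a, root_b)
        old = max(root_a, root_b)
        self.parent[old] = new
        self.size[new] += self.size[old]
        self.hist[new] += self.hist[old]
        self.color_sum[new] += self.color_sum[old]
        self.n_trees -= 1
        self.records.append(
            MergeRecord(len(self.records), int(root_a), int(root_b), new, float(distance))
        )
        return new


def build_pixel_graph(image: np.ndarray, n_bins: int = 20) -> Forest:
    """One singleton tree per pixel; arcs join 4-adjacent pixels with
    Euclidean color-space weights."""
    return Forest(image, n_bins=n_bins)


# -- distance measures ----------------------------------------------------

def min_arc_distance(forest: Forest, pairs: AdjacencyPairs) -> np.ndarray:
    """Pixel-level distance: minimum color-arc weight between the trees."""
    d = np.full(len(pairs.lo), np.inf)
    np.minimum.at(d, pairs.arc_pair, pairs.arc_weight)
    return d


def chi_squared_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Chi-squared distance between two normalized histograms.

    0.5 * sum (h1 - h2)^2 / (h1 + h2), with 0/0 terms defined as 0.
    Symmetric, and in [0, 1] for histograms that each sum to 1.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("histograms must have equal length")
    num = (h1 - h2) ** 2
    den = h1 + h2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return float(0.5 * terms.sum())


def _pair_border_means(
    forest: Forest, pairs: AdjacencyPairs, ie_flat: np.ndarray
) -> np.ndarray:
    """Mean edge strength over the distinct border pixels of each pair."""
    n = forest.n_pixels
    keys = np.concatenate(
        [pairs.arc_pair * n + pairs.arc_u, pairs.arc_pair * n + pairs.arc_v]
    )
    uniq = np.unique(keys)
    pix = uniq % n
    pair_of = uniq // n
    sums = np.bincount(pair_of, weights=ie_flat[pix], minlength=len(pairs.lo))
    counts = np.bincount(pair_of, minlength=len(pairs.lo))
    return sums / counts


def _pair_chi_squared(forest: Forest, pairs: AdjacencyPairs) -> np.ndarray:
    h1 = forest.hist[pairs.lo]
    h2 = forest.hist[pairs.hi]
    h1 = h1 / h1.sum(axis=1, keepdims=True)
    h2 = h2 / h2.sum(axis=1, keepdims=True)
    num = (h1 - h2) ** 2
    den = h1 + h2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return 0.5 * terms.sum(axis=1)


def make_region_distance(
    ie: np.ndarray, config: SegConfig
) -> Callable[[Forest, AdjacencyPairs], np.ndarray]:
    """Region-level distance De * Dc, optionally blended with a size term.

    With compactness weight lam the distance is
    ``(1 - lam) * De * Dc + lam * (|T1| + |T2|) / N``, which discourages
    very large trees from swallowing small ones; lam = 0 gives the pure
    product.
    """
    ie_flat = np.asarray(ie, dtype=float).ravel()
    lam = config.compactness

    def distance(forest: Forest, pairs: AdjacencyPairs) -> np.ndarray:
        de = _pair_border_means(forest, pairs, ie_flat)
        dc = _pair_chi_squared(forest, pairs)
        d = de * dc
        if lam > 0:
            sizes = (forest.size[pairs.lo] + forest.size[pairs.hi]) / forest.n_pixels
            d = (1.0 - lam) * d + lam * sizes
        return d

    return distance


# -- scalar spec surface ---------------------------------------------------

def boundary_edge_strength(
    forest: Forest, tree_a: int, tree_b: int, ie: np.ndarray
) -> float:
    """Mean edge strength over the distinct pixels on the shared border.

    Border pixels are the endpoints (from both sides, each counted once)
    of 4-adjacent pixel arcs crossing between the two trees.
    """
    r = forest.roots()
    ra, rb = forest.find(tree_a), forest.find(tree_b)
    ru, rv = r[forest.arc_u], r[forest.arc_v]
    on = ((ru == ra) & (rv == rb)) | ((ru == rb) & (rv == ra))
    if not on.any():
        raise ValueError("trees share no border")
    pixels = np.unique(np.concatenate([forest.arc_u[on], forest.arc_v[on]]))
    return float(np.asarray(ie, dtype=float).ravel()[pixels].mean())


def tree_distance(
    forest: Forest,
    tree_a: int,
    tree_b: int,
    ie: np.ndarray,
    config: SegConfig | None = None,
) -> float:
    """Region-level distance between two adjacent trees (scalar form)."""
    if config is None:
        config = SegConfig()
    ra, rb = forest.find(tree_a), forest.find(tree_b)
    de = boundary_edge_strength(forest, ra, rb, ie)
    dc = chi_squared_distance(
        forest.normalized_histogram(ra), forest.normalized_histogram(rb)
    )
    d = de * dc
    if config.compactness > 0:
        sizes = (forest.size[ra] + forest.size[rb]) / forest.n_pixels
        d = (1.0 - config.compactness) * d + config.compactness * sizes
    return float(d)


# -- Boruvka rounds --------------------------------------------------------

def boruvka_round(
    forest: Forest,
    distance_fn: Callable[[Forest, AdjacencyPairs], np.ndarray],
    min_trees: int = 1,
) -> Forest:
    """One Boruvka pass: every tree merges with its nearest neighbor.

    Each tree selects the neighboring tree at minimum distance (ties
    resolved toward the lower partner id); the union-find merges along
    all selected pairs, mutual selections merging once.  Merges are
    applied and recorded in ascending (distance, lower id, higher id)
    order, so each record references roots valid at its merge time and
    any prefix of the record list is a valid partition.  Merging stops
    early when the tree count reaches ``min_trees``.
    """
    if forest.n_trees < 2:
        raise ValueError("need at least 2 trees")
    pairs = forest.adjacency()
    present = np.unique(np.concatenate([pairs.lo, pairs.hi]))
    if len(present) < forest.n_trees:
        raise ValueError("forest is disconnected: some tree has no neighbor")
    dist = distance_fn(forest, pairs)

    trees = np.concatenate([pairs.lo, pairs.hi])
    partners = np.concatenate([pairs.hi, pairs.lo])
    dists = np.concatenate([dist, dist])
    order = np.lexsort((partners, dists, trees))
    trees_s = trees[order]
    first = np.ones(len(trees_s), dtype=bool)
    first[1:] = trees_s[1:] != trees_s[:-1]
    sel_tree = trees_s[first]
    sel_partner = partners[order][first]
    sel_dist = dists[order][first]

    lo = np.minimum(sel_tree, sel_partner)
    hi = np.maximum(sel_tree, sel_partner)
    key = lo * forest.n_pixels + hi
    _, uidx = np.unique(key, return_index=True)
    lo, hi, d = lo[uidx], hi[uidx], sel_dist[uidx]
    merge_order = np.lexsort((hi, lo, d))
    for k in merge_order:
        if forest.n_trees <= min_trees:
            break
        ra, rb = forest.find(int(lo[k])), forest.find(int(hi[k]))
        if ra != rb:
            forest._merge(ra, rb, float(d[k]))
    return forest


def preliminary_grouping(forest: Forest, tau: int, min_trees: int = 1) -> Forest:
    """Run ``tau`` Boruvka rounds with the pixel-level minimum arc
    distance (stops early once ``min_trees`` trees remain)."""
    for _ in range(tau):
        if forest.n_trees <= max(min_trees, 1):
            break
        boruvka_round(forest, min_arc_distance, min_trees=min_trees)
    return forest


# -- hierarchy --------------------------------------------------------------

@dataclass
class MergeHierarchy:
    """Ordered merge records of a full segmentation run.

    Replaying the first k records of ``records`` yields the partition
    with ``n_leaves - k`` trees; the preliminary (pixel-grouping) stage
    occupies the first ``n_preliminary_records`` records and is always
    replayed in full when extracting superpixels.
    """

    n_leaves: int
    shape: tuple[int, int]
    records: list[MergeRecord]
    n_preliminary_records: int
    config: SegConfig = field(default_factory=SegConfig)

    @property
    def leaves_after_preliminary(self) -> int:
        return self.n_leaves - self.n_preliminary_records

    @property
    def final_count(self) -> int:
        return self.n_leaves - len(self.records)

    def to_frame(self):
        """Merge records as a pandas DataFrame (step, idA, idB, idNew,
        distance)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [r.step for r in self.records],
                "idA": [r.id_a for r in self.records],
                "idB": [r.id_b for r in self.records],
                "idNew": [r.id_new for r in self.records],
                "distance": [r.distance for r in self.records],
            }
        )


def build_hierarchy(
    image: np.ndarray, ie: np.ndarray, config: SegConfig | None = None
) -> MergeHierarchy:
    """Full merge hierarchy of an image driven by its edge-strength map.

    Runs the preliminary pixel grouping for ``config.tau`` rounds, then
    Boruvka rounds with the region-level distance until 2 trees remain.
    Records are strictly ordered, so every intermediate superpixel count
    down to 2 is recoverable by replaying a prefix.
    """
    if config is None:
        config = SegConfig()
    ie = np.asarray(ie, dtype=float)
    if ie.shape != np.asarray(image).shape[:2]:
        raise ValueError("edge-strength map must be co-registered with the image")
    forest = build_pixel_graph(image, n_bins=config.n_bins)
    # keep at least 2 trees so a 2-superpixel partition is always extractable
    preliminary_grouping(forest, config.tau, min_trees=2)
    n_prelim = len(forest.records)
    region_distance = make_region_distance(ie, config)
    while forest.n_trees > 2:
        boruvka_round(forest, region_distance, min_trees=2)
    return MergeHierarchy(
        n_leaves=forest.n_pixels,
        shape=forest.shape,
        records=forest.records,
        n_preliminary_records=n_prelim,
        config=config,
    )


def extract_superpixels(hierarchy: MergeHierarchy, n: int) -> np.ndarray:
    """Label map with exactly ``n`` superpixels, replayed from the records.

    ``n`` must lie between 2 and the tree count after preliminary
    grouping.  Labels are contiguous 1..n in row-major order of first
    appearance; every superpixel is 4-connected because merges only ever
    join adjacent trees.
    """
    if not (hierarchy.final_count <= n <= hierarchy.leaves_after_preliminary):
        raise ValueError(
            f"n must lie in [{hierarchy.final_count}, "
            f"{hierarchy.leaves_after_preliminary}], got {n}"
        )
    k = hierarchy.n_leaves - n
    parent = np.arange(hierarchy.n_leaves, dtype=np.int64)
    for rec in hierarchy.records[:k]:
        parent[rec.id_a] = rec.id_new
        parent[rec.id_b] = rec.id_new
    while True:
        pp = parent[parent]
        if np.array_equal(pp, parent):
            break
        parent = pp
    _, labels = np.unique(parent, return_inverse=True)
    return (labels + 1).reshape(hierarchy.shape).astype(np.int32)
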