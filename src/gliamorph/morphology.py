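"""Microglial morphometry: region properties, skeleton analysis, Sholl
analysis, fractal dimension and lacunarity, a 512-dimensional morphology
embedding, and elbow-selected clustering into ordered ramification classes.

All measurements operate on the maximum projection of a cell's binary
compartment masks, matching how ramification is quantified from thin
z-stacks; :func:`projection_consistency` quantifies how well
section-limited projections reproduce full-depth measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure, morphology as skmorph, transform

from gliamorph.config import stage_rng
from gliamorph.containers import CellCompartments, MorphologyFeatures

# ---------------------------------------------------------------------------
# perimeter estimation
# ---------------------------------------------------------------------------

def perimeter(mask: np.ndarray) -> float:
    """Digital perimeter: mean of the weighted pixel-boundary estimator and
    the Crofton estimator.

    The two classical estimators are biased in opposite directions on
    smooth shapes (pixel-boundary over-, Crofton under-estimates for
    disks); their mean keeps the circularity of rasterized disks inside
    (0.95, 1.0] across radii 10-80 px.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return 0.5 * (
        measure.perimeter(mask) + measure.perimeter_crofton(mask, directions=4)
    )


# ---------------------------------------------------------------------------
# skeleton analysis
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_STEPS = [
    (dr, dc)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dr, dc) != (0, 0)
]


@dataclass
class SkeletonMeasures:
    """Topological summary of a cell skeleton."""

    skeleton: np.ndarray
    n_branches: int
    n_branching_points: int
    n_terminal_points: int
    skeleton_length: float
    mean_branch_length: float
    tortuosity: float
    euclidean_distance: float
    path_distance: float


def skeletonize_and_measure(mask: np.ndarray) -> SkeletonMeasures:
    """Skeletonize a 2D mask and measure its branch topology.

    Terminal points are skeleton pixels with exactly one neighbor;
    branching points have three or more.  Branches are maximal skeleton
    paths between node pixels (adjacent node pixels are merged into one
    junction), with path length accumulated in 1/sqrt(2) pixel steps.
    Tortuosity is the mean over branches of path length divided by the
    straight-line distance between the branch endpoints.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        empty = np.zeros_like(mask)
        return SkeletonMeasures(empty, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
    skel = skmorph.skeletonize(mask)
    return measure_skeleton(skel)


def measure_skeleton(skel: np.ndarray) -> SkeletonMeasures:
    skel = np.asarray(skel, dtype=bool)
    if skel.sum() < 2:
        return SkeletonMeasures(skel, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
    nbrs = ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")
    terminals = skel & (nbrs == 1)
    branchpts = skel & (nbrs >= 3)
    node_mask = terminals | branchpts
    node_labels, _ = ndimage.label(node_mask, structure=np.ones((3, 3), int))
    n_branch_clusters = len(np.unique(node_labels[branchpts])) if branchpts.any() else 0

    branches = _trace_branches(skel, node_labels)
    lengths = np.array([b[0] for b in branches]) if branches else np.array([])
    chords = np.array([b[1] for b in branches]) if branches else np.array([])
    skeleton_length = float(lengths.sum())
    mean_branch = float(lengths.mean()) if len(lengths) else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        torts = lengths[chords > 0] / chords[chords > 0]
    tortuosity = float(torts.mean()) if len(torts) else 0.0
    return SkeletonMeasures(
        skeleton=skel,
        n_branches=len(branches),
        n_branching_points=n_branch_clusters,
        n_terminal_points=int(terminals.sum()),
        skeleton_length=skeleton_length,
        mean_branch_length=mean_branch,
        tortuosity=tortuosity,
        euclidean_distance=float(chords.mean()) if len(chords) else 0.0,
        path_distance=float(lengths.mean()) if len(lengths) else 0.0,
    )


def _trace_branches(skel: np.ndarray, node_labels: np.ndarray):
    """Maximal paths between junction/terminal clusters.

    Returns a list of (path_length, chord_length) per branch.  A skeleton
    without any nodes (a closed loop) counts as one branch with undefined
    chord.
    """
    h, w = skel.shape
    visited = np.zeros_like(skel, dtype=bool)
    branches: list[tuple[float, float]] = []
    node_coords = np.argwhere(node_labels > 0)
    adjacent_pairs: set[tuple[int, int]] = set()

    def neighbors(r, c):
        for dr, dc in _STEPS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                yield rr, cc

    for r0, c0 in node_coords:
        start_cluster = node_labels[r0, c0]
        for r1, c1 in neighbors(r0, c0):
            lbl = node_labels[r1, c1]
            if lbl:
                if lbl != start_cluster:
                    key = (min(start_cluster, lbl), max(start_cluster, lbl))
                    if key not in adjacent_pairs:
                        adjacent_pairs.add(key)
                        step = float(np.hypot(r1 - r0, c1 - c0))
                        branches.append((step, step))
                continue
            if visited[r1, c1]:
                continue
            # walk a non-node corridor until we reach another node pixel
            length = float(np.hypot(r1 - r0, c1 - c0))
            prev, cur = (r0, c0), (r1, c1)
            visited[r1, c1] = True
            steps = 1
            end = cur
            while True:
                node_next = [
                    p
                    for p in neighbors(*cur)
                    if p != prev
                    and node_labels[p]
                    and not (steps == 1 and node_labels[p] == start_cluster)
                ]
                if node_next:
                    end = node_next[0]
                    length += float(
                        np.hypot(end[0] - cur[0], end[1] - cur[1])
                    )
                    break
                corridor = [
                    p
                    for p in neighbors(*cur)
                    if p != prev and not node_labels[p] and not visited[p]
                ]
                if not corridor:
                    end = cur
                    break
                prev, cur = cur, corridor[0]
                visited[cur] = True
                length += float(np.hypot(cur[0] - prev[0], cur[1] - prev[1]))
                steps += 1
            chord = float(np.hypot(end[0] - r0, end[1] - c0))
            branches.append((length, chord))

    # closed loops with no nodes at all
    if not len(node_coords):
        n_steps = _loop_length(skel)
        branches.append((n_steps, 0.0))
    return branches


def _loop_length(skel: np.ndarray) -> float:
    coords = np.argwhere(skel)
    total = 0.0
    visited = set()
    cur = tuple(coords[0])
    prev = None
    while True:
        visited.add(cur)
        nxt = None
        for dr, dc in _STEPS:
            cand = (cur[0] + dr, cur[1] + dc)
            if (
                0 <= cand[0] < skel.shape[0]
                and 0 <= cand[1] < skel.shape[1]
                and skel[cand]
                and cand != prev
                and cand not in visited
            ):
                nxt = cand
                break
        if nxt is None:
            break
        total += float(np.hypot(nxt[0] - cur[0], nxt[1] - cur[1]))
        prev, cur = cur, nxt
    return total


# ---------------------------------------------------------------------------
# fractal dimension / lacunarity
# ---------------------------------------------------------------------------

def fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary mask.

    The mask is cropped to its bounding box and occupied boxes are counted
    at dyadic sizes s = 2, 4, ..., side/4 on corner-anchored grids; N(s)
    averages the four corner anchorings, which makes the estimate exactly
    invariant to translation, 90-degree rotation and flips.  The dimension
    is the least-squares slope of log N(s) against log(1/s), clamped to
    the valid planar range [0, 2].
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() <= 1:
        return 0.0
    mask = _crop_to_bbox(mask)
    side = max(mask.shape)
    sizes = [s for s in (2 ** k for k in range(1, 30)) if s <= side // 4]
    if len(sizes) < 2:
        return 0.0
    counts = [
        np.mean(
            [
                _box_count(m, s)
                for m in (
                    mask,
                    mask[::-1],
                    mask[:, ::-1],
                    mask[::-1, ::-1],
                )
            ]
        )
        for s in sizes
    ]
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
    return float(np.clip(slope, 0.0, 2.0))


def _crop_to_bbox(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _box_count(mask: np.ndarray, s: int) -> int:
    h, w = mask.shape
    ph, pw = (-h) % s, (-w) % s
    padded = np.pad(mask, ((0, ph), (0, pw)))
    blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
    return int(blocks.any(axis=(1, 3)).sum())


def lacunarity(mask: np.ndarray) -> float:
    """Gliding-box lacunarity at box size ceil(bounding-box side / 8).

    Lambda = var(box mass) / mean(box mass)^2 + 1; equals exactly 1 for a
    homogeneously filled mask and grows with gappiness.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    mask = _crop_to_bbox(mask)
    b = int(np.ceil(max(mask.shape) / 8))
    b = max(1, min(b, min(mask.shape)))
    # gliding-box masses via a summed-area table (exact integer sums)
    csum = np.pad(mask.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    masses = (
        csum[b:, b:] - csum[:-b, b:] - csum[b:, :-b] + csum[:-b, :-b]
    ).ravel()
    mean = masses.mean()
    if mean == 0:
        return float("nan")
    return float(masses.var() / mean**2 + 1.0)


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

@dataclass
class ShollResult:
    """Sholl profile and its scalar summaries.

    ``ramification_index`` is the ratio of the radius with the greatest
    number of intersections to the first radius with a non-zero count
    (a radius-ratio definition); ``critical_radius`` is the radius with the
    greatest number of intersections and ``dendritic_maximum`` the largest
    radius that still intersects the skeleton.
    """

    radii: np.ndarray
    intersections: np.ndarray
    ramification_index: float
    critical_radius: float
    dendritic_maximum: float
    flagged: bool = False


def sholl(
    skeleton: np.ndarray,
    soma_centroid: tuple[float, float],
    radius_step: float = 2.0,
) -> ShollResult:
    """Count skeleton intersections with concentric circles.

    Intersections at radius r are connected components of the skeleton
    restricted to the annulus [r - step/2, r + step/2); consecutive
    annuli tile the plane, so 8-connected skeleton paths (diagonal pixel
    spacing sqrt(2)) cannot fall between rings.  Radii run from
    ``radius_step`` outward in steps of ``radius_step`` to the skeleton
    extent.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        raise ValueError("empty skeleton")
    cx, cy = soma_centroid
    yy, xx = np.nonzero(skel)
    dist = np.hypot(xx - cx, yy - cy)
    r_max = dist.max()
    radii = np.arange(radius_step, r_max + radius_step, radius_step)
    counts = np.zeros(len(radii), dtype=int)
    struct = np.ones((3, 3), int)
    half = radius_step / 2.0
    for i, r in enumerate(radii):
        ann = (dist >= r - half) & (dist < r + half)
        if not ann.any():
            continue
        band = np.zeros_like(skel)
        band[yy[ann], xx[ann]] = True
        _, n = ndimage.label(band, structure=struct)
        counts[i] = n
    nonzero = np.flatnonzero(counts)
    if not len(nonzero):
        return ShollResult(radii, counts, float("nan"), 0.0, 0.0, flagged=True)
    first_r = radii[nonzero[0]]
    critical_r = radii[np.argmax(counts)]
    dendritic_max = radii[nonzero[-1]]
    ri = float(critical_r / first_r)
    return ShollResult(radii, counts, ri, float(critical_r), float(dendritic_max))


# ---------------------------------------------------------------------------
# feature vector
# ---------------------------------------------------------------------------

def compute_features(
    cell: CellCompartments,
    intensity: Optional[np.ndarray] = None,
    return_supplementary: bool = False,
):
    """Compute the canonical 26-feature morphometric vector for a cell.

    Operates on the maximum projection of the cell's compartment masks.
    Returns a :class:`MorphologyFeatures`; with
    ``return_supplementary=True`` also returns a dict of non-canonical
    measurements (Sholl scalars, branch distances, intensity summaries,
    degenerate-input flags).
    """
    total = cell.max_projection("total")
    soma_mask = cell.max_projection("soma")
    if not total.any():
        raise ValueError(f"cell {cell.cell_id}: empty total mask")

    rp = measure.regionprops(total.astype(np.uint8))[0]
    area = float(total.sum())
    perim = perimeter(total)
    hull = _hull_image(total)
    convex_area = float(hull.sum())
    convex_perim = perimeter(hull)
    hull_rp = measure.regionprops(hull.astype(np.uint8))[0]
    minor = hull_rp.axis_minor_length
    span_ratio = float(hull_rp.axis_major_length / minor) if minor > 0 else 0.0

    supp: dict[str, float] = {}
    soma_flagged = not soma_mask.any()
    if soma_flagged:
        soma_area = soma_perim = soma_circ = 0.0
    else:
        soma_area = float(soma_mask.sum())
        soma_perim = perimeter(soma_mask)
        soma_circ = _circularity(soma_area, soma_perim)
    supp["soma_flagged"] = float(soma_flagged)

    sk = skeletonize_and_measure(total)
    fd = fractal_dimension(total)
    lac = lacunarity(total)

    feats = MorphologyFeatures(
        cell_area=area,
        cell_perimeter=perim,
        convex_area=convex_area,
        convex_perimeter=convex_perim,
        solidity=area / convex_area if convex_area else 0.0,
        convexity=convex_perim / perim if perim else 0.0,
        roughness=perim / convex_perim if convex_perim else 0.0,
        circularity=_circularity(area, perim),
        span_ratio=span_ratio,
        convex_circularity=_circularity(convex_area, convex_perim),
        eccentricity=float(rp.eccentricity),
        euler_number=float(rp.euler_number),
        extent=float(rp.extent),
        soma_area=soma_area,
        soma_perimeter=soma_perim,
        soma_circularity=soma_circ,
        soma_ratio=soma_area / area if area else 0.0,
        feret_diameter=float(rp.feret_diameter_max),
        skeleton_length=sk.skeleton_length,
        mean_branch_length=sk.mean_branch_length,
        n_branches=float(sk.n_branches),
        n_branching_points=float(sk.n_branching_points),
        n_terminal_points=float(sk.n_terminal_points),
        fractal_dimension=fd,
        lacunarity=lac,
        tortuosity=sk.tortuosity,
    )
    if not return_supplementary:
        return feats

    supp["euclidean_distance"] = sk.euclidean_distance
    supp["path_distance"] = sk.path_distance
    if sk.skeleton.any():
        try:
            sh = sholl(sk.skeleton, cell.soma_centroid)
            supp["ramification_index"] = sh.ramification_index
            supp["critical_radius"] = sh.critical_radius
            supp["dendritic_maximum"] = sh.dendritic_maximum
        except ValueError:
            pass
    if intensity is not None:
        vals = np.asarray(intensity, dtype=float)[total]
        denom = vals.max() if vals.size and vals.max() > 0 else 1.0
        supp["mean_intensity"] = float(vals.mean() / denom) if vals.size else 0.0
    return feats, supp


def _circularity(area: float, perim: float) -> float:
    return float(4 * np.pi * area / perim**2) if perim > 0 else 0.0


def _hull_image(mask: np.ndarray) -> np.ndarray:
    hull = np.zeros_like(mask, dtype=bool)
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    r0, c0, r1, c1 = rp.bbox
    hull[r0:r1, c0:c1] = rp.image_convex
    return hull


def features_table(cells: Sequence[CellCompartments]) -> pd.DataFrame:
    """Canonical feature vectors for many cells, indexed by cell id."""
    rows = {c.cell_id: compute_features(c).to_series() for c in cells}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# morphology embedding (deterministic multiscale backend)
# ---------------------------------------------------------------------------

EMBED_DIM = 512
_PAD_VALUE = 0.5  # middle gray
_N_LEVELS = 4
_GRID = 4
_N_ORI = 8


def prepare_crop(image: np.ndarray) -> np.ndarray:
    """Standardize a single-cell crop for embedding.

    The crop is rescaled so its longer side is 112 px (aspect preserved)
    and padded with middle gray to a 224 x 224 image, mirroring standard
    practice for pretrained-CNN inputs.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise ValueError("empty or non-2D crop")
    vmax = img.max()
    if vmax > 0:
        img = img / vmax
    scale = 112.0 / max(img.shape)
    new_shape = (
        max(1, int(round(img.shape[0] * scale))),
        max(1, int(round(img.shape[1] * scale))),
    )
    small = transform.resize(img, new_shape, anti_aliasing=True, preserve_range=True)
    out = np.full((224, 224), _PAD_VALUE)
    r0 = (224 - small.shape[0]) // 2
    c0 = (224 - small.shape[1]) // 2
    out[r0 : r0 + small.shape[0], c0 : c0 + small.shape[1]] = small
    return out


def embed_image(image: np.ndarray) -> np.ndarray:
    """512-dimensional multiscale morphology descriptor of one cell crop.

    A deterministic handcrafted backend: a four-level image pyramid of the
    standardized 224 x 224 crop, with an 8-orientation gradient-magnitude
    histogram pooled on a 4 x 4 spatial grid at each level
    (4 levels x 16 cells x 8 orientations = 512 values, L2-normalized per
    level).
    """
    img = prepare_crop(image)
    out = np.empty(EMBED_DIM)
    pos = 0
    level = img
    for _ in range(_N_LEVELS):
        gy, gx = np.gradient(level)
        mag = np.hypot(gx, gy)
        ori = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned orientation
        obin = np.minimum((ori / np.pi * _N_ORI).astype(int), _N_ORI - 1)
        h, w = level.shape
        rcell = np.minimum(np.arange(h) * _GRID // h, _GRID - 1)
        ccell = np.minimum(np.arange(w) * _GRID // w, _GRID - 1)
        cell_idx = (rcell[:, None] * _GRID + ccell[None, :]).ravel()
        flat_idx = cell_idx * _N_ORI + obin.ravel()
        hist = np.bincount(flat_idx, weights=mag.ravel(), minlength=_GRID * _GRID * _N_ORI)
        norm = np.linalg.norm(hist)
        if norm > 0:
            hist = hist / norm
        out[pos : pos + len(hist)] = hist
        pos += len(hist)
        level = transform.rescale(level, 0.5, anti_aliasing=True, preserve_range=True)
    assert pos == EMBED_DIM
    return out


def embed(images: Sequence[np.ndarray]) -> np.ndarray:
    """Embed many single-cell crops; returns an (n_cells, 512) array."""
    return np.stack([embed_image(im) for im in images])


# ---------------------------------------------------------------------------
# clustering of the morphology embedding
# ---------------------------------------------------------------------------

@dataclass
class MorphologyClusters:
    """k-means clusters of the morphology embedding, ordered C1..Ck from
    least to most ramified (ascending mean terminal-point count, ties
    broken by mean cell area)."""

    labels: np.ndarray  # integer class index, 0 -> C1
    k: int
    pca_components: np.ndarray  # (10, embed_dim) basis
    inertias: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def name_of(self, i: int) -> str:
        return self.class_names[i]


def kneedle(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the knee of a convex decreasing curve (Kneedle criterion).

    Normalizes both axes to [0, 1], flips y to an increasing concave
    curve, and returns the index maximizing the difference curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.ptp(y) == 0:
        return 0
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    diff = (1.0 - yn) - xn
    return int(np.argmax(diff))


def cluster_morphology(
    embeddings: np.ndarray,
    seed: int,
    order_values: Optional[np.ndarray] = None,
    tie_values: Optional[np.ndarray] = None,
    k_max: int = 10,
    n_components: int = 10,
) -> MorphologyClusters:
    """PCA + k-means clustering of morphology embeddings with elbow-selected k.

    Embeddings are projected onto their top 10 principal components;
    k-means is run for k = 1..k_max and k chosen at the knee of the
    inertia curve.  Clusters are relabeled C1..Ck in ascending order of
    ``order_values`` means (e.g. terminal-point counts), with
    ``tie_values`` (e.g. cell area) breaking ties; absent those, the
    first principal component orders the classes.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = np.asarray(embeddings, dtype=float)
    if len(X) < n_components:
        raise ValueError(f"need at least {n_components} cells")
    rng = stage_rng(seed, "cluster_morphology")
    pca = PCA(n_components=n_components, random_state=int(rng.integers(2**31)))
    Z = pca.fit_transform(X)

    ks = np.arange(1, min(k_max, len(X)) + 1)
    inertias = []
    fits = {}
    for k in ks:
        km = KMeans(
            n_clusters=int(k),
            n_init=10,
            random_state=int(stage_rng(seed, f"kmeans_{k}").integers(2**31)),
        ).fit(Z)
        inertias.append(km.inertia_)
        fits[int(k)] = km
    inertias = np.asarray(inertias)
    k = int(ks[kneedle(ks, inertias)])
    k = max(k, 1)
    raw = fits[k].labels_

    if order_values is None:
        order_values = Z[:, 0]
    order_values = np.asarray(order_values, dtype=float)
    tie = np.asarray(tie_values, dtype=float) if tie_values is not None else np.zeros(len(X))
    keys = [
        (order_values[raw == c].mean(), tie[raw == c].mean(), c) for c in range(k)
    ]
    order = [c for _, _, c in sorted(keys)]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    return MorphologyClusters(
        labels=labels,
        k=k,
        pca_components=pca.components_,
        inertias=inertias,
        class_names=[f"C{i + 1}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# projection-depth consistency
# ---------------------------------------------------------------------------

def projection_consistency(
    cells: Sequence[CellCompartments],
    soma_planes: Sequence[int],
    thicknesses_um: Sequence[float] = (10.0, 15.0, 20.0),
    z_spacing: float = 1.5,
):
    """Compare section-limited and full-depth fractal dimensions.

    For each cell, the fractal dimension of the full-depth maximum
    projection is compared with the mean over the family of fixed-
    thickness sliding windows containing the soma plane (from the window
    ending at the soma plane to the window starting there).  Returns a
    per-(cell, thickness) table and, per thickness, the least-squares
    slope/intercept and Pearson correlation of section FD against full FD.
    """
    records = []
    for cell, soma_z in zip(cells, soma_planes):
        full_fd = fractal_dimension(cell.max_projection("total"))
        n_z = cell.n_planes
        for t_um in thicknesses_um:
            w = max(1, int(round(t_um / z_spacing)))
            if w > n_z:
                continue  # thickness exceeds stack: skipped
            fds = []
            for start in range(max(0, soma_z - w + 1), min(soma_z, n_z - w) + 1):
                proj = cell.total[start : start + w].any(axis=0)
                fds.append(fractal_dimension(proj))
            records.append(
                {
                    "cell_id": cell.cell_id,
                    "thickness_um": t_um,
                    "full_fd": full_fd,
                    "section_fd": float(np.mean(fds)),
                }
            )
    table = pd.DataFrame(records)
    fits = {}
    for t_um, grp in table.groupby("thickness_um"):
        if len(grp) < 2 or grp["full_fd"].nunique() < 2:
            continue
        res = stats.linregress(grp["full_fd"], grp["section_fd"])
        fits[t_um] = {
            "slope": res.slope,
            "intercept": res.intercept,
            "correlation": res.rvalue,
        }
    return table, fits
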