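"""Image-derived cell delineation.

Coarse stain segmentation of the IBA1 maximum projection, unique matching
of image labels to transcriptomically derived boundary polygons,
soma/process decomposition from the DAPI/IBA1 channels with GFAP-based
astrocyte subtraction, transcript-to-compartment assignment, and
stain-aggregate detection.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, exposure, filters, measure, morphology as skmorph, restoration, util

from gliamorph.containers import (
    PROCESS,
    SOMA,
    BoundarySet,
    CellCompartments,
    CompartmentCounts,
    TranscriptTable,
)


class CellSkipped(RuntimeError):
    """A matched cell could not be decomposed into compartments."""


# ---------------------------------------------------------------------------
# coarse segmentation
# ---------------------------------------------------------------------------

def coarse_segment(
    iba1_maxproj: np.ndarray,
    background_radius: float = 25.0,
    blur_sigma: float = 2.0,
) -> np.ndarray:
    """Coarse IBA1 segmentation of a maximum projection.

    Pipeline: histogram equalization -> 8-bit conversion -> rolling-ball
    background subtraction -> suppression of low-edge-magnitude pixels
    (below the Otsu threshold of the Sobel edge image, removing smooth
    autofluorescent background) -> Gaussian blur -> Otsu threshold ->
    connected-component labeling.  A constant image yields zero labels.
    """
    img = np.asarray(iba1_maxproj, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    eq = exposure.equalize_hist(img)
    img8 = util.img_as_ubyte(eq)
    bg = restoration.rolling_ball(img8, radius=background_radius)
    sub = img8.astype(float) - bg
    edges = filters.sobel(sub)
    if np.ptp(edges) > 0:
        edge_thr = filters.threshold_otsu(edges)
        sub = np.where(edges >= edge_thr, sub, 0.0)
    blurred = filters.gaussian(sub, sigma=blur_sigma)
    if np.ptp(blurred) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    mask = blurred > filters.threshold_otsu(blurred)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# matching image labels to transcriptomic boundaries
# ---------------------------------------------------------------------------

def match_labels(
    labels: np.ndarray,
    boundaries: BoundarySet,
    annotations: Optional[dict[str, str]] = None,
    target_type: str = "microglia",
) -> list[tuple[int, str]]:
    """Uniquely map image labels to boundary polygons.

    A (label, cell) pair is retained iff the boundary polygon overlaps
    exactly one image label AND that label overlaps exactly one boundary
    (an injective partial mapping in both directions); when annotations
    are supplied the cell must also carry the target type, and cells whose
    annotation sources disagree (annotation is None-like or mismatched)
    are dropped.
    """
    labels = np.asarray(labels)
    overlaps: dict[str, set[int]] = {}
    label_hits: dict[int, set[str]] = {}
    for cid, ring in boundaries.rings.items():
        if annotations is not None and annotations.get(cid) != target_type:
            continue
        rr, cc = draw.polygon(ring[:, 1], ring[:, 0], shape=labels.shape)
        hit = set(np.unique(labels[rr, cc])) - {0}
        overlaps[cid] = hit
        for lab in hit:
            label_hits.setdefault(int(lab), set()).add(cid)
    matched = []
    for cid, hit in overlaps.items():
        if len(hit) != 1:
            continue
        lab = int(next(iter(hit)))
        if label_hits.get(lab, set()) == {cid}:
            matched.append((lab, cid))
    return sorted(matched)


# ---------------------------------------------------------------------------
# adaptive thresholding helper
# ---------------------------------------------------------------------------

def adaptive_mask(
    image: np.ndarray, window: int, offset: float = 2.0
) -> np.ndarray:
    """Local-mean adaptive threshold: pixel > local mean - offset.

    The local threshold is floored at half the global Otsu threshold so
    that structure-free (near-constant) background regions, where the
    local mean minus a small offset would fall below the pixel values,
    stay unsegmented.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        # constant image: every pixel exceeds (its local mean - offset) iff
        # there is any signal at all
        return np.full(img.shape, bool(img.flat[0] > 0))
    block = int(window) | 1  # threshold_local needs an odd block size
    local = filters.threshold_local(img, block_size=block, method="mean", offset=offset)
    floor = 0.5 * filters.threshold_otsu(img)
    return img > np.maximum(local, floor)


# ---------------------------------------------------------------------------
# soma / process decomposition
# ---------------------------------------------------------------------------

def refine_compartments(
    stack: np.ndarray,
    center_xy: tuple[float, float],
    cell_id: str,
    window_coarse: int = 200,
    window_fine: int = 50,
    crop: Optional[tuple[int, int, int, int]] = None,
    channels: tuple[int, int, int] = (0, 1, 2),
) -> CellCompartments:
    """Decompose one matched cell into soma and process masks.

    ``stack`` has shape (channels, z, H, W) with IBA1, DAPI and GFAP at
    the indices in ``channels``.  The soma is the connected component of
    the adaptive-threshold (window_coarse) DAPI-and-IBA1 overlap of the
    maximum projections that contains the cell center; the process mask
    is the cell's IBA1 component minus the soma.  Per z-plane the IBA1
    and GFAP channels are re-thresholded at window_fine and GFAP-positive
    pixels are removed from that plane's process mask; the total mask is
    the soma united with the GFAP-subtracted process, so compartment
    counts add exactly.

    Raises :class:`CellSkipped` when DAPI and IBA1 do not overlap at the
    cell center.
    """
    iba1_ix, dapi_ix, gfap_ix = channels
    if crop is not None:
        y0, y1, x0, x1 = crop
        stack = stack[:, :, y0:y1, x0:x1]
        origin = (y0, x0)
        cx, cy = center_xy[0] - x0, center_xy[1] - y0
    else:
        origin = (0, 0)
        cx, cy = center_xy
    iba1 = stack[iba1_ix].astype(float)
    dapi = stack[dapi_ix].astype(float)
    gfap = stack[gfap_ix].astype(float)
    n_planes = iba1.shape[0]

    iba1_coarse = adaptive_mask(iba1.max(axis=0), window_coarse)
    dapi_coarse = adaptive_mask(dapi.max(axis=0), window_coarse)

    struct = np.ones((3, 3), int)
    ic, ir = int(round(cx)), int(round(cy))
    ir = np.clip(ir, 0, iba1_coarse.shape[0] - 1)
    ic = np.clip(ic, 0, iba1_coarse.shape[1] - 1)

    cell_comp = _component_at(iba1_coarse, ir, ic, struct)
    if cell_comp is None:
        # concave cells: the matched centroid may fall just outside the
        # stain; snap to the nearest IBA1 pixel within a small radius
        ys, xs = np.nonzero(iba1_coarse)
        if len(ys):
            d = np.hypot(ys - ir, xs - ic)
            i = int(np.argmin(d))
            if d[i] <= 25:
                ir, ic = int(ys[i]), int(xs[i])
                cell_comp = _component_at(iba1_coarse, ir, ic, struct)
    if cell_comp is None:
        raise CellSkipped(f"cell {cell_id}: no IBA1 signal at the matched center")
    soma_seed = dapi_coarse & cell_comp
    soma2d = _component_at(soma_seed, ir, ic, struct)
    if soma2d is None:
        # center may sit just off the nucleus: take the component nearest it
        labs, n = ndimage.label(soma_seed, structure=struct)
        if n == 0:
            raise CellSkipped(f"cell {cell_id}: no DAPI/IBA1 overlap at the cell center")
        # fall back to the component nearest the center pixel
        best, best_d = None, np.inf
        for lab in range(1, n + 1):
            comp = labs == lab
            ys, xs = np.nonzero(comp)
            d = np.hypot(ys - ir, xs - ic).min()
            if d < best_d:
                best, best_d = comp, d
        if best_d > max(soma_seed.shape):  # pragma: no cover
            raise CellSkipped(f"cell {cell_id}: no DAPI/IBA1 overlap near the cell center")
        soma2d = best
    process2d = cell_comp & ~soma2d

    soma = np.broadcast_to(soma2d, (n_planes, *soma2d.shape)).copy()
    process = np.empty_like(soma)
    total = np.empty_like(soma)
    for z in range(n_planes):
        iba1_fine = adaptive_mask(iba1[z], window_fine)
        gfap_fine = adaptive_mask(gfap[z], window_fine)
        proc_z = process2d & iba1_fine & ~gfap_fine
        process[z] = proc_z
        total[z] = soma2d | proc_z

    centroid = _interior_centroid(soma2d)
    skeleton = skmorph.skeletonize(total.any(axis=0))
    return CellCompartments(
        cell_id=cell_id,
        total=total,
        soma=soma,
        process=process,
        soma_centroid=centroid,
        skeleton=skeleton,
        provenance={"origin": origin, "center": (cx, cy)},
    )


def _component_at(mask, r, c, struct):
    labs, n = ndimage.label(mask, structure=struct)
    lab = labs[r, c]
    if lab == 0:
        return None
    return labs == lab


def _interior_centroid(mask2d: np.ndarray) -> tuple[float, float]:
    """Centroid of a mask, snapped to the nearest mask pixel if outside."""
    ys, xs = np.nonzero(mask2d)
    cy, cx = ys.mean(), xs.mean()
    ry, rx = int(round(cy)), int(round(cx))
    if (
        0 <= ry < mask2d.shape[0]
        and 0 <= rx < mask2d.shape[1]
        and mask2d[ry, rx]
    ):
        return (cx, cy)
    i = np.argmin(np.hypot(ys - cy, xs - cx))
    return (float(xs[i]), float(ys[i]))


# ---------------------------------------------------------------------------
# transcript assignment
# ---------------------------------------------------------------------------

def assign_transcripts(
    transcripts: TranscriptTable, cell: CellCompartments
) -> tuple[TranscriptTable, CompartmentCounts]:
    """Label each molecule with its compartment and aggregate counts.

    Molecules are labeled soma or process when they fall inside the
    respective mask at their own z-plane, and unassigned otherwise
    (including molecules removed by GFAP subtraction); unassigned
    molecules are not counted.  Assignment is idempotent and independent
    of row order.
    """
    df = transcripts.df.copy()
    oy, ox = cell.provenance.get("origin", (0, 0))
    comp = cell.compartment_of(df["x"] - ox, df["y"] - oy, df["z"])
    df["compartment"] = comp
    genes = sorted(df["gene"].unique())
    table = pd.DataFrame(0, index=genes, columns=["soma", "process", "total"])
    for which in (SOMA, PROCESS):
        sub = df[df["compartment"] == which].groupby("gene").size()
        table.loc[sub.index, which] = sub.values
    table["total"] = table["soma"] + table["process"]
    return (
        TranscriptTable(df),
        CompartmentCounts(cell_id=cell.cell_id, table=table),
    )


# ---------------------------------------------------------------------------
# stain-aggregate detection
# ---------------------------------------------------------------------------

def detect_aggregates(
    channel_stack: np.ndarray,
    iba1_stack: np.ndarray,
    min_area: int = 51,
    window_fine: int = 50,
    solidity_reference: Optional[float] = None,
    fractal_reference: Optional[float] = None,
) -> list[dict]:
    """Detect stain aggregates (e.g. AXL puncta) inside microglial masks.

    Per plane, the target channel is Otsu-thresholded and components with
    area >= ``min_area`` pixels (i.e. strictly more than 50 px at the
    default) are kept; kept aggregates must intersect that plane's
    adaptive IBA1 mask restricted to the maximum-projection cell outline.
    When reference medians are supplied, the host cell outline is scored
    ramified (fractal dimension above the fractal reference and solidity
    below the solidity reference) or amoeboid.
    """
    from gliamorph.morphology import fractal_dimension

    channel_stack = np.asarray(channel_stack, dtype=float)
    iba1_stack = np.asarray(iba1_stack, dtype=float)
    outline = adaptive_mask(iba1_stack.max(axis=0), window_fine)
    struct = np.ones((3, 3), int)
    out = []
    for z in range(channel_stack.shape[0]):
        plane = channel_stack[z]
        if np.ptp(plane) == 0:
            continue
        mask = plane > filters.threshold_otsu(plane)
        labs, n = ndimage.label(mask, structure=struct)
        iba1_plane = adaptive_mask(iba1_stack[z], window_fine) & outline
        for rp in measure.regionprops(labs):
            if rp.area < min_area:
                continue
            comp = labs == rp.label
            inside = bool((comp & iba1_plane).any())
            rec = {
                "plane": z,
                "area": int(rp.area),
                "centroid_xy": (rp.centroid[1], rp.centroid[0]),
                "inside_iba1": inside,
            }
            if inside and solidity_reference is not None and fractal_reference is not None:
                host = _component_at(
                    outline, *np.argwhere(comp & iba1_plane)[0], struct
                )
                host_rp = measure.regionprops(host.astype(np.uint8))[0]
                fd = fractal_dimension(host)
                rec["host_class"] = (
                    "ramified"
                    if fd > fractal_reference and host_rp.solidity < solidity_reference
                    else "amoeboid"
                )
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# convenience: full segmentation of a synthetic or real field
# ---------------------------------------------------------------------------

def segment_field(
    stack: np.ndarray,
    boundaries: BoundarySet,
    transcripts: TranscriptTable,
    annotations: Optional[dict[str, str]] = None,
    window_coarse: int = 200,
    window_fine: int = 50,
    crop_margin: int = 8,
) -> tuple[list[CellCompartments], dict[str, CompartmentCounts], TranscriptTable]:
    """Run coarse segmentation, matching, refinement and assignment.

    Returns the refined cells, per-cell compartment counts, and the
    transcript table restricted to matched cells with compartment labels.
    """
    labels = coarse_segment(stack[0].max(axis=0))
    matches = match_labels(labels, boundaries, annotations)
    cells, counts, labeled = [], {}, []
    for lab, cid in matches:
        poly = boundaries.polygon(cid)
        cx, cy = poly.centroid.x, poly.centroid.y
        minx, miny, maxx, maxy = poly.bounds
        crop = (
            max(0, int(miny) - crop_margin),
            min(stack.shape[2], int(maxy) + crop_margin + 1),
            max(0, int(minx) - crop_margin),
            min(stack.shape[3], int(maxx) + crop_margin + 1),
        )
        try:
            cell = refine_compartments(
                stack, (cx, cy), cid, window_coarse, window_fine, crop=crop
            )
        except CellSkipped as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        cell.provenance["coarse_label"] = lab
        sub = TranscriptTable(
            transcripts.df[transcripts.df.get("cell_id", cid) == cid].reset_index(
                drop=True
            )
        )
        sub_labeled, cc = assign_transcripts(sub, cell)
        cells.append(cell)
        counts[cid] = cc
        labeled.append(sub_labeled.df)
    labeled_df = (
        pd.concat(labeled, ignore_index=True)
        if labeled
        else transcripts.df.iloc[0:0]
    )
    return cells, counts, TranscriptTable(labeled_df)
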