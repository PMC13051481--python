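"""Readers and writers for every external format the pipeline touches.

Formats: transcript tables (CSV/Parquet), cell boundaries (GeoJSON
FeatureCollection of polygons), image stacks (multi-page TIFF with a
declared channels-by-planes layout), and cell-by-gene count matrices
(dense CSV or MatrixMarket with gene/cell sidecars).  Downstream
operations accept only the in-memory containers returned here; nothing
else in the package reads files directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from gliamorph.containers import BoundarySet, FormatError, TranscriptTable

_DEFAULT_COLUMNS = {"gene": "gene", "x": "x", "y": "y", "z": "z", "cell_id": "cell_id"}


# ---------------------------------------------------------------------------
# transcript tables
# ---------------------------------------------------------------------------

def read_transcript_table(path: str | Path, columns: dict | None = None) -> TranscriptTable:
    """Read a decoded-molecule table from CSV or Parquet.

    ``columns`` maps canonical names (gene/x/y/z/cell_id) to the file's
    header names.  Rows with an empty gene label or a negative coordinate
    are rejected (not fatal) and reported in ``TranscriptTable.rejected``
    with 1-based data-row line numbers.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    if path.suffix == ".parquet":
        raw = pd.read_parquet(path)
    else:
        raw = pd.read_csv(path)
    missing = [colmap[c] for c in ("gene", "x", "y", "z") if colmap[c] not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    gene = raw["gene"].fillna("").astype(str)
    bad_gene = gene.str.len() == 0
    coords = raw[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad_coord = coords.isna().any(axis=1) | (coords < 0).any(axis=1)
    bad = bad_gene | bad_coord
    reasons = np.where(bad_gene, "empty gene", "invalid coordinate")
    rejected = pd.DataFrame(
        {"line": raw.index[bad] + 1, "reason": reasons[bad.to_numpy()]}
    ).reset_index(drop=True)

    keep = raw.loc[~bad].copy()
    keep["gene"] = gene[~bad]
    keep[["x", "y"]] = coords[~bad]
    cols = ["gene", "x", "y", "z"] + [
        c for c in ("cell_id", "compartment") if c in keep.columns
    ]
    return TranscriptTable(keep[cols].reset_index(drop=True), rejected=rejected)


def write_transcript_table(table: TranscriptTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        table.df.to_parquet(path, index=False)
    else:
        table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# boundary polygons
# ---------------------------------------------------------------------------

def read_boundaries(path: str | Path) -> BoundarySet:
    """Read a GeoJSON FeatureCollection of cell-boundary polygons.

    Every feature must be a Polygon carrying a ``cell_id`` property;
    duplicate ids and non-polygon geometries are format errors, and
    self-intersecting rings are reported with the offending cell id.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{Path(path).name}: not a GeoJSON FeatureCollection")
    rings: dict[str, np.ndarray] = {}
    annotations: dict[str, str] = {}
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        props = feat.get("properties", {}) or {}
        cid = props.get("cell_id")
        if cid is None:
            raise FormatError("feature without cell_id property")
        cid = str(cid)
        if geom.get("type") != "Polygon":
            raise FormatError(f"cell {cid!r}: geometry is {geom.get('type')}, not Polygon")
        if cid in rings:
            raise FormatError(f"duplicate cell_id {cid!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        rings[cid] = ring
        if "cell_type" in props and props["cell_type"] is not None:
            annotations[cid] = str(props["cell_type"])
    try:
        return BoundarySet(rings, annotations)
    except FormatError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise FormatError(str(exc)) from exc


def write_boundaries(boundaries: BoundarySet, path: str | Path) -> None:
    features = []
    for cid, ring in boundaries.rings.items():
        props = {"cell_id": cid}
        if cid in boundaries.annotations:
            props["cell_type"] = boundaries.annotations[cid]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, n_channels: int) -> np.ndarray:
    """Read a multi-page TIFF into shape (channels, z, y, x).

    Pages are laid out channel-major: all planes of channel 0, then all
    planes of channel 1, and so on.  A page count not divisible by the
    declared channel count is a layout error.
    """
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError("expected a stack of single-channel 2D pages")
    if len(pages) % n_channels:
        raise FormatError(
            f"{len(pages)} pages not divisible by {n_channels} channels"
        )
    n_z = len(pages) // n_channels
    return pages.reshape(n_channels, n_z, *pages.shape[1:])


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError("stack must have shape (channels, z, y, x)")
    tifffile.imwrite(path, stack.reshape(-1, *stack.shape[2:]))


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path: str | Path):
    """Read a cell-by-gene count matrix into an AnnData object.

    Dense CSV (cells as rows, genes as columns, first column = cell id)
    or MatrixMarket ``.mtx`` with ``<stem>_genes.txt`` / ``<stem>_cells.txt``
    sidecars.
    """
    import anndata as ad

    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        genes = Path(str(path)[: -len(".mtx")] + "_genes.txt").read_text().split()
        cells = Path(str(path)[: -len(".mtx")] + "_cells.txt").read_text().split()
        adata = ad.AnnData(
            X=mat,
            obs=pd.DataFrame(index=cells),
            var=pd.DataFrame(index=genes),
        )
    else:
        df = pd.read_csv(path, index_col=0)
        adata = ad.AnnData(
            X=df.to_numpy(dtype=float),
            obs=pd.DataFrame(index=df.index.astype(str)),
            var=pd.DataFrame(index=df.columns.astype(str)),
        )
    adata.uns["layer_tag"] = "total"
    return adata


def write_counts(adata, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(np.asarray(adata.X)))
        Path(str(path)[: -len(".mtx")] + "_genes.txt").write_text(
            "\n".join(adata.var_names) + "\n"
        )
        Path(str(path)[: -len(".mtx")] + "_cells.txt").write_text(
            "\n".join(adata.obs_names) + "\n"
        )
    else:
        pd.DataFrame(
            np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
        ).to_csv(path)
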