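"""In-memory containers shared by all pipeline stages.

Coordinate conventions: pixel units with the origin at the top-left corner,
x rightward (columns), y downward (rows); z is an integer imaging-plane
index.  Physical distances are computed only inside distance calculations,
as sqrt((dx*pixel_size)**2 + (dy*pixel_size)**2 + (dz*z_spacing)**2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

SOMA = "soma"
PROCESS = "process"
UNASSIGNED = "unassigned"
COMPARTMENTS = (SOMA, PROCESS, UNASSIGNED)

#: Canonical morphometric feature vector, in reporting order.
FEATURE_NAMES = (
    "cell_area",
    "cell_perimeter",
    "convex_area",
    "convex_perimeter",
    "solidity",
    "convexity",
    "roughness",
    "circularity",
    "span_ratio",
    "convex_circularity",
    "eccentricity",
    "euler_number",
    "extent",
    "soma_area",
    "soma_perimeter",
    "soma_circularity",
    "soma_ratio",
    "feret_diameter",
    "skeleton_length",
    "mean_branch_length",
    "n_branches",
    "n_branching_points",
    "n_terminal_points",
    "fractal_dimension",
    "lacunarity",
    "tortuosity",
)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


@dataclass
class TranscriptTable:
    """Decoded molecules: one row per molecule.

    ``df`` columns: ``gene`` (non-empty str), ``x``/``y`` (pixel coords,
    >= 0), ``z`` (plane index, int), optional ``cell_id`` and
    ``compartment`` (one of soma/process/unassigned).  ``rejected`` records
    rows dropped at parse time, with original line numbers and reasons.
    """

    df: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line", "reason"])
    )

    REQUIRED = ("gene", "x", "y", "z")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"transcript table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        self.df["gene"] = self.df["gene"].astype(str)
        self.df["z"] = self.df["z"].astype(int)
        if len(self.df):
            if (self.df["x"] < 0).any() or (self.df["y"] < 0).any():
                raise ValueError("negative transcript coordinates")
            if (self.df["gene"] == "").any():
                raise ValueError("empty gene labels")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())


@dataclass
class BoundarySet:
    """Closed cell-boundary rings in pixel coordinates, keyed by cell id.

    Each ring is an (N, 2) array of (x, y) vertices with first == last
    vertex; rings must be simple (non-self-intersecting).  ``annotations``
    optionally maps cell ids to a cell-type string.
    """

    rings: dict[str, np.ndarray]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from shapely.geometry import Polygon

        for cid, ring in self.rings.items():
            ring = np.asarray(ring, dtype=float)
            if ring.ndim != 2 or ring.shape[1] != 2 or len(ring) < 4:
                raise FormatError(f"boundary {cid!r}: not a closed ring")
            if not np.allclose(ring[0], ring[-1]):
                raise FormatError(f"boundary {cid!r}: ring not closed")
            if not Polygon(ring[:-1]).is_valid:
                raise FormatError(f"boundary {cid!r}: ring is not simple")
            self.rings[cid] = ring

    def __len__(self) -> int:
        return len(self.rings)

    def polygon(self, cell_id: str):
        from shapely.geometry import Polygon

        return Polygon(self.rings[cell_id][:-1])

    def area(self, cell_id: str) -> float:
        return self.polygon(cell_id).area


@dataclass
class CellCompartments:
    """Per-cell compartment masks across imaging planes.

    ``total``, ``soma`` and ``process`` are boolean arrays of identical
    shape (n_planes, H, W); on every plane soma and process are disjoint
    and their union is the total mask.  ``soma_centroid`` is (x, y) in
    pixels and lies inside the soma mask; ``skeleton`` is a 2D boolean
    mask of the max-projected cell skeleton.
    """

    cell_id: str
    total: np.ndarray
    soma: np.ndarray
    process: np.ndarray
    soma_centroid: tuple[float, float]
    skeleton: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("total", "soma", "process"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.ndim != 3:
                raise ValueError(f"{name} mask must be 3D (planes, H, W)")
            setattr(self, name, arr)
        if not (self.total.shape == self.soma.shape == self.process.shape):
            raise ValueError("compartment masks must share one shape")
        if (self.soma & self.process).any():
            raise ValueError("soma and process masks overlap")
        if ((self.soma | self.process) != self.total).any():
            raise ValueError("soma | process must equal total on every plane")

    @property
    def n_planes(self) -> int:
        return self.total.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.total.shape[1:]

    def max_projection(self, which: str = "total") -> np.ndarray:
        return getattr(self, which).any(axis=0)

    def compartment_of(self, x, y, z) -> np.ndarray:
        """Vectorized compartment lookup for pixel coordinates."""
        x = np.round(np.asarray(x)).astype(int)
        y = np.round(np.asarray(y)).astype(int)
        z = np.asarray(z, dtype=int)
        out = np.full(x.shape, UNASSIGNED, dtype=object)
        nz, h, w = self.total.shape
        ok = (z >= 0) & (z < nz) & (y >= 0) & (y < h) & (x >= 0) & (x < w)
        out[ok & _lookup(self.soma, z, y, x, ok)] = SOMA
        out[ok & _lookup(self.process, z, y, x, ok)] = PROCESS
        return out


def _lookup(mask, z, y, x, ok):
    res = np.zeros(ok.shape, dtype=bool)
    res[ok] = mask[z[ok], y[ok], x[ok]]
    return res


@dataclass
class CompartmentCounts:
    """Per-gene molecule counts in each compartment for one cell.

    ``table`` is indexed by gene with integer columns soma/process/total,
    satisfying soma + process == total elementwise.
    """

    cell_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"soma", "process", "total"}
        if set(self.table.columns) != need:
            raise ValueError(f"count table needs columns {sorted(need)}")
        t = self.table
        if (t < 0).any().any():
            raise ValueError("negative counts")
        if not (t["soma"] + t["process"] == t["total"]).all():
            raise ValueError("soma + process != total")


@dataclass
class MorphologyFeatures:
    """The canonical 26-scalar morphometric vector for one cell."""

    cell_area: float
    cell_perimeter: float
    convex_area: float
    convex_perimeter: float
    solidity: float
    convexity: float
    roughness: float
    circularity: float
    span_ratio: float
    convex_circularity: float
    eccentricity: float
    euler_number: float
    extent: float
    soma_area: float
    soma_perimeter: float
    soma_circularity: float
    soma_ratio: float
    feret_diameter: float
    skeleton_length: float
    mean_branch_length: float
    n_branches: float
    n_branching_points: float
    n_terminal_points: float
    fractal_dimension: float
    lacunarity: float
    tortuosity: float

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})

    @staticmethod
    def names() -> tuple[str, ...]:
        return FEATURE_NAMES


assert tuple(f.name for f in fields(MorphologyFeatures)) == FEATURE_NAMES
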