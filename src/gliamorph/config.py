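"""Run configuration and deterministic random-stream derivation.

One :class:`RunConfig` instance travels through a pipeline run.  Every
stochastic stage derives its generator from the run seed plus a stage tag via
:func:`stage_rng`, so runs are exactly reproducible and stages are
statistically independent of one another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_LOG_FORMAT = "%(asctime)s [%(name)s] %(levelname)s: %(message)s"


@dataclass
class RunConfig:
    """Global parameters of an analysis run.

    Parameters
    ----------
    seed:
        Master seed; every stochastic stage derives its stream from it.
    pixel_size:
        Lateral image resolution in micrometres per pixel.
    z_spacing:
        Axial distance between imaging planes in micrometres.
    qc_min_transcripts, qc_min_genes:
        Per-cell quality-control cutoffs on total molecule count and unique
        gene count.
    coloc_percentile:
        Percentile (percent) of pooled soma pairwise distances used as the
        gene-gene co-localization radius.
    n_null:
        Number of Monte-Carlo randomizations for null distributions.
    alpha:
        Significance level for adjusted p-values.
    """

    seed: int = 0
    pixel_size: float = 0.108
    z_spacing: float = 1.5
    qc_min_transcripts: int = 20
    qc_min_genes: int = 5
    coloc_percentile: float = 5.0
    n_null: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        for name in ("qc_min_transcripts", "qc_min_genes", "n_null"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.coloc_percentile < 100:
            raise ValueError("coloc_percentile must lie in (0, 100)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON config file; keyword arguments override file values."""
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    def rng(self, stage: str) -> np.random.Generator:
        """Random generator for a named pipeline stage."""
        return stage_rng(self.seed, stage)

    def distance_um(self, dx_px, dy_px, dz_planes):
        """Physical distance from pixel/plane displacements."""
        return np.sqrt(
            (np.asarray(dx_px) * self.pixel_size) ** 2
            + (np.asarray(dy_px) * self.pixel_size) ** 2
            + (np.asarray(dz_planes) * self.z_spacing) ** 2
        )


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a named random stream from a master seed.

    The stage tag is hashed (CRC-32) and combined with the seed in a
    ``SeedSequence``, so distinct stages get independent streams and the
    mapping is stable across platforms and sessions.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def get_logger(stage: str) -> logging.Logger:
    """Stage-tagged logger writing to stderr."""
    logger = logging.getLogger(f"gliamorph.{stage}")
    if not logger.handlers and not logging.getLogger().handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger
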