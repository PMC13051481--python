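"""Compartment-constrained spatial statistics of subcellular transcripts.

Two procedures: (1) a generalized 3D Ripley's K / H clustering test per
gene and compartment, with Monte-Carlo envelopes obtained by redrawing
the same number of molecules uniformly over the compartment's own voxel
set (so boundary effects cancel between observed and null, and no edge
correction is needed); and (2) a gene-gene co-localization network built
from close-pair counts at a distance-percentile radius, a
within-compartment randomization null, z-tests with Benjamini-Hochberg
correction, and mixture-model clustering of the significant-pair graph.

All coordinates here are micrometres; pixel/plane inputs are converted
once on entry via the run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from gliamorph.config import RunConfig, stage_rng
from gliamorph.containers import PROCESS, SOMA, CellCompartments, TranscriptTable

DEFAULT_RADII = np.arange(0.5, 5.01, 0.5)


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def transcripts_to_um(df: pd.DataFrame, config: RunConfig, origin=(0, 0)) -> np.ndarray:
    """(n, 3) micrometre coordinates from a pixel/plane transcript frame."""
    oy, ox = origin
    return np.column_stack(
        [
            (df["x"].to_numpy(float) - ox) * config.pixel_size,
            (df["y"].to_numpy(float) - oy) * config.pixel_size,
            df["z"].to_numpy(float) * config.z_spacing,
        ]
    )


def voxels_to_um(voxels_zyx: np.ndarray, config: RunConfig) -> np.ndarray:
    """Voxel centers (z, y, x) -> micrometre coordinates (x, y, z)."""
    v = np.asarray(voxels_zyx, dtype=float)
    return np.column_stack(
        [v[:, 2] * config.pixel_size, v[:, 1] * config.pixel_size, v[:, 0] * config.z_spacing]
    )


def _sample_uniform(rng, n: int, voxels_um: np.ndarray, config: RunConfig) -> np.ndarray:
    """Uniform points over a voxel set: random voxel plus in-plane jitter."""
    idx = rng.integers(len(voxels_um), size=n)
    pts = voxels_um[idx].copy()
    pts[:, :2] += rng.uniform(-0.5, 0.5, size=(n, 2)) * config.pixel_size
    return pts


# ---------------------------------------------------------------------------
# Ripley's K / H
# ---------------------------------------------------------------------------

def ripley_k3d(points_um: np.ndarray, volume_um3: float, radii: np.ndarray) -> np.ndarray:
    """Ripley's K for a 3D point pattern in a bounded domain.

    K(r) = V / (n (n-1)) * sum_{i != j} 1[d_ij <= r], without edge
    correction: the Monte-Carlo null shares the domain, so boundary bias
    cancels in the envelope comparison.
    """
    pts = np.asarray(points_um, dtype=float)
    if len(pts) < 2:
        raise ValueError("Ripley's K needs at least 2 points")
    d = np.sort(pdist(pts))
    counts = np.searchsorted(d, np.asarray(radii, float), side="right")
    n = len(pts)
    return volume_um3 / (n * (n - 1)) * 2.0 * counts


def h_transform(k_values: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Besag-style 3D variance stabilization: H(r) = (3K/(4 pi))^(1/3) - r."""
    return np.cbrt(3.0 * np.asarray(k_values, float) / (4.0 * np.pi)) - np.asarray(
        radii, float
    )


@dataclass
class RipleyResult:
    """Observed H curve with Monte-Carlo envelope and per-radius flags.

    ``flag`` is +1 where the observed H exceeds the upper (95%) envelope
    (clustering), -1 below the lower (5%) envelope (dispersion), else 0.
    ``n_domains`` records over how many individual processes the
    statistic was averaged (1 for the soma).
    """

    radii: np.ndarray
    h_obs: np.ndarray
    k_obs: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    flag: np.ndarray
    n_points: int
    n_domains: int
    n_null: int

    @property
    def significant(self) -> bool:
        return bool((self.flag != 0).any())

    @property
    def clustered(self) -> bool:
        return bool((self.flag > 0).any())


def ripley_envelope(
    points_per_domain: Sequence[np.ndarray],
    voxels_per_domain: Sequence[np.ndarray],
    radii: np.ndarray,
    n_null: int,
    seed: int,
    config: RunConfig,
    min_voxels: int = 10,
) -> RipleyResult:
    """Monte-Carlo Ripley H envelope over one or more subdomains.

    Each domain contributes an H curve (its own K under its own volume);
    the statistic is the unweighted mean over domains — for process
    compartments the degree of clustering is computed within each
    individual process and averaged.  Null curves redraw each domain's
    point count uniformly over that domain's voxels; the envelope is the
    pointwise 5% / 95% quantile band of the null statistics.
    """
    radii = np.asarray(radii, dtype=float)
    voxel_volume = config.pixel_size**2 * config.z_spacing
    domains = []
    for pts, vox in zip(points_per_domain, voxels_per_domain):
        if len(vox) < min_voxels:
            raise ValueError(f"domain with {len(vox)} voxels (< {min_voxels})")
        if len(pts) < 2:
            continue
        domains.append((np.asarray(pts, float), np.asarray(vox, float)))
    if not domains:
        raise ValueError("no domain holds at least 2 points")

    def statistic(point_sets):
        hs = []
        ks = []
        for (pts, vox), pset in zip(domains, point_sets):
            k = ripley_k3d(pset, len(vox) * voxel_volume, radii)
            hs.append(h_transform(k, radii))
            ks.append(k)
        return np.mean(hs, axis=0), np.mean(ks, axis=0)

    h_obs, k_obs = statistic([pts for pts, _ in domains])
    rng = stage_rng(seed, "ripley_envelope")
    null_h = np.empty((n_null, len(radii)))
    for b in range(n_null):
        draws = [
            _sample_uniform(rng, len(pts), vox, config) for pts, vox in domains
        ]
        null_h[b], _ = statistic(draws)
    # order-statistic quantiles: with B null draws the exchangeable-rank
    # probability of landing outside the band is ~0.05 per side
    lower = np.quantile(null_h, 0.05, axis=0, method="lower")
    upper = np.quantile(null_h, 0.95, axis=0, method="higher")
    flag = np.where(h_obs > upper, 1, np.where(h_obs < lower, -1, 0))
    return RipleyResult(
        radii=radii,
        h_obs=h_obs,
        k_obs=k_obs,
        lower=lower,
        upper=upper,
        flag=flag,
        n_points=int(sum(len(p) for p, _ in domains)),
        n_domains=len(domains),
        n_null=n_null,
    )


def ripley_cell_gene(
    cell: CellCompartments,
    transcripts: TranscriptTable,
    gene: str,
    compartment: str,
    config: RunConfig,
    radii: np.ndarray = DEFAULT_RADII,
    n_null: int = 100,
    seed: int = 0,
) -> RipleyResult:
    """Compartment-constrained Ripley H test for one gene in one cell.

    Soma: one domain (the soma voxel set).  Processes: each connected
    process (labeled on the max projection) is an individual domain;
    the statistic averages over processes holding >= 2 molecules.
    """
    df = transcripts.df
    sub = df[(df["gene"] == gene) & (df["compartment"] == compartment)]
    origin = cell.provenance.get("origin", (0, 0))
    pts = transcripts_to_um(sub, config, origin)
    if compartment == SOMA:
        vox = np.argwhere(cell.soma)
        return ripley_envelope(
            [pts], [voxels_to_um(vox, config)], radii, n_null, seed, config
        )
    if compartment != PROCESS:
        raise ValueError(f"unknown compartment {compartment!r}")
    proc2d = cell.max_projection("process")
    labels, n = ndimage.label(proc2d, structure=np.ones((3, 3), int))
    if n == 0:
        raise ValueError("empty process mask")
    ix = np.round(sub["x"].to_numpy(float)).astype(int) - origin[1]
    iy = np.round(sub["y"].to_numpy(float)).astype(int) - origin[0]
    ix = np.clip(ix, 0, labels.shape[1] - 1)
    iy = np.clip(iy, 0, labels.shape[0] - 1)
    mol_lab = labels[iy, ix]
    points_per, voxels_per = [], []
    for lab in range(1, n + 1):
        vox = np.argwhere(cell.process & (labels == lab)[None])
        if len(vox) < 10:
            continue
        points_per.append(pts[mol_lab == lab])
        voxels_per.append(voxels_to_um(vox, config))
    return ripley_envelope(points_per, voxels_per, radii, n_null, seed, config)


# ---------------------------------------------------------------------------
# co-localization radius and pair counts
# ---------------------------------------------------------------------------

def coloc_radius(distances_um: np.ndarray, percentile: float = 5.0) -> float:
    """Linear-interpolation percentile of pooled soma pairwise distances."""
    d = np.asarray(distances_um, dtype=float)
    if len(d) < 20:
        raise ValueError("need at least 20 pairwise distances")
    return float(np.percentile(d, percentile))


def soma_pairwise_distances(
    cell: CellCompartments, transcripts: TranscriptTable, config: RunConfig
) -> np.ndarray:
    """All 3D pairwise distances between soma molecules of one cell."""
    df = transcripts.df
    sub = df[df["compartment"] == SOMA]
    pts = transcripts_to_um(sub, config, cell.provenance.get("origin", (0, 0)))
    if len(pts) < 2:
        return np.empty(0)
    return pdist(pts)


def _pair_counts(pts_um: np.ndarray, gene_codes: np.ndarray, n_genes: int, r: float):
    """Close-pair counts per unordered distinct gene pair (encoded i*G+j, i<j)."""
    counts = np.zeros(n_genes * (n_genes - 1) // 2, dtype=np.int64)
    if len(pts_um) < 2:
        return counts
    tree = cKDTree(pts_um)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if not len(pairs):
        return counts
    gi = gene_codes[pairs[:, 0]]
    gj = gene_codes[pairs[:, 1]]
    keep = gi != gj  # same-gene pairs excluded
    gi, gj = gi[keep], gj[keep]
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    flat = _pair_offset(lo, n_genes) + (hi - lo - 1)
    np.add.at(counts, flat, 1)
    return counts


def _pair_offset(lo: np.ndarray, n: int) -> np.ndarray:
    # offset of row `lo` in the condensed upper-triangle ordering
    lo = lo.astype(np.int64)
    return lo * (2 * n - lo - 1) // 2


def pair_names(genes: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered gene pairs in condensed upper-triangle order."""
    return [
        (genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]


@dataclass
class CellColoc:
    """Observed and null close-pair counts for one cell compartment."""

    cell_id: str
    genes: list[str]
    observed: np.ndarray  # (n_pairs,)
    null: np.ndarray  # (n_null, n_pairs)
    r_coloc: float

    def pairs(self) -> list[tuple[str, str]]:
        return pair_names(self.genes)


def coloc_counts(
    cell: CellCompartments,
    transcripts: TranscriptTable,
    compartment: str,
    r_coloc: float,
    config: RunConfig,
) -> tuple[list[str], np.ndarray]:
    """Observed close-pair counts for one cell compartment.

    For each unordered pair of distinct genes, the number of molecule
    pairs within ``r_coloc`` micrometres (3D distance); same-gene pairs
    are excluded.
    """
    df = transcripts.df
    sub = df[df["compartment"] == compartment]
    genes = sorted(sub["gene"].unique())
    pts = transcripts_to_um(sub, config, cell.provenance.get("origin", (0, 0)))
    codes = pd.Categorical(sub["gene"], categories=genes).codes.astype(np.int64)
    return genes, _pair_counts(pts, codes, len(genes), r_coloc)


def coloc_null(
    cell: CellCompartments,
    transcripts: TranscriptTable,
    compartment: str,
    r_coloc: float,
    config: RunConfig,
    n_null: int = 1000,
    seed: int = 0,
) -> CellColoc:
    """Observed plus randomized close-pair counts for one cell compartment.

    Each randomization redraws every molecule uniformly within its own
    compartment's voxel set, preserving per-gene molecule counts and
    compartment assignment, and recomputes all pair counts.
    """
    import warnings

    if n_null < 100:
        warnings.warn(f"n_null={n_null} < 100: null quantiles will be coarse")
    df = transcripts.df
    sub = df[df["compartment"] == compartment]
    genes = sorted(sub["gene"].unique())
    n_genes = len(genes)
    pts = transcripts_to_um(sub, config, cell.provenance.get("origin", (0, 0)))
    codes = pd.Categorical(sub["gene"], categories=genes).codes.astype(np.int64)
    observed = _pair_counts(pts, codes, n_genes, r_coloc)

    vox = voxels_to_um(np.argwhere(getattr(cell, compartment)), config)
    rng = stage_rng(seed, f"coloc_null_{cell.cell_id}_{compartment}")
    n_mol = len(pts)
    null = np.zeros((n_null, len(observed)), dtype=np.int64)
    for b in range(n_null):
        draw = _sample_uniform(rng, n_mol, vox, config)
        null[b] = _pair_counts(draw, codes, n_genes, r_coloc)
    return CellColoc(cell.cell_id, genes, observed, null, r_coloc)


# ---------------------------------------------------------------------------
# significance, network, clustering
# ---------------------------------------------------------------------------

@dataclass
class ColocNetwork:
    """Significant co-localization graph with mixture-model clusters."""

    graph: nx.Graph
    components: list[set[str]]
    cluster_labels: dict[str, tuple[int, int]]  # gene -> (component, cluster)
    threshold_count: float


def coloc_significance(
    cell_colocs: Sequence[CellColoc],
    alpha: float = 0.05,
    min_observations: int = 4,
    count_percentile: float = 90.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, ColocNetwork]:
    """Aggregate per-cell co-localization into a significant-pair network.

    Per cell and pair, z = (observed - null mean) / null sd (pairs with
    zero null sd are skipped in that cell) with a one-sided upper p.
    Across cells, observed counts and z are averaged per pair and the
    p-value recomputed from the averaged z, then BH-corrected across
    pairs.  An edge is kept iff the average observed count reaches the
    ``count_percentile`` of non-zero average null contacts, the pair was
    observed (count >= 1) in at least ``min_observations`` cells, and
    padj < alpha; connected components of <= 2 genes are dropped.
    Surviving components are clustered with a Gaussian mixture on their
    z-weighted adjacency rows, the component count chosen by BIC over
    k = 1..min(5, n_nodes).
    """
    acc: dict[tuple[str, str], dict[str, list[float]]] = {}
    for cc in cell_colocs:
        null_mean = cc.null.mean(axis=0)
        null_sd = cc.null.std(axis=0, ddof=1)
        for idx, pair in enumerate(cc.pairs()):
            rec = acc.setdefault(
                pair, {"obs": [], "z": [], "null_mean": [], "n_seen": []}
            )
            obs = float(cc.observed[idx])
            rec["obs"].append(obs)
            rec["null_mean"].append(float(null_mean[idx]))
            rec["n_seen"].append(1.0 if obs >= 1 else 0.0)
            if null_sd[idx] > 0:
                rec["z"].append((obs - null_mean[idx]) / null_sd[idx])

    rows = []
    for (ga, gb), rec in sorted(acc.items()):
        if not rec["z"]:
            continue
        z_avg = float(np.mean(rec["z"]))
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "mean_obs": float(np.mean(rec["obs"])),
                "mean_null": float(np.mean(rec["null_mean"])),
                "z": z_avg,
                "p": float(stats.norm.sf(z_avg)),
                "n_observations": int(sum(rec["n_seen"])),
                "n_cells": len(rec["obs"]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "mean_obs", "mean_null", "z", "p",
            "n_observations", "n_cells",
        ],
    )
    if len(table):
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = pd.Series(dtype=float)

    nonzero_null = table.loc[table["mean_null"] > 0, "mean_null"]
    threshold = (
        float(np.percentile(nonzero_null, count_percentile))
        if len(nonzero_null)
        else 0.0
    )
    sig = table[
        (table["padj"] < alpha)
        & (table["n_observations"] >= min_observations)
        & (table["mean_obs"] >= threshold)
    ]

    graph = nx.Graph()
    for _, row in sig.iterrows():
        graph.add_edge(row["gene_a"], row["gene_b"], z=row["z"], padj=row["padj"])
    # components of <= 2 genes are dropped
    components = [c for c in nx.connected_components(graph) if len(c) > 2]
    graph = graph.subgraph(set().union(*components) if components else set()).copy()

    cluster_labels = _cluster_components(graph, components, seed)
    return table, ColocNetwork(graph, components, cluster_labels, threshold)


def _cluster_components(
    graph: nx.Graph, components: list[set[str]], seed: int
) -> dict[str, tuple[int, int]]:
    from sklearn.mixture import GaussianMixture

    labels: dict[str, tuple[int, int]] = {}
    for ci, comp in enumerate(sorted(components, key=lambda c: sorted(c)[0])):
        nodes = sorted(comp)
        A = nx.to_numpy_array(graph.subgraph(nodes), nodelist=nodes, weight="z")
        best_labels, best_bic = np.zeros(len(nodes), dtype=int), np.inf
        rs = int(stage_rng(seed, f"coloc_gmm_{ci}").integers(2**31))
        for k in range(1, min(5, len(nodes)) + 1):
            gm = GaussianMixture(
                n_components=k, covariance_type="diag", random_state=rs
            ).fit(A)
            bic = gm.bic(A)
            if bic < best_bic - 1e-9:
                best_bic = bic
                best_labels = gm.predict(A)
        for node, lab in zip(nodes, best_labels):
            labels[node] = (ci, int(lab))
    return labels
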