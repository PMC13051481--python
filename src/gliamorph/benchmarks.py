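"""Self-contained benchmark scenarios exercising the pipeline end to end.

Each function simulates its own inputs under the package's study
conditions (via :mod:`gliamorph.synthetic`), runs the relevant analysis
stage, and returns the measured quantities: calibration rates of the
Ripley test, recovery of planted co-localized pairs and
compartment-enriched genes, classifier AUROCs, and the analytic
morphometry/normalization values.  Problem sizes are chosen so a full
run completes in minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gliamorph import expression as E, morpho_corr as MC, morphology as M
from gliamorph import spatial as sp, synthetic as S
from gliamorph.config import RunConfig, stage_rng
from gliamorph.containers import FEATURE_NAMES, SOMA


# ---------------------------------------------------------------------------
# conformance and analytic values
# ---------------------------------------------------------------------------

def embedding_conformance() -> dict:
    """Embedding length, padded input shape, and feature-vector length."""
    rng = np.random.default_rng(0)
    crop = rng.random((48, 31))
    padded = M.prepare_crop(crop)
    vec = M.embed_image(crop)
    return {
        "embedding_length": int(vec.shape[0]),
        "padded_side": int(padded.shape[0]),
        "n_canonical_features": len(FEATURE_NAMES),
    }


def sierpinski_mask(depth: int = 7) -> np.ndarray:
    m = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m], [m, z]])
    return m


def morphometry_analytics() -> dict:
    """Fractal/lacunarity/skeleton values on analytically known shapes."""
    line = np.zeros((256, 256), dtype=bool)
    line[128, :] = True
    bar = np.zeros((20, 60), dtype=bool)
    bar[8:12, 5:55] = True
    y_mask = np.zeros((80, 80), dtype=bool)
    for t in range(30):
        y_mask[40 - t, 40] = True
        y_mask[40 + t, 40 - t] = True
        y_mask[40 + t, 40 + t] = True
    bar_sk = M.skeletonize_and_measure(bar)
    y_sk = M.measure_skeleton(y_mask)
    return {
        "fd_filled_square": M.fractal_dimension(np.ones((256, 256), dtype=bool)),
        "fd_line": M.fractal_dimension(line),
        "fd_sierpinski_depth7": M.fractal_dimension(sierpinski_mask(7)),
        "lacunarity_filled": M.lacunarity(np.ones((64, 64), dtype=bool)),
        "bar_terminal_points": bar_sk.n_terminal_points,
        "bar_branching_points": bar_sk.n_branching_points,
        "y_terminal_points": y_sk.n_terminal_points,
        "y_branching_points": y_sk.n_branching_points,
        "y_branches": y_sk.n_branches,
    }


def normalization_analytics(seed: int = 0) -> dict:
    """Library-size conservation and analytic tau values."""
    rng = stage_rng(seed, "normalization_bench")
    counts = pd.DataFrame(
        rng.poisson(20, size=(50, 30)),
        index=[f"c{i}" for i in range(50)],
        columns=[f"g{i}" for i in range(30)],
    )
    counts = E.qc_filter(counts)
    ln = E.lognormalize(counts)
    conservation_err = float(
        np.abs(np.expm1(ln).sum(axis=1) - E.LOGNORM_SCALE).max()
    )
    return {
        "lognorm_conservation_error": conservation_err,
        "tau_uniform": E.tau([2.0, 2.0, 2.0, 2.0]),
        "tau_single_type": E.tau([0.0, 7.0, 0.0]),
        "tau_graded": E.tau([1.0, 0.5, 0.0]),
    }


# ---------------------------------------------------------------------------
# Ripley calibration and power
# ---------------------------------------------------------------------------

_RIPLEY_RADII = np.array([1.0, 1.5, 2.0])


def _soma_domain(cfg: RunConfig, n_planes: int = 6, side: int = 60) -> np.ndarray:
    vox = np.argwhere(np.ones((n_planes, side, side), dtype=bool))
    return sp.voxels_to_um(vox, cfg)


def ripley_calibration(
    seed: int, n_genes: int = 500, n_molecules: int = 80, n_null: int = 200
) -> dict:
    """Type-I flag rate of the Ripley test on CSR point patterns.

    Each "gene" is an independent CSR pattern of ``n_molecules`` points
    in a soma-sized compartment; the pointwise 5%/95% envelope targets a
    10% two-sided flag rate per radius.
    """
    cfg = RunConfig(seed=seed)
    dom = _soma_domain(cfg)
    rng = stage_rng(seed, "ripley_calibration")
    flags = np.zeros((n_genes, len(_RIPLEY_RADII)))
    for g in range(n_genes):
        pts = sp._sample_uniform(rng, n_molecules, dom, cfg)
        res = sp.ripley_envelope(
            [pts], [dom], _RIPLEY_RADII, n_null, seed=int(rng.integers(2**31)),
            config=cfg,
        )
        flags[g] = res.flag != 0
    rates = flags.mean(axis=0)
    return {
        f"csr_flag_rate_r{r:g}um": float(v)
        for r, v in zip(_RIPLEY_RADII, rates)
    }


def ripley_thomas_power(
    seed: int,
    n_runs: int = 100,
    n_molecules: int = 60,
    cluster_sigma: float = 1.0,
    children: int = 10,
    n_null: int = 200,
) -> dict:
    """Detection rate for Thomas-process clustering (sigma 1 um)."""
    cfg = RunConfig(seed=seed)
    dom = _soma_domain(cfg)
    rng = stage_rng(seed, "ripley_power")
    hits = 0
    for _ in range(n_runs):
        n_parents = max(1, int(rng.poisson(n_molecules / children)))
        parents = sp._sample_uniform(rng, n_parents, dom, cfg)
        pts = parents[rng.integers(n_parents, size=n_molecules)].copy()
        pts[:, :2] += rng.normal(0, cluster_sigma, size=(n_molecules, 2))
        dz = np.round(rng.normal(0, cluster_sigma, n_molecules) / cfg.z_spacing)
        pts[:, 2] = np.clip(pts[:, 2] + dz * cfg.z_spacing, 0, 5 * cfg.z_spacing)
        res = sp.ripley_envelope(
            [pts], [dom], _RIPLEY_RADII, n_null, seed=int(rng.integers(2**31)),
            config=cfg,
        )
        hits += res.clustered
    return {"thomas_detection_rate": hits / n_runs}


# ---------------------------------------------------------------------------
# co-localization recovery
# ---------------------------------------------------------------------------

def _coloc_panel(planted: bool) -> list[S.GeneModel]:
    genes = [S.GeneModel(f"bg{i}", 30, -1.0) for i in range(8)]
    if planted:
        for tag in ("p1", "p2"):
            genes += [
                S.GeneModel(
                    f"{tag}a", 30, -1.0, cluster_sigma=1.0, cluster_children=8,
                    coloc_partner=f"{tag}b",
                ),
                S.GeneModel(
                    f"{tag}b", 30, -1.0, cluster_sigma=1.0, cluster_children=8,
                    coloc_partner=f"{tag}a",
                ),
            ]
    else:
        genes += [S.GeneModel(f"bg{i}", 30, -1.0) for i in range(8, 12)]
    return genes


def _run_coloc_dataset(cfg, seed: int, planted: bool, n_cells: int, n_null: int):
    shape = S.ShapeParams(soma_radius=30, n_primary_branches=4, image_size=256)
    genes = _coloc_panel(planted)
    rng = stage_rng(seed, "coloc_dataset")
    cells = []
    dists = []
    for i in range(n_cells):
        cell = S.simulate_cell(shape, int(rng.integers(2**31)), cell_id=f"c{i}")
        tx = S.simulate_transcripts(cell, genes, int(rng.integers(2**31)), cfg)
        cells.append((cell, tx))
        d = sp.soma_pairwise_distances(cell, tx, cfg)
        if len(d):
            dists.append(d)
    r = sp.coloc_radius(np.concatenate(dists), cfg.coloc_percentile)
    colocs = [
        sp.coloc_null(cell, tx, SOMA, r, cfg, n_null=n_null,
                      seed=int(rng.integers(2**31)))
        for cell, tx in cells
    ]
    return sp.coloc_significance(colocs, alpha=cfg.alpha, seed=seed)


def coloc_recovery(
    seed: int, n_datasets: int = 20, n_cells: int = 50, n_null: int = 200
) -> dict:
    """Recovery of planted shared-parent pairs and CSR false-edge rate.

    ``planted_pair_recovery_rate``: fraction of planted pairs reaching
    padj < alpha across datasets.  ``csr_zero_edge_rate``: fraction of
    fully CSR datasets whose final network has no edges.
    """
    cfg = RunConfig(seed=seed)
    planted_pairs = [("p1a", "p1b"), ("p2a", "p2b")]
    recovered = 0
    for d in range(n_datasets):
        table, _ = _run_coloc_dataset(cfg, seed * 1009 + d, True, n_cells, n_null)
        sig = set(
            map(tuple, table.loc[table["padj"] < cfg.alpha, ["gene_a", "gene_b"]].values)
        )
        recovered += sum(p in sig for p in planted_pairs)
    zero_edges = 0
    for d in range(n_datasets):
        _, net = _run_coloc_dataset(cfg, seed * 2003 + d, False, n_cells, n_null)
        zero_edges += net.graph.number_of_edges() == 0
    return {
        "planted_pair_recovery_rate": recovered / (n_datasets * len(planted_pairs)),
        "csr_zero_edge_rate": zero_edges / n_datasets,
    }


# ---------------------------------------------------------------------------
# compartment-enrichment recovery
# ---------------------------------------------------------------------------

def enrichment_recovery(seed: int, n_cells: int = 200) -> dict:
    """Sensitivity and FDR for planted |log-odds| >= 2 enriched genes."""
    cfg = RunConfig(seed=seed)
    panel = (
        [S.GeneModel(f"proc{i}", 30, 2.0) for i in range(5)]
        + [S.GeneModel(f"soma{i}", 30, -2.0) for i in range(5)]
        + [S.GeneModel(f"neutral{i}", 30, 0.0) for i in range(20)]
    )
    shape = S.ShapeParams(soma_radius=12, n_primary_branches=5)
    rng = stage_rng(seed, "enrichment_bench")
    gene_names = [g.gene for g in panel]
    soma_rows, proc_rows, ids = [], [], []
    for i in range(n_cells):
        cell = S.simulate_cell(shape, int(rng.integers(2**31)), cell_id=f"c{i}")
        tx = S.simulate_transcripts(cell, panel, int(rng.integers(2**31)), cfg)
        by = tx.df.groupby(["compartment", "gene"]).size()
        soma_rows.append([by.get(("soma", g), 0) for g in gene_names])
        proc_rows.append([by.get(("process", g), 0) for g in gene_names])
        ids.append(f"c{i}")
    soma = pd.DataFrame(soma_rows, index=ids, columns=gene_names)
    proc = pd.DataFrame(proc_rows, index=ids, columns=gene_names)
    res = E.compartment_enrichment(soma, proc, ids, alpha=cfg.alpha)
    called = set(res.process_enriched) | set(res.soma_enriched)
    true_proc = {f"proc{i}" for i in range(5)}
    true_soma = {f"soma{i}" for i in range(5)}
    hits = len(set(res.process_enriched) & true_proc) + len(
        set(res.soma_enriched) & true_soma
    )
    false_calls = len(called - true_proc - true_soma) + len(
        set(res.process_enriched) & true_soma
    ) + len(set(res.soma_enriched) & true_proc)
    return {
        "enrichment_sensitivity": hits / 10,
        "enrichment_fdr": false_calls / max(len(called), 1),
        "n_process_enriched": len(res.process_enriched),
        "n_soma_enriched": len(res.soma_enriched),
    }


# ---------------------------------------------------------------------------
# shape classifier
# ---------------------------------------------------------------------------

def classifier_benchmark(
    seed: int, n_per_class: int = 200, effect: float = 4.0, n_perm: int = 20
) -> dict:
    """AUROC on planted shape-linked expression and under label permutation."""
    rng = stage_rng(seed, "classifier_bench")
    n = 2 * n_per_class
    cells = [f"c{i}" for i in range(n)]
    labels = pd.Series(
        ["amoeboid"] * n_per_class + ["ramified"] * n_per_class, index=cells
    )
    base = rng.poisson(20, size=(n, 15)).astype(float)
    base[n_per_class:, :8] *= effect  # process-enriched genes up in ramified
    counts = pd.DataFrame(
        rng.poisson(base), index=cells, columns=[f"g{i}" for i in range(15)]
    )
    ln = E.lognormalize(counts)
    report = MC.train_classifier(ln, list(ln.columns), labels, seed=seed)
    perm_aurocs = []
    for p in range(n_perm):
        shuffled = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        perm = MC.train_classifier(ln, list(ln.columns), shuffled, seed=seed + p + 1)
        perm_aurocs.append(perm.auroc)
    return {
        "classifier_auroc": report.auroc,
        "permuted_auroc_median": float(np.median(perm_aurocs)),
    }


# ---------------------------------------------------------------------------
# distance-CDF analytic check
# ---------------------------------------------------------------------------

def distance_cdf_ks(seed: int, n_molecules: int = 5000) -> dict:
    """Kolmogorov distance of uniform-in-disk distances from CDF x^2."""
    cfg = RunConfig(seed=seed)
    disk = S.simulate_cell(
        S.ShapeParams(soma_radius=60, n_primary_branches=0, image_size=160),
        seed=seed,
        plane_noise=0.0,
    )
    genes = [S.GeneModel("u", float(n_molecules), process_logodds=-20.0)]
    tx = S.simulate_transcripts(disk, genes, seed=seed, config=cfg)
    out = MC.transcript_distance_cdf(disk, tx)
    d = np.sort(out["normalized_distance"].to_numpy())
    ecdf = np.arange(1, len(d) + 1) / len(d)
    return {
        "distance_cdf_ks": float(np.abs(ecdf - d**2).max()),
        "n_distance_samples": len(d),
    }


# ---------------------------------------------------------------------------
# determinism and structural invariants
# ---------------------------------------------------------------------------

def determinism_invariants(seed: int) -> dict:
    """Byte-identical regeneration plus segmentation/count invariants."""
    from gliamorph import segmentation as seg

    cfg = RunConfig(seed=seed)
    panel = [
        S.GeneModel("proc_hi", 40, 3.0),
        S.GeneModel("soma_hi", 40, -3.0),
        S.GeneModel("neutral", 40, 0.0),
    ]
    ds1 = S.simulate_dataset(cfg, 9, panel, seed=seed)
    ds2 = S.simulate_dataset(cfg, 9, panel, seed=seed)
    identical = ds1.transcripts.df.equals(ds2.transcripts.df) and np.array_equal(
        ds1.stack, ds2.stack
    )
    cells, counts, _ = seg.segment_field(
        ds1.stack, ds1.boundaries, ds1.transcripts, ds1.boundaries.annotations
    )
    partition_ok = all(
        not (c.soma & c.process).any()
        and ((c.soma | c.process) == c.total).all()
        for c in cells
    )
    conservation_ok = all(
        (cc.table["soma"] + cc.table["process"] == cc.table["total"]).all()
        for cc in counts.values()
    )
    labels = seg.coarse_segment(ds1.stack[0].max(axis=0))
    matched = seg.match_labels(labels, ds1.boundaries, ds1.boundaries.annotations)
    labs = [l for l, _ in matched]
    cids = [c for _, c in matched]
    unique_ok = len(set(labs)) == len(labs) and len(set(cids)) == len(cids)
    return {
        "regeneration_identical": float(identical),
        "mask_partition_holds": float(partition_ok),
        "count_conservation_holds": float(conservation_ok),
        "matching_bijective": float(unique_ok),
        "match_rate": len(matched) / len(ds1.cells),
    }
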