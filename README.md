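# gliamorph

Joint analysis of microglial **morphology** and **subcellular transcript
localization** from imaging spatial transcriptomics (MERFISH-style decoded
molecule tables) paired with immunostaining (IBA1/DAPI/GFAP). The package is
aimed at people analyzing single-molecule spatial data of branched brain cell
types who want to ask: *which mRNAs live in the soma versus the processes, do
they cluster or co-localize there, and does any of that predict the cell's
shape?*

## What it computes

- **Compartment segmentation** — coarse IBA1 segmentation, unique matching to
  transcriptomically derived boundary polygons, soma/process decomposition
  from DAPI∩IBA1 with per-plane GFAP (astrocyte) subtraction, and
  molecule-to-compartment assignment with exact count conservation
  (soma + process = total per gene).
- **Morphometry** — a canonical 26-feature vector per cell (areas, perimeter
  ratios, solidity = A/A_hull, circularity = 4πA/P², Feret diameter, skeleton
  branch/terminal counts, Sholl scalars, box-counting fractal dimension,
  gliding-box lacunarity Λ = σ²/μ² + 1, tortuosity), a deterministic
  512-dimensional multiscale morphology embedding, and elbow-selected k-means
  classes C1…Ck ordered from least to most ramified.
- **Expression statistics** — QC (≥20 molecules, ≥5 genes per cell),
  ln(1 + CP10K) normalization, Mann-Whitney-Wilcoxon differential expression
  with Benjamini-Hochberg correction, compartment-enrichment calls
  (|log₂FC| > 1, p_adj < 0.05 on ramified cells), tau specificity
  τ = Σ(1 − x̂ᵢ)/(N − 1), and expression-matched gene-set scores.
- **Morphology–expression coupling** — Spearman ρ_s per gene-feature pair on a
  75/25 train/held-out split, top-5-per-feature gene sets, held-out
  hierarchical clustering scored by adjusted Rand index, and a random-forest
  ramified-vs-amoeboid classifier reporting held-out AUROC and MDI
  importances.
- **Compartment-constrained spatial statistics** — 3D Ripley
  K(r) = V/(n(n−1)) Σ 1[d_ij ≤ r] with H(r) = (3K/4π)^⅓ − r and Monte-Carlo
  envelopes drawn inside the compartment's own voxel set (per-process
  averaging for the arbor), and gene–gene co-localization networks: close-pair
  counts at the 5th-percentile distance radius, a within-compartment
  randomization null, z-tests with BH correction, conjunctive edge rules, and
  BIC-selected Gaussian-mixture clustering of network components.
- **Synthetic data with ground truth** — ramified/amoeboid cell shapes across
  z-planes, per-gene compartment enrichment at controlled log-odds,
  Thomas-process clustering, planted co-localized pairs (shared cluster
  parents), astrocyte contamination, and an age effect that attenuates
  enrichment and prunes co-localization links. Every dataset ships a truth
  manifest that regenerates it bit-exactly.

## Worked example

Simulate a 16-cell field with planted compartment enrichment, segment it, and
recover the planted genes:

```python
from gliamorph import synthetic as S, segmentation as seg, morphology as M, expression as E
from gliamorph.config import RunConfig

cfg = RunConfig(seed=0)
panel = (
    [S.GeneModel(f"proc{i}", 30, 2.0) for i in range(2)]    # process-enriched
    + [S.GeneModel(f"soma{i}", 30, -2.0) for i in range(2)]  # soma-enriched
    + [S.GeneModel(f"neutral{i}", 30, 0.0) for i in range(4)]
)
ds = S.simulate_dataset(cfg, 16, panel, seed=42)
cells, counts, labeled = seg.segment_field(
    ds.stack, ds.boundaries, ds.transcripts, ds.boundaries.annotations
)
print(f"segmented {len(cells)}/16 cells")

feats = M.features_table(cells)
print(feats[["cell_area", "n_terminal_points", "fractal_dimension", "solidity"]].head(3).round(3))

ramified = [c for c, s in ds.truth.shape_class.items() if s == "ramified"]
res = E.compartment_enrichment(ds.counts["soma"], ds.counts["process"], ramified)
print("process-enriched:", res.process_enriched)
print("soma-enriched:   ", res.soma_enriched)
```

Output:

```
segmented 16/16 cells
           cell_area  n_terminal_points  fractal_dimension  solidity
cell_0001     1707.0                7.0              1.329     0.158
cell_0003     1601.0                6.0              1.448     0.216
cell_0002     1450.0                5.0              1.429     0.209
process-enriched: ['proc0', 'proc1']
soma-enriched:    ['soma0', 'soma1']
```

Every cell matched its boundary uniquely; the low solidity and fractal
dimension ≈ 1.3–1.45 are what branched arbors look like (a filled disk would
sit near solidity 1 and FD 2). Both genes planted at +2 log-odds
(≈ 88% of molecules in processes) are called process-enriched, both −2
log-odds genes soma-enriched, and no neutral gene is called.

A CLI mirrors the pipeline stages (`gliamorph simulate | segment | features |
embed-cluster | enrich | correlate | classify | ripley | coloc`); run
`gliamorph --help` for details.

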