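"""Morphology-expression correlation, gene-set selection, held-out
clustering, transcript-distance CDFs, and the ramified-vs-amoeboid
expression classifier.

Correlations are Spearman rank coefficients computed on a seeded
training split only; the held-out split is reserved for clustering and
classifier evaluation, so no test cell ever influences gene selection or
hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from gliamorph.config import stage_rng
from gliamorph.containers import CellCompartments, TranscriptTable

#: Ramification-related features used for region-stratified gene ranking.
RAMIFICATION_FEATURES = (
    "cell_area",
    "convex_perimeter",
    "convex_area",
    "cell_perimeter",
    "n_branches",
    "skeleton_length",
    "roughness",
    "n_terminal_points",
    "n_branching_points",
    "soma_ratio",
    "fractal_dimension",
    "tortuosity",
)


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Spearman rho for every (gene, feature) pair on the training split."""

    rho: pd.DataFrame  # genes x features
    train_cells: list[str]
    test_cells: list[str]
    seed: int
    flagged: list[tuple[str, str]] = field(default_factory=list)


def correlate(
    features: pd.DataFrame,
    lognorm: pd.DataFrame,
    seed: int,
    train_frac: float = 0.75,
) -> CorrelationMatrix:
    """Spearman correlation of every gene against every morphology feature.

    Cells are split into a seeded training fraction (used for the
    correlations) and a held-out remainder; ties get average ranks.
    Pairs where either variable is constant on the training set are set
    to 0 and flagged.
    """
    cells = sorted(set(features.index) & set(lognorm.index))
    if not cells:
        raise ValueError("no shared cells between features and expression")
    rng = stage_rng(seed, "correlate_split")
    perm = rng.permutation(len(cells))
    n_train = int(round(train_frac * len(cells)))
    train = [cells[i] for i in perm[:n_train]]
    test = [cells[i] for i in perm[n_train:]]
    if len(train) < 20:
        raise ValueError("need at least 20 training cells")

    F = features.loc[train]
    X = lognorm.loc[train]
    # ranked once, correlations via Pearson on ranks (= Spearman)
    rf = F.rank(axis=0)
    rx = X.rank(axis=0)
    rf_c = rf - rf.mean(axis=0)
    rx_c = rx - rx.mean(axis=0)
    denom = np.outer(
        np.sqrt((rx_c**2).sum(axis=0)), np.sqrt((rf_c**2).sum(axis=0))
    )
    num = rx_c.T.to_numpy() @ rf_c.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / denom, 0.0)
    table = pd.DataFrame(rho, index=X.columns, columns=F.columns)
    flagged = [
        (g, f)
        for g in X.columns[(rx_c**2).sum(axis=0) == 0]
        for f in F.columns
    ] + [
        (g, f)
        for f in F.columns[(rf_c**2).sum(axis=0) == 0]
        for g in X.columns
    ]
    return CorrelationMatrix(table, train, test, seed, flagged)


def top_gene_sets(
    corr: CorrelationMatrix, k: int = 5, signed: bool = False
) -> tuple[list[str], dict[str, list[str]]]:
    """Union of the top-k correlated genes per morphological feature.

    Ranks by |rho| by default (``signed=True`` ranks by rho); ties at
    rank k resolve by stable sort order.  Returns the union and the
    per-feature provenance.
    """
    if len(corr.rho.index) < k:
        raise ValueError(f"need at least {k} genes")
    per_feature: dict[str, list[str]] = {}
    union: list[str] = []
    for feat in corr.rho.columns:
        vals = corr.rho[feat] if signed else corr.rho[feat].abs()
        top = list(vals.sort_values(ascending=False, kind="stable").index[:k])
        per_feature[feat] = top
        for g in top:
            if g not in union:
                union.append(g)
    return union, per_feature


def cluster_heldout(
    lognorm: pd.DataFrame,
    gene_set: Sequence[str],
    morphology_labels: pd.Series,
    test_cells: Sequence[str],
    ramified_classes: Sequence[int] = (2, 3, 4),
) -> tuple[pd.Series, float]:
    """Two-group hierarchical clustering of held-out cells on a gene set.

    Average-linkage (Euclidean) clustering on the gene-set expression of
    the held-out cells, cut at two groups; agreement is the adjusted Rand
    index against the binary amoeboid (C1+C2) versus ramified (C3-C5)
    morphology partition.  Returns (cluster labels, ARI); ARI is NaN if
    the expression is degenerate (single cluster).
    """
    from sklearn.metrics import adjusted_rand_score

    genes = [g for g in gene_set if g in lognorm.columns]
    X = lognorm.loc[list(test_cells), sorted(genes)]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 held-out cells")
    d = pdist(X.to_numpy())
    if np.all(d == 0):
        return pd.Series(1, index=X.index), float("nan")
    Z = linkage(d, method="average")
    labels = pd.Series(fcluster(Z, t=2, criterion="maxclust"), index=X.index)
    truth = morphology_labels.loc[X.index].isin(ramified_classes).astype(int)
    if labels.nunique() < 2:
        return labels, float("nan")
    return labels, float(adjusted_rand_score(truth, labels))


def region_stratified_top_genes(
    features: pd.DataFrame,
    lognorm: pd.DataFrame,
    regions: pd.Series,
    seed: int,
    ramification_features: Sequence[str] = RAMIFICATION_FEATURES,
    k: int = 5,
    min_cells: int = 20,
) -> tuple[dict[str, list[str]], pd.Series]:
    """Per-region top-k ramification-correlated genes and occurrence counts.

    Within each region (>= ``min_cells`` cells; smaller regions are
    skipped with a warning), each gene's mean Spearman rho across the
    ramification feature list is computed on that region's training
    cells, and the k genes with the largest mean |rho| are kept; the
    occurrence count says in how many regions each gene appears.
    """
    import warnings

    feats = [f for f in ramification_features if f in features.columns]
    per_region: dict[str, list[str]] = {}
    for region in sorted(regions.unique()):
        cells = list(regions.index[regions == region])
        if len(cells) < min_cells:
            warnings.warn(f"region {region!r}: fewer than {min_cells} cells, skipped")
            continue
        corr = correlate(
            features.loc[cells, feats],
            lognorm.loc[cells],
            seed=seed,
            train_frac=1.0,
        )
        mean_rho = corr.rho.abs().mean(axis=1)
        per_region[str(region)] = list(
            mean_rho.sort_values(ascending=False, kind="stable").index[:k]
        )
    counts = pd.Series(
        pd.Series([g for genes in per_region.values() for g in genes]).value_counts()
    )
    return per_region, counts


# ---------------------------------------------------------------------------
# transcript-distance CDF
# ---------------------------------------------------------------------------

def transcript_distance_cdf(
    cell: CellCompartments, transcripts: TranscriptTable
) -> pd.DataFrame:
    """Normalized transcript-to-soma-centroid distances for one cell.

    Per molecule, the in-plane Euclidean distance to the soma centroid is
    divided by the maximum centroid-to-mask-pixel distance of the cell,
    so 0 is the centroid and 1 the outermost cell edge.  Pool the
    returned samples over cells and genes to draw per-gene CDFs.
    """
    cx, cy = cell.soma_centroid
    mask = cell.max_projection("total")
    ys, xs = np.nonzero(mask)
    max_d = np.hypot(xs - cx, ys - cy).max()
    oy, ox = cell.provenance.get("origin", (0, 0))
    df = transcripts.df
    d = np.hypot(df["x"] - ox - cx, df["y"] - oy - cy) / max_d
    return pd.DataFrame(
        {"gene": df["gene"].to_numpy(), "normalized_distance": d.to_numpy()}
    )


# ---------------------------------------------------------------------------
# ramified vs amoeboid classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    """Held-out AUROC and impurity-based gene importances."""

    auroc: float
    importances: pd.Series
    best_params: dict
    seed: int
    train_cells: list[str] = field(default_factory=list)
    test_cells: list[str] = field(default_factory=list)


def train_classifier(
    lognorm: pd.DataFrame,
    gene_set: Sequence[str],
    labels: pd.Series,
    seed: int,
    test_frac: float = 0.2,
) -> ClassifierReport:
    """Random-forest classification of ramified vs amoeboid cells.

    Features are whole-cell log-normalized expression of the supplied
    (process-enriched) gene set; an 80/20 seeded split with a small
    cross-validated hyperparameter grid (trees in {100, 300}, depth in
    {None, 10}) tuned on the training split only.  Reports held-out
    AUROC and mean-decrease-in-impurity importances (non-negative,
    summing to 1).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import GridSearchCV, train_test_split

    genes = [g for g in gene_set if g in lognorm.columns]
    if not genes:
        raise ValueError("empty gene set")
    y = labels.loc[lognorm.index]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if min((y == c).sum() for c in classes) < 20:
        raise ValueError("each class needs at least 20 cells")
    X = lognorm[genes]
    rng = stage_rng(seed, "classifier_split")
    rs = int(rng.integers(2**31))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_frac, random_state=rs, stratify=y
    )
    grid = {"n_estimators": [100, 300], "max_depth": [None, 10]}
    search = GridSearchCV(
        RandomForestClassifier(random_state=rs),
        grid,
        scoring="accuracy",
        cv=3,
    )
    search.fit(X_tr, (y_tr == classes[1]).astype(int))
    model = search.best_estimator_
    proba = model.predict_proba(X_te)[:, 1]
    auroc = float(roc_auc_score((y_te == classes[1]).astype(int), proba))
    return ClassifierReport(
        auroc=auroc,
        importances=pd.Series(model.feature_importances_, index=genes),
        best_params=search.best_params_,
        seed=seed,
        train_cells=list(X_tr.index),
        test_cells=list(X_te.index),
    )


def avg_compartment_correlation(
    corr: CorrelationMatrix, gene_sets: dict[str, Sequence[str]]
) -> pd.DataFrame:
    """Mean Spearman rho per gene set, per feature plus an overall column.

    Genes absent from the correlation matrix are skipped with a warning.
    """
    import warnings

    rows = {}
    for name, genes in gene_sets.items():
        if not len(genes):
            raise ValueError(f"gene set {name!r} is empty")
        present = [g for g in genes if g in corr.rho.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"set {name!r}: genes absent from matrix: {missing}")
        if not present:
            continue
        mean_by_feature = corr.rho.loc[present].mean(axis=0)
        mean_by_feature["overall"] = float(corr.rho.loc[present].to_numpy().mean())
        rows[name] = mean_by_feature
    return pd.DataFrame(rows).T
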