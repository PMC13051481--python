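"""Count-matrix QC, normalization, differential expression and gene-set
statistics.

Matrices are cells-by-genes pandas DataFrames (integer counts) or the
log-normalized transform thereof; differential expression uses the
two-sided Mann-Whitney-Wilcoxon test with Benjamini-Hochberg correction,
and the compartment-enrichment caller applies the DEG rule (|log2 fold
change| > 1 and adjusted p < 0.05) to process-versus-soma normalized
counts of the most ramified cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gliamorph.config import stage_rng

LOGNORM_SCALE = 10_000.0


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    counts: pd.DataFrame, min_transcripts: int = 20, min_genes: int = 5
) -> pd.DataFrame:
    """Drop cells with too few molecules or too few expressed genes.

    Thresholds are inclusive: a cell with exactly ``min_transcripts``
    molecules across exactly ``min_genes`` genes is retained.  The gene
    set is unchanged.
    """
    total = counts.sum(axis=1)
    n_genes = (counts > 0).sum(axis=1)
    return counts.loc[(total >= min_transcripts) & (n_genes >= min_genes)]


def lognormalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalization to 10,000 followed by ln(1 + x).

    value = ln(1 + count / cell_total * 10,000); consequently, per cell,
    sum(expm1(values)) == 10,000 exactly (up to float error).
    """
    total = counts.sum(axis=1)
    if (total == 0).any():
        bad = list(counts.index[total == 0][:5])
        raise ValueError(f"cells with zero total counts (QC first): {bad}")
    return np.log1p(counts.div(total, axis=0) * LOGNORM_SCALE)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

_FC_EPS = 1e-9


@dataclass
class DEResult:
    """Per-gene Mann-Whitney differential expression.

    ``table`` columns: log2FC (group A over group B on expm1 means), U,
    p, padj (Benjamini-Hochberg), deg_up, deg_down.  The DEG rule is
    log2FC > 1 (resp. < -1) with padj < 0.05, both strict.
    """

    table: pd.DataFrame
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["deg_up"]])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["deg_down"]])


def mww_de(
    lognorm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> DEResult:
    """Two-sided Mann-Whitney-Wilcoxon DE between two cell groups.

    Tie-corrected normal approximation per gene, BH correction across
    genes; log2FC compares group means of expm1(lognorm) with a 1e-9
    pseudocount.  Genes that are all-zero in both groups get p = 1 and
    log2FC = 0.
    """
    a = lognorm.loc[list(group_a)]
    b = lognorm.loc[list(group_b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 cells")
    expr_a = np.expm1(a.to_numpy())
    expr_b = np.expm1(b.to_numpy())
    mean_a = expr_a.mean(axis=0)
    mean_b = expr_b.mean(axis=0)
    log2fc = np.log2((mean_a + _FC_EPS) / (mean_b + _FC_EPS))

    nonzero = (expr_a.sum(axis=0) + expr_b.sum(axis=0)) > 0
    u = np.full(lognorm.shape[1], np.nan)
    p = np.ones(lognorm.shape[1])
    if nonzero.any():
        res = stats.mannwhitneyu(
            expr_a[:, nonzero], expr_b[:, nonzero], alternative="two-sided", axis=0
        )
        u[nonzero] = res.statistic
        p[nonzero] = res.pvalue
    log2fc = np.where(nonzero, log2fc, 0.0)
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "U": u,
            "p": p,
            "padj": padj,
            "deg_up": (log2fc > lfc_threshold) & (padj < alpha),
            "deg_down": (log2fc < -lfc_threshold) & (padj < alpha),
        },
        index=lognorm.columns,
    )
    return DEResult(table, list(group_a), list(group_b))


# ---------------------------------------------------------------------------
# compartment enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichedGeneSets:
    """Soma- and process-enriched gene sets from ramified cells."""

    soma_enriched: list[str]
    process_enriched: list[str]
    cells_used: list[str]
    de: Optional[DEResult] = None


def compartment_enrichment(
    soma_counts: pd.DataFrame,
    process_counts: pd.DataFrame,
    ramified_cells: Sequence[str],
    alpha: float = 0.05,
) -> EnrichedGeneSets:
    """Call compartment-enriched genes on the most ramified cells.

    Soma and process count layers are log-normalized independently and
    compared process-versus-soma with the MWW test; process-enriched
    genes are the up-DEGs and soma-enriched genes the down-DEGs under the
    DEG rule.  Restricting to ramified cells maximizes process area
    relative to the soma.
    """
    cells = [c for c in ramified_cells if c in soma_counts.index]
    if not cells:
        raise ValueError("no ramified cells available")
    soma = soma_counts.loc[cells]
    proc = process_counts.loc[cells]
    keep = (soma.sum(axis=1) > 0) & (proc.sum(axis=1) > 0)
    soma, proc = soma.loc[keep], proc.loc[keep]
    soma_ln = lognormalize(soma)
    proc_ln = lognormalize(proc)
    proc_ln.index = [f"{c}|process" for c in proc_ln.index]
    soma_ln.index = [f"{c}|soma" for c in soma_ln.index]
    stacked = pd.concat([proc_ln, soma_ln])
    de = mww_de(stacked, list(proc_ln.index), list(soma_ln.index), alpha=alpha)
    return EnrichedGeneSets(
        soma_enriched=de.down,
        process_enriched=de.up,
        cells_used=list(soma.index),
        de=de,
    )


# ---------------------------------------------------------------------------
# tau specificity
# ---------------------------------------------------------------------------

@dataclass
class TauResult:
    """Tau specificity of one gene across cell types at two levels."""

    tau_class: float
    tau_subclass: float
    argmax_type: Optional[str]
    category: str  # specific-to-target | ubiquitous | other


def tau(expression: Sequence[float]) -> float:
    """Tau specificity index: sum(1 - x_i / max(x)) / (N - 1).

    0 for perfectly uniform expression, 1 for single-type expression;
    NaN for an all-zero profile.
    """
    x = np.asarray(expression, dtype=float)
    if len(x) < 2:
        raise ValueError("tau needs at least 2 cell types")
    m = x.max()
    if m <= 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def tau_specificity(
    class_means: pd.Series,
    subclass_means: pd.Series,
    target_type: str,
    specific_threshold: float = 0.85,
    ubiquitous_threshold: float = 0.80,
) -> TauResult:
    """Classify one gene by tau at class and subclass level.

    specific-to-target iff subclass tau >= 0.85 with the subclass argmax
    being the target type; ubiquitous iff tau < 0.80 at both levels;
    otherwise (or for an all-zero gene) other.
    """
    t_class = tau(class_means.to_numpy())
    t_sub = tau(subclass_means.to_numpy())
    if np.isnan(t_class) or np.isnan(t_sub):
        return TauResult(t_class, t_sub, None, "other")
    argmax_type = str(subclass_means.idxmax())
    if t_sub >= specific_threshold and argmax_type == target_type:
        cat = "specific-to-target"
    elif t_class < ubiquitous_threshold and t_sub < ubiquitous_threshold:
        cat = "ubiquitous"
    else:
        cat = "other"
    return TauResult(t_class, t_sub, argmax_type, cat)


# ---------------------------------------------------------------------------
# gene-set scoring
# ---------------------------------------------------------------------------

def score_gene_set(
    lognorm: pd.DataFrame,
    gene_set: Sequence[str],
    seed: int,
    n_bins: int = 25,
    n_controls: int = 50,
) -> pd.Series:
    """Expression-matched control-gene score per cell.

    Mean expression of the gene set minus the mean of a seeded control
    set: panel genes are binned by mean expression into ``n_bins``
    equal-size bins and, for each set gene, ``n_controls`` controls are
    sampled (with replacement) from its bin.
    """
    genes = [g for g in gene_set if g in lognorm.columns]
    if not genes:
        raise ValueError("gene set is empty or absent from the panel")
    rng = stage_rng(seed, "score_gene_set")
    means = lognorm.mean(axis=0)
    order = means.rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(means)), labels=False)
    controls: list[str] = []
    for g in genes:
        pool = means.index[bins == bins[g]]
        controls.extend(rng.choice(pool, size=n_controls, replace=True))
    return lognorm[genes].mean(axis=1) - lognorm[list(controls)].mean(axis=1)
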