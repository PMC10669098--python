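"""QC filtering, library-size normalization and cluster marker detection.

QC removes lowly covered genes first, then cells by expressed-gene count and
mitochondrial fraction. Normalization is the standard log1p of library-size
scaled counts. Markers are found per subtype vs the rest with a two-sided
tie-corrected Wilcoxon rank-sum test on the normalized layer; both BH and
Bonferroni adjustments are reported and the configured one is filtered on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyResultError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Gene/cell quality-control cutoffs.

    Defaults: drop genes expressed by fewer than 50 cells, cells with fewer
    than 200 or more than 6000 expressed genes, and cells with more than 20%
    of counts on mitochondrial (``MT-``-prefixed) genes.
    """

    min_cells_per_gene: int = 50
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 6000
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValidationError("need 0 < min_genes_per_cell < max_genes_per_cell")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must be in (0, 1]")


def qc_filter(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    t: QcThresholds | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Apply gene then cell QC filters; returns (matrix, annotation, report)."""
    t = t or QcThresholds()
    counts = m.counts

    cells_per_gene = (counts > 0).sum(axis=1).A1
    gene_keep = cells_per_gene >= t.min_cells_per_gene
    m2 = m.subset_genes(gene_keep)

    genes_per_cell = (m2.counts > 0).sum(axis=0).A1
    total = m2.counts.sum(axis=0).A1.astype(float)
    is_mito = np.asarray(m2.genes.str.upper().str.startswith(t.mito_prefix.upper()))
    mito = m2.counts[is_mito, :].sum(axis=0).A1.astype(float) if is_mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    low = genes_per_cell < t.min_genes_per_cell
    high = genes_per_cell > t.max_genes_per_cell
    mito_bad = mito_frac > t.max_mito_fraction
    cell_keep = ~(low | high | mito_bad)
    if not cell_keep.any():
        raise EmptyResultError("QC removed every cell")

    m3 = m2.subset_obs(cell_keep)
    kept = set(m3.obs)
    ann_out = ann[ann["cell_id"].isin(kept)].reset_index(drop=True)
    report = {
        "genes_removed_min_cells": int((~gene_keep).sum()),
        "cells_removed_low_genes": int(low.sum()),
        "cells_removed_high_genes": int(high.sum()),
        "cells_removed_mito": int(mito_bad.sum()),
        "genes_kept": m3.shape[0],
        "cells_kept": m3.shape[1],
    }
    return m3, ann_out, report


def normalize(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Attach normalized layer log(1 + scale * count / cell_total).

    All-zero cells stay all-zero (with a warning) rather than dividing by 0.
    """
    total = m.counts.sum(axis=0).A1.astype(float)
    zero_cells = total == 0
    if zero_cells.any():
        logger.warning("%d all-zero cells left unnormalized", int(zero_cells.sum()))
    inv = np.where(zero_cells, 0.0, scale / np.maximum(total, 1e-300))
    norm = m.counts.astype(float) @ sp.diags(inv)
    norm.data = np.log1p(norm.data)
    return ExpressionMatrix(
        genes=m.genes, obs=m.obs, counts=m.counts, normalized=sp.csr_matrix(norm)
    )


def find_markers(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    min_pct: float = 0.5,
    min_lfc: float = 0.0,
    q_max: float = 0.05,
    adjust_on: str = "q_bh",
) -> pd.DataFrame:
    """Per-subtype marker genes by Wilcoxon rank-sum on normalized expression.

    For each subtype with >= 3 cells, each gene is tested in-cluster vs all
    other cells (two-sided, mid-ranks, tie-corrected normal approximation).
    log_fc = ln(mean expm1(norm)+1 in) - ln(mean expm1(norm)+1 out). Genes are
    retained when pct_in >= min_pct, log_fc > min_lfc and the configured
    adjusted q <= q_max; adjustments are computed per cluster over all genes.
    """
    if m.normalized is None:
        raise ValidationError("find_markers requires a normalized layer")
    if adjust_on not in ("q_bh", "q_bonf"):
        raise ValidationError("adjust_on must be 'q_bh' or 'q_bonf'")
    ann = ann.set_index("cell_id").loc[list(m.obs)]
    subtype = ann["subtype"].to_numpy()
    labels = [s for s in pd.unique(subtype)]
    usable = []
    for s in sorted(labels):
        n = int((subtype == s).sum())
        if n < 3:
            logger.warning("skipping subtype %s with %d cells (< 3)", s, n)
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValidationError("need >= 2 subtypes with >= 3 cells each")

    X = np.asarray(m.normalized.todense())  # genes x cells
    expm1 = np.expm1(X)
    frames = []
    for s in usable:
        in_mask = subtype == s
        xin, xout = X[:, in_mask], X[:, ~in_mask]
        res = stats.mannwhitneyu(xin, xout, axis=1, alternative="two-sided", method="asymptotic")
        # constant genes (all ties) have zero rank variance -> no evidence
        p_raw = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
        pct_in = (xin > 0).mean(axis=1)
        pct_out = (xout > 0).mean(axis=1)
        log_fc = np.log(expm1[:, in_mask].mean(axis=1) + 1) - np.log(
            expm1[:, ~in_mask].mean(axis=1) + 1
        )
        q_bh = multipletests(p_raw, method="fdr_bh")[1]
        q_bonf = multipletests(p_raw, method="bonferroni")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cluster": s,
                    "gene": m.genes,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "log_fc": log_fc,
                    "p_raw": p_raw,
                    "q_bh": q_bh,
                    "q_bonf": q_bonf,
                }
            )
        )
    deg = pd.concat(frames, ignore_index=True)
    keep = (
        (deg["pct_in"] >= min_pct)
        & (deg["log_fc"] > min_lfc)
        & (deg[adjust_on] <= q_max)
    )
    out = deg[keep].copy()
    out = out.sort_values(
        ["cluster", "log_fc"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return out


def top_markers(deg: pd.DataFrame, n: int = 10) -> dict[str, list[str]]:
    """Top-n marker genes per cluster from a find_markers table."""
    return {
        cluster: grp.sort_values("log_fc", ascending=False, kind="mergesort")["gene"]
        .head(n)
        .tolist()
        for cluster, grp in deg.groupby("cluster")
    }
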