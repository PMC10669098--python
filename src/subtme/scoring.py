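"""Three-level subTME scoring and single-sample gene-set enrichment.

Signature genes for a cell subtype are scored by specificity,

    Sgi = 1 - Qgi / Pgi,

where Pgi is the fraction of the subtype's cells "highly expressing" gene gi
(normalized value above the lower quartile of the subtype's nonzero values)
and Qgi the fraction of all other cells above the same threshold. Genes with
Sgi > 0.7 form the subtype signature and Ssubj is their mean Sgi. The
per-sample module score is

    SsubTME = (sum_j Ssubj * Psubj) / n,

with Psubj the subtype's relative abundance in the sample. Bulk samples are
scored with ssGSEA over each subtype's top DEGs and averaged within a module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import SubTMEModule
from .exceptions import EmptyResultError, EmptySignatureError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SsgseaParams:
    """Rank-weight exponent and normalization mode for ssGSEA.

    "range" normalization is the conventional cohort-level rescale: scores
    are divided by (max - min) over the whole score matrix, so it applies in
    :func:`ssgsea_matrix` and leaves a single profile's statistic unscaled.
    """

    alpha: float = 0.25
    normalization: str = "range"  # "range" or "none"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.normalization not in ("range", "none"):
            raise ValidationError("normalization must be 'range' or 'none'")


@dataclass
class ExpressingFraction:
    p: float  # Pgi: in-subtype fraction above threshold
    q: float  # Qgi: out-of-subtype fraction above the same threshold
    threshold: float
    eligible: bool


@dataclass
class SubtypeSignature:
    subtype: str
    genes: list[str]
    gene_scores: pd.DataFrame  # gene, Pgi, Qgi, Sgi, selected (all eligible genes)
    s_subj: float = field(init=False)

    def __post_init__(self) -> None:
        sel = self.gene_scores[self.gene_scores["selected"]]
        self.s_subj = float(sel["Sgi"].mean()) if len(sel) else float("nan")


def _expression_rows(m: ExpressionMatrix) -> np.ndarray:
    return np.asarray(m.layer("normalized").todense())


def expressing_fraction(
    m: ExpressionMatrix, ann: pd.DataFrame, gene: str, subtype: str
) -> ExpressingFraction:
    """(Pgi, Qgi) for one gene and subtype on the normalized layer.

    The threshold is the linear-interpolation lower quartile of the gene's
    nonzero values within the subtype; a gene with no nonzero value in the
    subtype is ineligible (Pgi = 0).
    """
    if gene not in m.genes:
        raise ValidationError(f"gene {gene!r} not in matrix")
    labels = ann.set_index("cell_id").loc[list(m.obs), "subtype"].to_numpy()
    in_mask = labels == subtype
    if not in_mask.any():
        raise ValidationError(f"subtype {subtype!r} has no cells")
    x = np.asarray(m.layer("normalized")[m.genes.get_loc(gene), :].todense()).ravel()
    return _fraction_from_values(x[in_mask], x[~in_mask])


def _fraction_from_values(xin: np.ndarray, xout: np.ndarray) -> ExpressingFraction:
    nz = xin[xin > 0]
    if nz.size == 0:
        return ExpressingFraction(p=0.0, q=float("nan"), threshold=float("nan"), eligible=False)
    t = float(np.quantile(nz, 0.25))  # linear interpolation between order stats
    p = float((xin > t).mean())
    q = float((xout > t).mean()) if xout.size else 0.0
    return ExpressingFraction(p=p, q=q, threshold=t, eligible=p > 0)


def signature_gene_score(p: float, q: float) -> float:
    """Sgi = 1 - Qgi/Pgi; requires Pgi > 0 (ineligible genes are excluded)."""
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValidationError("Pgi and Qgi must lie in [0, 1]")
    if p == 0:
        raise ValidationError("Sgi undefined for Pgi = 0 (gene ineligible)")
    return 1.0 - q / p


def build_subtype_signature(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    subtype: str,
    s_min: float = 0.7,
    min_cells: int = 10,
) -> SubtypeSignature:
    """Score every eligible gene for a subtype and keep those with Sgi > s_min."""
    labels = ann.set_index("cell_id").loc[list(m.obs), "subtype"].to_numpy()
    in_mask = labels == subtype
    n_cells = int(in_mask.sum())
    if n_cells < min_cells:
        raise ValidationError(f"subtype {subtype!r} has {n_cells} cells (< {min_cells})")
    X = _expression_rows(m)
    rows = []
    for gi, gene in enumerate(m.genes):
        frac = _fraction_from_values(X[gi, in_mask], X[gi, ~in_mask])
        if not frac.eligible:
            continue
        s = signature_gene_score(frac.p, frac.q)
        rows.append({"gene": gene, "Pgi": frac.p, "Qgi": frac.q, "Sgi": s})
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise EmptySignatureError(f"no eligible gene for subtype {subtype!r}")
    scores["selected"] = scores["Sgi"] > s_min
    if not scores["selected"].any():
        raise EmptySignatureError(
            f"no gene passed Sgi > {s_min} for subtype {subtype!r}"
        )
    genes = scores.loc[scores["selected"], "gene"].tolist()
    return SubtypeSignature(subtype=subtype, genes=genes, gene_scores=scores)


def subtme_score(
    signatures: dict[str, SubtypeSignature] | dict[str, float],
    abundance: pd.DataFrame,
    module: SubTMEModule,
) -> pd.DataFrame:
    """Per-sample SsubTME = mean over module subtypes of Ssubj * Psubj.

    Subtypes with missing abundance in a sample are skipped with n reduced
    (flagged); a sample with every Psubj missing gets a missing score.
    """
    s_subj = {
        s: (sig.s_subj if isinstance(sig, SubtypeSignature) else float(sig))
        for s, sig in signatures.items()
    }
    for s in module.member_subtypes:
        if s not in s_subj:
            raise ValidationError(f"module subtype {s!r} lacks a signature")
        if s not in abundance.columns:
            raise ValidationError(f"module subtype {s!r} lacks an abundance column")
    rows = []
    for sample in abundance.index:
        terms = []
        skipped = 0
        for s in module.member_subtypes:
            p = abundance.loc[sample, s]
            if pd.isna(p):
                skipped += 1
                continue
            terms.append(s_subj[s] * float(p))
        score = float(np.mean(terms)) if terms else float("nan")
        rows.append(
            {
                "module_id": module.module_id,
                "sample_id": sample,
                "score": score,
                "n_subtypes_used": len(terms),
                "n_subtypes_skipped": skipped,
            }
        )
    return pd.DataFrame(rows)


def ssgsea_score(
    expr: pd.Series, gene_set, params: SsgseaParams | None = None
) -> float:
    """ssGSEA enrichment of one expression profile against one gene set.

    Genes are ranked by expression descending (ties broken by gene name
    ascending); the statistic is the sum over positions of the weighted
    in-set ECDF minus the out-set ECDF, with in-set weights rank^alpha
    (top gene has rank N). Range normalization is cohort-level (see
    :func:`ssgsea_matrix`) and does not alter a single profile's statistic.
    """
    params = params or SsgseaParams()
    gene_set = {str(g) for g in gene_set}
    if not gene_set:
        raise ValidationError("empty gene set")
    expr = expr.astype(float)
    in_universe = expr.index.isin(gene_set)
    if not in_universe.any():
        raise ValidationError("gene set does not overlap the expression universe")
    if in_universe.all():
        raise ValidationError("gene set covers the whole universe")

    order = np.lexsort((expr.index.to_numpy(), -expr.to_numpy()))
    in_set = in_universe[order]
    n = len(expr)
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank N
    w = ranks**params.alpha
    w_in = np.where(in_set, w, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    step_out = np.where(in_set, 0.0, 1.0)
    cdf_out = np.cumsum(step_out) / step_out.sum()
    diff = cdf_in - cdf_out
    return float(diff.sum())


def ssgsea_matrix(
    expr: pd.DataFrame, gene_sets: dict[str, list[str]], params: SsgseaParams | None = None
) -> pd.DataFrame:
    """ssGSEA scores for every (gene set, sample) of a genes x samples frame.

    With range normalization all scores are divided by (max - min) over the
    whole score matrix — a single global rescale that preserves every
    within- and between-sample ordering.
    """
    params = params or SsgseaParams()
    out = pd.DataFrame(
        {
            name: {col: ssgsea_score(expr[col], genes, params) for col in expr.columns}
            for name, genes in gene_sets.items()
        }
    ).T
    if params.normalization == "range":
        rng = float(out.to_numpy().max() - out.to_numpy().min())
        if rng > 0:
            out = out / rng
    return out


def bulk_subtme_score(
    bulk: ExpressionMatrix,
    module_signatures: dict[str, list[str]],
    params: SsgseaParams | None = None,
    method: str = "ssgsea",
) -> pd.DataFrame:
    """Per-sample subTME score for bulk data from per-subtype gene sets.

    Each subtype's signature (e.g. its top-10 DEGs) is scored per sample —
    ssGSEA by default, mean z-score as the alternative — and the scores are
    averaged across the module's subtypes. Signatures overlapping the bulk
    genes by < 2 genes are skipped with a warning; all skipped is an error.
    """
    if method not in ("ssgsea", "mean_z"):
        raise ValidationError("method must be 'ssgsea' or 'mean_z'")
    expr = bulk.to_frame("normalized")
    usable = {}
    for subtype, genes in module_signatures.items():
        present = [g for g in genes if g in expr.index]
        if len(present) < 2:
            logger.warning(
                "signature for %s overlaps bulk genes by %d (< 2); skipped",
                subtype,
                len(present),
            )
            continue
        usable[subtype] = present
    if not usable:
        raise EmptyResultError("no signature overlaps the bulk gene universe")
    if method == "mean_z":
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1).replace(0, np.nan), axis=0)
    rows = []
    for sample in bulk.obs:
        per_sig = []
        for subtype in sorted(usable):
            if method == "ssgsea":
                per_sig.append(ssgsea_score(expr[sample], usable[subtype], params))
            else:
                per_sig.append(float(z.loc[usable[subtype], sample].mean()))
        rows.append({"sample_id": sample, "score": float(np.mean(per_sig)), "n_signatures": len(per_sig)})
    return pd.DataFrame(rows)
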