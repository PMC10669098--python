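"""Ligand-receptor interaction inference within a subTME.

The interaction score for (sender subtype, receiver subtype, L-R pair) is the
mean of the ligand summary (mean normalized expression in sender cells;
multi-component complexes take the minimum over component means) and the
receptor summary in receiver cells, gated to 0 when any component is
expressed in less than a minimum fraction of its side's cells. Significance
is assessed by shuffling subtype labels; specificity across subtype pairs by
the coefficient of variation of a pair's scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .group_stats import adjust_batch
from .io import ExpressionMatrix, LRDatabase, LRPair

logger = logging.getLogger(__name__)

MIN_CELLS_PER_SUBTYPE = 10


@dataclass
class _Workspace:
    """Dense expression slices and label codes for score computation."""

    expr: np.ndarray  # used genes x cells, normalized
    expressed: np.ndarray  # same shape, expr > 0
    gene_index: dict[str, int]
    codes: np.ndarray  # per-cell subtype code
    subtypes: list[str]


def _prepare(m: ExpressionMatrix, ann: pd.DataFrame, pairs: list[LRPair]):
    genes_needed = sorted({g for p in pairs for g in (*p.ligand, *p.receptor)})
    missing = [g for g in genes_needed if g not in m.genes]
    usable = []
    for p in pairs:
        if any(g not in m.genes for g in (*p.ligand, *p.receptor)):
            logger.warning("pair %s skipped: missing gene(s)", p.pair_id)
        else:
            usable.append(p)
    genes_used = sorted({g for p in usable for g in (*p.ligand, *p.receptor)})
    sub = m.subset_genes(genes_used) if genes_used else None
    labels = ann.set_index("cell_id").loc[list(m.obs), "subtype"]
    subtypes = sorted(labels.value_counts()[lambda s: s >= MIN_CELLS_PER_SUBTYPE].index)
    codes = pd.Categorical(labels, categories=subtypes).codes.astype(np.int64)
    expr = np.asarray(sub.layer("normalized").todense()) if sub is not None else np.empty((0, len(m.obs)))
    return _Workspace(
        expr=expr,
        expressed=expr > 0,
        gene_index={g: i for i, g in enumerate(genes_used)},
        codes=codes,
        subtypes=subtypes,
    ), usable, missing


def _group_stats(ws: _Workspace, codes: np.ndarray):
    """Per-subtype mean expression and expressing fraction for used genes."""
    k = len(ws.subtypes)
    onehot = np.zeros((k, len(codes)))
    valid = codes >= 0
    onehot[codes[valid], np.flatnonzero(valid)] = 1.0
    sizes = onehot.sum(axis=1)
    sizes_safe = np.maximum(sizes, 1.0)
    means = (onehot @ ws.expr.T) / sizes_safe[:, None]  # k x genes
    fracs = (onehot @ ws.expressed.T) / sizes_safe[:, None]
    return means, fracs


def _scores_from_stats(
    pairs: list[LRPair],
    ws: _Workspace,
    means: np.ndarray,
    fracs: np.ndarray,
    min_expr_frac: float,
) -> np.ndarray:
    """Score array of shape (n_pairs, k senders, k receivers)."""
    k = len(ws.subtypes)
    out = np.zeros((len(pairs), k, k))
    for pi, p in enumerate(pairs):
        li = [ws.gene_index[g] for g in p.ligand]
        ri = [ws.gene_index[g] for g in p.receptor]
        lig = means[:, li].min(axis=1)  # per sender subtype
        rec = means[:, ri].min(axis=1)  # per receiver subtype
        lig_gate = (fracs[:, li] >= min_expr_frac).all(axis=1)
        rec_gate = (fracs[:, ri] >= min_expr_frac).all(axis=1)
        score = 0.5 * (lig[:, None] + rec[None, :])
        score *= lig_gate[:, None] * rec_gate[None, :]
        out[pi] = score
    return out


def interaction_score(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    pair: LRPair,
    sender: str,
    receiver: str,
    min_expr_frac: float = 0.1,
) -> float:
    """Mean-of-means interaction score for one pair and subtype pair."""
    ws, usable, _ = _prepare(m, ann, [pair])
    if not usable:
        raise ValidationError(f"pair {pair.pair_id}: gene(s) missing from matrix")
    for s in (sender, receiver):
        if s not in ws.subtypes:
            raise ValidationError(
                f"subtype {s!r} absent or below {MIN_CELLS_PER_SUBTYPE} cells"
            )
    means, fracs = _group_stats(ws, ws.codes)
    scores = _scores_from_stats(usable, ws, means, fracs, min_expr_frac)
    si, ri = ws.subtypes.index(sender), ws.subtypes.index(receiver)
    return float(scores[0, si, ri])


def permutation_test(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    pairs: LRDatabase | list[LRPair],
    n_perm: int = 1000,
    seed: int = 0,
    min_expr_frac: float = 0.1,
) -> pd.DataFrame:
    """Label-permutation significance for all pairs over all subtype pairs.

    The null shuffles subtype labels among the participating cells; the
    add-one estimator p = (1 + #{null >= observed}) / (1 + n_perm) avoids
    p = 0, and observed score 0 gets p = 1 by convention. BH q-values are
    computed over all pair x subtype-pair tests.
    """
    pairs = list(pairs)
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse")
    ws, usable, _ = _prepare(m, ann, pairs)
    if len(ws.subtypes) < 2:
        raise ValidationError("need >= 2 subtypes with enough cells")
    if not usable:
        raise ValidationError("no pair has all genes present")
    rng = np.random.default_rng(seed)
    means, fracs = _group_stats(ws, ws.codes)
    obs = _scores_from_stats(usable, ws, means, fracs, min_expr_frac)
    exceed = np.zeros_like(obs)
    participating = np.flatnonzero(ws.codes >= 0)
    for _ in range(n_perm):
        perm_codes = ws.codes.copy()
        perm_codes[participating] = ws.codes[participating][
            rng.permutation(len(participating))
        ]
        pm, pf = _group_stats(ws, perm_codes)
        null = _scores_from_stats(usable, ws, pm, pf, min_expr_frac)
        exceed += null >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[obs == 0] = 1.0

    k = len(ws.subtypes)
    rows = []
    for pi, pr in enumerate(usable):
        for si in range(k):
            for ri in range(k):
                rows.append(
                    {
                        "pair_id": pr.pair_id,
                        "sender": ws.subtypes[si],
                        "receiver": ws.subtypes[ri],
                        "score": obs[pi, si, ri],
                        "p": p[pi, si, ri],
                    }
                )
    res = pd.DataFrame(rows)
    res["q"] = adjust_batch(res["p"].to_numpy(), "bh")
    return res


def count_interactions(scores: pd.DataFrame, alpha: float = 0.05):
    """Counts of significant interactions per ordered (sender, receiver) pair.

    Returns (directed count matrix, symmetrized total matrix).
    """
    subtypes = sorted(set(scores["sender"]) | set(scores["receiver"]))
    directed = pd.DataFrame(0, index=subtypes, columns=subtypes, dtype=int)
    sig = scores[scores["p"] < alpha]
    for (s, r), grp in sig.groupby(["sender", "receiver"]):
        directed.loc[s, r] = len(grp)
    total = directed + directed.T
    # self-pairs would be double-counted by the symmetrization
    for s in subtypes:
        total.loc[s, s] = directed.loc[s, s]
    return directed, total


def subsample_cells(ann: pd.DataFrame, per_subtype: int, seed: int = 0) -> pd.DataFrame:
    """Uniform per-subtype subsample without replacement (deterministic)."""
    if per_subtype < 10:
        raise ValidationError("per_subtype must be >= 10")
    rng = np.random.default_rng(seed)
    kept = []
    for subtype in sorted(ann["subtype"].unique()):
        cells = ann.loc[ann["subtype"] == subtype, "cell_id"].sort_values().to_numpy()
        if len(cells) > per_subtype:
            cells = rng.choice(cells, size=per_subtype, replace=False)
        kept.extend(cells)
    kept_set = set(kept)
    return ann[ann["cell_id"].isin(kept_set)].reset_index(drop=True)


def specificity_filter(scores: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """CV-based specificity ranking of the top-scoring pairs per subtype.

    For each cell subtype, its top_n highest-scoring interactions (as sender
    or receiver; ties broken by pair_id) are retained; each retained pair's
    coefficient of variation (population SD / mean, zeros included) is taken
    over its scores across all subtype pairs. Sorted by cv descending.
    """
    if scores[["sender", "receiver"]].drop_duplicates().shape[0] < 2:
        raise ValidationError("need scores over >= 2 subtype pairs")
    subtypes = sorted(set(scores["sender"]) | set(scores["receiver"]))
    retained: set[str] = set()
    for s in subtypes:
        mine = scores[(scores["sender"] == s) | (scores["receiver"] == s)]
        mine = mine.sort_values(
            ["score", "pair_id"], ascending=[False, True], kind="mergesort"
        )
        retained.update(mine.head(top_n)["pair_id"])
    rows = []
    for pair_id in sorted(retained):
        vec = scores.loc[scores["pair_id"] == pair_id]
        v = vec["score"].to_numpy(dtype=float)
        mean = v.mean()
        if mean == 0:
            logger.warning("pair %s has mean score 0; cv undefined, dropped", pair_id)
            continue
        cv = v.std(ddof=0) / mean
        best = vec.sort_values(
            ["score", "sender", "receiver"], ascending=[False, True, True], kind="mergesort"
        ).iloc[0]
        rows.append(
            {
                "pair_id": pair_id,
                "cv": cv,
                "top_sender": best["sender"],
                "top_receiver": best["receiver"],
                "top_score": best["score"],
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["cv", "pair_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
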