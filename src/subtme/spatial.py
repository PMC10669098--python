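"""Spot-level signature scoring and co-localization analysis.

Spots are treated as a plain observation matrix; two cell-type signatures
(or a gene pair) are scored per spot with ssGSEA (or normalized expression)
and co-localization is the Spearman correlation of the two score vectors
across spots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import ExpressionMatrix
from .preprocess import normalize
from .scoring import SsgseaParams, ssgsea_score


def _ensure_normalized(spots: ExpressionMatrix) -> ExpressionMatrix:
    return spots if spots.normalized is not None else normalize(spots)


def spot_signature_scores(
    spots: ExpressionMatrix,
    coords: pd.DataFrame,
    sig_a,
    sig_b,
    params: SsgseaParams | None = None,
    names: tuple[str, str] = ("score_a", "score_b"),
) -> pd.DataFrame:
    """Per-spot ssGSEA scores of two signatures; one row per spot."""
    spots = _ensure_normalized(spots)
    for label, sig in (("sig_a", sig_a), ("sig_b", sig_b)):
        overlap = sum(g in spots.genes for g in set(sig))
        if overlap < 2:
            raise ValidationError(f"{label} overlaps spot genes by {overlap} (< 2)")
    expr = spots.to_frame("normalized")
    coords = coords.set_index("spot_id").loc[list(spots.obs)]
    rows = []
    for spot in spots.obs:
        rows.append(
            {
                "spot_id": spot,
                "x": coords.loc[spot, "x"],
                "y": coords.loc[spot, "y"],
                names[0]: ssgsea_score(expr[spot], sig_a, params),
                names[1]: ssgsea_score(expr[spot], sig_b, params),
            }
        )
    return pd.DataFrame(rows)


def colocalization(
    scores: pd.DataFrame, cols: tuple[str, str] = ("score_a", "score_b")
) -> tuple[float, float]:
    """Spearman correlation of two per-spot score columns (r, p)."""
    a = scores[cols[0]].to_numpy(dtype=float)
    b = scores[cols[1]].to_numpy(dtype=float)
    if len(a) < 10:
        raise ValidationError("need >= 10 spots")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("constant score vector; correlation undefined")
    r, p = stats.spearmanr(a, b)
    return float(r), float(p)


def gene_pair_coexpression(
    spots: ExpressionMatrix, gene_a: str, gene_b: str
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation and per-spot co-expression flags for a gene pair.

    A spot co-expresses the pair when both normalized values exceed 0.
    """
    spots = _ensure_normalized(spots)
    for g in (gene_a, gene_b):
        if g not in spots.genes:
            raise ValidationError(f"gene {g!r} absent from spots")
    a = np.asarray(spots.normalized[spots.genes.get_loc(gene_a), :].todense()).ravel()
    b = np.asarray(spots.normalized[spots.genes.get_loc(gene_b), :].todense()).ravel()
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("constant expression vector; correlation undefined")
    r, p = stats.spearmanr(a, b)
    flags = pd.DataFrame(
        {
            "spot_id": list(spots.obs),
            gene_a: a,
            gene_b: b,
            "coexpressed": (a > 0) & (b > 0),
        }
    )
    return float(r), float(p), flags
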