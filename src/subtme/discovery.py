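"""subTME discovery: relative abundances, co-infiltration edges, modules.

The relative abundance of a cell subtype in a sample is its cell count
divided by the cell count of its parent major type in that sample (missing,
not zero, when the parent type is absent). Subtype pairs are correlated
across tumor samples by Spearman's rank correlation, and the full
correlation matrix is clustered (average linkage on 1 - r) into modules of
co-infiltrating subtypes — the tumor-microenvironment subtypes. The display
thresholds r > 0.3 and FDR < 0.05 are retained as a post-hoc edge-quality
flag rather than a hard pre-filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .exceptions import EmptyResultError, ValidationError
from .group_stats import adjust_batch, compare_groups

logger = logging.getLogger(__name__)


@dataclass
class SubTMEModule:
    module_id: str
    member_subtypes: list[str]
    weakly_assigned: list[str] = field(default_factory=list)
    label: str = ""


def relative_abundance(ann: pd.DataFrame, tissue_filter: str = "tumor") -> pd.DataFrame:
    """Samples x subtypes table of within-major-type relative abundances.

    tissue_filter is 'tumor', 'normal' or 'both'. Cells of a subtype are
    divided by cells of its parent major type in the same sample; samples
    lacking the parent type entirely get NaN for its subtypes.
    """
    if tissue_filter not in ("tumor", "normal", "both"):
        raise ValidationError("tissue_filter must be tumor, normal or both")
    sub = ann if tissue_filter == "both" else ann[ann["tissue"] == tissue_filter]
    if sub.empty:
        raise EmptyResultError(f"no samples pass tissue filter {tissue_filter!r}")
    parent = sub.drop_duplicates("subtype").set_index("subtype")["major_type"]
    counts = sub.groupby(["sample_id", "subtype"], sort=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=sorted(parent.index), fill_value=0)
    major_tot = {}
    for major in parent.unique():
        members = parent.index[parent == major]
        major_tot[major] = counts[members].sum(axis=1)
    tab = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for s in counts.columns:
        tot = major_tot[parent[s]]
        tab[s] = np.where(tot > 0, counts[s] / tot.replace(0, np.nan), np.nan)
    tab.index.name = "sample_id"
    return tab


def correlate_abundance(tab: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """Pairwise Spearman correlation of subtype abundances across samples.

    Pairwise-complete: a pair is tested on samples where both abundances are
    defined, and skipped (logged) below min_samples. BH q-values are computed
    over all tested pairs.
    """
    subtypes = sorted(tab.columns)
    if len(subtypes) < 3:
        raise ValidationError("need >= 3 subtypes to correlate")
    rows = []
    for i, a in enumerate(subtypes):
        for b in subtypes[i + 1 :]:
            ok = tab[a].notna() & tab[b].notna()
            n = int(ok.sum())
            if n < min_samples:
                logger.warning("skipping pair (%s, %s): %d complete samples", a, b, n)
                continue
            r, p = stats.spearmanr(tab.loc[ok, a], tab.loc[ok, b])
            if np.isnan(r):  # constant vector
                r, p = 0.0, 1.0
            rows.append({"subtype_a": a, "subtype_b": b, "r": r, "p_raw": p, "n": n})
    edges = pd.DataFrame(rows)
    if edges.empty:
        raise EmptyResultError("no subtype pair had enough complete samples")
    edges["q"] = adjust_batch(edges["p_raw"].to_numpy(), "bh")
    return edges


def _corr_matrix(edges: pd.DataFrame) -> pd.DataFrame:
    subtypes = sorted(set(edges["subtype_a"]) | set(edges["subtype_b"]))
    r = pd.DataFrame(np.eye(len(subtypes)), index=subtypes, columns=subtypes)
    for row in edges.itertuples(index=False):
        r.loc[row.subtype_a, row.subtype_b] = row.r
        r.loc[row.subtype_b, row.subtype_a] = row.r
    return r


def build_modules(
    edges: pd.DataFrame,
    k: int | None = None,
    r_pos: float = 0.3,
    q_max: float = 0.05,
) -> list[SubTMEModule]:
    """Cluster the subtype correlation matrix into co-infiltration modules.

    Average-linkage agglomerative clustering on distance 1 - r over the full
    (unthresholded) correlation matrix. Unless k is given, the module count
    maximizes the mean silhouette over k in [2, min(10, n-1)]; silhouette
    ties resolve to the larger k (maximal fragmentation). Subtypes without a
    within-module edge satisfying r > r_pos and q < q_max are flagged weakly
    assigned.
    """
    r = _corr_matrix(edges)
    subtypes = list(r.index)
    n = len(subtypes)
    if k is not None and k > n:
        raise ValidationError(f"k={k} exceeds {n} subtypes")
    dist = (1.0 - r.to_numpy())
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)

    def _cut(kk: int) -> np.ndarray:
        if kk == 1:
            return np.zeros(n, dtype=int)
        model = AgglomerativeClustering(n_clusters=kk, metric="precomputed", linkage="average")
        return model.fit_predict(dist)

    if k is None:
        best_k, best_s = None, -np.inf
        for kk in range(2, min(10, n - 1) + 1):
            lab = _cut(kk)
            s = silhouette_score(dist, lab, metric="precomputed")
            if s >= best_s:  # ties -> larger k
                best_k, best_s = kk, s
        k = best_k
    labels = _cut(k)

    # q lookup for the edge-quality flag
    qmap: dict[tuple[str, str], tuple[float, float]] = {}
    for row in edges.itertuples(index=False):
        qmap[(row.subtype_a, row.subtype_b)] = (row.r, row.q)
        qmap[(row.subtype_b, row.subtype_a)] = (row.r, row.q)

    modules = []
    for cl in sorted(set(labels)):
        members = sorted(s for s, l in zip(subtypes, labels) if l == cl)
        weak = []
        for s in members:
            ok = any(
                qmap.get((s, t), (0.0, 1.0))[0] > r_pos
                and qmap.get((s, t), (0.0, 1.0))[1] < q_max
                for t in members
                if t != s
            )
            if not ok:
                weak.append(s)
        modules.append(
            SubTMEModule(
                module_id=f"subTME{cl + 1}",
                member_subtypes=members,
                weakly_assigned=weak,
            )
        )
    modules.sort(key=lambda m: m.member_subtypes[0])
    for i, mod in enumerate(modules, start=1):
        mod.module_id = f"subTME{i}"
    return modules


def modules_to_frame(modules: list[SubTMEModule]) -> pd.DataFrame:
    rows = []
    for mod in modules:
        for s in mod.member_subtypes:
            rows.append(
                {
                    "module_id": mod.module_id,
                    "subtype": s,
                    "weakly_assigned": s in mod.weakly_assigned,
                }
            )
    return pd.DataFrame(rows)


def compare_module_presence(score_by_sample: pd.Series, tissue_labels: pd.Series) -> dict:
    """Tumor vs normal comparison of a per-sample module score.

    Returns the two-sided Wilcoxon rank-sum p and a direction call at
    alpha = 0.05 ('tumor-enriched', 'normal-enriched' or 'n.s.').
    """
    common = score_by_sample.index.intersection(tissue_labels.index)
    scores = score_by_sample.loc[common]
    tissue = tissue_labels.loc[common]
    for grp in ("tumor", "normal"):
        if (tissue == grp).sum() == 0:
            raise ValidationError(f"no {grp} samples")
    res = compare_groups(scores.to_numpy(), tissue.to_numpy())
    t_med = float(scores[tissue == "tumor"].median())
    n_med = float(scores[tissue == "normal"].median())
    if res.p < 0.05:
        direction = "tumor-enriched" if t_med > n_med else "normal-enriched"
    else:
        direction = "n.s."
    return {
        "p": res.p,
        "direction": direction,
        "median_tumor": t_med,
        "median_normal": n_med,
    }
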