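"""subTME-marker prognostic modeling.

Univariate Cox screen over marker genes (partial likelihood with Efron tie
handling), a linear risk score

    risk = sum_x Exp(mRNA_x) * coef_x,

median-split stratification into high/low risk groups, Kaplan-Meier curves
with a two-group log-rank test, and IPCW cumulative/dynamic time-dependent
ROC AUC. The published 11-gene colorectal-cancer subTME1 model ships as a
packaged fixture (``load_crc_subtme1_model``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Ordered gene list with matching log-hazard coefficients."""

    genes: list[str]
    coefs: np.ndarray

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if len(self.genes) != len(self.coefs) or len(self.genes) == 0:
            raise ValidationError("genes and coefs must align and be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in risk model")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "coef": self.coefs})


def load_risk_model(path) -> RiskModel:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "coef"} <= set(df.columns):
        raise ValidationError(f"{path}: risk model needs columns gene, coef")
    return RiskModel(genes=df["gene"].tolist(), coefs=df["coef"].to_numpy())


def load_crc_subtme1_model() -> RiskModel:
    """The published 11-gene colorectal-cancer subTME1 risk model."""
    ref = resources.files("subtme").joinpath("data/crc_subtme1_model.tsv")
    with resources.as_file(ref) as path:
        return load_risk_model(Path(path))


def univariate_cox(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    genes: list[str] | None = None,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene univariate Cox fits on a genes x samples expression frame.

    Returns (gene, coef, se, p, selected) with selected = p < p_max. Genes
    failing to converge (e.g. separation) are dropped with a warning.
    Requires >= 10 events.
    """
    if int(surv["event"].sum()) < 10:
        raise ValidationError("need >= 10 events for the Cox screen")
    genes = list(genes) if genes is not None else list(expr.index)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"genes absent from expression: {missing[:5]}")
    surv = surv.set_index("sample_id").loc[list(expr.columns)]
    rows = []
    for g in genes:
        df = pd.DataFrame(
            {
                "time": surv["time"].to_numpy(dtype=float),
                "event": surv["event"].to_numpy(dtype=int),
                "x": expr.loc[g].to_numpy(dtype=float),
            }
        )
        if df["x"].std() == 0:
            logger.warning("gene %s constant across samples; dropped", g)
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # non-convergence / separation
            logger.warning("gene %s dropped: %s", g, exc)
            continue
        rows.append(
            {
                "gene": g,
                "coef": float(cph.params_["x"]),
                "se": float(cph.standard_errors_["x"]),
                "p": float(cph.summary.loc["x", "p"]),
            }
        )
    fits = pd.DataFrame(rows)
    if not fits.empty:
        fits["selected"] = fits["p"] < p_max
    return fits


def risk_score(model: RiskModel, expr) -> pd.Series | float:
    """Linear risk score: sum of expression x coefficient, no intercept.

    ``expr`` is a Series (one sample, indexed by gene) or a genes x samples
    DataFrame. Expression values are used as supplied (the normalized layer
    by convention); missing model genes are an error listing the symbols.
    """
    if isinstance(expr, pd.Series):
        frame = expr.to_frame("sample")
        single = True
    else:
        frame = expr
        single = False
    missing = [g for g in model.genes if g not in frame.index]
    if missing:
        raise ValidationError(f"expression missing model genes: {missing}")
    mat = frame.loc[model.genes].to_numpy(dtype=float)
    scores = model.coefs @ mat
    if single:
        return float(scores[0])
    return pd.Series(scores, index=frame.columns, name="risk_score")


def stratify_median(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> 'high', otherwise 'low' (ties low)."""
    if len(scores) < 4:
        raise ValidationError("need >= 4 samples to stratify")
    if scores.nunique() == 1:
        raise ValidationError("all scores identical; degenerate split")
    med = float(scores.median())
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="risk_group"
    )


def km_logrank(surv: pd.DataFrame, groups: pd.Series) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per group and the two-group log-rank p-value."""
    surv = surv.set_index("sample_id").loc[list(groups.index)]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValidationError("km_logrank expects exactly two groups")
    curves = {}
    parts = {}
    for name in names:
        mask = (groups == name).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"group {name!r} is empty")
        t = surv["time"].to_numpy(dtype=float)[mask]
        e = surv["event"].to_numpy(dtype=int)[mask]
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=str(name))
        tab = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[str(name)].to_numpy(),
                "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        parts[name] = (t, e)
    (t1, e1), (t2, e2) = parts[names[0]], parts[names[1]]
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return curves, float(res.p_value)


def time_dependent_roc(
    scores: pd.Series, surv: pd.DataFrame, horizons
) -> pd.DataFrame:
    """IPCW cumulative-case / dynamic-control AUC at each horizon.

    Cases are subjects with an event by t, controls those still at risk after
    t; censoring is weighted by the KM estimate of the censoring
    distribution. Horizons at or beyond the last follow-up (or before the
    first event) are reported as missing.
    """
    surv = surv.set_index("sample_id").loc[list(scores.index)]
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=bool)
    if not e.any():
        raise ValidationError("no events observed")
    y = Surv.from_arrays(event=e, time=t)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    rows = []
    t_events = t[e]
    for h in horizons:
        has_case = (t_events <= h).any()
        has_control = (t > h).any()
        if not (has_case and has_control) or h >= t.max():
            rows.append({"horizon": h, "auc": np.nan})
            continue
        auc, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(dtype=float), [h])
        rows.append({"horizon": h, "auc": float(auc[0])})
    return pd.DataFrame(rows)
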