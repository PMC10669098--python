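"""Synthetic cohorts with the statistical structure the analysis assumes.

Per-sample subtype compositions are drawn from Dirichlet distributions whose
log-concentrations are shifted by a shared per-sample latent factor for each
planted module (scaled by ``module_strength``) and by ``tumor_shift`` in
tumor samples, so within-module subtype abundances are Spearman-correlated
across samples. Gene counts are zero-truncated negative binomial gated by a
Bernoulli expressing indicator — Bernoulli(p_in) inside a marker's subtype,
Bernoulli(p_out) outside — which makes the expressing-cell fractions behind
the Sgi score analytic. Planted ligand-receptor genes are up-scaled in their
sender/receiver subtypes; survival times are exponential with a log-linear
hazard in z-scored bulk expression; spatial spots mix subtype profiles with
spatially smooth weight fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import ndimage, optimize

from .exceptions import ValidationError
from .io import ExpressionMatrix


@dataclass
class MarkerSpec:
    """Marker-gene design per subtype.

    p_in/p_out are the expressing-cell fractions inside/outside the subtype;
    counts for expressing cells are zero-truncated NB(nb_mean, nb_dispersion)
    so the empirical expressing fraction matches p_in exactly in expectation.
    """

    n_markers: int = 5
    p_in: float = 0.85
    p_out: float = 0.05
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValidationError("need 0 <= p_out < p_in <= 1")


@dataclass
class PlantedLR:
    ligand: str
    sender: str
    receptor: str
    receiver: str
    fold: float = 3.0


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 0.1
    betas: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")


@dataclass
class SpatialSpec:
    n_spots: int = 900
    smoothness: float = 1.0  # Gaussian kernel width (in spots) of the weight fields
    base_rate: float = 0.5
    amplitude: float = 8.0
    n_background_genes: int = 1000


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic single-cell cohort.

    Defaults: 40 samples (half tumor), 3 major types x 4 subtypes = 12
    subtypes all assigned to two planted modules of 6, module_strength 2,
    module M1 shifted up in tumor samples, 5 markers per subtype and ~400
    cells per sample.
    """

    n_samples: int = 40
    tissue_split: float = 0.5  # fraction of samples that are tumor
    majors: dict[str, list[str]] = field(default_factory=dict)
    module_assignment: dict[str, str] = field(default_factory=dict)
    module_strength: float = 2.0
    tumor_shift: dict[str, float] = field(default_factory=lambda: {"M1": 2.0})
    marker_spec: MarkerSpec = field(default_factory=MarkerSpec)
    n_background_genes: int = 40
    n_mito_genes: int = 3
    cells_per_sample: int = 400
    planted_lr: list[PlantedLR] = field(default_factory=list)
    lr_baseline_p: float = 0.9
    lr_baseline_mean: float = 1.5
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    spatial_spec: SpatialSpec = field(default_factory=SpatialSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        if self.module_strength < 0:
            raise ValidationError("module_strength must be >= 0")
        if not self.majors:
            self.majors = {
                major: [f"{major}_{i}" for i in range(1, 5)]
                for major in ("Lymphoid", "Myeloid", "Stromal")
            }
        if not self.module_assignment:
            assignment: dict[str, str] = {}
            for subtypes in self.majors.values():
                for i, s in enumerate(subtypes):
                    assignment[s] = "M1" if i < len(subtypes) // 2 else "M2"
            self.module_assignment = assignment
        known = {s for subs in self.majors.values() for s in subs}
        unknown = set(self.module_assignment) - known
        if unknown:
            raise ValidationError(f"module_assignment references unknown subtypes {sorted(unknown)}")

    @property
    def subtypes(self) -> list[str]:
        return [s for subs in self.majors.values() for s in subs]

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.module_assignment.values()))

    def marker_genes(self, subtype: str) -> list[str]:
        return [f"MK-{subtype}-{i}" for i in range(1, self.marker_spec.n_markers + 1)]

    def true_module_labels(self) -> pd.Series:
        """Ground-truth module label per subtype (for recovery checks)."""
        return pd.Series(
            {s: self.module_assignment.get(s, f"noise_{s}") for s in sorted(self.subtypes)}
        )


def _zt_negative_binomial(rng, mean: float, dispersion: float, size) -> np.ndarray:
    """Zero-truncated NB draws by rejection (resampling zeros)."""
    theta = dispersion
    p = theta / (theta + mean)
    out = rng.negative_binomial(theta, p, size=size)
    zero = out == 0
    # P(0) = p^theta < 1, so this terminates quickly in practice
    for _ in range(64):
        n_zero = int(zero.sum())
        if n_zero == 0:
            break
        out[zero] = rng.negative_binomial(theta, p, size=n_zero)
        zero = out == 0
    out[out == 0] = 1
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate (ExpressionMatrix, per-cell annotation) from the config."""
    rng = np.random.default_rng(config.seed)
    n_tumor = int(round(config.n_samples * config.tissue_split))
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    tissues = ["tumor"] * n_tumor + ["normal"] * (config.n_samples - n_tumor)

    modules = config.modules
    latent = rng.standard_normal((config.n_samples, len(modules)))
    mod_idx = {m: j for j, m in enumerate(modules)}

    majors = list(config.majors)
    cells_per_major = max(1, config.cells_per_sample // len(majors))

    cell_rows = []
    for k, (sample, tissue) in enumerate(zip(samples, tissues)):
        for major in majors:
            subs = config.majors[major]
            log_conc = np.full(len(subs), np.log(5.0))
            for i, s in enumerate(subs):
                mod = config.module_assignment.get(s)
                if mod is not None:
                    log_conc[i] += config.module_strength * latent[k, mod_idx[mod]]
                    if tissue == "tumor":
                        log_conc[i] += config.tumor_shift.get(mod, 0.0)
            props = rng.dirichlet(np.exp(log_conc))
            counts = rng.multinomial(cells_per_major, props)
            for s, c in zip(subs, counts):
                cell_rows.extend(
                    {"sample_id": sample, "tissue": tissue, "major_type": major, "subtype": s}
                    for _ in range(c)
                )
    ann = pd.DataFrame(cell_rows)
    ann.insert(0, "cell_id", [f"C{i + 1:06d}" for i in range(len(ann))])
    n_cells = len(ann)
    subtype_arr = ann["subtype"].to_numpy()

    # gene panel: per-subtype markers, background, mito, planted L-R genes
    genes: list[str] = []
    for s in config.subtypes:
        genes.extend(config.marker_genes(s))
    genes.extend(f"BG-{i}" for i in range(1, config.n_background_genes + 1))
    genes.extend(f"MT-SIM{i}" for i in range(1, config.n_mito_genes + 1))
    lr_genes = []
    for pl in config.planted_lr:
        for g in (pl.ligand, pl.receptor):
            if g not in genes and g not in lr_genes:
                lr_genes.append(g)
    genes.extend(lr_genes)

    ms = config.marker_spec
    X = np.zeros((len(genes), n_cells), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(genes)}

    for s in config.subtypes:
        in_mask = subtype_arr == s
        for g in config.marker_genes(s):
            p = np.where(in_mask, ms.p_in, ms.p_out)
            gate = rng.random(n_cells) < p
            n_on = int(gate.sum())
            if n_on:
                X[gidx[g], gate] = _zt_negative_binomial(rng, ms.nb_mean, ms.nb_dispersion, n_on)

    for g in [f"BG-{i}" for i in range(1, config.n_background_genes + 1)] + [
        f"MT-SIM{i}" for i in range(1, config.n_mito_genes + 1)
    ]:
        gate = rng.random(n_cells) < 0.9
        n_on = int(gate.sum())
        X[gidx[g], gate] = _zt_negative_binomial(rng, 1.5, ms.nb_dispersion, n_on)

    # planted L-R genes: baseline expression everywhere, fold-up in the role subtype
    roles: dict[str, list[tuple[str, float]]] = {}
    for pl in config.planted_lr:
        roles.setdefault(pl.ligand, []).append((pl.sender, pl.fold))
        roles.setdefault(pl.receptor, []).append((pl.receiver, pl.fold))
    for g, role_list in roles.items():
        mean = np.full(n_cells, config.lr_baseline_mean)
        for role_subtype, fold in role_list:
            mean[subtype_arr == role_subtype] *= fold
        gate = rng.random(n_cells) < config.lr_baseline_p
        n_on = int(gate.sum())
        if n_on:
            theta = ms.nb_dispersion
            p_nb = theta / (theta + mean[gate])
            draws = rng.negative_binomial(theta, p_nb)
            draws[draws == 0] = 1
            X[gidx[g], gate] = draws

    m = ExpressionMatrix(
        genes=pd.Index(genes), obs=pd.Index(ann["cell_id"]), counts=sp.csr_matrix(X)
    )
    return m, ann


def simulate_bulk(sc: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Pseudo-bulk: sum counts over each sample's cells (genes x samples)."""
    missing = set(sc.obs) - set(ann["cell_id"])
    if missing:
        raise ValidationError(f"{len(missing)} cells lack annotation")
    sample_of = ann.set_index("cell_id").loc[list(sc.obs), "sample_id"]
    samples = sorted(sample_of.unique())
    codes = pd.Categorical(sample_of, categories=samples).codes
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(samples)),
    )
    bulk = sc.counts @ indicator
    return ExpressionMatrix(genes=sc.genes, obs=pd.Index(samples), counts=sp.csr_matrix(bulk))


def simulate_survival(config: SimulationConfig, bulk: ExpressionMatrix) -> pd.DataFrame:
    """Exponential survival with hazard baseline * exp(sum beta_g z(expr_g)).

    Expression enters z-scored across samples (log1p CPM of the bulk
    counts). Censoring is independent Uniform(0, c_max) with c_max solved so
    the expected censored fraction is about censor_rate.
    """
    spec = config.survival_spec
    rng = np.random.default_rng(config.seed + 1)
    unknown = [g for g in spec.betas if g not in bulk.genes]
    if unknown:
        raise ValidationError(f"betas reference genes absent from bulk: {unknown}")
    n = len(bulk.obs)
    lp = np.zeros(n)
    if spec.betas:
        dense = np.asarray(bulk.counts.todense(), dtype=float)
        tot = dense.sum(axis=0)
        logcpm = np.log1p(1e6 * dense / np.maximum(tot, 1.0))
        for g, beta in spec.betas.items():
            x = logcpm[bulk.genes.get_loc(g)]
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            lp += beta * z
    hazard = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        lam = float(hazard.mean())

        def censored_frac(c_max: float) -> float:
            return (1 - np.exp(-lam * c_max)) / (lam * c_max) - spec.censor_rate

        c_max = optimize.brentq(censored_frac, 1e-9 / lam, 1e6 / lam)
        t_cens = rng.uniform(0, c_max, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    return pd.DataFrame({"sample_id": list(bulk.obs), "time": time, "event": event})


@dataclass
class SpatialSignature:
    name: str
    genes: list[str]
    field_id: int  # signatures sharing a field_id are co-localized


def simulate_spatial(
    config: SimulationConfig, signatures: list[SpatialSignature]
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Spot expression as a mixture of signature profiles with smooth weights.

    Each weight field is spatially smoothed Gaussian noise scaled to [0, 1];
    signatures with the same field_id share a field (co-localization).
    Background genes are added so gene-set scores have an out-set universe.
    """
    spec = config.spatial_spec
    if spec.n_spots <= 0:
        raise ValidationError("n_spots must be positive")
    if len(signatures) < 2:
        raise ValidationError("need >= 2 signatures")
    rng = np.random.default_rng(config.seed + 2)
    side = int(np.ceil(np.sqrt(spec.n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    coords = pd.DataFrame(
        {"spot_id": [f"SP{i + 1:05d}" for i in range(side * side)],
         "x": xs.ravel(), "y": ys.ravel()}
    ).iloc[: spec.n_spots]
    n_spots = len(coords)

    fields: dict[int, np.ndarray] = {}
    for sig in signatures:
        if sig.field_id not in fields:
            raw = ndimage.gaussian_filter(rng.standard_normal((side, side)), spec.smoothness)
            raw = raw.ravel()[:n_spots]
            lo, hi = raw.min(), raw.max()
            fields[sig.field_id] = (raw - lo) / (hi - lo) if hi > lo else np.zeros(n_spots)

    genes: list[str] = []
    for sig in signatures:
        genes.extend(g for g in sig.genes if g not in genes)
    background = [f"BGS-{i}" for i in range(1, spec.n_background_genes + 1)]
    genes.extend(background)

    X = np.zeros((len(genes), n_spots), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(genes)}
    for sig in signatures:
        w = fields[sig.field_id]
        for g in sig.genes:
            X[gidx[g]] += rng.poisson(spec.base_rate + spec.amplitude * w)
    for g in background:
        X[gidx[g]] = rng.poisson(spec.base_rate + 1.0, size=n_spots)

    m = ExpressionMatrix(
        genes=pd.Index(genes), obs=pd.Index(coords["spot_id"]), counts=sp.csr_matrix(X)
    )
    return m, coords.reset_index(drop=True)
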