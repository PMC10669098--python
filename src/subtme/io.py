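"""Data model and file readers/writers shared by all stages.

Counts travel as :class:`ExpressionMatrix` (genes x observations, sparse);
annotations, survival tables and result tables are pandas DataFrames backed
by TSV on disk; ligand-receptor databases are CSV with ``+``-separated
multi-component entries.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("cell_id", "sample_id", "tissue", "major_type", "subtype")
TISSUES = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Gene x observation count matrix with an optional normalized layer.

    Observations are cells, bulk samples or spatial spots depending on stage;
    the container is agnostic. Gene and observation identifiers must be unique
    and identifiers are treated as plain symbols (no ID mapping).
    """

    genes: pd.Index
    obs: pd.Index
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.obs = pd.Index(self.obs, name="obs")
        if self.genes.has_duplicates:
            dup = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup[:5]}")
        if self.obs.has_duplicates:
            dup = self.obs[self.obs.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate observation identifiers: {dup[:5]}")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.obs)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.obs)} observations"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.normalized is not None:
            self.normalized = sp.csr_matrix(self.normalized)
            if self.normalized.shape != self.counts.shape:
                raise ValidationError("normalized layer shape differs from counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def layer(self, which: str = "normalized") -> sp.csr_matrix:
        """Return the requested layer, falling back to counts."""
        if which == "normalized" and self.normalized is not None:
            return self.normalized
        return self.counts

    def subset_obs(self, mask_or_ids) -> "ExpressionMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.obs.get_indexer(mask_or_ids)
            if (idx < 0).any():
                missing = [m for m, i in zip(list(mask_or_ids), idx) if i < 0]
                raise ValidationError(f"unknown observations: {missing[:5]}")
        return ExpressionMatrix(
            genes=self.genes,
            obs=self.obs[idx],
            counts=self.counts[:, idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.genes.get_indexer(mask_or_ids)
            if (idx < 0).any():
                missing = [m for m, i in zip(list(mask_or_ids), idx) if i < 0]
                raise ValidationError(f"unknown genes: {missing[:5]}")
        return ExpressionMatrix(
            genes=self.genes[idx],
            obs=self.obs,
            counts=self.counts[idx, :],
            normalized=None if self.normalized is None else self.normalized[idx, :],
        )

    def to_frame(self, layer: str = "counts") -> pd.DataFrame:
        mat = self.counts if layer == "counts" else self.layer(layer)
        return pd.DataFrame(mat.toarray(), index=self.genes, columns=self.obs)


@dataclass
class LRPair:
    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]


@dataclass
class LRDatabase:
    pairs: list[LRPair] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.update(p.ligand)
            out.update(p.receptor)
        return out


def _read_id_list(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Read a MatrixMarket counts matrix with gene and barcode sidecar lists.

    On-disk orientation is auto-detected from the list lengths; the returned
    matrix is always gene x observation. A square matrix with equally long
    lists is taken as gene x observation with a warning.
    """
    matrix_path, genes_path, barcodes_path = map(Path, (matrix_path, genes_path, barcodes_path))
    for p in (matrix_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    genes = _read_id_list(genes_path)
    barcodes = _read_id_list(barcodes_path)
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    n_g, n_b = len(genes), len(barcodes)
    if mat.shape == (n_g, n_b):
        if n_g == n_b:
            warnings.warn(
                f"{matrix_path}: square matrix; assuming gene x observation orientation"
            )
    elif mat.shape == (n_b, n_g):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"{matrix_path}: declared shape {mat.shape} matches neither "
            f"{n_g} genes ({genes_path}) x {n_b} barcodes ({barcodes_path}) "
            "nor its transpose"
        )
    return ExpressionMatrix(genes=pd.Index(genes), obs=pd.Index(barcodes), counts=mat)


def write_counts(m: ExpressionMatrix, out_dir) -> None:
    """Write MTX + genes.tsv + barcodes.tsv; inverse of :func:`read_counts`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "matrix.mtx", sp.coo_matrix(m.counts))
    pd.Series(m.genes).to_csv(out_dir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(m.obs).to_csv(out_dir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_lr_database(csv_path) -> LRDatabase:
    """Read a ligand-receptor pair CSV (pair_id, ligand, receptor).

    Multi-component complexes use ``+`` between gene symbols. Symbols are
    upper-cased; duplicated pair_ids are collapsed to the first occurrence
    with a logged warning.
    """
    df = pd.read_csv(csv_path, dtype=str)
    required = {"pair_id", "ligand", "receptor"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{csv_path}: missing columns {sorted(missing)}")
    if df["pair_id"].duplicated().any():
        dups = df.loc[df["pair_id"].duplicated(), "pair_id"].unique().tolist()
        logger.warning("collapsing duplicated pair_ids: %s", dups)
        df = df.drop_duplicates("pair_id", keep="first")
    pairs = []
    for row in df.itertuples(index=False):
        ligand = tuple(g.strip().upper() for g in str(row.ligand).split("+") if g.strip())
        receptor = tuple(g.strip().upper() for g in str(row.receptor).split("+") if g.strip())
        if not ligand or not receptor:
            raise FormatError(f"{csv_path}: empty component list for pair {row.pair_id}")
        pairs.append(LRPair(pair_id=str(row.pair_id), ligand=ligand, receptor=receptor))
    return LRDatabase(pairs=pairs)


def read_annotation(tsv_path) -> pd.DataFrame:
    ann = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str)
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame, m: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check the per-cell annotation invariants; returns the frame unchanged.

    Every cell_id unique, tissue in {tumor, normal}, each subtype nested under
    exactly one major type, and (when a matrix is given) every cell present in
    the matrix observations.
    """
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"annotation missing columns {sorted(missing)}")
    if ann["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in annotation")
    bad = set(ann["tissue"].unique()) - set(TISSUES)
    if bad:
        raise ValidationError(f"tissue labels outside {TISSUES}: {sorted(bad)}")
    parents = ann.groupby("subtype")["major_type"].nunique()
    multi = parents[parents > 1].index.tolist()
    if multi:
        raise ValidationError(f"subtypes mapped to multiple major types: {multi}")
    if m is not None:
        unknown = set(ann["cell_id"]) - set(m.obs)
        if unknown:
            raise ValidationError(
                f"{len(unknown)} annotated cells absent from matrix observations"
            )
    return ann


def read_survival(tsv_path) -> pd.DataFrame:
    surv = pd.read_csv(tsv_path, sep="\t", comment="#")
    return validate_survival(surv)


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    missing = {"sample_id", "time", "event"} - set(surv.columns)
    if missing:
        raise FormatError(f"survival table missing columns {sorted(missing)}")
    if surv["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in survival table")
    if (surv["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 (censored) or 1 (event)")
    return surv


def params_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping, for output provenance lines."""
    canon = repr(sorted(params.items())).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def write_table(
    records: pd.DataFrame,
    path,
    *,
    seed: int | None = None,
    params: dict | None = None,
    sort_by: Sequence[str] | None = None,
    allow_empty: bool = False,
) -> None:
    """Write a result table as TSV with a provenance comment line.

    Rows are sorted by ``sort_by`` (default: all columns, left to right) so
    re-running with the same seed yields a byte-identical file.
    """
    from . import __version__

    if records.empty and not allow_empty:
        raise ValidationError(f"refusing to write empty table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not records.empty:
        keys = list(sort_by) if sort_by else list(records.columns)
        records = records.sort_values(keys, kind="mergesort").reset_index(drop=True)
    header = f"# subtme v{__version__} seed={seed}"
    if params is not None:
        header += f" params_hash={params_hash(params)}"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        records.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g.upper() for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path, description: str = "subtme") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
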