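"""On-disk formats: 10x-style Matrix Market triplets, TSV tables with
provenance headers, gene-set and regulon files, YAML configuration.

In memory nuclei are rows and genes are columns (the analysis
convention); the 10x triplet layout stores features as rows, so matrices
are transposed on write and read back. Matrix Market indices are 1-based
per the standard; everything in memory is 0-based.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

__version__ = "0.1.0"

METADATA_COLUMNS = [
    "barcode",
    "subject_id",
    "batch_id",
    "sex",
    "aod",
    "genotype_group",
    "ms4a_genotype",
    "apoe_e4",
    "cell_type",
    "cell_state",
    "n_umi",
    "n_genes",
    "pct_mito",
    "doublet",
]


class FormatError(ValueError):
    """A file or in-memory object violates the expected format."""


@dataclass
class CountMatrix:
    """Sparse nucleus x gene raw counts with identifiers.

    ``values`` is CSR with nuclei as rows. ``mito_gene_mask`` marks
    mitochondrial genes by a configurable gene-name prefix (default
    ``MT-``).
    """

    values: sparse.csr_matrix
    gene_ids: list[str]
    gene_names: list[str]
    barcodes: list[str]
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        n, g = self.values.shape
        if len(self.barcodes) != n:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a matrix with {n} nuclei"
            )
        if len(self.gene_ids) != g or len(self.gene_names) != g:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids / {len(self.gene_names)} names "
                f"for a matrix with {g} genes"
            )
        if len(set(self.barcodes)) != n:
            raise FormatError("duplicate barcodes")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def mito_gene_mask(self) -> np.ndarray:
        return np.array([g.startswith(self.mito_prefix) for g in self.gene_names])

    def umi_per_nucleus(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def genes_per_nucleus(self) -> np.ndarray:
        return np.asarray((self.values > 0).sum(axis=1)).ravel()

    def pct_mito(self) -> np.ndarray:
        tot = self.umi_per_nucleus()
        mito = np.asarray(self.values[:, self.mito_gene_mask].sum(axis=1)).ravel()
        return np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)

    def subset(self, nuclei=None, genes=None) -> "CountMatrix":
        X = self.values
        barcodes, gids, gnames = self.barcodes, self.gene_ids, self.gene_names
        if nuclei is not None:
            nuclei = np.asarray(nuclei)
            X = X[nuclei]
            barcodes = [barcodes[i] for i in np.flatnonzero(nuclei)] if nuclei.dtype == bool else [
                barcodes[i] for i in nuclei
            ]
        if genes is not None:
            genes = np.asarray(genes)
            X = X[:, genes]
            idx = np.flatnonzero(genes) if genes.dtype == bool else genes
            gids = [self.gene_ids[i] for i in idx]
            gnames = [self.gene_names[i] for i in idx]
        return CountMatrix(X, gids, gnames, barcodes, self.mito_prefix)


def write_10x_mtx(cm: CountMatrix, path: str | Path) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv (features as rows)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(cm.values.T.astype(np.int64))
    spio.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    with open(path / "features.tsv", "w") as fh:
        for gid, name in zip(cm.gene_ids, cm.gene_names):
            fh.write(f"{gid}\t{name}\tGene Expression\n")
    with open(path / "barcodes.tsv", "w") as fh:
        for bc in cm.barcodes:
            fh.write(bc + "\n")


def read_10x_mtx(path: str | Path, mito_prefix: str = "MT-") -> CountMatrix:
    """Read a 10x-style triplet directory into a CountMatrix.

    Raises :class:`FormatError` naming the offending file when the three
    files are mutually inconsistent or the matrix is not integer.
    """
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    if not mtx_file.exists():
        raise FormatError(f"missing {mtx_file}")
    mat = spio.mmread(str(mtx_file))
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.tocoo().data if sparse.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{mtx_file}: non-integer entries")
        mat = mat.astype(np.int64)
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    barcodes = [
        line.strip()
        for line in open(path / "barcodes.tsv")
        if line.strip()
    ]
    n_genes, n_cells = mat.shape
    if len(feats) != n_genes:
        raise FormatError(
            f"{path / 'features.tsv'}: {len(feats)} features for a matrix with {n_genes} rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"{path / 'barcodes.tsv'}: {len(barcodes)} barcodes for a matrix with {n_cells} columns"
        )
    return CountMatrix(
        values=sparse.csr_matrix(mat.T),
        gene_ids=list(feats[0]),
        gene_names=list(feats[1]),
        barcodes=barcodes,
        mito_prefix=mito_prefix,
    )


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """TSV with a comment header carrying tool version and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# snstates {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    bad = meta[(meta.pct_mito < 0) | (meta.pct_mito > 1)]
    if len(bad):
        raise FormatError(f"{path}: pct_mito outside [0, 1]")
    if meta.barcode.duplicated().any():
        raise FormatError(f"{path}: duplicate barcodes")
    return meta


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """GMT-like TSV: name, description, then one gene per column."""
    sets: dict[str, list[str]] = {}
    for line in open(path):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: gene-set line with fewer than 3 columns")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_regulons(path: str | Path):
    """Regulon TSV: tf, comma-separated targets, cohort tag."""
    from .replication import Regulon

    out = []
    df = read_table(path)
    for col in ("tf", "targets"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    for _, row in df.iterrows():
        out.append(
            Regulon(
                tf=row["tf"],
                targets=[t for t in str(row["targets"]).split(",") if t],
                cohort=row.get("cohort", ""),
            )
        )
    return out


def write_regulons(regulons, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "tf": [r.tf for r in regulons],
            "targets": [",".join(r.targets) for r in regulons],
            "cohort": [r.cohort for r in regulons],
        }
    )
    write_table(df, path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return cfg
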