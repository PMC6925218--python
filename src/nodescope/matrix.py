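"""Count-matrix containers and digital-gene-expression (DGE) file I/O.

The central object is :class:`CountMatrix`: a genes x barcodes matrix of
nonnegative integer UMI counts together with per-gene annotations (species
tag, mitochondrial flag, transgene flag) and per-barcode annotations (animal
id, treatment arm).  Two on-disk dialects are supported: dense TSV (genes as
rows, first column the gene identifier, header row of barcodes) and
MatrixMarket coordinate triplets with ``genes.tsv`` / ``barcodes.tsv``
sidecars.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneAnnotationRules",
    "DGEParseError",
    "read_dge",
    "write_dge",
]

GENE_COLUMNS = ["species", "mito", "transgene"]
BARCODE_COLUMNS = ["animal", "arm"]


class DGEParseError(ValueError):
    """Raised when a DGE file is malformed; the message names the offending record."""


@dataclass
class GeneAnnotationRules:
    """How gene identifiers are turned into annotations when no sidecar exists.

    ``species_prefixes`` maps an identifier prefix (e.g. ``"hg19_"``) to a
    species tag; identifiers with no listed prefix get ``default_species``.
    Mitochondrial genes are recognised by prefix on the identifier with any
    species prefix stripped (``mt-`` by default, case-insensitive).
    """

    species_prefixes: dict[str, str] = field(default_factory=lambda: {"hg19_": "human"})
    default_species: str = "mouse"
    mito_prefixes: tuple[str, ...] = ("mt-",)
    transgenes: tuple[str, ...] = ("Yfp", "SmoM2", "Cre")

    def annotate(self, gene_ids: pd.Index) -> pd.DataFrame:
        species = np.full(len(gene_ids), self.default_species, dtype=object)
        stripped = np.asarray(gene_ids, dtype=object).copy()
        for prefix, tag in self.species_prefixes.items():
            hit = np.array([g.startswith(prefix) for g in gene_ids])
            species[hit] = tag
            stripped[hit] = [g[len(prefix):] for g in np.asarray(gene_ids)[hit]]
        low = np.array([str(g).lower() for g in stripped])
        mito = np.zeros(len(gene_ids), dtype=bool)
        for p in self.mito_prefixes:
            mito |= np.char.startswith(low, p.lower())
        transgene = np.isin(stripped, list(self.transgenes))
        return pd.DataFrame(
            {"species": species, "mito": mito, "transgene": transgene},
            index=pd.Index(gene_ids, name="gene"),
        )


@dataclass
class CountMatrix:
    """Genes x barcodes UMI counts with gene and barcode annotations.

    ``counts`` is a CSR sparse matrix of shape (n_genes, n_barcodes).
    ``genes`` is indexed by gene identifier with columns ``species`` (tag),
    ``mito`` (bool) and ``transgene`` (bool); ``barcodes`` is indexed by
    barcode string with columns ``animal`` and ``arm``.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    barcodes: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.genes.index.has_duplicates:
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise DGEParseError(f"duplicate gene identifier: {dup!r}")
        if self.barcodes.index.has_duplicates:
            dup = self.barcodes.index[self.barcodes.index.duplicated()][0]
            raise DGEParseError(f"duplicate barcode: {dup!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DGEParseError("negative count encountered")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def barcode_totals(self) -> np.ndarray:
        """Total UMI count per barcode (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per barcode."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_detected(self) -> np.ndarray:
        """Number of barcodes with count > 0 per gene."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = self._resolve(mask_or_index, self.genes.index)
        return CountMatrix(self.counts[idx, :], self.genes.iloc[idx].copy(), self.barcodes.copy())

    def subset_barcodes(self, mask_or_index) -> "CountMatrix":
        idx = self._resolve(mask_or_index, self.barcodes.index)
        return CountMatrix(self.counts[:, idx], self.genes.copy(), self.barcodes.iloc[idx].copy())

    @staticmethod
    def _resolve(mask_or_index, index: pd.Index) -> np.ndarray:
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        if arr.dtype.kind in "iu":
            return arr
        return index.get_indexer(arr)

    # -- interop ---------------------------------------------------------
    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_anndata(self):
        """Barcodes-as-observations AnnData view (requires :mod:`anndata`)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(), obs=self.barcodes.copy(), var=self.genes.copy()
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes.index.equals(other.genes.index)
            and self.barcodes.index.equals(other.barcodes.index)
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Genes x barcodes log-normalized expression (dense, float64).

    ``values[g, c] = log(1 + count * scale_total / barcode_total)`` so a zero
    count always maps to zero.  Natural log throughout.
    """

    values: np.ndarray
    genes: pd.DataFrame
    barcodes: pd.DataFrame
    scale_total: float = 10_000.0

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.values.shape[1]

    def gene_vector(self, gene: str) -> np.ndarray:
        i = self.genes.index.get_loc(gene)
        return self.values[i, :]

    def subset_genes(self, mask_or_index) -> "NormalizedMatrix":
        idx = CountMatrix._resolve(mask_or_index, self.genes.index)
        return NormalizedMatrix(
            self.values[idx, :], self.genes.iloc[idx].copy(), self.barcodes.copy(), self.scale_total
        )

    def subset_barcodes(self, mask_or_index) -> "NormalizedMatrix":
        idx = CountMatrix._resolve(mask_or_index, self.barcodes.index)
        return NormalizedMatrix(
            self.values[:, idx], self.genes.copy(), self.barcodes.iloc[idx].copy(), self.scale_total
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_dge(matrix: CountMatrix, path: str, dialect: str = "tsv") -> None:
    """Write a CountMatrix in the dense-TSV or MatrixMarket dialect.

    ``tsv`` writes ``<path>`` as a genes x barcodes table plus annotation
    sidecars ``<path>.genes.tsv`` / ``<path>.barcodes.tsv``.  ``mtx`` treats
    ``path`` as a directory receiving ``matrix.mtx``, ``genes.tsv`` and
    ``barcodes.tsv``.
    """
    if dialect == "tsv":
        df = pd.DataFrame(matrix.to_dense(), index=matrix.genes.index, columns=matrix.barcodes.index)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
        matrix.genes.to_csv(path + ".genes.tsv", sep="\t")
        matrix.barcodes.to_csv(path + ".barcodes.tsv", sep="\t")
    elif dialect == "mtx":
        os.makedirs(path, exist_ok=True)
        coo = matrix.counts.tocoo()
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), coo, field="integer")
        matrix.genes.to_csv(os.path.join(path, "genes.tsv"), sep="\t")
        matrix.barcodes.to_csv(os.path.join(path, "barcodes.tsv"), sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_dge(
    path: str,
    dialect: str = "tsv",
    rules: GeneAnnotationRules | None = None,
) -> CountMatrix:
    """Load a DGE matrix losslessly from either supported dialect.

    Gene/barcode annotations come from sidecar files when present, otherwise
    they are parsed from identifier prefixes via ``rules``.  Malformed input
    (non-integer or negative counts, duplicated identifiers) raises
    :class:`DGEParseError` naming the offending record.
    """
    rules = rules or GeneAnnotationRules()
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        _check_integer(values, df.index)
        counts = sp.csr_matrix(values.astype(np.int64))
        gene_ids = pd.Index(df.index.astype(str), name="gene")
        barcode_ids = pd.Index(df.columns.astype(str), name="barcode")
        genes = _read_sidecar(path + ".genes.tsv", gene_ids)
        if genes is None:
            genes = rules.annotate(gene_ids)
        else:
            genes = _coerce_gene_frame(genes, rules)
        barcodes = _read_sidecar(path + ".barcodes.tsv", barcode_ids)
        if barcodes is None:
            barcodes = pd.DataFrame(
                {"animal": "unknown", "arm": "unknown"}, index=barcode_ids
            )
    elif dialect == "mtx":
        mat = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat)
        genes_df = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", index_col=0)
        barcodes_df = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", index_col=0)
        _check_integer(values, genes_df.index)
        counts = sp.csr_matrix(values.astype(np.int64))
        genes = _coerce_gene_frame(genes_df, rules)
        barcodes = _coerce_barcode_frame(barcodes_df)
        gene_ids, barcode_ids = genes.index, barcodes.index
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if pd.Index(gene_ids).has_duplicates:
        dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()][0]
        raise DGEParseError(f"duplicate gene identifier: {dup!r}")
    return CountMatrix(counts, genes, barcodes)


def _check_integer(values: np.ndarray, index: pd.Index) -> None:
    if values.size == 0:
        return
    if not np.issubdtype(values.dtype, np.number):
        raise DGEParseError("non-numeric counts in matrix")
    bad = ~np.isfinite(values) | (values < 0) | (np.mod(values, 1) != 0)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise DGEParseError(f"negative or non-integer count in record {index[row]!r}")


def _read_sidecar(path: str, expected_index: pd.Index) -> pd.DataFrame | None:
    if not os.path.exists(path):
        return None
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.loc[expected_index]


def _coerce_gene_frame(df: pd.DataFrame, rules: GeneAnnotationRules) -> pd.DataFrame:
    df = df.copy()
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if not set(GENE_COLUMNS).issubset(df.columns):
        return rules.annotate(df.index)
    df["mito"] = df["mito"].astype(bool)
    df["transgene"] = df["transgene"].astype(bool)
    return df[GENE_COLUMNS]


def _coerce_barcode_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.index = df.index.astype(str)
    df.index.name = "barcode"
    for col in BARCODE_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
    return df[BARCODE_COLUMNS]
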