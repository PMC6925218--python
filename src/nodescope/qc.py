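"""Barcode- and gene-level quality control for DGE matrices.

Implements the standard Drop-seq inclusion criteria: species-purity
filtering against a foreign-species spike-in, removal of low-information
barcodes (<=500 UMIs or genes by default), removal of outlier barcodes
(total counts, detected genes, or mitochondrial fraction beyond
median + 4.5 SD within an animal's sample), a 30-cell gene detection floor,
and per-cell log normalization.

Order of application is fixed: species purity -> cell QC -> gene floor,
and the QC report reconciles removal counts exactly against that order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "species_purity_filter",
    "qc_filter_cells",
    "filter_genes",
    "normalize_log",
    "run_qc",
]


@dataclass
class QCThresholds:
    """Inclusion criteria for barcodes and genes.

    ``sd_multiplier`` resolves the conventional "4-5 standard deviations
    above the median" band to a single configurable value (default 4.5);
    ``center`` chooses the center statistic (median by default, mean
    optionally).  Lower bounds are strict (> min), upper bounds are strict
    (< center + k*SD) except in the degenerate SD = 0 case, where ties at
    the center are kept.
    """

    min_umis: int = 500
    min_genes: int = 500
    sd_multiplier: float = 4.5
    mito_sd_multiplier: float = 4.5
    species_purity: float = 0.90
    min_cells_per_gene: int = 30
    center: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        if not (0 < self.species_purity <= 1):
            raise ValueError("species_purity must lie in (0, 1]")
        if self.min_umis < 0 or self.min_genes < 0 or self.min_cells_per_gene < 0:
            raise ValueError("count thresholds must be nonnegative")
        if self.sd_multiplier <= 0 or self.mito_sd_multiplier <= 0:
            raise ValueError("SD multipliers must be positive")
        if not (4.0 <= self.sd_multiplier <= 5.0):
            warnings.warn(
                f"sd_multiplier {self.sd_multiplier} is outside the conventional "
                "4-5 band",
                stacklevel=2,
            )


@dataclass
class QCReport:
    """Removal accounting for one QC pass; counts reconcile sequentially."""

    n_barcodes_in: int = 0
    n_barcodes_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_species: int = 0
    removed_low_content: int = 0
    removed_high_content: int = 0
    removed_high_mito: int = 0
    removed_genes: int = 0
    per_animal_cells: dict = field(default_factory=dict)

    @property
    def pass_fraction(self) -> float:
        return self.n_barcodes_out / self.n_barcodes_in if self.n_barcodes_in else 0.0

    def reconciles(self) -> bool:
        removed = (
            self.removed_species
            + self.removed_low_content
            + self.removed_high_content
            + self.removed_high_mito
        )
        return self.n_barcodes_in - removed == self.n_barcodes_out

    def to_json(self, path: str | None = None) -> str:
        payload = asdict(self)
        payload["pass_fraction"] = self.pass_fraction
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def species_purity_filter(
    matrix: CountMatrix,
    purity: float = 0.90,
    target_species: str = "mouse",
) -> tuple[CountMatrix, QCReport]:
    """Keep barcodes whose target-species count fraction strictly exceeds
    ``purity``; foreign-species gene rows are dropped afterwards.

    With fewer than two species among the genes this is a no-op (warning).
    """
    report = QCReport(
        n_barcodes_in=matrix.n_barcodes,
        n_genes_in=matrix.n_genes,
    )
    species = matrix.genes["species"]
    if species.nunique() < 2:
        warnings.warn("single-species matrix: purity filter is a no-op", stacklevel=2)
        report.n_barcodes_out = matrix.n_barcodes
        report.n_genes_out = matrix.n_genes
        return matrix, report
    target_rows = (species == target_species).to_numpy()
    totals = matrix.barcode_totals().astype(float)
    target_counts = np.asarray(matrix.counts[target_rows, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore"):
        frac = np.divide(target_counts, totals, out=np.zeros_like(totals), where=totals > 0)
    keep = frac > purity
    out = matrix.subset_barcodes(keep).subset_genes(target_rows)
    report.removed_species = int((~keep).sum())
    report.n_barcodes_out = out.n_barcodes
    report.n_genes_out = out.n_genes
    return out, report


def _upper_cut(values: np.ndarray, multiplier: float, center: str) -> np.ndarray:
    """Strict upper outlier mask; with SD = 0 ties at the center are kept."""
    c = np.median(values) if center == "median" else values.mean()
    sd = values.std()
    if sd == 0:
        return values > c
    return values > c + multiplier * sd


def qc_filter_cells(
    matrix: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Apply the barcode inclusion criteria.

    A barcode is removed when its total counts or detected genes are at or
    below the configured floors, when either exceeds center + k*SD, or when
    its mitochondrial count fraction exceeds center + k*SD.  Center and SD
    are computed per animal (batch scope) over all input barcodes of that
    animal.  Removal categories are assigned sequentially (low content,
    then high content, then high mito) so the report reconciles exactly.
    """
    thresholds = thresholds or QCThresholds()
    if matrix.n_barcodes == 0:
        raise ValueError("empty matrix")
    totals = matrix.barcode_totals().astype(float)
    ngenes = matrix.genes_detected().astype(float)
    mito_rows = matrix.genes["mito"].to_numpy(bool)
    mito_counts = np.asarray(matrix.counts[mito_rows, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore"):
        mito_frac = np.divide(
            mito_counts, totals, out=np.zeros_like(totals), where=totals > 0
        )

    low = (totals <= thresholds.min_umis) | (ngenes <= thresholds.min_genes)
    high = np.zeros(matrix.n_barcodes, dtype=bool)
    himito = np.zeros(matrix.n_barcodes, dtype=bool)
    animals = matrix.barcodes["animal"].to_numpy()
    for animal in pd.unique(animals):
        sel = animals == animal
        high[sel] = _upper_cut(
            totals[sel], thresholds.sd_multiplier, thresholds.center
        ) | _upper_cut(ngenes[sel], thresholds.sd_multiplier, thresholds.center)
        himito[sel] = _upper_cut(
            mito_frac[sel], thresholds.mito_sd_multiplier, thresholds.center
        )

    removed_low = low
    removed_high = high & ~low
    removed_mito = himito & ~low & ~high
    keep = ~(low | high | himito)
    if not keep.any():
        raise ValueError("QC removed every barcode; thresholds are misconfigured")
    out = matrix.subset_barcodes(keep)
    report = QCReport(
        n_barcodes_in=matrix.n_barcodes,
        n_barcodes_out=out.n_barcodes,
        n_genes_in=matrix.n_genes,
        n_genes_out=out.n_genes,
        removed_low_content=int(removed_low.sum()),
        removed_high_content=int(removed_high.sum()),
        removed_high_mito=int(removed_mito.sum()),
        per_animal_cells=out.barcodes["animal"].value_counts().to_dict(),
    )
    return out, report


def filter_genes(matrix: CountMatrix, min_cells: int = 30) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` barcodes.

    Transgene-flagged genes are exempt: lineage-reporter calls need them
    even when detection is rare.
    """
    detected = matrix.cells_detected()
    keep = (detected >= min_cells) | matrix.genes["transgene"].to_numpy(bool)
    return matrix.subset_genes(keep)


def normalize_log(matrix: CountMatrix, scale_total: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell scaling + natural-log transform:
    ``value = log(1 + count * scale_total / barcode_total)``."""
    totals = matrix.barcode_totals().astype(float)
    if (totals == 0).any():
        bad = matrix.barcodes.index[totals == 0][0]
        raise ValueError(f"zero-total barcode {bad!r}; run QC first")
    dense = matrix.to_dense().astype(float)
    values = np.log1p(dense * (scale_total / totals)[None, :])
    return NormalizedMatrix(values, matrix.genes.copy(), matrix.barcodes.copy(), scale_total)


def run_qc(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    target_species: str = "mouse",
) -> tuple[CountMatrix, QCReport]:
    """Full QC sequence: species purity -> cell QC -> gene detection floor."""
    thresholds = thresholds or QCThresholds()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pure, sp_report = species_purity_filter(
            matrix, thresholds.species_purity, target_species
        )
    filtered, report = qc_filter_cells(pure, thresholds)
    out = filter_genes(filtered, thresholds.min_cells_per_gene)
    report.removed_species = sp_report.removed_species
    report.n_barcodes_in = matrix.n_barcodes
    report.n_genes_in = matrix.n_genes
    report.n_genes_out = out.n_genes
    report.removed_genes = filtered.n_genes - out.n_genes
    return out, report
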