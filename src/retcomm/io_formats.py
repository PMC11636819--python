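"""Reading/writing the standard on-disk formats and per-cell QC filtering.

The central in-memory object is :class:`ExpressionAtlas`: a sparse
gene x cell count matrix plus a per-cell metadata table.  Atlases are
stored on disk in the 10x-style triplet layout (Matrix Market ``.mtx``
with 1-based indices, ``features.tsv``, ``barcodes.tsv``) plus a
``cell_metadata.tsv`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionAtlas",
    "QCThresholds",
    "QC_WHOLE_RETINA",
    "QC_PURIFIED_RGC",
    "AtlasParseError",
    "load_expression",
    "save_expression",
    "qc_filter_cells",
    "write_results",
]

METADATA_COLUMNS = ["barcode", "cell_type", "subclass", "survival_class", "timepoint", "sample"]


class AtlasParseError(ValueError):
    """Raised when on-disk atlas components are inconsistent."""


@dataclass
class ExpressionAtlas:
    """Labeled count matrix: genes on rows, cells on columns.

    Parameters
    ----------
    counts
        Sparse non-negative integer matrix, shape ``(n_genes, n_cells)``.
    genes
        Unique gene identifiers, one per row.
    cells
        Per-cell metadata with columns ``barcode, cell_type, subclass,
        survival_class, timepoint, sample``.  ``subclass`` and
        ``survival_class`` are ``None``/NaN for cells outside the RGC
        cell type.
    timepoints
        The declared ordered timepoint labels; the first is the
        uninjured control.
    rgc_type
        Name of the cell type whose cells carry a subclass label.
    """

    counts: sp.csr_matrix
    genes: list[str]
    cells: pd.DataFrame
    timepoints: tuple[str, ...] = ("control", "12h", "24h", "48h")
    rgc_type: str = "RGC"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = list(self.genes)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise AtlasParseError(
                f"matrix has {n_genes} rows but {len(self.genes)} gene ids"
            )
        if len(self.cells) != n_cells:
            raise AtlasParseError(
                f"matrix has {n_cells} columns but {len(self.cells)} cell records"
            )
        if len(set(self.genes)) != n_genes:
            raise AtlasParseError("duplicate gene ids")
        barcodes = self.cells["barcode"]
        if barcodes.duplicated().any():
            dup = barcodes[barcodes.duplicated()].iloc[0]
            raise AtlasParseError(f"duplicate barcode: {dup!r}")
        bad_tp = set(self.cells["timepoint"]) - set(self.timepoints)
        if bad_tp:
            raise AtlasParseError(f"unknown timepoint(s): {sorted(bad_tp)}")
        has_sub = self.cells["subclass"].notna()
        if (self.cells.loc[has_sub, "cell_type"] != self.rgc_type).any():
            raise AtlasParseError(
                f"subclass set on a cell whose cell_type is not {self.rgc_type!r}"
            )
        if (self.counts.data < 0).any():
            raise AtlasParseError("negative counts")

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def group_labels(self, group_by: str = "mixed") -> pd.Series:
        """Per-cell group label for profile summarization.

        ``cell_type`` groups every cell by its type; ``subclass`` keeps
        only RGC cells, grouped by subclass; ``mixed`` uses the subclass
        for RGC cells and the cell type for everything else (the
        grouping used for interaction scoring).
        """
        if group_by == "cell_type":
            return self.cells["cell_type"].copy()
        if group_by == "subclass":
            labels = self.cells["subclass"].copy()
            labels[self.cells["cell_type"] != self.rgc_type] = np.nan
            return labels
        if group_by == "mixed":
            labels = self.cells["cell_type"].copy()
            rgc = self.cells["cell_type"] == self.rgc_type
            labels[rgc] = self.cells.loc[rgc, "subclass"]
            return labels
        raise ValueError(f"unknown group_by: {group_by!r}")

    def subset_cells(self, mask: np.ndarray) -> "ExpressionAtlas":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            counts=self.counts[:, mask],
            cells=self.cells.loc[mask].reset_index(drop=True),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell QC cutoffs.  Cells are REMOVED on strict violations
    (e.g. nUMI < ``numi_min`` or nUMI > ``numi_max``), so boundary
    values are retained."""

    numi_min: int = 800
    numi_max: float = 30_000
    ngene_min: int = 350
    ngene_max: float = 7_500
    mito_rate_max: float = 0.20
    log10_genes_per_umi_min: float = 0.8
    mito_gene_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not self.numi_min < self.numi_max:
            raise ValueError("numi_min must be < numi_max")
        if not self.ngene_min < self.ngene_max:
            raise ValueError("ngene_min must be < ngene_max")
        if not 0.0 <= self.mito_rate_max <= 1.0:
            raise ValueError("mito_rate_max must be in [0, 1]")


#: whole-retina dataset preset
QC_WHOLE_RETINA = QCThresholds()
#: purified-RGC dataset preset; no upper bounds are imposed
QC_PURIFIED_RGC = QCThresholds(numi_min=500, numi_max=math.inf, ngene_min=250, ngene_max=math.inf)


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def load_expression(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path,
    timepoints: tuple[str, ...] = ("control", "12h", "24h", "48h"),
    rgc_type: str = "RGC",
) -> ExpressionAtlas:
    """Load a 10x-style triplet atlas plus cell metadata.

    The metadata table must have a header row with the columns of
    ``METADATA_COLUMNS`` and one row per barcode in the barcode file;
    barcodes missing from either side are an error.
    """
    matrix = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if matrix.shape[0] != len(genes):
        raise AtlasParseError(
            f"matrix rows ({matrix.shape[0]}) != features ({len(genes)})"
        )
    if matrix.shape[1] != len(barcodes):
        raise AtlasParseError(
            f"matrix columns ({matrix.shape[1]}) != barcodes ({len(barcodes)})"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise AtlasParseError(f"metadata missing column(s): {sorted(missing_cols)}")
    unknown = set(meta["barcode"]) - set(barcodes)
    if unknown:
        raise AtlasParseError(
            f"metadata barcode(s) absent from barcode file: {sorted(unknown)[:5]}"
        )
    missing = set(barcodes) - set(meta["barcode"])
    if missing:
        raise AtlasParseError(
            f"barcode(s) missing from metadata: {sorted(missing)[:5]}"
        )
    bc_to_col = {bc: i for i, bc in enumerate(barcodes)}
    order = np.array([bc_to_col[bc] for bc in meta["barcode"]], dtype=int)
    return ExpressionAtlas(
        counts=matrix[:, order],
        genes=genes,
        cells=meta[METADATA_COLUMNS].reset_index(drop=True),
        timepoints=tuple(timepoints),
        rgc_type=rgc_type,
    )


def save_expression(atlas: ExpressionAtlas, out_dir: str | Path) -> dict[str, Path]:
    """Write the triplet layout (1-based MTX) plus cell_metadata.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "metadata": out / "cell_metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(atlas.counts), field="integer")
    paths["features"].write_text("\n".join(atlas.genes) + "\n")
    paths["barcodes"].write_text("\n".join(atlas.cells["barcode"]) + "\n")
    atlas.cells[METADATA_COLUMNS].to_csv(paths["metadata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def cell_qc_metrics(atlas: ExpressionAtlas, mito_gene_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell nUMI, nGene, mitochondrial rate and log10GenesPerUMI.

    ``log10GenesPerUMI`` is log10(nGene)/log10(nUMI); cells with
    nUMI <= 1 get 0 for that metric (they fail any sane nUMI floor
    anyway).
    """
    counts = atlas.counts.tocsc()
    numi = np.asarray(counts.sum(axis=0)).ravel()
    ngene = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_rows = [i for i, g in enumerate(atlas.genes) if g.lower().startswith(mito_gene_prefix.lower())]
    if mito_rows:
        mito_umi = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito_umi = np.zeros_like(numi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_rate = np.where(numi > 0, mito_umi / np.maximum(numi, 1), 0.0)
        ratio = np.where(
            (numi > 1) & (ngene > 0),
            np.log10(np.maximum(ngene, 1)) / np.log10(np.maximum(numi, 2)),
            0.0,
        )
    return pd.DataFrame(
        {"numi": numi, "ngene": ngene, "mito_rate": mito_rate, "log10_genes_per_umi": ratio}
    )


QC_CRITERIA = ["numi_low", "numi_high", "ngene_low", "ngene_high", "mito_high", "ratio_low"]


def qc_filter_cells(
    atlas: ExpressionAtlas, th: QCThresholds
) -> tuple[ExpressionAtlas, dict]:
    """Remove cells violating any QC cutoff (strict inequalities).

    Returns the filtered atlas and a report counting removals per
    criterion (a cell can fail several criteria and is counted under
    each).
    """
    m = cell_qc_metrics(atlas, th.mito_gene_prefix)
    fails = {
        "numi_low": m["numi"] < th.numi_min,
        "numi_high": m["numi"] > th.numi_max,
        "ngene_low": m["ngene"] < th.ngene_min,
        "ngene_high": m["ngene"] > th.ngene_max,
        "mito_high": m["mito_rate"] > th.mito_rate_max,
        "ratio_low": m["log10_genes_per_umi"] < th.log10_genes_per_umi_min,
    }
    removed = np.zeros(atlas.n_cells, dtype=bool)
    report = {"n_input": atlas.n_cells, "removed_by": {}}
    for name in QC_CRITERIA:
        mask = np.asarray(fails[name], dtype=bool)
        report["removed_by"][name] = int(mask.sum())
        removed |= mask
    report["n_removed"] = int(removed.sum())
    report["n_retained"] = int((~removed).sum())
    return atlas.subset_cells(~removed), report


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  summary: dict | None = None) -> dict[str, Path]:
    """Write tabular results as TSV (plus an optional JSON run summary).

    Round-trip contract: ``pd.read_csv(path, sep="\\t")`` returns a frame
    equal to the one written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        written[name] = path
    if summary is not None:
        path = out / "report.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written["report"] = path
    return written
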