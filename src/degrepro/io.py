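"""Tab-separated readers and writers for counts, annotations, truth and reports.

Dialect: tab-separated, UTF-8, '.' decimal, no quoting; floats written with
six significant digits so reruns diff cleanly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .decore import DEResult, validate_annotation, validate_counts
from .resampling import REPEAT_LABELS, GridResult
from .simulate import SimTruth

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "write_truth",
    "write_outlier_positions",
    "write_de_table",
    "write_grid_manifest",
    "write_report",
]

FLOAT_FORMAT = "%.6g"


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count TSV (first column gene id, header of sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ValueError(f"cannot parse count matrix {path}: {exc}") from exc
    df.index.name = "gene"
    df.columns.name = "sample"
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t")


def read_annotation(path) -> pd.Series:
    """Read a two-column TSV mapping sample id to group in {tumor, normal}."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ValueError(f"cannot parse annotation {path}: {exc}") from exc
    ann = df.iloc[:, 0].rename("group")
    validate_annotation(ann, ann.index)
    return ann


def write_annotation(ann: pd.Series, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ann.rename("group").to_csv(path, sep="\t", index_label="sample")


def write_truth(truth: SimTruth, path) -> None:
    """Write per-gene truth: gene, is_true_de, true_log2fc, dispersion."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "is_true_de": truth.is_true_de,
            "true_log2fc": truth.true_log2fc,
            "dispersion": truth.gene_dispersions,
        }
    )
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def write_outlier_positions(truth: SimTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.outlier_cells.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_de_table(result: DEResult, path) -> None:
    """Write the DE table sorted by FDR ascending, then gene id."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # stable sort: gene id breaks FDR ties
    table = result.table.sort_index().sort_values("FDR", kind="mergesort")
    table.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def write_grid_manifest(grid: GridResult, path) -> None:
    """Write the sampling design: columns n, repeat, group, sample_id."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for n in grid.n_values:
        design = grid.designs[n]
        for label in REPEAT_LABELS:
            for grp in ("tumor", "normal"):
                for sid in design.repeats[label][grp]:
                    rows.append((n, label, grp, sid))
    pd.DataFrame(rows, columns=["n", "repeat", "group", "sample_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_report(report: pd.DataFrame, path) -> None:
    """Write a tidy per-n report table (one row per n)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
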