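"""Plain-text readers/writers for the pipeline's tabular formats.

All tables are TSV with a header; intervals are BED (0-based, half-open);
haplotype tables are long format (sample, amplicon, bin, count, prevalence).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_haplotype_table", "write_haplotype_table",
    "read_beta_matrix", "write_beta_matrix",
    "read_labels", "write_labels",
    "read_bed", "write_bed",
]


def read_haplotype_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    expected = {"sample", "amplicon", "bin", "count", "prevalence"}
    missing = expected - set(table.columns)
    if missing:
        raise ValueError(f"haplotype table missing columns: {sorted(missing)}")
    table["bin"] = table["bin"].astype(float).round(1)
    return table


def write_haplotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_beta_matrix(path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t")
    if beta.columns[0] != "chrom" or beta.columns[1] != "pos":
        raise ValueError("beta matrix must start with chrom and pos columns")
    return beta


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index=False)


def read_labels(path, value_col: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels TSV needs a sample column and a label column")
    col = value_col or df.columns[1]
    return df.set_index(df.columns[0])[col]


def write_labels(labels: pd.Series, path, name: str = "label") -> None:
    labels.rename(name).rename_axis("sample").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    return bed


def write_bed(intervals: pd.DataFrame, path, extra_cols: list | None = None) -> None:
    cols = ["chrom", "start", "end"] + [c for c in (extra_cols or [])
                                        if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)
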