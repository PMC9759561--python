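"""Reading and writing the pipeline's plain-text interchange formats.

TSV for peptide tables, sample designs, count matrices and result tables;
FASTA for protein sequences (via :class:`ProteinSequenceSet`); JSON for
truth tables and reports. Thin pandas wrappers with column validation.
"""

from __future__ import annotations

import json

import pandas as pd

from .containers import check_design, check_peptides


def read_peptides(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["is_unique"] = table["is_unique"].astype(bool)
    return check_peptides(table)


def write_peptides(table: pd.DataFrame, path) -> None:
    check_peptides(table).to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    check_design(design)
    return design


def write_design(design: pd.DataFrame, path) -> None:
    check_design(design)
    design.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    with open(path) as fh:
        records = json.load(fh)
    return pd.DataFrame(records).set_index("gene_id", drop=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    records = truth.reset_index(drop=True).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1, default=bool)
        fh.write("\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Generic result-table writer (DE results, Venn calls, motif stats)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" in df.columns:
        df = df.set_index("gene_id", drop=False)
    return df
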