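"""Peptide-to-protein summarization and the expression/detection/AHA filters.

Protein abundance is the log2 of the median intensity of all peptides
attributed to the protein in a sample. A protein is *expressed* when it is
represented by more than two distinct unique peptides, *detected* when it is
observed in at least three of four replicates of every biological group, and
*AHA-enriched* when its mean linear abundance in labelled samples is at least
five-fold above the non-labelled background. A single blank replicate within
a group is imputed with the mean of the other replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    BACKGROUND,
    ProteinMatrix,
    check_design,
    check_peptides,
    empty_protein_matrix,
)


def summarize_proteins(peptides: pd.DataFrame, min_unique: int = 3) -> ProteinMatrix:
    """Median-peptide protein quantification with the unique-peptide rule.

    Per gene and sample the abundance is ``log2(median intensity)`` over the
    peptides observed there; a gene is flagged ``expressed`` iff it has at
    least ``min_unique`` distinct unique peptides across the experiment
    (default 3, i.e. "more than 2"). Genes with no observed peptide in a
    sample are missing (NaN) there. An empty table yields an empty matrix
    with a warning rather than an error.
    """
    if peptides.empty:
        return empty_protein_matrix()
    peptides = check_peptides(peptides)

    med = (
        peptides.groupby(["gene_id", "sample_id"], sort=True)["intensity"]
        .median()
        .unstack("sample_id")
    )
    log2 = np.log2(med.where(med > 0))

    n_unique = (
        peptides.loc[peptides["is_unique"].astype(bool)]
        .groupby("gene_id")["peptide_id"]
        .nunique()
        .reindex(log2.index, fill_value=0)
    )
    matrix = ProteinMatrix(log2)
    matrix.flags["expressed"] = (n_unique >= min_unique).astype("boolean")
    matrix.meta["n_unique_peptides"] = n_unique
    return matrix


def _group_samples(design: pd.DataFrame, matrix: ProteinMatrix) -> dict[str, list[str]]:
    design = check_design(design)
    present = design[design["sample_id"].isin(matrix.samples)]
    return {g: list(sub["sample_id"]) for g, sub in present.groupby("group", sort=True)}


def filter_detection(
    matrix: ProteinMatrix, design: pd.DataFrame, min_present: int = 3
) -> ProteinMatrix:
    """Flag genes observed in >= ``min_present`` replicates of every group.

    Background samples do not count towards (or against) detection. All rows
    are preserved; only the ``detected`` flag is toggled.
    """
    groups = _group_samples(design, matrix)
    bio_groups = {g: s for g, s in groups.items() if g != BACKGROUND}
    if not bio_groups:
        raise ValueError("design contains no biological groups for the matrix samples")
    for g, samples in bio_groups.items():
        if len(samples) < min_present:
            raise ValueError(
                f"group {g!r} has {len(samples)} samples, fewer than min_present={min_present}"
            )
    out = matrix.copy()
    detected = pd.Series(True, index=out.genes)
    for samples in bio_groups.values():
        detected &= out.log2[samples].notna().sum(axis=1) >= min_present
    out.flags["detected"] = detected.astype("boolean")
    return out


def filter_aha_enrichment(
    matrix: ProteinMatrix, design: pd.DataFrame, min_fold: float = 5.0
) -> ProteinMatrix:
    """Flag genes enriched >= ``min_fold`` in AHA-labelled samples vs background.

    The comparison is on the linear intensity scale (a fold is a linear
    ratio): mean over observed labelled samples against mean over observed
    Background samples. A gene never observed in Background passes (the ratio
    is treated as infinite).
    """
    groups = _group_samples(design, matrix)
    bg_samples = groups.get(BACKGROUND, [])
    if not bg_samples:
        raise ValueError("design contains no Background samples for the matrix")
    labelled = [s for g, ss in groups.items() if g != BACKGROUND for s in ss]

    linear = matrix.linear()
    lab_mean = linear[labelled].mean(axis=1, skipna=True)
    bg_obs = linear[bg_samples].notna().sum(axis=1)
    bg_mean = linear[bg_samples].mean(axis=1, skipna=True)

    out = matrix.copy()
    # tiny relative epsilon: abundances round-trip through log2 storage
    passes = (bg_obs == 0) | (lab_mean >= min_fold * bg_mean * (1.0 - 1e-9))
    passes &= lab_mean.notna()
    out.flags["aha_enriched"] = passes.astype("boolean")
    return out


def impute_single_missing(matrix: ProteinMatrix, design: pd.DataFrame) -> ProteinMatrix:
    """Replace a single blank replicate by the mean of the group's others.

    For each detected gene and biological group with exactly one missing
    replicate and at least three observed, the blank is set to the arithmetic
    mean of the other replicates' log2 values and flagged in ``imputed``.
    Groups with two or more blanks are left untouched, as are genes whose
    ``detected`` flag is False (they carry no imputed values downstream).
    """
    groups = _group_samples(design, matrix)
    out = matrix.copy()
    detected = out.flags["detected"]
    eligible = detected.fillna(True).astype(bool) if detected.notna().any() else pd.Series(True, index=out.genes)
    for group, samples in groups.items():
        if group == BACKGROUND or len(samples) < 4:
            continue
        block = out.log2[samples]
        n_missing = block.isna().sum(axis=1)
        rows = eligible & (n_missing == 1)
        if not rows.any():
            continue
        fill = block.loc[rows].mean(axis=1, skipna=True)
        for gene in block.index[rows]:
            col = block.columns[block.loc[gene].isna()][0]
            out.log2.at[gene, col] = fill[gene]
            out.imputed.at[gene, col] = True
    return out
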