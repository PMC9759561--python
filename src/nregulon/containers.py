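"""Core data containers shared across the pipeline.

Tabular data (peptide evidence, sample designs, truth tables, test results)
travels as :class:`pandas.DataFrame` with documented column contracts; the two
bespoke containers are :class:`ProteinSequenceSet` (an ordered gene -> amino
acid sequence mapping with FASTA round-tripping) and :class:`ProteinMatrix`
(a genes x samples log2-abundance matrix carrying filter provenance flags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: biological groups of the four-arm design; Background is the non-labelled control
GROUPS = ("Mock", "GC7", "WT", "KO")
BACKGROUND = "Background"

#: required columns of a long-format peptide table
PEPTIDE_COLUMNS = ("peptide_id", "gene_id", "sample_id", "intensity", "is_unique")
#: required columns of a sample design table
DESIGN_COLUMNS = ("sample_id", "group", "replicate", "pair_id", "input_cells")


class ProteinSequenceSet:
    """Ordered mapping of gene identifiers to amino-acid sequences.

    Sequences are restricted to the 20 canonical residues and must be
    non-empty; gene identifiers are unique by construction of the dict.
    """

    def __init__(self, sequences: Mapping[str, str]):
        seqs = dict(sequences)
        if not seqs:
            raise ValueError("sequence set must not be empty")
        for gene, seq in seqs.items():
            if not seq:
                raise ValueError(f"empty sequence for {gene!r}")
            bad = set(seq) - _AA_SET
            if bad:
                raise ValueError(
                    f"non-canonical residues {sorted(bad)} in sequence of {gene!r}"
                )
        self.sequences: dict[str, str] = seqs

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def items(self):
        return self.sequences.items()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> pd.Series:
        return pd.Series({g: len(s) for g, s in self.sequences.items()}, name="length")

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def subset(self, gene_ids: Iterable[str]) -> "ProteinSequenceSet":
        wanted = list(gene_ids)
        missing = [g for g in wanted if g not in self.sequences]
        if missing:
            raise KeyError(f"gene ids not in sequence set: {missing[:5]}")
        return ProteinSequenceSet({g: self.sequences[g] for g in wanted})

    def genes_with_motifs(self, motifs: Iterable[str]) -> list[str]:
        """Gene ids whose sequence contains at least one of the given motifs."""
        motifs = list(motifs)
        return [g for g, s in self.sequences.items() if any(m in s for m in motifs)]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ProteinSequenceSet":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)


@dataclass
class ProteinMatrix:
    """Genes x samples log2-abundance matrix with filter provenance.

    ``log2`` holds log2-scale abundances with ``NaN`` marking missing values.
    ``flags`` is indexed by gene and carries three nullable booleans set by the
    successive filters: ``expressed`` (unique-peptide rule), ``detected``
    (replicate rule) and ``aha_enriched`` (labelled-vs-background rule); a flag
    is ``NA`` until its filter has run. ``imputed`` marks cells filled by
    single-blank imputation.
    """

    log2: pd.DataFrame
    flags: pd.DataFrame = None
    imputed: pd.DataFrame = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.flags is None:
            self.flags = pd.DataFrame(
                pd.NA,
                index=self.log2.index,
                columns=["expressed", "detected", "aha_enriched"],
                dtype="boolean",
            )
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.log2.index, columns=self.log2.columns
            )

    @property
    def genes(self) -> pd.Index:
        return self.log2.index

    @property
    def samples(self) -> pd.Index:
        return self.log2.columns

    def linear(self) -> pd.DataFrame:
        """Abundances back on the linear intensity scale (NaN preserved)."""
        return np.power(2.0, self.log2)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.log2.copy(), self.flags.copy(), self.imputed.copy(), dict(self.meta)
        )

    def analysis_genes(self) -> pd.Index:
        """Genes passing every filter whose flag has been computed."""
        keep = pd.Series(True, index=self.genes)
        for col in ("expressed", "detected", "aha_enriched"):
            flag = self.flags[col]
            if flag.notna().any():
                keep &= flag.fillna(False).astype(bool)
        return self.genes[keep]

    def subset_genes(self, gene_ids) -> "ProteinMatrix":
        idx = pd.Index(gene_ids)
        return ProteinMatrix(
            self.log2.loc[idx],
            self.flags.loc[idx],
            self.imputed.loc[idx],
            dict(self.meta),
        )

    def subset_samples(self, sample_ids) -> "ProteinMatrix":
        cols = pd.Index(sample_ids)
        return ProteinMatrix(
            self.log2[cols], self.flags.copy(), self.imputed[cols], dict(self.meta)
        )


@dataclass
class BootstrapNull:
    """Observed statistic with its resampling null distribution.

    ``empirical_p`` uses the add-one estimator
    ``(1 + #{null at least as extreme as observed}) / (n_reps + 1)`` so a
    resampling p-value is never exactly zero.
    """

    observed: float
    null_values: np.ndarray
    n_reps: int
    empirical_p: float
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.n_reps:
            raise ValueError("null_values length must equal n_reps")

    def box_stats(self) -> dict:
        """Median / quartile / 1.5*IQR-whisker summary of the null values."""
        return box_summary(self.null_values)


def box_summary(values) -> dict:
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if inside.size else float(q1),
        "whisker_high": float(inside.max()) if inside.size else float(q3),
    }


def check_design(design: pd.DataFrame, require_background: bool = False) -> pd.DataFrame:
    """Validate a sample design table and return it indexed by sample_id."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    known = set(GROUPS) | {BACKGROUND}
    bad = set(design["group"]) - known
    if bad:
        raise ValueError(f"unknown groups in design: {sorted(bad)}")
    if (design["input_cells"] <= 0).any():
        raise ValueError("input_cells must be positive")
    if require_background and not (design["group"] == BACKGROUND).any():
        raise ValueError("design contains no Background samples")
    # KO/WT sharing a pair_id must come in matched pairs
    paired = design[design["group"].isin(("KO", "WT"))]
    for pid, sub in paired.groupby("pair_id"):
        if set(sub["group"]) != {"KO", "WT"}:
            raise ValueError(f"pair_id {pid!r} does not link one KO and one WT sample")
    return design.set_index("sample_id", drop=False)


def check_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEPTIDE_COLUMNS if c not in peptides.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if (peptides["intensity"] < 0).any():
        raise ValueError("peptide intensities must be non-negative")
    if peptides.duplicated(subset=["peptide_id", "sample_id"]).any():
        raise ValueError("(peptide_id, sample_id) pairs must be unique")
    return peptides


def empty_protein_matrix(samples=()) -> ProteinMatrix:
    warnings.warn("building protein matrix from an empty peptide table", stacklevel=3)
    return ProteinMatrix(pd.DataFrame(dtype=float, columns=pd.Index(samples)))
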