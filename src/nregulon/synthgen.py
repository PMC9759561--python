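"""Synthetic data generator for the four-group nascent-proteome study design.

Emulates a click-chemistry (AHA) nascent proteomics experiment on CD8+ T
cells: four biological groups (Mock, GC7, WT, KO) with four replicates each
plus non-labelled Background samples, log-normal peptide intensities with
sample-loading effects proportional to the number of input cells, a global
per-cell down-shift in GC7-treated samples, targeted down-shifts in KO
samples enriched among polyproline-motif proteins, missing-at-random blanks,
and negative-binomial RNA counts with mostly unchanged mRNA. The planted
effects are recorded in a truth table so every downstream stage can be scored
against ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    AMINO_ACIDS,
    BACKGROUND,
    GROUPS,
    ProteinSequenceSet,
    check_design,
)

#: motifs whose translation depends on eIF5a-assisted elongation
PPP_MOTIFS = ("PPP", "PPG")

#: default input cell numbers per group (cells); GC7 cultures are loaded at
#: 2.6x the Mock number to compensate the global drop in nascent-protein
#: yield per cell, sorted fixed KO/WT cells at 10e6
DEFAULT_INPUT_CELLS = {
    "Mock": 12.5e6,
    "GC7": 32.5e6,
    "WT": 10.0e6,
    "KO": 10.0e6,
    BACKGROUND: 12.5e6,
}

TRUTH_COLUMNS = (
    "gene_id",
    "true_log2fc_gc7",
    "true_log2fc_ko",
    "is_translational_target",
    "rna_log2fc",
    "has_ppp",
    "is_top",
)


def _contains_ppp(seq: str) -> bool:
    return any(m in seq for m in PPP_MOTIFS)


def generate_proteome(
    n_genes: int,
    ppp_fraction: float | None = 0.3,
    mean_length: int = 300,
    seed: int = 0,
    residue_freqs: dict[str, float] | None = None,
) -> ProteinSequenceSet:
    """Generate random protein sequences with a controlled polyproline fraction.

    Exactly ``round(ppp_fraction * n_genes)`` sequences contain at least one
    PPP or PPG trimer: motif-positive genes get an explicit insertion, the
    rest are rejection-sampled until free of chance hits, so the emitted
    fraction is deterministic. ``ppp_fraction=None`` disables the control and
    leaves motif occurrence to chance. Residues are otherwise i.i.d. from
    ``residue_freqs`` (uniform over the 20 canonical residues by default) and
    lengths are Poisson around ``mean_length`` (floor 30).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_length < 1:
        raise ValueError("mean_length must be >= 1")
    if ppp_fraction is not None and not 0.0 <= ppp_fraction <= 1.0:
        raise ValueError("ppp_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    if residue_freqs is None:
        probs = None
    else:
        probs = np.array([residue_freqs.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("residue_freqs must have positive total mass")
        probs = probs / probs.sum()

    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]

    if ppp_fraction is None:
        with_motif = None
    else:
        n_ppp = int(round(ppp_fraction * n_genes))
        order = rng.permutation(n_genes)
        with_motif = np.zeros(n_genes, dtype=bool)
        with_motif[order[:n_ppp]] = True

    lengths = np.maximum(30, rng.poisson(mean_length, size=n_genes))
    sequences: dict[str, str] = {}
    for i, gene in enumerate(gene_ids):
        seq = "".join(rng.choice(aa, size=lengths[i], p=probs))
        if with_motif is None:
            sequences[gene] = seq
            continue
        if with_motif[i]:
            motif = PPP_MOTIFS[rng.integers(len(PPP_MOTIFS))]
            pos = int(rng.integers(0, len(seq) - 2))
            seq = seq[:pos] + motif + seq[pos + 3 :]
        else:
            while _contains_ppp(seq):
                seq = "".join(rng.choice(aa, size=lengths[i], p=probs))
        sequences[gene] = seq
    return ProteinSequenceSet(sequences)


def plant_motif_occurrences(
    seqs: ProteinSequenceSet, motif: str, n_occurrences: int, seed: int = 0
) -> ProteinSequenceSet:
    """Write ``n_occurrences`` copies of a trimer into random sequence slots.

    Slots are drawn uniformly over all 3-mer windows of the set (so long
    proteins receive proportionally more insertions) without overlap between
    insertions. Used to plant a motif at a controlled rate for power studies.
    """
    if len(motif) != 3:
        raise ValueError("motif must have length 3")
    rng = np.random.default_rng(seed)
    genes = seqs.gene_ids
    arrs = {g: list(seqs[g]) for g in genes}
    windows = np.array([max(len(seqs[g]) - 2, 0) for g in genes])
    if n_occurrences > windows.sum() // 3:
        raise ValueError("too many occurrences for the available windows")
    weights = windows / windows.sum()
    used: set[tuple[str, int]] = set()
    planted = 0
    attempts = 0
    while planted < n_occurrences:
        attempts += 1
        if attempts > 1000 * (n_occurrences + 1):
            raise RuntimeError("could not place all motif occurrences")
        g = genes[rng.choice(len(genes), p=weights)]
        pos = int(rng.integers(0, max(len(arrs[g]) - 2, 1)))
        if any((g, p) in used for p in range(pos - 2, pos + 3)):
            continue
        # writing next to an identical flanking residue would create extra
        # overlapping occurrences (e.g. P|PPP -> two PPP hits); skip such slots
        before = "".join(arrs[g][max(pos - 2, 0) : pos])
        after = "".join(arrs[g][pos + 3 : pos + 5])
        if _overlap_count(before + motif + after, motif) != 1:
            continue
        arrs[g][pos : pos + 3] = list(motif)
        used.add((g, pos))
        planted += 1
    return ProteinSequenceSet({g: "".join(arrs[g]) for g in genes})


def _overlap_count(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def make_design(
    n_reps: int = 4,
    input_cells: dict[str, float] | None = None,
    with_background: bool = True,
) -> pd.DataFrame:
    """Sample design table for the four-group study (plus Background).

    KO and WT replicates with the same index are sorted from the same culture
    and share a ``pair_id``.
    """
    cells = dict(DEFAULT_INPUT_CELLS)
    if input_cells:
        cells.update(input_cells)
    groups = list(GROUPS) + ([BACKGROUND] if with_background else [])
    rows = []
    for group in groups:
        for r in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{group}_{r}",
                    "group": group,
                    "replicate": r,
                    "pair_id": f"P{r}" if group in ("KO", "WT") else pd.NA,
                    "input_cells": cells[group],
                }
            )
    return pd.DataFrame(rows)


def make_truth(
    proteome: ProteinSequenceSet,
    n_targets: int = 60,
    target_log2fc_ko: float = -1.5,
    target_log2fc_gc7: float = -1.5,
    gc7_global_log2fc: float = -float(np.log2(3.0)),
    ppp_enrichment_odds: float = 3.0,
    rna_down_fraction: float = 0.05,
    rna_down_log2fc: float = -1.5,
    n_top: int = 80,
    top_ko_log2fc: float = float(np.log2(1.29)),
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth table of planted effects for a generated proteome.

    Translational targets (eIF5a-regulated genes) are down-shifted in both KO
    and GC7 nascent protein with unchanged mRNA, and are drawn preferentially
    from PPP/PPG-containing genes with the given enrichment odds so the motif
    stage has signal. All non-target genes share the global GC7 per-cell
    down-shift; a small fraction are transcriptionally down (mRNA and protein
    reduced together) and must be rejected by the Venn logic. A disjoint
    random subset is annotated as 5'TOP with a mild positive KO shift.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(proteome.gene_ids)
    n = len(genes)
    if n_targets > n:
        raise ValueError("n_targets exceeds number of genes")
    has_ppp = np.array([_contains_ppp(proteome[g]) for g in genes])

    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    weights = np.where(has_ppp, ppp_enrichment_odds, 1.0)
    keys = rng.random(n) ** (1.0 / weights)
    target_idx = np.argsort(keys)[-n_targets:]
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    rna_log2fc = np.zeros(n)
    pool = np.flatnonzero(~is_target)
    n_rna_down = int(round(rna_down_fraction * n))
    rna_down_idx = rng.choice(pool, size=min(n_rna_down, len(pool)), replace=False)
    rna_log2fc[rna_down_idx] = rna_down_log2fc

    true_gc7 = np.full(n, gc7_global_log2fc)
    # transcriptionally down genes lose nascent protein through their mRNA
    true_gc7[rna_down_idx] += rna_down_log2fc
    true_gc7[is_target] = target_log2fc_gc7

    true_ko = np.zeros(n)
    true_ko[is_target] = target_log2fc_ko

    is_top = np.zeros(n, dtype=bool)
    top_pool = np.flatnonzero(~is_target)
    top_idx = rng.choice(top_pool, size=min(n_top, len(top_pool)), replace=False)
    is_top[top_idx] = True
    true_ko[top_idx] += top_ko_log2fc

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_log2fc_gc7": true_gc7,
            "true_log2fc_ko": true_ko,
            "is_translational_target": is_target,
            "rna_log2fc": rna_log2fc,
            "has_ppp": has_ppp,
            "is_top": is_top,
        }
    ).set_index("gene_id", drop=False)

    bad = truth["is_translational_target"] & (
        (truth["true_log2fc_ko"] > -np.log2(1.5)) | (truth["rna_log2fc"] < 0)
    )
    if bad.any():  # pragma: no cover - guards future parameter misuse
        raise ValueError("planted targets violate the translational-target invariant")
    return truth


def generate_nascent_experiment(
    design: pd.DataFrame,
    truth: pd.DataFrame,
    peptide_rate: float = 7.0,
    noise_sd: float = 0.25,
    missing_rate: float = 0.03,
    seed: int = 0,
    baseline_mean: float = 17.0,
    baseline_sd: float = 2.5,
    peptide_offset_sd: float = 1.0,
    unique_fraction: float = 0.95,
    background_log2_shift: float = -3.5,
    contaminant_fraction: float = 0.02,
) -> pd.DataFrame:
    """Simulate a long-format peptide intensity table for the full design.

    Each protein receives ``1 + Poisson(peptide_rate)`` peptides. A peptide's
    log2 intensity is baseline + planted group effect + loading term
    ``log2(input_cells / min input_cells)`` + peptide offset + Gaussian noise.
    Background (non-AHA) samples sit ``background_log2_shift`` below the
    labelled baseline (about 11-fold, comfortably failing a 5x enrichment
    filter) except for a contaminant fraction of proteins that carry full
    signal. Whole protein/sample cells are blanked missing-at-random at
    ``missing_rate``.
    """
    design = check_design(design, require_background=True)
    for group in GROUPS:
        if not (design["group"] == group).any():
            raise ValueError(f"design is missing required group {group!r}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    genes = truth["gene_id"].to_numpy()
    n_genes = len(genes)
    samples = design["sample_id"].to_numpy()
    groups = design["group"].to_numpy()
    loading = np.log2(design["input_cells"].to_numpy() / design["input_cells"].min())

    group_effect = np.zeros((n_genes, len(samples)))
    gc7 = truth["true_log2fc_gc7"].to_numpy()
    ko = truth["true_log2fc_ko"].to_numpy()
    contaminant = rng.random(n_genes) < contaminant_fraction
    bg = np.where(contaminant, 0.0, background_log2_shift)
    for j, grp in enumerate(groups):
        if grp == "GC7":
            group_effect[:, j] = gc7
        elif grp == "KO":
            group_effect[:, j] = ko
        elif grp == BACKGROUND:
            group_effect[:, j] = bg

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    n_pep = 1 + rng.poisson(peptide_rate, size=n_genes)
    total_pep = int(n_pep.sum())
    pep_gene_idx = np.repeat(np.arange(n_genes), n_pep)
    pep_offset = rng.normal(0.0, peptide_offset_sd, size=total_pep)
    is_unique = rng.random(total_pep) < unique_fraction

    pep_num = np.concatenate([np.arange(1, k + 1) for k in n_pep])
    peptide_ids = np.array(
        [f"{genes[g]}_p{j}" for g, j in zip(pep_gene_idx, pep_num)]
    )

    # log2 intensity per peptide x sample
    log2 = (
        baseline[pep_gene_idx, None]
        + group_effect[pep_gene_idx, :]
        + loading[None, :]
        + pep_offset[:, None]
        + rng.normal(0.0, noise_sd, size=(total_pep, len(samples)))
    )

    observed_protein = rng.random((n_genes, len(samples))) >= missing_rate
    observed = observed_protein[pep_gene_idx, :]

    table = pd.DataFrame(
        {
            "peptide_id": np.repeat(peptide_ids, len(samples)),
            "gene_id": np.repeat(genes[pep_gene_idx], len(samples)),
            "sample_id": np.tile(samples, total_pep),
            "intensity": np.power(2.0, log2).ravel(),
            "is_unique": np.repeat(is_unique, len(samples)),
        }
    )
    return table.loc[observed.ravel()].reset_index(drop=True)


def annotate_filter_casualties(
    truth: pd.DataFrame,
    peptides: pd.DataFrame,
    design: pd.DataFrame,
    min_unique: int = 3,
    min_present: int = 3,
) -> pd.DataFrame:
    """Mark genes whose simulated evidence cannot survive the input filters.

    Adds a boolean ``filter_casualty`` column to the truth table: genes with
    fewer than ``min_unique`` distinct unique peptides, or blanked in more
    than ``4 - min_present`` replicates of some biological group, are
    legitimate losses of the filter cascade rather than analysis errors.
    """
    design = check_design(design)
    unique_counts = (
        peptides.loc[peptides["is_unique"].astype(bool)]
        .groupby("gene_id")["peptide_id"]
        .nunique()
        .reindex(truth.index, fill_value=0)
    )
    casualty = unique_counts < min_unique
    observed = (
        peptides.groupby(["gene_id", "sample_id"])
        .size()
        .unstack("sample_id")
        .notna()
        .reindex(truth.index, fill_value=False)
    )
    for group in GROUPS:
        samples = [s for s in design.index[design["group"] == group] if s in observed.columns]
        casualty |= observed[samples].sum(axis=1) < min_present
    out = truth.copy()
    out["filter_casualty"] = casualty.to_numpy()
    return out


def generate_rna_counts(
    truth: pd.DataFrame,
    design: pd.DataFrame | None = None,
    lib_sizes: float | pd.Series = 1.0e6,
    dispersion: float = 0.1,
    seed: int = 0,
    expression_sd: float = 2.0,
) -> pd.DataFrame:
    """Negative-binomial RNA counts for the GC7-vs-Mock sequencing arm.

    Per-gene relative expression is log-normal; the expected count of gene g
    in sample s is ``lib_size(s) * rel_expr(g) * 2^rna_log2fc(g)`` for GC7
    samples and without the fold term otherwise. ``dispersion = 0``
    degenerates to Poisson sampling.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if design is None:
        design = make_design()
    design = check_design(design)
    rna_design = design[design["group"].isin(("Mock", "GC7"))]
    samples = rna_design["sample_id"].to_numpy()
    if isinstance(lib_sizes, (int, float)):
        libs = pd.Series(float(lib_sizes), index=samples)
    else:
        libs = pd.Series(lib_sizes).reindex(samples)
        if libs.isna().any():
            raise ValueError("lib_sizes missing for some RNA samples")
    if (libs <= 0).any():
        raise ValueError("lib_sizes must be positive")

    rng = np.random.default_rng(seed)
    genes = truth["gene_id"].to_numpy()
    rel = np.power(2.0, rng.normal(0.0, expression_sd, size=len(genes)))
    rel = rel / rel.sum()
    fold = np.power(2.0, truth["rna_log2fc"].to_numpy())
    is_gc7 = (rna_design["group"] == "GC7").to_numpy()

    mean = rel[:, None] * libs.to_numpy()[None, :]
    mean = mean * np.where(is_gc7[None, :], fold[:, None], 1.0)
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
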