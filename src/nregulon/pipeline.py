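"""End-to-end orchestration: synthetic data -> filters -> normalization ->
differential tests -> Venn calls -> motif and bootstrap analyses.

Every stage logs its gene counts to stderr (the headline numbers of this
kind of study are cohort sizes) and the final report collects them together
with the Venn set sizes, motif statistics, bootstrap summaries and, because
the inputs are synthetic, recovery metrics against the planted truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffexpr, motifs, normalize, quantify, regulon, synthgen
from .containers import BACKGROUND, ProteinMatrix, ProteinSequenceSet

logger = logging.getLogger("nregulon")


@dataclass
class PipelineConfig:
    """Study conditions and analysis thresholds of a full synthetic run."""

    n_genes: int = 3000
    ppp_fraction: float = 0.3
    mean_length: int = 300
    n_targets: int = 60
    target_log2fc: float = -1.5
    noise_sd: float = 0.25
    missing_rate: float = 0.03
    n_reps: int = 4
    rna_dispersion: float = 0.1
    rna_lib_size: float = 1.0e6
    n_random_trimers: int = 50
    bootstrap_draw: int = 2900
    bootstrap_reps: int = 1000
    min_unique: int = 3
    min_present: int = 3
    aha_fold: float = 5.0
    impute_stage: str = "post"  # impute before or after normalization
    missing_rna: str = "exclude"
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "PipelineConfig":
        if not mapping:
            return cls()
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class PipelineResult:
    proteome: ProteinSequenceSet
    design: pd.DataFrame
    truth: pd.DataFrame
    peptides: pd.DataFrame
    counts: pd.DataFrame
    matrix: ProteinMatrix
    gc7: pd.DataFrame
    ko: pd.DataFrame
    rna: pd.DataFrame
    calls: pd.DataFrame
    motif_stats: pd.DataFrame
    pp_bootstrap: object
    top_shift: object | None
    report: dict


def prepare_matrix(
    peptides: pd.DataFrame, design: pd.DataFrame, config: PipelineConfig
) -> ProteinMatrix:
    """Quantify, filter, normalize and impute the protein matrix.

    Applies, in order: median summarization with the unique-peptide rule, the
    3-of-4 detection rule, the 5x AHA-enrichment rule; then restricts to the
    surviving genes, drops Background columns, runs glog normalization and
    the input-cell adjustment, and imputes single blanks (before
    normalization instead when ``impute_stage="pre"``).
    """
    matrix = quantify.summarize_proteins(peptides, min_unique=config.min_unique)
    logger.info("quantified %d proteins from %d peptide rows", len(matrix.genes), len(peptides))
    matrix = quantify.filter_detection(matrix, design, min_present=config.min_present)
    matrix = quantify.filter_aha_enrichment(matrix, design, min_fold=config.aha_fold)
    flags = matrix.flags
    logger.info(
        "filters: expressed %d, detected %d, aha_enriched %d, all %d",
        int(flags["expressed"].fillna(False).sum()),
        int(flags["detected"].fillna(False).sum()),
        int(flags["aha_enriched"].fillna(False).sum()),
        len(matrix.analysis_genes()),
    )
    analysis = matrix.subset_genes(matrix.analysis_genes())
    labelled = [
        s
        for s in analysis.samples
        if design.set_index("sample_id").loc[s, "group"] != BACKGROUND
    ]
    analysis = analysis.subset_samples(labelled)
    if config.impute_stage == "pre":
        analysis = quantify.impute_single_missing(analysis, design)
    analysis = normalize.vsn_like_normalize(analysis)
    analysis = normalize.cell_number_adjust(analysis, design)
    if config.impute_stage == "post":
        analysis = quantify.impute_single_missing(analysis, design)
    return analysis


def run_all(config: PipelineConfig | dict | None = None, seed: int = 0) -> PipelineResult:
    """Run the complete synthetic-data pipeline and report every stage."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_mapping(config)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    proteome = synthgen.generate_proteome(
        config.n_genes, config.ppp_fraction, config.mean_length, seed=int(seeds[0])
    )
    design = synthgen.make_design(n_reps=config.n_reps)
    truth = synthgen.make_truth(
        proteome,
        n_targets=config.n_targets,
        target_log2fc_ko=config.target_log2fc,
        target_log2fc_gc7=config.target_log2fc,
        seed=int(seeds[1]),
    )
    peptides = synthgen.generate_nascent_experiment(
        design,
        truth,
        noise_sd=config.noise_sd,
        missing_rate=config.missing_rate,
        seed=int(seeds[2]),
    )
    counts = synthgen.generate_rna_counts(
        truth,
        design,
        lib_sizes=config.rna_lib_size,
        dispersion=config.rna_dispersion,
        seed=int(seeds[3]),
    )

    matrix = prepare_matrix(peptides, design, config)

    gc7 = diffexpr.unpaired_t_bh(matrix, design, ("GC7", "Mock"))
    ko = diffexpr.paired_t(matrix, design, ("KO", "WT"))
    rna = diffexpr.nb_rna_test(counts, design, ("GC7", "Mock"))

    calls = regulon.call_translational_sets(
        rna, gc7, ko, thresholds=config.thresholds, missing_rna=config.missing_rna
    )
    sizes = regulon.set_sizes(calls)
    logger.info("venn sets: %s", sizes)

    regulated = calls.index[calls["eif5a_regulated"]]
    pp_reference = proteome.genes_with_motifs(synthgen.PPP_MOTIFS)
    universe = list(truth["gene_id"])

    if len(regulated) > 0:
        motif_stats = motifs.motif_enrichment(
            proteome.subset(regulated),
            n_random=config.n_random_trimers,
            seed=int(seeds[4]),
        )
        # cap the draw below the universe size: drawing (almost) the whole
        # universe without replacement degenerates the null to a constant
        pp_boot = motifs.polyproline_bootstrap(
            regulated,
            pp_reference,
            universe,
            n_draw=min(config.bootstrap_draw, int(0.8 * len(universe))),
            n_reps=config.bootstrap_reps,
            seed=int(seeds[5]),
        )
    else:  # degenerate run with no called genes
        motif_stats = pd.DataFrame(columns=["motif", "count", "windows", "freq", "p"])
        pp_boot = None

    top_genes = [g for g in truth.index[truth["is_top"]] if g in ko.index and not np.isnan(ko.loc[g, "log2fc"])]
    top_shift = (
        regulon.top_mrna_shift(ko, top_genes, n_reps=config.bootstrap_reps, seed=int(seeds[6]))
        if len(top_genes) >= 2
        else None
    )

    recovery = regulon.recovery_metrics(
        regulated, truth.index[truth["is_translational_target"]]
    )
    logger.info("recovery vs truth: %s", recovery)

    report = {
        "stage_counts": {
            "genes_simulated": config.n_genes,
            "peptide_rows": int(len(peptides)),
            "analysis_genes": int(len(matrix.genes)),
        },
        "de_counts": {
            "gc7_down": int(((gc7["fdr"] < 0.05) & (gc7["log2fc"] < -np.log2(1.5))).sum()),
            "gc7_up": int(((gc7["fdr"] < 0.05) & (gc7["log2fc"] > np.log2(1.5))).sum()),
            "ko_down": int(((ko["p"] < 0.05) & (ko["log2fc"] < -np.log2(1.5))).sum()),
            "ko_up": int(((ko["p"] < 0.05) & (ko["log2fc"] > np.log2(1.5))).sum()),
        },
        "venn_sizes": sizes,
        "recovery": recovery,
        "motif_stats": motif_stats.to_dict(orient="records"),
        "pp_bootstrap": None
        if pp_boot is None
        else {
            "observed_percent": pp_boot.observed,
            "empirical_p": pp_boot.empirical_p,
            "null_box": pp_boot.box_stats(),
        },
        "top_shift": None
        if top_shift is None
        else {
            "median_fc": top_shift.observed,
            "empirical_p": top_shift.empirical_p,
            **{k: v for k, v in top_shift.extras.items() if k != "median_fc"},
        },
    }
    return PipelineResult(
        proteome,
        design,
        truth,
        peptides,
        counts,
        matrix,
        gc7,
        ko,
        rna,
        calls,
        motif_stats,
        pp_boot,
        top_shift,
        report,
    )


def report_json(result: PipelineResult, path=None) -> str:
    text = json.dumps(result.report, indent=2, default=float)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
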