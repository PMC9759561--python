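"""Venn classification of translational regulation and gene-list shift tests.

A gene is *translationally regulated under GC7* when its mRNA is not reduced
(RNA FDR > 0.1, or FDR < 0.01 with linear fold > 2, i.e. significantly
increased) while its nascent protein is down (protein FDR < 0.05 and linear
fold < -1.5). The *eIF5a-regulated* set further requires nascent-protein
reduction in the KO (paired p < 0.05 and fold < -1.5). The 5'TOP comparison
tests whether an annotated gene list is shifted in KO fold change relative
to bootstrapped same-size gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BootstrapNull

#: selection thresholds of the Venn classification
DEFAULT_THRESHOLDS = {
    "rna_fdr_hi": 0.1,
    "rna_fdr_lo": 0.01,
    "rna_fc": 2.0,
    "prot_fdr": 0.05,
    "prot_p": 0.05,
    "prot_fc": 1.5,
}


def call_translational_sets(
    rna: pd.DataFrame,
    gc7: pd.DataFrame,
    ko: pd.DataFrame,
    thresholds: dict | None = None,
    missing_rna: str = "exclude",
) -> pd.DataFrame:
    """Per-gene boolean Venn classification from the three test results.

    The "not reduced in mRNA" rule is read as A OR (B AND C): either the RNA
    change is non-significant (FDR above the high cut) or it is a significant
    *increase* (FDR below the low cut with linear fold above ``rna_fc``).
    Genes without an RNA measurement are excluded from the translational sets
    by default (``missing_rna="pass"`` treats them as not reduced instead).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if missing_rna not in ("exclude", "pass"):
        raise ValueError("missing_rna must be 'exclude' or 'pass'")
    for name, df in (("rna", rna), ("gc7", gc7), ("ko", ko)):
        if df.index.duplicated().any():
            raise ValueError(f"duplicate gene ids in {name} results")

    genes = gc7.index.intersection(ko.index)
    lfc_prot = np.log2(thr["prot_fc"])
    lfc_rna = np.log2(thr["rna_fc"])

    rna_al = rna.reindex(genes)
    has_rna = rna_al["fdr"].notna()
    not_reduced = (rna_al["fdr"] > thr["rna_fdr_hi"]) | (
        (rna_al["fdr"] < thr["rna_fdr_lo"]) & (rna_al["log2fc"] > lfc_rna)
    )
    if missing_rna == "pass":
        not_reduced = not_reduced | ~has_rna
    rna_not_reduced = not_reduced.fillna(False).astype(bool)

    gc7_al, ko_al = gc7.loc[genes], ko.loc[genes]
    gc7_down = (
        (gc7_al["fdr"] < thr["prot_fdr"]) & (gc7_al["log2fc"] < -lfc_prot)
    ).fillna(False)
    ko_down = ((ko_al["p"] < thr["prot_p"]) & (ko_al["log2fc"] < -lfc_prot)).fillna(
        False
    )

    calls = pd.DataFrame(
        {
            "gene_id": genes,
            "has_rna": has_rna.to_numpy(),
            "rna_not_reduced": rna_not_reduced.to_numpy(),
            "gc7_protein_down": gc7_down.to_numpy(),
            "ko_protein_down": ko_down.to_numpy(),
        }
    ).set_index("gene_id", drop=False)
    calls["translational_gc7"] = calls["rna_not_reduced"] & calls["gc7_protein_down"]
    calls["eif5a_regulated"] = calls["translational_gc7"] & calls["ko_protein_down"]
    return calls


def set_sizes(calls: pd.DataFrame) -> dict[str, int]:
    """Cohort sizes of every Venn flag (the headline numbers of a run)."""
    cols = (
        "rna_not_reduced",
        "gc7_protein_down",
        "ko_protein_down",
        "translational_gc7",
        "eif5a_regulated",
    )
    return {c: int(calls[c].sum()) for c in cols}


def recovery_metrics(called: pd.Index | list, truth_positive: pd.Index | list) -> dict:
    """Sensitivity and precision of a called gene set against planted truth."""
    called, truth_positive = set(called), set(truth_positive)
    tp = len(called & truth_positive)
    fp = len(called - truth_positive)
    fn = len(truth_positive - called)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
    }


def top_mrna_shift(
    ko: pd.DataFrame,
    top_genes: list,
    n_reps: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> BootstrapNull:
    """Bootstrap test of a gene list's median KO fold change.

    The observed statistic is the median linear fold change (2^log2fc) of the
    listed genes; the null resamples same-size gene sets without replacement
    from all tested genes. The two-sided empirical p counts null medians at
    least as far from the null median as the observed value (add-one rule);
    one-sided alternatives count directly. A two-tailed t test of the listed
    genes' log2fc against all other tested genes is reported alongside
    (``extras``), as is a t test of the observed median against the null
    medians.
    """
    tested = ko.loc[ko["log2fc"].notna()]
    universe = tested.index
    top = pd.Index(top_genes)
    if not top.isin(universe).all():
        raise ValueError("top_genes must be a subset of tested genes")
    if len(top) < 2:
        raise ValueError("need at least 2 genes in the list")
    if len(top) > len(universe):
        raise ValueError("gene list larger than the tested universe")

    rng = np.random.default_rng(seed)
    lfc = tested["log2fc"].to_numpy()
    fc = np.power(2.0, lfc)
    top_mask = universe.isin(top)
    observed = float(np.median(fc[top_mask]))

    k = len(top)
    nulls = np.empty(n_reps)
    for i in range(n_reps):
        idx = rng.choice(len(fc), size=k, replace=False)
        nulls[i] = np.median(fc[idx])

    if alternative == "greater":
        hits = int(np.sum(nulls >= observed))
    elif alternative == "less":
        hits = int(np.sum(nulls <= observed))
    elif alternative == "two-sided":
        center = float(np.median(nulls))
        hits = int(np.sum(np.abs(nulls - center) >= abs(observed - center)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    empirical_p = (1 + hits) / (n_reps + 1)

    extras = {}
    other = lfc[~top_mask]
    if len(other) >= 2 and np.ptp(lfc[top_mask]) + np.ptp(other) > 0:
        t_pool = stats.ttest_ind(lfc[top_mask], other, equal_var=True)
        extras["t_p_pool"] = float(t_pool.pvalue)
        extras["t_stat_pool"] = float(t_pool.statistic)
    if np.ptp(nulls) > 0:
        t_null = stats.ttest_1samp(nulls, observed)
        extras["t_p_null_medians"] = float(t_null.pvalue)
    extras["median_fc"] = observed
    extras["n_genes"] = k

    return BootstrapNull(observed, nulls, n_reps, float(empirical_p), seed, extras)
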