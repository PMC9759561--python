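# nregulon

Analysis pipeline for identifying genes **translationally regulated by
eIF5a** in effector CD8+ T cells from nascent-proteome (AHA click-chemistry
LC-MS) and RNA-seq data. It is written for computational biologists who want
the complete, tested chain from a peptide-level intensity table to the final
gene sets and motif statistics — and for method developers who need a
synthetic-data generator with planted, recoverable ground truth to validate
each stage.

eIF5a assists ribosomes through hard-to-translate motifs, most prominently
polyproline (PPP/PPG). Losing eIF5a (CRISPR KO) or its activating
hypusination (the inhibitor GC7) should therefore reduce the *synthesis* of
specific proteins without touching their mRNA. The pipeline implements that
logic end to end:

1. **quantify** — protein abundance = log2(median attributed-peptide
   intensity); filters: >2 unique peptides, observed in ≥3 of 4 replicates
   of every group, ≥5x above the non-labelled background; single blanks
   imputed with the group mean.
2. **normalize** — per-sample generalized-log (glog) transform
   `h(x) = log2((x·b_s + √((x·b_s)² + a²))/2)` aligning columns and
   stabilizing variance, then division by input cell numbers; classical MDS
   for quality control.
3. **diffexpr** — unpaired t + Benjamini–Hochberg (GC7 vs Mock), paired t
   (KO vs WT, cultures matched by `pair_id`), and a negative-binomial LRT
   for the RNA counts.
4. **regulon** — the Venn rule: a gene is *translationally regulated* when
   its mRNA is not reduced (RNA FDR > 0.1, or FDR < 0.01 with fold > 2) but
   its nascent protein is down under GC7 (FDR < 0.05, fold < −1.5);
   *eIF5a-regulated* additionally requires KO reduction (p < 0.05,
   fold < −1.5).
5. **motifs** — overlapping amino-acid trimer counts, one-sided Fisher
   enrichment against 50 random trimers, and a bootstrap comparing the
   PPP/PPG gene content of a called set with random transcriptome draws
   (2900 genes × 1000 repeats); the same bootstrap machinery tests annotated
   lists such as 5'TOP genes for fold-change shifts.
6. **synthgen** — generates proteomes with a controlled PPP/PPG fraction,
   the four-group × 4-replicate peptide experiment (loading effects, global
   GC7 shift, targeted KO shifts, missing-at-random blanks, background
   contamination) and negative-binomial RNA counts, all recorded in a truth
   table.
7. **assay_metrics** — exact arithmetic for the accompanying assay readouts
   (loading-normalized western-blot folds, autophagic flux, specific lysis).

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Running the full pipeline on a synthetic study with 40 planted targets
(`python examples/04_translational_regulon.py`):

```
Venn set sizes:
  rna_not_reduced      1337
  gc7_protein_down     1415
  ko_protein_down      38
  translational_gc7    1337
  eif5a_regulated      37

recovery against planted truth: {'tp': 37, 'fp': 0, 'fn': 3,
                                 'sensitivity': 0.925, 'precision': 1.0}
```

Nearly every protein is "down" under GC7 — the drug suppresses global
translation ~3-fold per cell, which re-emerges after input-cell
normalization — while the KO effect is small and specific; intersecting the
two with the unchanged-mRNA criterion recovers 37 of the 40 planted
eIF5a targets with no false positives (3 were lost to the detection filters,
not the statistics). The downstream motif stage
(`python examples/05_motifs_and_bootstrap.py`) then reports:

```
motif  count  windows    freq      p
  PPP     12    10963 0.00109 0.0000
  PPG     10    10963 0.00091 0.0000
  ...
polyproline bootstrap: observed 48.6% PPP/PPG genes
null (random draws): median 30.1%, IQR [29.7, 30.4]%, p = 0.0010
5'TOP gene shift in KO: median FC 1.29, bootstrap p = 0.0010
```

The called set is enriched for PPP/PPG both at the trimer level (Fisher vs
random trimers) and at the gene level (48.6% polyproline genes vs ~30% in
random draws), and the annotated 5'TOP genes are slightly *more* synthesised
in the KO — all three are planted features of the generator, recovered by
the analysis.

Other entry points: `examples/01–06` cover each capability, and a thin CLI
(`nregulon synth|quantify|normalize|de|regulon|motifs|metrics|run-all`)
wraps the same library functions for shell use, e.g.

```bash
nregulon run-all --seed 7 --out results/run7
```

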