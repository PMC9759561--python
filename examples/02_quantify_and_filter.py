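"""Summarize peptides to proteins and apply the filter cascade.

Protein abundance = log2(median attributed-peptide intensity); proteins must
have >2 unique peptides, be observed in >=3 of 4 replicates of every group,
and be >=5x more abundant in AHA-labelled samples than in the non-labelled
background. Single blanks are imputed with the group mean.
"""

import nregulon as nr
from nregulon import quantify

proteome = nr.generate_proteome(400, ppp_fraction=0.3, seed=1)
design = nr.make_design()
truth = nr.make_truth(proteome, n_targets=15, seed=2)
peptides = nr.generate_nascent_experiment(design, truth, missing_rate=0.06, seed=3)

matrix = quantify.summarize_proteins(peptides)
matrix = quantify.filter_detection(matrix, design)
matrix = quantify.filter_aha_enrichment(matrix, design)

flags = matrix.flags
print(f"proteins quantified:     {len(matrix.genes)}")
print(f"  expressed (>2 unique): {int(flags['expressed'].sum())}")
print(f"  detected (3 of 4):     {int(flags['detected'].sum())}")
print(f"  AHA-enriched (>=5x):   {int(flags['aha_enriched'].sum())}")
print(f"  pass all filters:      {len(matrix.analysis_genes())}")

analysis = matrix.subset_genes(matrix.analysis_genes())
imputed = quantify.impute_single_missing(analysis, design)
print(f"imputed single blanks:   {int(imputed.imputed.to_numpy().sum())} cells")
print()
print("Filter losses are real features of the rules, not bugs: proteins with")
print("few unique peptides or >=2 blanks in a group are legitimately dropped.")
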