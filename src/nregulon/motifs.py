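"""Amino-acid trimer counting, Fisher enrichment and the polyproline bootstrap.

Counts overlapping 3-mer occurrences in protein sequence sets, tests each
target motif against the pooled rate of randomly drawn trimers with a
one-sided Fisher's exact test, and compares the polyproline (PPP/PPG) gene
content of a called set against random transcriptome draws.
"""

from __future__ import annotations

from collections import Counter
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AMINO_ACIDS, BootstrapNull, ProteinSequenceSet, box_summary

#: trimer motifs at which eIF5a-depleted ribosomes stall
DEFAULT_TARGET_MOTIFS = ("PPP", "PPG", "DVG", "DDG", "GGT", "RDK")

_AA_SET = frozenset(AMINO_ACIDS)


def _check_motif(motif: str) -> str:
    if len(motif) != 3 or set(motif) - _AA_SET:
        raise ValueError(f"motif must be 3 uppercase canonical residues, got {motif!r}")
    return motif


def _overlapping_count(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def count_motif(seqs: ProteinSequenceSet, motif: str) -> tuple[int, int, float]:
    """Overlapping occurrences of a trimer across a sequence set.

    Returns ``(count, windows, freq)`` where windows is the number of 3-mer
    windows (sum of max(len - 2, 0); no window spans two sequences) and freq
    is the count normalised by the total residue length of the set.
    """
    _check_motif(motif)
    count = sum(_overlapping_count(s, motif) for s in seqs.sequences.values())
    windows = sum(max(len(s) - 2, 0) for s in seqs.sequences.values())
    freq = count / seqs.total_length()
    return count, windows, freq


def _all_trimer_counts(seqs: ProteinSequenceSet) -> Counter:
    counts: Counter = Counter()
    for s in seqs.sequences.values():
        for i in range(len(s) - 2):
            counts[s[i : i + 3]] += 1
    return counts


def fisher_one_sided(table) -> float:
    """One-sided (greater) Fisher's exact test p-value for a 2x2 table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="greater")[1])


def motif_enrichment(
    set_seqs: ProteinSequenceSet,
    target_motifs=DEFAULT_TARGET_MOTIFS,
    n_random: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of target trimers over randomly drawn trimers, within a set.

    For each target motif m the 2x2 table contrasts m's window count against
    the pooled count of ``n_random`` random trimers in the same sequences:
    ``[[count(m), windows - count(m)], [random_total, n_random*windows -
    random_total]]``, tested one-sided (greater). Random trimers are drawn
    uniformly from the 8000-trimer alphabet excluding the targets, so the
    null rate is not contaminated by the motifs under test. A motif that
    never occurs gets p = 1.
    """
    if len(set_seqs) == 0:
        raise ValueError("empty sequence set")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    targets = [_check_motif(m) for m in target_motifs]

    rng = np.random.default_rng(seed)
    pool = np.array(
        ["".join(t) for t in product(AMINO_ACIDS, repeat=3) if "".join(t) not in targets]
    )
    random_trimers = rng.choice(pool, size=n_random, replace=False)

    counts = _all_trimer_counts(set_seqs)
    windows = sum(max(len(s) - 2, 0) for s in set_seqs.sequences.values())
    total_len = set_seqs.total_length()
    random_total = int(sum(counts[m] for m in random_trimers))

    rows = []
    for m in targets:
        c = int(counts[m])
        if c == 0:
            p = 1.0
        else:
            table = [
                [c, windows - c],
                [random_total, n_random * windows - random_total],
            ]
            p = fisher_one_sided(table)
        rows.append((m, c, windows, c / total_len, p))
    out = pd.DataFrame(rows, columns=["motif", "count", "windows", "freq", "p"])
    out.attrs["random_trimers"] = list(random_trimers)
    out.attrs["random_total"] = random_total
    return out


def polyproline_bootstrap(
    set_genes,
    pp_reference,
    universe,
    n_draw: int = 2900,
    n_reps: int = 1000,
    seed: int = 0,
) -> BootstrapNull:
    """Polyproline content of a gene set vs random transcriptome draws.

    The statistic is the percentage of genes contained in the PPP/PPG
    reference list. The null redraws ``n_draw`` genes without replacement
    from the universe ``n_reps`` times; the empirical p is one-sided
    (greater, add-one rule). Box-plot statistics of the null (median,
    quartiles, 1.5*IQR whiskers) are attached in ``extras``.
    """
    set_genes = pd.Index(set_genes)
    universe = pd.Index(universe)
    reference = set(pp_reference)
    if len(set_genes) == 0:
        raise ValueError("empty gene set")
    if not set_genes.isin(universe).all():
        raise ValueError("set_genes must be a subset of the universe")
    if n_draw > len(universe):
        raise ValueError("n_draw exceeds the size of the universe")

    in_ref = np.asarray(universe.isin(reference))
    observed = 100.0 * float(set_genes.isin(reference).mean())

    rng = np.random.default_rng(seed)
    nulls = np.empty(n_reps)
    n_uni = len(universe)
    for i in range(n_reps):
        idx = rng.choice(n_uni, size=n_draw, replace=False)
        nulls[i] = 100.0 * in_ref[idx].mean()

    hits = int(np.sum(nulls >= observed))
    empirical_p = (1 + hits) / (n_reps + 1)
    extras = {"box": box_summary(nulls), "n_set": int(len(set_genes)), "n_draw": n_draw}
    return BootstrapNull(observed, nulls, n_reps, float(empirical_p), seed, extras)
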