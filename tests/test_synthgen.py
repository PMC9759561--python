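"""Generator contracts: motif-fraction control, seed determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

import nregulon as nr
from nregulon.synthgen import PPP_MOTIFS, _contains_ppp


def n_with_motif(seqs):
    return sum(_contains_ppp(s) for s in seqs.sequences.values())


class TestGenerateProteome:
    @pytest.mark.parametrize(
        "n_genes,fraction,expected",
        [(10, 1.0, 10), (10, 0.0, 0), (3000, 0.3, 900)],
    )
    def test_motif_fraction_is_exact(self, n_genes, fraction, expected):
        seqs = nr.generate_proteome(n_genes, fraction, mean_length=150, seed=1)
        assert n_with_motif(seqs) == expected

    def test_deterministic_given_seed(self):
        a = nr.generate_proteome(50, 0.4, seed=9)
        b = nr.generate_proteome(50, 0.4, seed=9)
        assert a.sequences == b.sequences
        c = nr.generate_proteome(50, 0.4, seed=10)
        assert a.sequences != c.sequences

    def test_alphabet_and_lengths(self):
        seqs = nr.generate_proteome(30, 0.5, mean_length=80, seed=0)
        canon = set("ACDEFGHIKLMNPQRSTVWY")
        for s in seqs.sequences.values():
            assert set(s) <= canon and len(s) >= 30

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nr.generate_proteome(0, 0.5)
        with pytest.raises(ValueError):
            nr.generate_proteome(10, 0.5, mean_length=0)
        with pytest.raises(ValueError):
            nr.generate_proteome(10, 1.5)

    def test_uncontrolled_fraction_leaves_chance_hits(self):
        seqs = nr.generate_proteome(300, ppp_fraction=None, mean_length=300, seed=5)
        # ~7% of length-300 uniform sequences contain PPP/PPG by chance
        assert 0 < n_with_motif(seqs) < 100


class TestPlantMotifOccurrences:
    def test_plants_requested_count(self):
        seqs = nr.generate_proteome(50, ppp_fraction=0.0, mean_length=200, seed=3)
        planted = nr.plant_motif_occurrences(seqs, "PPP", 20, seed=4)
        count, _, _ = nr.count_motif(planted, "PPP")
        assert count == 20

    def test_rejects_bad_motif(self):
        seqs = nr.generate_proteome(5, 0.0, seed=0)
        with pytest.raises(ValueError):
            nr.plant_motif_occurrences(seqs, "PP", 1)


class TestNascentExperiment:
    def test_noiseless_loading_term_only(self, noiseless_run):
        proteome, design, truth, peptides = noiseless_run
        from nregulon.quantify import summarize_proteins

        matrix = summarize_proteins(peptides)
        null_genes = truth.index[
            (truth.true_log2fc_ko == 0) & (truth.rna_log2fc == 0)
        ]
        g = null_genes[0]
        # between Mock replicates: identical; Mock vs WT differ by the loading term
        mock = matrix.log2.loc[g, [f"Mock_{r}" for r in range(1, 5)]]
        assert mock.nunique() == 1
        wt = matrix.log2.at[g, "WT_1"]
        loading = np.log2(12.5e6 / 10e6)
        assert matrix.log2.at[g, "Mock_1"] - wt == pytest.approx(loading, abs=1e-9)

    def test_noiseless_planted_ko_effect(self, noiseless_run):
        proteome, design, truth, peptides = noiseless_run
        from nregulon.quantify import summarize_proteins

        matrix = summarize_proteins(peptides)
        target = truth.index[truth.is_translational_target][0]
        diff = matrix.log2.at[target, "KO_1"] - matrix.log2.at[target, "WT_1"]
        assert diff == pytest.approx(truth.at[target, "true_log2fc_ko"], abs=1e-9)

    def test_background_sits_below_labelled(self, noiseless_run):
        proteome, design, truth, peptides = noiseless_run
        from nregulon.quantify import summarize_proteins

        matrix = summarize_proteins(peptides)
        g = truth.index[0]
        # Background and Mock share input cells: difference is the planted shift
        assert matrix.log2.at[g, "Background_1"] - matrix.log2.at[g, "Mock_1"] == (
            pytest.approx(-3.5, abs=1e-9)
        )

    def test_deterministic_given_seed(self, design):
        seqs = nr.generate_proteome(20, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=3, seed=2)
        a = nr.generate_nascent_experiment(design, truth, seed=5)
        b = nr.generate_nascent_experiment(design, truth, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_group_raises(self, design):
        seqs = nr.generate_proteome(10, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=2, seed=2)
        no_bg = design[design.group != "Background"]
        with pytest.raises(ValueError):
            nr.generate_nascent_experiment(no_bg, truth, seed=1)

    def test_missing_rate_blanks_whole_proteins(self, design):
        seqs = nr.generate_proteome(200, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=5, seed=2)
        pep = nr.generate_nascent_experiment(design, truth, missing_rate=0.2, seed=3)
        obs = pep.groupby(["gene_id", "sample_id"]).size().unstack()
        frac_missing = obs.isna().to_numpy().mean()
        assert 0.15 < frac_missing < 0.25
        # a blanked protein/sample cell has no peptides at all: per-gene peptide
        # counts are constant across its observed samples
        counts = pep.groupby(["gene_id", "sample_id"]).size().unstack()
        assert (counts.nunique(axis=1) == 1).all()


class TestTruthTable:
    def test_targets_respect_invariant(self, small_proteome):
        truth = nr.make_truth(small_proteome, n_targets=10, seed=7)
        t = truth[truth.is_translational_target]
        assert (t.true_log2fc_ko <= -np.log2(1.5)).all()
        assert (t.rna_log2fc >= 0).all()

    def test_ppp_flag_matches_sequence(self, small_proteome):
        truth = nr.make_truth(small_proteome, n_targets=5, seed=7)
        for g in truth.index:
            assert truth.at[g, "has_ppp"] == any(
                m in small_proteome[g] for m in PPP_MOTIFS
            )

    def test_targets_enriched_in_ppp(self):
        seqs = nr.generate_proteome(2000, 0.3, mean_length=60, seed=1)
        truth = nr.make_truth(seqs, n_targets=200, ppp_enrichment_odds=3.0, seed=2)
        frac_targets = truth.loc[truth.is_translational_target, "has_ppp"].mean()
        assert frac_targets > 0.40  # odds 3 vs background 0.30

    def test_casualty_annotation(self, design):
        seqs = nr.generate_proteome(300, 0.3, seed=5)
        truth = nr.make_truth(seqs, n_targets=10, seed=6)
        pep = nr.generate_nascent_experiment(design, truth, missing_rate=0.15, seed=7)
        annotated = nr.annotate_filter_casualties(truth, pep, design)
        assert annotated["filter_casualty"].any()
        # a casualty gene really is unrecoverable: blanked >1 rep in some group
        # or short of unique peptides
        g = annotated.index[annotated.filter_casualty][0]
        sub = pep[pep.gene_id == g]
        n_unique = sub[sub.is_unique].peptide_id.nunique()
        obs = sub.groupby("sample_id").size()
        per_group = {
            grp: sum(1 for r in range(1, 5) if f"{grp}_{r}" in obs.index)
            for grp in ("Mock", "GC7", "WT", "KO")
        }
        assert n_unique < 3 or min(per_group.values()) < 3


class TestRnaCounts:
    def test_null_poisson_group_means_match(self, design):
        seqs = nr.generate_proteome(300, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=0, rna_down_fraction=0.0, n_top=0, seed=2)
        counts = nr.generate_rna_counts(truth, design, dispersion=0.0, seed=3)
        gc7 = counts[[c for c in counts if c.startswith("GC7")]].mean(axis=1)
        mock = counts[[c for c in counts if c.startswith("Mock")]].mean(axis=1)
        high = counts.mean(axis=1) > 200
        ratio = (gc7[high] + 1) / (mock[high] + 1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)

    def test_planted_fold_recovered_at_high_expression(self):
        seqs = nr.generate_proteome(1000, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=0, rna_down_fraction=0.0, n_top=0, seed=2)
        truth["rna_log2fc"] = 1.5
        counts = nr.generate_rna_counts(truth, dispersion=0.0, seed=4, lib_sizes=1e6)
        gc7 = counts[[c for c in counts if c.startswith("GC7")]].to_numpy().mean(axis=1)
        mock = counts[[c for c in counts if c.startswith("Mock")]].to_numpy().mean(axis=1)
        high = mock > 500
        assert gc7[high].sum() / mock[high].sum() == pytest.approx(2 ** 1.5, rel=0.05)

    def test_lib_size_scaling(self, design):
        seqs = nr.generate_proteome(500, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=0, rna_down_fraction=0.0, n_top=0, seed=2)
        libs = pd.Series(1e6, index=[f"{g}_{r}" for g in ("Mock", "GC7") for r in range(1, 5)])
        libs["Mock_1"] = 2e6
        counts = nr.generate_rna_counts(truth, design, lib_sizes=libs, dispersion=0.0, seed=5)
        totals = counts.sum()
        assert totals["Mock_1"] / totals["Mock_2"] == pytest.approx(2.0, rel=0.02)

    def test_negative_arguments_raise(self, design):
        seqs = nr.generate_proteome(10, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=0, seed=2)
        with pytest.raises(ValueError):
            nr.generate_rna_counts(truth, design, dispersion=-0.1)
        with pytest.raises(ValueError):
            nr.generate_rna_counts(truth, design, lib_sizes=-5.0)

    def test_deterministic_given_seed(self, design):
        seqs = nr.generate_proteome(50, 0.5, seed=1)
        truth = nr.make_truth(seqs, n_targets=5, seed=2)
        a = nr.generate_rna_counts(truth, design, seed=9)
        b = nr.generate_rna_counts(truth, design, seed=9)
        pd.testing.assert_frame_equal(a, b)
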