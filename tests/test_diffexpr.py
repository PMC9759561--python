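"""Differential-testing oracles: t conventions, BH step-up, NB calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import nregulon as nr
from nregulon import diffexpr

from conftest import toy_matrix

GROUP_SAMPLES = [f"{g}_{r}" for g in ("GC7", "Mock") for r in range(1, 5)]


def de_matrix(gc7, mock):
    vals = list(gc7) + list(mock)
    return toy_matrix({"g": vals}, GROUP_SAMPLES[: len(vals)])


def brute_force_bh(p):
    """Independent step-up oracle: p*m/rank with cumulative min from the worst."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestUnpairedT:
    def test_identical_groups_null(self, design):
        res = diffexpr.unpaired_t_bh(de_matrix([1, 2, 3, 3], [1, 2, 3, 3]), design)
        assert res.at["g", "log2fc"] == 0.0
        assert res.at["g", "p"] == pytest.approx(1.0)

    def test_zero_variance_conventions(self, design):
        same = diffexpr.unpaired_t_bh(de_matrix([2, 2, 2, 2], [2, 2, 2, 2]), design)
        assert same.at["g", "p"] == 1.0
        shifted = diffexpr.unpaired_t_bh(de_matrix([0, 0, 0, 0], [1, 1, 1, 1]), design)
        assert shifted.at["g", "p"] == 0.0
        assert shifted.at["g", "log2fc"] == -1.0

    def test_insufficient_replicates_reported_missing(self, design):
        m = de_matrix([1.0, np.nan, np.nan, np.nan], [1, 2, 3, 4])
        res = diffexpr.unpaired_t_bh(m, design)
        assert np.isnan(res.at["g", "p"])
        assert res.at["g", "log2fc"] == pytest.approx(1.0 - 2.5)

    def test_unknown_group_raises(self, design):
        with pytest.raises(ValueError):
            diffexpr.unpaired_t_bh(de_matrix([1, 2], [1, 2]), design, ("GC7", "Vehicle"))

    def test_contrast_swap_negates_lfc_keeps_p(self, design):
        rng = np.random.default_rng(0)
        vals = {f"g{i}": list(rng.normal(0, 1, 8)) for i in range(20)}
        m = toy_matrix(vals, GROUP_SAMPLES)
        fwd = diffexpr.unpaired_t_bh(m, design, ("GC7", "Mock"))
        rev = diffexpr.unpaired_t_bh(m, design, ("Mock", "GC7"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_p_matches_incomplete_beta(self, design):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.normal(0, 1, 4), rng.normal(0.3, 1, 4)
            m = de_matrix(a, b)
            p = diffexpr.unpaired_t_bh(m, design).at["g", "p"]
            # equal-variance t statistic evaluated independently
            n1, n2 = 4, 4
            sp = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
            p_beta = special.betainc(df / 2, 0.5, df / (df + t * t))
            assert p == pytest.approx(p_beta, abs=1e-9)


class TestPairedT:
    def paired_matrix(self, ko, wt):
        samples = [f"KO_{r}" for r in range(1, 5)] + [f"WT_{r}" for r in range(1, 5)]
        return toy_matrix({"g": list(ko) + list(wt)}, samples)

    def test_constant_difference_convention(self, design):
        res = diffexpr.paired_t(self.paired_matrix([1, 2, 3, 4], [2, 3, 4, 5]), design)
        assert res.at["g", "log2fc"] == -1.0
        assert res.at["g", "p"] == 0.0

    def test_closed_form_example(self, design):
        # diffs [-1, -2, 0, missing]: t = -sqrt(3), df 2
        res = diffexpr.paired_t(
            self.paired_matrix([1, 2, 3, np.nan], [2, 4, 3, 5]), design
        )
        assert res.at["g", "log2fc"] == pytest.approx(-1.0)
        assert res.at["g", "p"] == pytest.approx(0.22540333, abs=1e-7)
        assert res.at["g", "n_used"] == 3

    def test_single_pair_excluded(self, design):
        res = diffexpr.paired_t(
            self.paired_matrix([1, np.nan, np.nan, np.nan], [2, np.nan, np.nan, np.nan]),
            design,
        )
        assert np.isnan(res.at["g", "p"])

    def test_unmatched_pairs_raise(self, design):
        broken = design.copy()
        broken.loc[(broken.group == "KO") & (broken.replicate == 1), "pair_id"] = "P9"
        m = self.paired_matrix([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            diffexpr.paired_t(m, broken)

    def test_pairing_uses_pair_id_not_column_order(self, design):
        # swap KO columns: pairing must still subtract the matched culture
        samples = ["KO_2", "KO_1", "KO_3", "KO_4"] + [f"WT_{r}" for r in range(1, 5)]
        m = toy_matrix({"g": [5.0, 2.0, 5.0, 5.0, 1.0, 5.0, 5.0, 5.0]}, samples)
        res = diffexpr.paired_t(m, design)
        # pairs: (KO_1=2, WT_1=1) diff 1; others 0 -> mean 0.25
        assert res.at["g", "log2fc"] == pytest.approx(0.25)


class TestBenjaminiHochberg:
    def test_spec_example(self):
        fdr = diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 50))
            assert np.abs(diffexpr.bh_adjust(p) - brute_force_bh(p)).max() < 1e-12

    def test_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        fdr = diffexpr.bh_adjust(p)
        assert (np.diff(fdr[np.argsort(p)]) >= -1e-15).all()

    def test_nan_p_propagates(self):
        fdr = diffexpr.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(fdr[1]) and not np.isnan(fdr[0])


class TestNbRnaTest:
    def test_duplicated_columns_are_null(self, design):
        rng = np.random.default_rng(3)
        col = rng.poisson(100, 300)
        counts = pd.DataFrame(
            np.column_stack([col] * 8),
            columns=[f"{g}_{r}" for g in ("GC7", "Mock") for r in range(1, 5)],
            index=[f"g{i}" for i in range(300)],
        )
        counts.index.name = "gene_id"
        res = diffexpr.nb_rna_test(counts, design)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p"] >= 0.99).all()

    def test_poisson_limit_matches_closed_form(self, design):
        rng = np.random.default_rng(0)
        n_bg, n_test = 300, 100
        Y = np.vstack(
            [
                rng.poisson(500, (n_bg, 8)),
                np.hstack([rng.poisson(200, (n_test, 4)), rng.poisson(100, (n_test, 4))]),
            ]
        )
        cols = [f"GC7_{i}" for i in range(1, 5)] + [f"Mock_{i}" for i in range(1, 5)]
        counts = pd.DataFrame(Y, columns=cols, index=[f"g{i}" for i in range(len(Y))])
        counts.index.name = "gene_id"
        res = diffexpr.nb_rna_test(counts, design, dispersion=0.0)
        libs = Y.sum(axis=0)
        neff = libs / libs.mean()

        def poisson_lrt_p(y):
            mu0 = y.sum() / neff.sum()
            mu1, mu2 = y[:4].sum() / neff[:4].sum(), y[4:].sum() / neff[4:].sum()
            ll = lambda yy, mm: float((yy * np.log(mm) - mm).sum())
            lrt = 2 * (
                ll(y[:4], mu1 * neff[:4]) + ll(y[4:], mu2 * neff[4:]) - ll(y, mu0 * neff)
            )
            return stats.chi2.sf(max(lrt, 0.0), 1)

        oracle = np.array([poisson_lrt_p(Y[i].astype(float)) for i in range(len(Y))])
        rel = np.abs(res["p"].to_numpy() - oracle) / np.maximum(oracle, 1e-12)
        assert rel.max() < 0.10

    def test_power_monotone_in_effect_size(self, design):
        # shift a 10% subset (a global shift would be absorbed by the
        # total-count normalization) and track detection on that subset
        seqs = nr.generate_proteome(1000, 0.5, seed=1)
        rates = []
        for lfc in (0.5, 1.0, 2.0):
            truth = nr.make_truth(seqs, n_targets=0, rna_down_fraction=0.0, n_top=0, seed=2)
            shifted = truth.index[:100]
            truth.loc[shifted, "rna_log2fc"] = -lfc
            counts = nr.generate_rna_counts(truth, design, dispersion=0.1, seed=5)
            res = diffexpr.nb_rna_test(counts, design)
            rates.append(float((res.loc[shifted, "p"] < 0.05).mean()))
        assert rates[0] < rates[1] < rates[2]

    def test_non_integer_counts_raise(self, design):
        counts = pd.DataFrame(
            np.full((5, 8), 1.5),
            columns=[f"{g}_{r}" for g in ("GC7", "Mock") for r in range(1, 5)],
        )
        with pytest.raises(ValueError):
            diffexpr.nb_rna_test(counts, design)
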