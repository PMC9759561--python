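"""Differential testing: protein t tests with BH correction and an RNA NB test.

Nascent-protein contrasts use a two-sided equal-variance t test (GC7 vs Mock,
unpaired) or a paired t test on per-culture differences (KO vs WT), both on
log2 abundances, with Benjamini-Hochberg step-up FDR across genes. The RNA
side is a deliberately simple negative-binomial likelihood-ratio test:
total-count library normalization, method-of-moments tagwise dispersion
shrunk toward the common value, and a chi-square(1) LRT of equal group means.
Its fidelity requirement is calibration (type-I error near nominal), not
agreement with any particular published framework.

Zero-variance convention: groups identical within and across -> p = 1;
identical within each group but different across -> p = 0 (the limit of the
t statistic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .containers import BACKGROUND, ProteinMatrix, check_design


def bh_adjust(p: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _t_two_group(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided equal-variance two-sample t p-value with the zero-variance rule."""
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def unpaired_t_bh(
    matrix: ProteinMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("GC7", "Mock"),
) -> pd.DataFrame:
    """Unpaired two-sided t test per gene with BH FDR over the contrast.

    ``log2fc`` is mean(contrast group) - mean(reference group). Genes with
    fewer than two non-missing values in either group are reported with
    missing p (and excluded from the BH family).
    """
    design = check_design(design)
    g1, g2 = contrast
    for g in contrast:
        if not (design["group"] == g).any():
            raise ValueError(f"unknown group {g!r} in contrast")
    s1 = [s for s in design.index[design["group"] == g1] if s in matrix.samples]
    s2 = [s for s in design.index[design["group"] == g2] if s in matrix.samples]

    rows = []
    for gene in matrix.genes:
        a = matrix.log2.loc[gene, s1].dropna().to_numpy(dtype=float)
        b = matrix.log2.loc[gene, s2].dropna().to_numpy(dtype=float)
        lfc = a.mean() - b.mean() if len(a) and len(b) else np.nan
        p = _t_two_group(a, b) if len(a) >= 2 and len(b) >= 2 else np.nan
        rows.append((gene, lfc, p, len(a) + len(b)))
    res = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p", "n_used"]).set_index(
        "gene_id", drop=False
    )
    res["fdr"] = bh_adjust(res["p"])
    res["contrast"] = f"{g1}-{g2}"
    return res


def paired_t(
    matrix: ProteinMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("KO", "WT"),
) -> pd.DataFrame:
    """Paired two-sided t test on per-pair log2 differences (contrast - reference).

    Pairs are matched by ``pair_id`` (samples sorted from the same culture);
    genes need at least two complete pairs. The ``fdr`` column is populated
    by BH, although downstream KO calls use the raw p per the selection rule.
    """
    design = check_design(design)
    g1, g2 = contrast
    for g in contrast:
        if not (design["group"] == g).any():
            raise ValueError(f"unknown group {g!r} in contrast")
    d1 = design[(design["group"] == g1) & design["sample_id"].isin(matrix.samples)]
    d2 = design[(design["group"] == g2) & design["sample_id"].isin(matrix.samples)]
    pairs1 = d1.set_index("pair_id")["sample_id"]
    pairs2 = d2.set_index("pair_id")["sample_id"]
    if set(pairs1.index) != set(pairs2.index):
        raise ValueError("unmatched pair_id between contrast groups")
    pair_ids = list(pairs1.index)
    cols1 = [pairs1[p] for p in pair_ids]
    cols2 = [pairs2[p] for p in pair_ids]

    rows = []
    for gene in matrix.genes:
        v1 = matrix.log2.loc[gene, cols1].to_numpy(dtype=float)
        v2 = matrix.log2.loc[gene, cols2].to_numpy(dtype=float)
        diffs = v1 - v2
        diffs = diffs[~np.isnan(diffs)]
        if len(diffs) >= 2:
            lfc = float(diffs.mean())
            if diffs.var(ddof=1) == 0:
                p = 1.0 if lfc == 0 else 0.0
            else:
                p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        elif len(diffs) == 1:
            lfc, p = float(diffs[0]), np.nan
        else:
            lfc, p = np.nan, np.nan
        rows.append((gene, lfc, p, len(diffs)))
    res = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p", "n_used"]).set_index(
        "gene_id", drop=False
    )
    res["fdr"] = bh_adjust(res["p"])
    res["contrast"] = f"{g1}-{g2}"
    return res


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood (alpha = 0 rows fall back to Poisson)."""
    y = np.asarray(y, dtype=float)
    ll = np.empty(y.shape[0])
    alpha = np.asarray(alpha, dtype=float)
    pois = alpha <= 0
    mu = np.maximum(mu, 1e-300)
    if pois.any():
        m = mu[pois]
        ll[pois] = np.sum(y[pois] * np.log(m) - m - gammaln(y[pois] + 1.0), axis=1)
    if (~pois).any():
        a = alpha[~pois][:, None]
        r = 1.0 / a
        m = mu[~pois]
        yy = y[~pois]
        ll[~pois] = np.sum(
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m)),
            axis=1,
        )
    return ll


def _nb_fit_mu(y: np.ndarray, n_eff: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB mean MLE with offsets: E[y_gs] = mu_g * n_eff_s.

    Newton iterations on log(mu); exact in one step when alpha = 0.
    """
    mu = np.maximum(y.sum(axis=1) / n_eff.sum(), 1e-8)
    eta = np.log(mu)
    a = np.asarray(alpha, dtype=float)[:, None]
    for _ in range(50):
        m = np.exp(eta)[:, None] * n_eff[None, :]
        w = 1.0 + a * m
        score = np.sum((y - m) / w, axis=1)
        info = np.sum(m / w, axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(eta)


def nb_rna_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("GC7", "Mock"),
    tagwise_weight: float = 0.3,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Negative-binomial likelihood-ratio test of equal group means.

    Libraries are total-count normalized. Per-gene dispersion is a
    method-of-moments estimate from pooled within-group variances, shrunk
    toward the common (mean) dispersion: the tagwise component is very noisy
    with few replicates, so it retains only ``tagwise_weight`` (default 0.3)
    and the common value carries the rest — with n = 4 per group a weaker
    shrinkage leaves the test visibly anticonservative. The test statistic
    is the NB LRT against a single shared mean, referred to chi-square(1);
    log2fc comes from normalized group means with a 0.5 pseudo-count. FDR is
    BH over all genes.
    """
    shrink = 1.0 - tagwise_weight
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValueError("counts must be non-negative integers")
    design = check_design(design)
    g1, g2 = contrast
    s1 = [s for s in design.index[design["group"] == g1] if s in counts.columns]
    s2 = [s for s in design.index[design["group"] == g2] if s in counts.columns]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need at least 2 samples per contrast group")

    y = counts[s1 + s2].to_numpy(dtype=float)
    libs = y.sum(axis=0)
    n_eff = libs / libs.mean()  # total-count size factors
    z = y / n_eff[None, :]  # normalized counts on the common scale
    n1 = len(s1)

    # method-of-moments dispersion from pooled within-group variance
    m1, m2 = z[:, :n1].mean(axis=1), z[:, n1:].mean(axis=1)
    v1, v2 = z[:, :n1].var(axis=1, ddof=1), z[:, n1:].var(axis=1, ddof=1)
    v_pooled = ((n1 - 1) * v1 + (len(s2) - 1) * v2) / (n1 + len(s2) - 2)
    m_all = (n1 * m1 + len(s2) * m2) / (n1 + len(s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tagwise = np.where(m_all > 0, (v_pooled - m_all) / m_all**2, 0.0)
    tagwise = np.clip(np.nan_to_num(tagwise), 0.0, 10.0)
    if dispersion is not None:
        if dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        alpha = np.full(y.shape[0], float(dispersion))
    else:
        informative = m_all >= 1.0
        common = float(tagwise[informative].mean()) if informative.any() else 0.0
        alpha = (1.0 - shrink) * tagwise + shrink * common

    mu_null = _nb_fit_mu(y, n_eff, alpha)
    mu_1 = _nb_fit_mu(y[:, :n1], n_eff[:n1], alpha)
    mu_2 = _nb_fit_mu(y[:, n1:], n_eff[n1:], alpha)

    ll_null = _nb_loglik(y, mu_null[:, None] * n_eff[None, :], alpha)
    ll_alt = _nb_loglik(y[:, :n1], mu_1[:, None] * n_eff[None, :n1], alpha) + _nb_loglik(
        y[:, n1:], mu_2[:, None] * n_eff[None, n1:], alpha
    )
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    log2fc = np.log2(m1 + 0.5) - np.log2(m2 + 0.5)
    res = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "p": p,
            "dispersion": alpha,
        }
    ).set_index("gene_id", drop=False)
    res["fdr"] = bh_adjust(res["p"])
    res["contrast"] = f"{g1}-{g2}"
    return res
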