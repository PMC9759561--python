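"""Between-sample normalization and MDS quality control.

The variance-stabilizing step transforms each sample's linear abundances with
a generalized log, ``h(x) = log2((x*b_s + sqrt((x*b_s)^2 + a^2)) / 2)``. At
high intensity ``h`` behaves like ``log2(b_s * x)``, so the per-sample scale
``b_s`` aligns columns: it is fitted so the trimmed mean difference to the
reference profile is zero. The shared glog offset ``a`` damps the variance
explosion of low intensities; it is chosen to flatten the dependence of
between-replicate spread on mean abundance (the defining property of a
variance-stabilizing transform), found by bisection since that slope is
monotone in ``a``. This is a deliberately simple stand-in for the published
robust-ML vsn fit with the same testable outcomes: comparable columns and
stabilized variance.

A second step divides by the number of input cells so abundances are
per-cell comparable across groups, and classical (Torgerson) MDS on
between-sample distances provides the quality-control embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import trim_mean

from .containers import ProteinMatrix, check_design


def glog2(x, a: float, b: float):
    """Generalized log2: asinh-style transform, defined for all real x."""
    xb = np.asarray(x, dtype=float) * b
    return np.log2((xb + np.sqrt(xb * xb + a * a)) / 2.0)


@dataclass
class MdsEmbedding:
    """Classical-MDS coordinates with per-dimension variance fractions."""

    coordinates: pd.DataFrame
    variance_fraction: np.ndarray
    eigenvalues: np.ndarray


def _polish_b(x: np.ndarray, ref: np.ndarray, a: float, b: float, trim: float) -> float:
    """Scale ``b`` so the trimmed mean residual to the reference is ~0.

    Multiplying ``b`` by ``2**(-delta)`` lowers high-intensity values by
    ``delta``; the iteration is a contraction and converges in a few steps.
    """
    for _ in range(100):
        delta = trim_mean(glog2(x, a, b) - ref, trim / 2.0)
        if abs(delta) < 1e-11:
            break
        b *= 2.0 ** (-delta)
    return b


class _GlogFitter:
    """Joint fit of per-sample scales and the shared glog offset."""

    def __init__(self, X: np.ndarray, masks: np.ndarray, trim: float, ref_col: int | None):
        self.X = X  # genes x samples, linear scale, NaN for missing
        self.masks = masks  # finite-value masks per column
        self.trim = trim
        self.ref_col = ref_col
        self.complete = masks.all(axis=1)

    def transform(self, a: float, b: np.ndarray) -> np.ndarray:
        out = np.full_like(self.X, np.nan)
        for j in range(self.X.shape[1]):
            m = self.masks[:, j]
            out[m, j] = glog2(self.X[m, j], a, b[j])
        return out

    def _reference(self, tr: np.ndarray) -> np.ndarray:
        if self.ref_col is not None:
            return tr[:, self.ref_col]
        return np.nanmedian(tr, axis=1)

    def align(self, a: float, b: np.ndarray, rounds: int = 3) -> np.ndarray:
        for _ in range(rounds):
            ref = self._reference(self.transform(a, b))
            for j in range(self.X.shape[1]):
                m = self.masks[:, j] & np.isfinite(ref)
                b[j] = _polish_b(self.X[m, j], ref[m], a, b[j], self.trim)
        return b

    def sd_slope(self, a: float, b: np.ndarray) -> float:
        """LS slope of replicate SD on mean over complete rows, SD winsorized
        at its 95th percentile to resist genes with real between-group shifts."""
        tr = self.transform(a, b)[self.complete]
        mean = tr.mean(axis=1)
        sd = np.minimum(tr.std(axis=1, ddof=1), np.percentile(tr.std(axis=1, ddof=1), 95))
        if np.ptp(mean) == 0:
            return 0.0
        return float(np.polyfit(mean, sd, 1)[0])

    def fit(self) -> tuple[float, np.ndarray]:
        pos = self.X[np.isfinite(self.X) & (self.X > 0)]
        lo = np.log2(max(np.percentile(pos, 1) * 1e-3, 1e-12))
        hi = np.log2(pos.max() * 10.0)
        b = self.align(2.0 ** lo, np.ones(self.X.shape[1]))
        if self.sd_slope(2.0 ** lo, b) >= -1e-6:
            return 2.0 ** lo, b  # already homoscedastic: plain log2 limit
        b_hi = self.align(2.0 ** hi, np.ones(self.X.shape[1]))
        if self.sd_slope(2.0 ** hi, b_hi) <= 0:
            return 2.0 ** hi, b_hi
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            b = self.align(2.0 ** mid, b, rounds=2)
            if self.sd_slope(2.0 ** mid, b) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 0.01:
                break
        a = 2.0 ** (0.5 * (lo + hi))
        b = self.align(a, b)
        return a, b

    def final_reference(self, a: float, b: np.ndarray) -> np.ndarray:
        """Freeze the reference profile and polish scales against it once more,
        so every column's trimmed mean residual to the *stored* reference is
        zero to numerical precision."""
        ref = self._reference(self.transform(a, b))
        for j in range(self.X.shape[1]):
            m = self.masks[:, j] & np.isfinite(ref)
            b[j] = _polish_b(self.X[m, j], ref[m], a, b[j], self.trim)
        return ref


def vsn_like_normalize(
    matrix: ProteinMatrix, reference: str = "median", trim: float = 0.2
) -> ProteinMatrix:
    """Variance-stabilizing glog normalization against a reference profile.

    ``reference`` is either ``"median"`` (per-gene median of the transformed
    columns; no sample privileged) or a sample id. After the fit the trimmed
    mean difference between any sample and the reference profile is zero
    within 1e-6 over the genes used in its fit, and the transform is strictly
    monotone within each sample.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples to normalize")
    if not 0.0 <= trim < 1.0:
        raise ValueError("trim must be in [0, 1)")
    linear = matrix.linear().to_numpy(dtype=float)
    masks = np.isfinite(linear)
    if masks.all(axis=1).sum() < 10:
        raise ValueError("fewer than 10 genes shared across all samples")
    for j, s in enumerate(matrix.samples):
        vals = linear[masks[:, j], j]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise ValueError(f"sample {s!r} is constant; cannot normalize")
    if reference == "median":
        ref_col = None
    else:
        if reference not in matrix.samples:
            raise ValueError(f"reference sample {reference!r} not in matrix")
        ref_col = int(matrix.samples.get_loc(reference))

    fitter = _GlogFitter(linear, masks, trim, ref_col)
    a, b = fitter.fit()
    ref_profile = fitter.final_reference(a, b)
    out = matrix.copy()
    out.log2 = pd.DataFrame(
        fitter.transform(a, b), index=matrix.genes, columns=matrix.samples
    )
    out.meta["glog_params"] = pd.DataFrame(
        {"a": a, "b": b}, index=matrix.samples
    )
    out.meta["reference"] = reference
    out.meta["reference_profile"] = pd.Series(ref_profile, index=matrix.genes)
    return out


def cell_number_adjust(matrix: ProteinMatrix, design: pd.DataFrame) -> ProteinMatrix:
    """Adjust abundances by input cell number (per-minimum-cell-count scale).

    Subtracts ``log2(input_cells(s) / min input_cells)`` from every value of
    sample s, putting all samples on the per-cell scale of the smallest
    input. A pure additive shift per column: contrasts are unaffected by the
    choice of baseline.
    """
    design = check_design(design)
    missing = [s for s in matrix.samples if s not in design.index]
    if missing:
        raise ValueError(f"design has no input_cells for samples: {missing}")
    cells = design.loc[list(matrix.samples), "input_cells"].astype(float)
    if cells.isna().any() or (cells <= 0).any():
        raise ValueError("input_cells must be recorded and positive for every sample")
    out = matrix.copy()
    out.log2 = out.log2.sub(np.log2(cells / cells.min()), axis=1)
    return out


def mds_embed(
    matrix: ProteinMatrix, n_dims: int = 3, distance: str = "euclidean"
) -> MdsEmbedding:
    """Classical (Torgerson) MDS of samples from complete-case gene rows.

    Distances between sample columns are Euclidean by default (``distance=
    "correlation"`` uses 1 - Pearson). Variance fractions are eigenvalues
    over the sum of positive eigenvalues, reported for every positive
    dimension; coordinates are returned for the top ``n_dims``.
    """
    complete = matrix.log2.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete gene rows for MDS")
    n_samples = complete.shape[1]
    if n_samples < n_dims + 1:
        raise ValueError("need at least n_dims + 1 samples")
    cols = complete.T.to_numpy()
    if distance == "euclidean":
        d = squareform(pdist(cols, metric="euclidean"))
    elif distance == "correlation":
        d = 1.0 - np.corrcoef(cols)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")

    d2 = d ** 2
    j = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(eigvals.max(), 0.0) * 1e-12
    pos = eigvals > tol
    pos_vals = eigvals[pos]
    variance_fraction = pos_vals / pos_vals.sum()

    k = min(n_dims, int(pos.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    coordinates = pd.DataFrame(
        coords,
        index=complete.columns,
        columns=[f"dim{i + 1}" for i in range(k)],
    )
    return MdsEmbedding(coordinates, variance_fraction, eigvals)
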