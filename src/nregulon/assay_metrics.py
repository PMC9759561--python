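"""Exactly specified arithmetic for the flow-cytometry and blot readouts.

Small, deterministic helpers: loading-control-normalized fold change for
western-blot series, autophagic flux from lysosome-inhibited vs vehicle
LC3-II signal, and specific lysis from pulsed:unpulsed target-cell ratios.
"""

from __future__ import annotations

import pandas as pd


def loading_normalized_fold(
    target: pd.Series, loading_control: pd.Series, baseline_index
) -> pd.Series:
    """Fold change of a signal series relative to a baseline point, after
    normalisation against a loading control at the same point.

    fold(t) = (target(t)/control(t)) / (target(t0)/control(t0)); the baseline
    fold is exactly 1. Scale-invariant in both series.
    """
    target = pd.Series(target, dtype=float)
    control = pd.Series(loading_control, dtype=float)
    if not target.index.equals(control.index):
        raise ValueError("target and loading control must share the same index")
    if baseline_index not in target.index:
        raise ValueError(f"baseline {baseline_index!r} not in series index")
    if (control <= 0).any():
        raise ValueError("loading control must be positive everywhere")
    if target[baseline_index] <= 0:
        raise ValueError("baseline target signal must be positive")
    ratio = target / control
    fold = ratio / ratio[baseline_index]
    fold[baseline_index] = 1.0
    return fold


def autophagic_flux(mfi_treated: float, mfi_vehicle: float) -> float:
    """LC3-II MFI in lysosomal-inhibitor-treated cells over vehicle-treated.

    Flux 1 means no autophagosome turnover; larger values mean LC3-II would
    have been degraded without the inhibitor.
    """
    if mfi_vehicle <= 0:
        raise ValueError("vehicle MFI must be positive")
    return float(mfi_treated) / float(mfi_vehicle)


def specific_lysis(ratio_with_t: float, ratio_without_t: float) -> float:
    """Percent specific lysis from pulsed:unpulsed target-cell ratios.

    100 * (1 - ratio_with_T / ratio_without_T): 0 when effector T cells kill
    nothing, approaching 100 as peptide-pulsed targets are eliminated.
    """
    if ratio_with_t <= 0 or ratio_without_t <= 0:
        raise ValueError("target-cell ratios must be positive")
    return 100.0 * (1.0 - ratio_with_t / ratio_without_t)
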