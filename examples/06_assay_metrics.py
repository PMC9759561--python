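"""Assay arithmetic: loading-normalized folds, autophagic flux, specific lysis."""

import pandas as pd

from nregulon import autophagic_flux, loading_normalized_fold, specific_lysis

# western blot: eIF5a signal over a time course, normalized to the ZAP70
# loading control at the same time point and to the 0 h baseline
target = pd.Series([10.0, 25.0, 60.0], index=["0h", "24h", "48h"])
control = pd.Series([5.0, 6.0, 10.0], index=["0h", "24h", "48h"])
fold = loading_normalized_fold(target, control, "0h")
print("loading-normalized fold:", fold.round(2).to_dict())

# autophagic flux: LC3-II MFI with lysosomal inhibitor / vehicle
print(f"autophagic flux (200 vs 100 MFI): {autophagic_flux(200, 100):.1f}")

# cytotoxicity: pulsed:unpulsed target ratio with vs without effector T cells
print(f"specific lysis (ratio 0.4 vs 1.6): {specific_lysis(0.4, 1.6):.0f}%")
print()
print("Flux 2.0 means half the autophagosomal LC3-II would have been degraded")
print("without the inhibitor; 75% lysis means three quarters of peptide-pulsed")
print("targets were eliminated by the T cells.")
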