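"""Published parameter estimates used as reference inputs.

These are the global-fit parameter sets and IC50s reported for recombinant
human SIRT3 and SIRT1 (fluorometric deacetylation assays, 37 °C, saturating
acetyl-peptide). They serve two roles: as generating parameters for the
synthetic assays (the round-trip identifiability analyses) and as the
fitted constants from which the mechanistic diagnostics are computed.
"""

from __future__ import annotations

from .models import BaseExchangeParams, MixedInhibitionParams

__all__ = [
    "SIRT3_NAM",
    "SIRT1_NAM",
    "SIRT3_ISONAM",
    "IC50_NAM_SIRT3_UM",
    "IC50_NAM_SIRT1_UM",
    "IC50_ISONAM_SIRT3_UM",
    "IC50_ISONAM_SIRT1_UM",
    "DEREPRESSION_MEASURED",
]

#: SIRT3 / NAM global fit of the base-exchange model (K1 term omitted):
#: Km(NAD+) = 673.3 µM, vmax = 0.197 µM/min, K2 = 29.4 µM, alpha = 2.735.
SIRT3_NAM = BaseExchangeParams(vmax=0.197, km=673.3, k2=29.4, alpha=2.735)

#: SIRT1 / NAM global fit (K1 term omitted): Km = 168.2 µM,
#: vmax = 0.863 µM/min, K2 = 51.3 µM, alpha = 0.848 (near-noncompetitive).
SIRT1_NAM = BaseExchangeParams(vmax=0.863, km=168.2, k2=51.3, alpha=0.848)

#: SIRT3 / isoNAM global fit of the standard mixed model: Km = 1402 µM,
#: vmax = 0.167 µM/min, Ki = 4623 µM, alpha = 8.87e18 (competitive limit).
SIRT3_ISONAM = MixedInhibitionParams(vmax=0.167, km=1402.0, ki=4623.0, alpha=8.87e18)

#: Measured IC50s (90 min incubation, 1 mM NAD+ for the headline assays).
IC50_NAM_SIRT3_UM = 36.7
IC50_NAM_SIRT1_UM = 68.1
IC50_ISONAM_SIRT3_UM = 13.8e3
IC50_ISONAM_SIRT1_UM = 12.2e3

#: Measured percent inhibition of SIRT3 by 100 µM NAM at 500 µM NAD+ as a
#: function of added isoNAM (µM): the derepression series.
DEREPRESSION_MEASURED = {0.0: 69.7, 900.0: 56.5}
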