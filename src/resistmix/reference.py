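"""Reference values for the MCF-7 / MCF-7-ADR doxorubicin system.

Published point estimates for this cell-line pair under pulsed
doxorubicin, used as generative defaults by the synthetic-assay module
and as the ground truth of the recovery experiments.
"""

from __future__ import annotations

from .models import SigmoidState

#: Doxorubicin panel of the weekly drug-sensitivity assay (µM).
DOSE_PANEL = (0.0, 4.0, 14.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0,
              120.0, 144.0)

#: Extra high doses appended when assaying the highly resistant
#: MCF-7/ADR line, whose LD50 lies beyond the standard panel.
EXTENDED_DOSES = (200.0, 250.0, 300.0, 400.0)

#: Resistant fractions of the validation mixtures
#: (wild-type : ADR ratios 1:0, 3:1, 1:1, 1:3, 0:1).
MIXTURE_RESISTANT_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Two-population states estimated from the 8-week pulse-treatment
#: course: sensitive LD50 22.4 µM, resistant LD50 79.7 µM, with the
#: model-column slopes of the mixture validation (0.060, 0.028 1/µM).
SENSITIVE_STATE = SigmoidState(ld50=22.4, slope=0.060)
RESISTANT_STATE = SigmoidState(ld50=79.7, slope=0.028)

#: Untreated wild-type MCF-7 under the single static model.
MCF7_LD50 = 37.0
MCF7_SLOPE = 0.055

#: Pure MCF-7/ADR resistant line (measured, single static model).
ADR_LD50 = 187.5
ADR_SLOPE = 0.034

#: Default sensitive-fraction trajectory over the 8 weekly assays:
#: resistance peaks two to three weeks after the drug pulse and then
#: relaxes back toward baseline.
DEFAULT_FSENS_TRAJECTORY = (0.90, 0.45, 0.40, 0.50, 0.60, 0.70, 0.85, 0.95)

#: Default replicate count per (group, dose) cell.
DEFAULT_REPLICATES = 4

#: Default per-dose noise sd of viability when none is estimated.
DEFAULT_NOISE_SD = 0.05
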