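"""Published summary tables shipped as package inputs.

These are the printed per-patient scores and calls of the independent
validation cohort (17 IO-treated early-stage breast cancer patients) and
the published virtual-trial counts, used to evaluate the statistics layer
against the published report.  They are inputs, not computed results.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_validation_cohort", "load_trial_counts"]

# (subtype, patient, score, predicted call, clinical call)
_VALIDATION_ROWS = [
    ("HR+/HER2-", "Patient 1", 0.401, "pCR", "pCR"),
    ("HR+/HER2-", "Patient 2", -1.060, "residual", "residual"),
    ("HR+/HER2-", "Patient 3", 0.713, "pCR", "pCR"),
    ("HR+/HER2-", "Patient 4", 0.255, "residual", "residual"),
    ("HR+/HER2-", "Patient 5", -0.139, "residual", "residual"),
    ("TNBC", "Patient 1", 0.625, "pCR", "pCR"),
    ("TNBC", "Patient 2", 0.621, "pCR", "pCR"),
    ("TNBC", "Patient 3", 1.001, "pCR", "pCR"),
    ("TNBC", "Patient 4", 0.681, "pCR", "residual"),
    ("TNBC", "Patient 5", 0.996, "pCR", "pCR"),
    ("TNBC", "Patient 6", 0.809, "pCR", "pCR"),
    ("TNBC", "Patient 7", 0.727, "pCR", "pCR"),
    ("TNBC", "Patient 8", 1.085, "pCR", "pCR"),
    ("TNBC", "Patient 9", 0.495, "residual", "residual"),
    ("TNBC", "Patient 10", 0.496, "residual", "residual"),
    ("TNBC", "Patient 11", 0.491, "residual", "pCR"),
    ("TNBC", "Patient 12", 0.661, "pCR", "pCR"),
]


def load_validation_cohort() -> pd.DataFrame:
    """Printed validation-cohort scores and pCR calls (n = 17)."""
    return pd.DataFrame(
        _VALIDATION_ROWS,
        columns=["subtype", "patient_id", "score", "predicted", "truth"],
    )


def load_trial_counts() -> pd.DataFrame:
    """Published virtual-trial denominators and pCR counts per subtype.

    ``chemo_pcr`` are the observed control-arm counts; ``io_pcr`` are the
    counts of patients called pCR under simulated chemo+immunotherapy.
    Counts are the integers forced by the published rates and denominators.
    """
    return pd.DataFrame(
        {
            "subtype": ["TNBC", "HR+/HER2-"],
            "n": [158, 134],
            "chemo_pcr": [61, 12],
            "io_pcr": [106, 24],
        }
    )
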