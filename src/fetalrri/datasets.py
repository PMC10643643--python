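"""Bundled reference data.

:func:`validation_table` returns the published 14-subject external-validation
cohort of the fetal-RRI prediction study this package re-implements: held-out
pregnancies with gestational age, maternal age, the actual fetal RRI measured
from non-invasive fetal ECG, and the fetal RRI predicted by the trained SVR
model. Prediction errors are *not* stored — they are always recomputed from
the error-percentage definition, which is what the worked examples in the
test-suite exercise.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["validation_table"]

# subject, ga_weeks, maternal_age_years, actual_frri_ms, predicted_frri_ms
_VALIDATION_ROWS = [
    (1, 28, 43, 445.0, 434.0),
    (2, 32, 43, 434.0, 420.0),
    (3, 37, 30, 412.0, 416.0),
    (4, 25, 39, 408.0, 435.0),
    (5, 29, 35, 385.0, 438.0),
    (6, 37, 31, 370.0, 388.0),
    (7, 23, 29, 419.0, 418.0),
    (8, 26, 30, 383.0, 370.0),
    (9, 29, 29, 432.0, 422.0),
    (10, 37, 42, 446.0, 431.0),
    (11, 38, 27, 409.0, 429.0),
    (12, 38, 32, 407.0, 420.0),
    (13, 39, 45, 502.0, 410.0),
    (14, 33, 32, 418.0, 435.0),
]


def validation_table() -> pd.DataFrame:
    """The 14-subject external-validation cohort (actual vs SVR-predicted fRRI)."""
    return pd.DataFrame(
        _VALIDATION_ROWS,
        columns=["subject", "ga_weeks", "maternal_age_years", "actual_frri_ms", "predicted_frri_ms"],
    )
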