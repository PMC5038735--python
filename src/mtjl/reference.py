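"""Published indicator-screening reference values.

One-way ANOVA results (F statistic and significance) for the fifteen
eye-tracking indicators screened in the 74-participant reading study this
package models, as printed in that study's screening table. A printed
significance of 0 means "rounds to 0 at two decimals", i.e. p < 0.005; it is
stored as 0.0 here and the alpha rule treats it as below any conventional
threshold.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_screening_table", "flag_sensitive"]

# (family, indicator, scale, F, p)
_REFERENCE_ROWS = [
    ("pupil", "pupil diameter", "pixels", 2544.09, 0.0),
    ("blink", "blink count", "count", 156.92, 0.0),
    ("blink", "blink rate", "blinks per second", 133.89, 0.0),
    ("fixation", "fixation count", "count", 15.64, 0.0),
    ("fixation", "fixation rate", "fixations per second", 560.07, 0.0),
    ("fixation", "fixation duration", "ms", 18.12, 0.0),
    ("fixation", "fixation position X", "pixels", 14.74, 0.0),
    ("fixation", "fixation position Y", "pixels", 0.15, 0.83),
    ("saccade", "saccade count", "count", 50.76, 0.0),
    ("saccade", "saccade rate", "saccades per second", 4.28, 0.04),
    ("saccade", "saccade duration", "ms", 127.73, 0.0),
    ("saccade", "saccade amplitude", "degrees of visual angle", 34.44, 0.0),
    ("regression", "regression count", "count", 742.83, 0.0),
    ("regression", "regression rate", "regressions per second", 905.39, 0.0),
    ("regression", "regression length", "pixels", 1.71, 0.19),
]


def reference_screening_table() -> pd.DataFrame:
    """The published screening table as a DataFrame (family, indicator,
    scale, F, p)."""
    return pd.DataFrame(
        _REFERENCE_ROWS, columns=["family", "indicator", "scale", "F", "p"]
    )


def flag_sensitive(table: pd.DataFrame | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the p < alpha rule to a screening table (default: the published
    reference values), adding a boolean ``sensitive`` column."""
    if table is None:
        table = reference_screening_table()
    out = table.copy()
    out["sensitive"] = out["p"] < alpha
    return out
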