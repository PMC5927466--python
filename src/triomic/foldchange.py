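"""Log2 fold/relative-change matrices against the day-0 group mean.

Shared kernel for the expression (log2FC) and metabolite (log2RC) layers:
each feature's value is divided by that feature's mean over the baseline-day
samples, after adding a small positive floor so that zero measurements stay
finite on the log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def log2_ratio_matrix(
    values: pd.DataFrame,
    design: pd.DataFrame,
    baseline_day: int = 0,
    floor: float = 0.01,
) -> pd.DataFrame:
    """Per-feature log2 ratio to the baseline-day mean.

    Parameters
    ----------
    values
        feature x sample matrix of nonnegative measurements (RPKM, abundance).
        Columns must match ``design['sample_id']``.
    design
        Sample design table with ``sample_id`` and ``day`` columns.
    baseline_day
        Day whose per-feature mean is the denominator.
    floor
        Additive floor applied to every value (numerator and the values the
        baseline mean is computed from) before taking logs.  Must be > 0 when
        any baseline mean would otherwise be zero.

    Returns
    -------
    DataFrame of the same shape: ``log2((x + floor) / mean_baseline(x + floor))``.
    """
    if (values.values < 0).any():
        raise ValueError("negative measurements are not allowed")
    baseline_ids = design.loc[design["day"] == baseline_day, "sample_id"].tolist()
    if not baseline_ids:
        raise ValueError(f"no samples at baseline day {baseline_day}")
    missing = [s for s in design["sample_id"] if s not in values.columns]
    if missing:
        raise ValueError(f"samples in design but not in matrix: {missing[:5]}")
    floored = values + floor
    baseline_mean = floored[baseline_ids].mean(axis=1)
    if (baseline_mean <= 0).any():
        bad = baseline_mean.index[baseline_mean <= 0][:5].tolist()
        raise ValueError(
            f"baseline mean is zero for features {bad}; use a positive floor"
        )
    out = np.log2(floored.div(baseline_mean, axis=0))
    return out
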