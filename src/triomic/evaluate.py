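"""Scoring calls against planted truth (synthetic studies only)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def confusion(called, truth) -> dict[str, float]:
    """Sensitivity, observed FDR and raw counts of boolean calls vs truth.

    ``fdr`` is NaN when nothing is called; ``sensitivity`` is NaN when no
    feature is truly positive.
    """
    called = np.asarray(called, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if called.shape != truth.shape:
        raise ValueError("calls and truth are misaligned")
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    n_pos = tp + fn
    n_called = tp + fp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "fdr": fp / n_called if n_called else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "n_called": n_called,
    }


def called_fraction(p_adj: pd.Series | np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of features with adjusted p <= alpha (null-calibration check)."""
    arr = np.asarray(p_adj, dtype=float)
    return float((arr <= alpha).mean())
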