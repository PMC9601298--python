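"""Descriptive summaries of paired-count panels.

These quantify the phenomenon the model exists for: when the total number
of trials is itself random, the success and failure series can rise and
fall together, so their correlation over time is positive even though the
success probability is constant. Under a fixed total the two counts would
be negatively associated instead.
"""

from __future__ import annotations

import numpy as np

from .model_core import PanelData


def success_failure_correlation(data: PanelData) -> np.ndarray:
    """Per-subject Pearson correlation between y1 and y2 across time.

    Subjects with fewer than two time points or a constant series yield NaN.
    """
    out = np.full(data.m, np.nan)
    for i, s in enumerate(data.subjects):
        if s.T < 2 or np.std(s.y1) == 0 or np.std(s.y2) == 0:
            continue
        out[i] = np.corrcoef(s.y1, s.y2)[0, 1]
    return out


def success_proportion(data: PanelData) -> float:
    """Pooled success proportion sum(y1) / sum(y1 + y2) over all rows."""
    num = sum(float(s.y1.sum()) for s in data.subjects)
    den = sum(float(s.totals.sum()) for s in data.subjects)
    if den == 0:
        return float("nan")
    return num / den


def zero_total_fraction(data: PanelData) -> float:
    """Fraction of subject-time cells whose total N_it = y1 + y2 is zero."""
    zeros = sum(int(np.sum(s.totals == 0)) for s in data.subjects)
    return zeros / data.n_obs
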