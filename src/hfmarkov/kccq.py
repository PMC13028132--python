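"""KCCQ total-summary-score quartile bands used as model health states.

The four alive health states are quartiles of the baseline KCCQ-TSS
distribution of a contemporary HFmr/pEF trial population.  Bands are
lower-closed: a score exactly on a cut point belongs to the band above it.
The cut points are held fixed over the model horizon.
"""

from __future__ import annotations

import numpy as np

#: Quartile cut points (Q1: 1 to <50, Q2: 50 to <69.8, Q3: 69.8 to <87.5,
#: Q4: 87.5 to 100).  100 is included in Q4.
KCCQ_BOUNDS = (1.0, 50.0, 69.8, 87.5, 100.0)

#: State labels in trace/matrix order.
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def assign_quartile(scores) -> np.ndarray:
    """Map KCCQ-TSS scores to 0-based quartile indices.

    Lower-closed bands: 50 -> Q2, 69.8 -> Q3, 87.5 -> Q4; 100 -> Q4.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < KCCQ_BOUNDS[0]) or np.any(scores > KCCQ_BOUNDS[-1]):
        raise ValueError("KCCQ scores must lie in [1, 100]")
    idx = np.digitize(scores, KCCQ_BOUNDS[1:-1], right=False)
    return idx.astype(np.int64)


def quartile_occupancy(scores) -> np.ndarray:
    """Fraction of scores in each quartile band (sums to 1)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores supplied")
    idx = assign_quartile(scores)
    return np.bincount(idx, minlength=4) / scores.size
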