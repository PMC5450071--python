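"""Small summary-layer formulas used in characterization reports."""

from __future__ import annotations

import numpy as np


def ts_tv_ratio(n_transitions: int, n_transversions: int) -> float:
    """Transition/transversion ratio from event counts."""
    if n_transversions <= 0:
        raise ValueError("transversion count must be positive")
    return n_transitions / n_transversions


def density_per_mbp(n_markers: int, length_kbp: float) -> float:
    """Markers per megabase given a chromosome length in kbp."""
    if length_kbp <= 0:
        raise ValueError("length must be positive")
    return n_markers / (length_kbp / 1000.0)


def mean_count(counts) -> float:
    """Arithmetic mean of a list of per-chromosome counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count list")
    return float(counts.mean())
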