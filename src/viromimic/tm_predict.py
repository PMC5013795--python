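"""Hydropathy-based transmembrane segment prediction.

A sliding Kyte-Doolittle window (default 19 residues, the scale authors'
recommended setting for transmembrane detection) is averaged over the
protein; maximal runs of window centers at or above the threshold (default
1.6) become predicted membrane-spanning segments, each expanded to the full
window extent and merged when expansions overlap.  This is a deliberately
simple hydropathy predictor — it does not model topology or signal
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple, Union

import numpy as np

from .seqio import SeqRecord

__all__ = ["KYTE_DOOLITTLE", "TMRecord", "hydropathy_profile", "predict_tm_segments"]

# Kyte & Doolittle (1982) hydropathy index; X and unknowns contribute 0.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class TMRecord:
    protein_id: str
    segments: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if start <= prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _values(protein: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein], dtype=np.float64)


def hydropathy_profile(protein: Union[SeqRecord, str], window: int = 19) -> np.ndarray:
    """Mean hydropathy of each full centered window.

    Entry ``i`` of the returned array is the mean over residues
    ``[i, i + window)``; the window center is ``i + window // 2``.  A protein
    shorter than the window yields an empty profile.
    """
    residues = protein.residues if hasattr(protein, "residues") else protein
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = _values(residues)
    if vals.shape[0] < window:
        return np.zeros(0, dtype=np.float64)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    return (csum[window:] - csum[:-window]) / window


def predict_tm_segments(
    protein: Union[SeqRecord, str],
    window: int = 19,
    threshold: float = 1.6,
) -> TMRecord:
    """Predict membrane-spanning segments from the hydropathy profile.

    Runs of consecutive window centers with mean hydropathy >= threshold are
    expanded to the full extent of their first and last windows; expansions
    that overlap are merged into one segment.
    """
    pid = protein.id if hasattr(protein, "id") else ""
    profile = hydropathy_profile(protein, window=window)
    if profile.shape[0] == 0:
        return TMRecord(protein_id=pid, segments=[])
    above = profile >= threshold
    segments: List[Tuple[int, int]] = []
    i = 0
    n = above.shape[0]
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = i            # window [i, i + window) of the first center
        end = j + window     # last window ends at j + window
        if segments and start <= segments[-1][1]:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))
        i = j + 1
    return TMRecord(protein_id=pid, segments=segments)
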