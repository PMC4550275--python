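"""Hydropathy-profile transmembrane-segment counting.

A deterministic Kyte-Doolittle sliding-window scanner stands in for an HMM
topology predictor: only the *count* of membrane-spanning segments enters
the downstream filters (3-4 for desaturases, 5-7 for elongases), and a
hydropathy scanner decides that count reproducibly with no external
dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
    # Unknown residues are treated as neutral.
    "X": 0.0, "*": 0.0,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_LEN = 19
DEFAULT_MIN_GAP = 5

FAD_TM_RANGE = (3, 4)
ELOVL_TM_RANGE = (5, 7)


@dataclass(frozen=True)
class TmSegment:
    start: int  # 0-based half-open protein coordinates
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start


def hydropathy_profile(
    protein: str, window: int = DEFAULT_WINDOW, scale=None
) -> np.ndarray:
    """Centred moving average of the hydropathy scale.

    Output length is ``len(protein) - window + 1``; entry i averages
    residues ``i .. i+window-1`` (window centre at ``i + window//2``).
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(protein):
        raise ValueError(
            f"window {window} exceeds protein length {len(protein)}"
        )
    scale = scale or KYTE_DOOLITTLE
    values = np.array([scale[aa] for aa in protein], dtype=float)
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def tm_segments(
    protein: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    min_gap: int = DEFAULT_MIN_GAP,
    scale=None,
) -> List[TmSegment]:
    """Predicted membrane-spanning segments.

    Maximal runs of window positions with mean hydropathy >= ``threshold``
    are extended to their full window extents, merged when separated by
    fewer than ``min_gap`` residues, and discarded when shorter than
    ``min_len``.  Returned segments are non-overlapping and sorted.
    """
    scale = scale or KYTE_DOOLITTLE
    profile = hydropathy_profile(protein, window, scale=scale)
    above = profile >= threshold
    spans: List[List[int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            # profile index i covers residues [i, i+window); run [i, j]
            # extends to [i, j + window).
            spans.append([i, j + window])
            i = j + 1
        else:
            i += 1
    merged: List[List[int]] = []
    for span in spans:
        if merged and span[0] - merged[-1][1] < min_gap:
            merged[-1][1] = span[1]
        else:
            merged.append(span)
    values = np.array([scale[aa] for aa in protein], dtype=float)
    return [
        TmSegment(start=s, end=e, mean_hydropathy=float(values[s:e].mean()))
        for s, e in merged
        if e - s >= min_len
    ]


def tm_count(protein: str, **kwargs) -> int:
    """Number of predicted membrane-spanning segments."""
    return len(tm_segments(protein, **kwargs))


def tm_count_ok(count: int, family: str) -> bool:
    """Is the segment count inside the family's accepted window
    (3-4 for Fad desaturases, 5-7 for Elovl elongases)?"""
    if count < 0:
        raise ValueError("count must be >= 0")
    if family == "Fad":
        lo, hi = FAD_TM_RANGE
    elif family == "Elovl":
        lo, hi = ELOVL_TM_RANGE
    else:
        raise ValueError(f"unknown family {family!r}")
    return lo <= count <= hi
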