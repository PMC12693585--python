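"""Dominant-TSS selection from CAGE signal.

Genes often carry several annotated TSSs; the one backed by the strongest
local CAGE signal is taken as dominant. To absorb single-base inaccuracy
in CAGE peak positions, each candidate is scored with f: the sum of CAGE
signal in a nine-nucleotide window centered on the candidate base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic import SignalTrack


@dataclass(frozen=True)
class TssCandidate:
    gene: str
    position: int  # index within the scored track
    f_score: float


def cage_window_score(track: SignalTrack, offset: int, window: int = 9) -> float:
    """f score: CAGE signal summed over a centered window, truncated at track ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    values = track.values
    if not (0 <= offset < len(values)):
        raise IndexError(f"offset {offset} outside track of length {len(values)}")
    if (values < 0).any():
        raise ValueError("CAGE signal must be non-negative")
    half = (window - 1) // 2
    lo = max(0, offset - half)
    hi = min(len(values), offset + half + 1)
    return float(values[lo:hi].sum())


def f_profile(track: SignalTrack, window: int = 9) -> np.ndarray:
    """f score at every base of the track (centered window, truncated ends)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    return np.convolve(track.values, np.ones(window), mode="same")


def dominant_tss(
    gene: str,
    candidates,
    track: SignalTrack,
    strand: str = "+",
    window: int = 9,
) -> TssCandidate:
    """The annotated TSS with the highest f score.

    Exact ties go to the most 5' candidate on the gene's strand (smallest
    track index on '+', largest on '-').
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate TSS")
    scored = [(cage_window_score(track, pos, window=window), pos) for pos in candidates]
    best_f = max(f for f, _ in scored)
    tied = [pos for f, pos in scored if f == best_f]
    pos = min(tied) if strand == "+" else max(tied)
    return TssCandidate(gene=gene, position=pos, f_score=best_f)
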