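"""Genomic coordinate primitives shared by every pipeline stage.

All coordinates are 0-based half-open. Positions relative to a TSS use
signed offsets where the TSS base itself is offset 0 and upstream is
negative; on minus-strand genes tracks are reversed so offsets always
increase downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")


def _normalise_strand(strand: str) -> str:
    # BED files in the wild occasionally carry a unicode minus sign
    if strand in ("-", "−"):
        return "-"
    if strand == "+":
        return "+"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _normalise_strand(self.strand))
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Per-base numeric signal over an interval (one value per base)."""

    interval: GenomicInterval
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.interval):
            raise ValueError(
                f"track over {self.interval} needs {len(self.interval)} values, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values) | np.isnan(self.values)):
            raise ValueError("track values must be finite (NaN allowed for missing)")

    def __len__(self) -> int:
        return len(self.values)


def track_to_offsets(
    track: SignalTrack,
    tss: int,
    strand: str = "+",
    upstream: int = 1000,
    downstream: int = 300,
    fill: float = np.nan,
) -> np.ndarray:
    """Re-index a track onto TSS-relative offsets [-upstream, +downstream).

    ``tss`` is the genomic coordinate of the TSS base (0-based). Offset 0
    maps to index ``upstream`` of the returned array. On the minus strand
    the values are reversed so that offsets increase downstream. Bases
    outside the track are set to ``fill``.
    """
    strand = _normalise_strand(strand)
    out = np.full(upstream + downstream, fill, dtype=float)
    lo, hi = track.interval.start, track.interval.end
    for i, off in enumerate(range(-upstream, downstream)):
        pos = tss + off if strand == "+" else tss - off
        if lo <= pos < hi:
            out[i] = track.values[pos - lo]
    return out


def offset_index(offsets: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Boolean mask selecting offsets in the inclusive range [lo, hi]."""
    offsets = np.asarray(offsets)
    if lo > hi:
        raise ValueError(f"empty offset region [{lo}, {hi}]")
    return (offsets >= lo) & (offsets <= hi)
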