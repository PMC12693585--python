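"""Event coding of reference-anchored multi-species promoter alignments.

Each non-reference species is compared column-by-column to the reference
row and every reference base receives a 0/1 code: 0 if the position is
conserved, 1 if it changed (a base change or an indel). Deletions mark
every affected reference base; insertions carry no reference base and are
collapsed to a single 1 at the reference position immediately 5' of the
insertion. For positional (G-function) analyses each contiguous indel is
instead collapsed to one event located at the 5' site of its start in the
alignment.

Coding is always species-vs-reference, never all-pairs. N and gaps in
both rows are treated as carrying no event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MODES = ("all", "base", "indel")
_VALID = set("ACGTN-")


@dataclass
class PromoterAlignment:
    """Gapped multi-species alignment anchored at a reference TSS column."""

    gene: str
    ref_species: str
    rows: dict[str, str]  # species -> gapped uppercase row, equal widths
    tss_column: int  # alignment column of the reference TSS base

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment rows: widths {sorted(widths)}")
        if self.ref_species not in self.rows:
            raise ValueError(f"reference species {self.ref_species!r} missing")
        ref = self.rows[self.ref_species]
        if set(ref) == {"-"}:
            raise ValueError("reference row is gap-only")
        width = widths.pop()
        if not (0 <= self.tss_column < width):
            raise ValueError(f"tss_column {self.tss_column} outside alignment width {width}")
        if ref[self.tss_column] == "-":
            raise ValueError("tss_column must index a reference base, not a gap")

    @property
    def width(self) -> int:
        return len(self.rows[self.ref_species])

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ref_columns(self) -> np.ndarray:
        """Alignment columns holding a reference base, in order."""
        ref = self.rows[self.ref_species]
        return np.flatnonzero(np.frombuffer(ref.encode(), dtype="S1") != b"-")

    def ref_offsets(self) -> np.ndarray:
        """Signed TSS-relative offset of each reference base (TSS base = 0)."""
        cols = self.ref_columns()
        t = int(np.searchsorted(cols, self.tss_column))
        if cols[t] != self.tss_column:
            raise ValueError("tss_column is not a reference base column")
        return np.arange(len(cols)) - t


@dataclass
class EventVector:
    """Per-reference-offset 0/1 change coding for one species pair."""

    gene: str
    species_pair: tuple[str, str]  # (reference, other)
    mode: str
    offsets: np.ndarray
    bits: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.offsets.shape != self.bits.shape:
            raise ValueError("offsets and bits must have equal length")
        if self.bits.size and self.bits.max() > 1:
            raise ValueError("bits must be 0/1")


@dataclass
class EventTally:
    """Summed event counts over many species pairs / genes at shared offsets."""

    group: str
    mode: str
    offsets: np.ndarray
    counts: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size and (self.counts.min() < 0 or self.counts.max() > self.n_pairs):
            raise ValueError("counts must lie in [0, n_pairs]")


@dataclass(frozen=True)
class EventRecord:
    """One collapsed event: a base change or a whole indel at its 5' start."""

    offset: int  # reference offset of the event (indel: 5' start)
    column: int  # alignment column where the event starts
    kind: str  # substitution | deletion | insertion
    length: int


def trim_to_window(
    alignment: PromoterAlignment, upstream: int = 1000, downstream: int = 300
) -> PromoterAlignment:
    """Restrict the alignment to reference offsets [-upstream, +downstream).

    Offsets are counted in reference (non-gap) bases from the TSS column.
    Columns gapped in the reference between retained reference bases are
    kept; insertions outside the window are dropped. If the reference is
    shorter than the requested window the result is truncated with a
    warning.
    """
    cols = alignment.ref_columns()
    offs = alignment.ref_offsets()
    lo, hi = -upstream, downstream - 1
    if offs[0] > lo or offs[-1] < hi:
        warnings.warn(
            f"{alignment.gene}: reference spans offsets [{offs[0]}, {offs[-1]}], "
            f"truncating requested window [{lo}, {hi}]",
            stacklevel=2,
        )
    keep = (offs >= lo) & (offs <= hi)
    if not keep.any():
        raise ValueError("requested window contains no reference bases")
    first_col, last_col = int(cols[keep][0]), int(cols[keep][-1])
    rows = {sp: row[first_col : last_col + 1] for sp, row in alignment.rows.items()}
    return PromoterAlignment(
        gene=alignment.gene,
        ref_species=alignment.ref_species,
        rows=rows,
        tss_column=alignment.tss_column - first_col,
    )


def _walk(alignment: PromoterAlignment, other_species: str):
    """Yield per-column comparison states between reference and other row.

    States: ("match"|"mismatch", offset, col), ("del", offset, col),
    ("ins", anchor_offset, col). Columns gapped in both rows are skipped.
    """
    if other_species == alignment.ref_species:
        raise ValueError("other_species must differ from the reference")
    if other_species not in alignment.rows:
        raise KeyError(f"species {other_species!r} not in alignment")
    ref = alignment.rows[alignment.ref_species]
    oth = alignment.rows[other_species]
    bad = (set(ref) | set(oth)) - _VALID
    if bad:
        raise ValueError(f"invalid alignment characters: {sorted(bad)}")
    offs = alignment.ref_offsets()
    ref_idx = -1  # index into reference bases seen so far
    first_offset = int(offs[0])
    for col, (r, o) in enumerate(zip(ref, oth)):
        if r != "-":
            ref_idx += 1
            offset = int(offs[ref_idx])
            if o == "-":
                yield ("del", offset, col)
            elif r == o or r == "N" or o == "N":
                yield ("match", offset, col)
            else:
                yield ("mismatch", offset, col)
        else:
            if o == "-":
                continue  # gap in both rows: no information
            # insertion in the other species: anchor to the reference base
            # immediately 5' of the insertion (first base if none exists)
            if ref_idx < 0:
                warnings.warn(
                    f"{alignment.gene}: insertion before the first reference base "
                    "anchored to the first offset",
                    stacklevel=3,
                )
            anchor = int(offs[ref_idx]) if ref_idx >= 0 else first_offset
            yield ("ins", anchor, col)


def pairwise_events(
    alignment: PromoterAlignment, other_species: str, mode: str = "all"
) -> EventVector:
    """0/1 change coding of one species against the reference, per offset."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    offsets = alignment.ref_offsets()
    pos = {int(o): i for i, o in enumerate(offsets)}
    base = np.zeros(len(offsets), dtype=np.uint8)
    indel = np.zeros(len(offsets), dtype=np.uint8)
    for state, offset, _col in _walk(alignment, other_species):
        if state == "mismatch":
            base[pos[offset]] = 1
        elif state in ("del", "ins"):
            indel[pos[offset]] = 1
    bits = {"base": base, "indel": indel, "all": base | indel}[mode]
    return EventVector(
        gene=alignment.gene,
        species_pair=(alignment.ref_species, other_species),
        mode=mode,
        offsets=offsets,
        bits=bits,
    )


def event_positions_5prime(
    alignment: PromoterAlignment, other_species: str
) -> list[EventRecord]:
    """Collapsed event list: one record per base change and per whole indel.

    Contiguous indels collapse to a single event at the 5' site of their
    start; records are sorted by alignment column. This is the event list
    consumed by the positional (G-function) hotspot analysis.
    """
    records: list[EventRecord] = []
    run_kind: str | None = None
    run_offset = 0
    run_col = 0
    run_len = 0

    def flush() -> None:
        nonlocal run_kind, run_len
        if run_kind is not None:
            records.append(EventRecord(run_offset, run_col, run_kind, run_len))
        run_kind = None
        run_len = 0

    for state, offset, col in _walk(alignment, other_species):
        if state == "del":
            if run_kind == "deletion":
                run_len += 1
            else:
                flush()
                run_kind, run_offset, run_col, run_len = "deletion", offset, col, 1
        elif state == "ins":
            if run_kind == "insertion" and offset == run_offset:
                run_len += 1
            else:
                flush()
                run_kind, run_offset, run_col, run_len = "insertion", offset, col, 1
        else:
            flush()
            if state == "mismatch":
                records.append(EventRecord(offset, col, "substitution", 1))
    flush()
    records.sort(key=lambda r: r.column)
    return records


def tally_events(vectors: list[EventVector], group: str = "group") -> EventTally:
    """Sum event vectors across pairs/genes sharing mode and offset range."""
    if not vectors:
        raise ValueError("need at least one event vector")
    mode = vectors[0].mode
    offsets = vectors[0].offsets
    for v in vectors[1:]:
        if v.mode != mode:
            raise ValueError("cannot tally mixed modes")
        if not np.array_equal(v.offsets, offsets):
            raise ValueError("cannot tally vectors with different offset ranges")
    counts = np.sum([v.bits for v in vectors], axis=0).astype(int)
    return EventTally(group=group, mode=mode, offsets=offsets, counts=counts, n_pairs=len(vectors))
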