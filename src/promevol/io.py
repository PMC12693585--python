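"""Readers and writers for the plain-text formats the pipeline consumes.

BED (TSS anchors), bedGraph (CAGE and conservation tracks), aligned FASTA
(multi-species promoter alignments) and TSV tables. All parsing lands in
0-based half-open coordinates.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genomic import GenomicInterval, SignalTrack, _normalise_strand

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def read_tss_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read width-1 TSS anchors from a BED file with a name column.

    Strand is taken from column 6 when present, else '+'. Returns
    (gene id, interval) pairs in file order.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected BED4+, got {len(fields)} fields")
            chrom, start, end, name = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                iv = GenomicInterval(chrom, start_i, end_i, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(iv) != 1:
                raise ParseError(f"{path}:{lineno}: TSS anchor must have width 1, got {len(iv)}")
            out.append((name, iv))
    return out


def write_tss_bed(records: list[tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w") as fh:
        for name, iv in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path, interval: GenomicInterval, fill: float = 0.0) -> SignalTrack:
    """Expand a (possibly sparse) bedGraph into per-base values over ``interval``.

    Bases not covered by any record take ``fill``. Overlapping records are
    an error (ambiguous signal). A chromosome absent from the file yields an
    all-fill track with a logged warning.
    """
    if interval.end <= interval.start:  # GenomicInterval forbids this, belt and braces
        raise ValueError("cannot request a zero-length track")
    values = np.full(len(interval), fill, dtype=float)
    covered = np.zeros(len(interval), dtype=bool)
    seen_chrom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields
            if chrom != interval.chrom:
                continue
            seen_chrom = True
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if e <= s:
                raise ParseError(f"{path}:{lineno}: end <= start")
            lo = max(s, interval.start) - interval.start
            hi = min(e, interval.end) - interval.start
            if hi <= lo:
                continue
            if covered[lo:hi].any():
                raise ParseError(f"{path}:{lineno}: overlapping bedGraph records")
            values[lo:hi] = v
            covered[lo:hi] = True
    if not seen_chrom:
        log.warning("chromosome %s absent from %s; returning all-fill track", interval.chrom, path)
        warnings.warn(f"chromosome {interval.chrom} absent from {path}", stacklevel=2)
    return SignalTrack(interval, values)


def write_bedgraph(track: SignalTrack, path, name: str | None = None) -> None:
    """Write a track as run-length-merged bedGraph records."""
    iv = track.interval
    with open(path, "w") as fh:
        if name:
            fh.write(f"track type=bedGraph name={name}\n")
        start = 0
        vals = track.values
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                fh.write(f"{iv.chrom}\t{iv.start + start}\t{iv.start + i}\t{vals[start]:g}\n")
                start = i


def read_alignment_fasta(path, ref_species: str) -> dict[str, str]:
    """Read a gapped multi-species alignment; uppercase, gap char '-'.

    All records must share the gapped length and ``ref_species`` must be
    present. Returns an ordered mapping species -> gapped row.
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ParseError(f"{path}: no FASTA records")
    widths = {len(s) for s in rows.values()}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged alignment, record lengths {sorted(widths)}")
    if ref_species not in rows:
        raise ParseError(f"{path}: reference species {ref_species!r} not among {list(rows)}")
    return rows


def write_alignment_fasta(rows: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in rows.items():
            fh.write(f">{name}\n{seq}\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV with a header row (expression, count, ortholog tables)."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV gene -> ortholog; genes missing an ortholog are dropped."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog map needs two columns")
    df = df.dropna()
    dropped = df.shape[0]
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if len(mapping) < dropped:
        log.info("ortholog map %s: %d duplicate source genes collapsed", path, dropped - len(mapping))
    return mapping


__all__ = [
    "ParseError",
    "read_tss_bed",
    "write_tss_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_table",
    "write_table",
    "read_ortholog_map",
]
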