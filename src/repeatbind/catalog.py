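"""Tandem-repeat catalogue handling, array tiling, and sub-genome assembly.

A catalogue record describes one tandem-repeat instance (a TRF-style entry:
coordinates, unit length, copy number, unit and full sequence).  Records are
broken into fixed-length array tiles; repeats shorter than the tile length
are extended in tandem fashion before tiling.  Sub-genomes (FASTA collections
of repeat or element sequences used as alignment references instead of the
whole genome) are assembled with an optional minimum-length filter.
"""
from __future__ import annotations

import io
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "RepeatRecord",
    "Tile",
    "CatalogueError",
    "parse_repeat_catalogue",
    "write_repeat_catalogue",
    "tile_repeat",
    "tile_catalogue",
    "build_subgenome",
    "write_fasta",
    "read_fasta",
]

CATALOGUE_COLUMNS = [
    "repeat_id",
    "chrom",
    "start",
    "end",
    "unit_length",
    "copy_number",
    "family",
    "unit_sequence",
    "full_sequence",
]


class CatalogueError(ValueError):
    """Malformed or inconsistent catalogue input."""


@dataclass(frozen=True)
class RepeatRecord:
    """One catalogued tandem repeat (coordinates 0-based half-open)."""

    repeat_id: str
    chrom: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    unit_sequence: str
    full_sequence: str
    family: str = "TR"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.full_sequence):
            raise CatalogueError(
                f"{self.repeat_id}: span {self.end - self.start} != "
                f"sequence length {len(self.full_sequence)}"
            )
        if self.unit_length < 1:
            raise CatalogueError(f"{self.repeat_id}: unit_length < 1")
        if self.copy_number < 1:
            raise CatalogueError(f"{self.repeat_id}: copy_number < 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def subgenome_entry(self) -> tuple[str, str, str, int, int]:
        return (self.repeat_id, self.full_sequence, self.chrom, self.start, self.end)


@dataclass(frozen=True)
class Tile:
    """A fixed-length array feature cut from a repeat (or a control sequence)."""

    tile_id: str
    repeat_id: str | None
    offset: int
    sequence: str
    is_control: bool = False


def parse_repeat_catalogue(stream: TextIO | str) -> list[RepeatRecord]:
    """Parse a tab-separated catalogue; validates every record.

    The first line must be the header naming the standard columns.  Errors
    carry the 1-based line number of the offending record.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    header = stream.readline()
    if not header.strip():
        return []
    cols = header.rstrip("\n").split("\t")
    if cols != CATALOGUE_COLUMNS:
        raise CatalogueError(f"line 1: unexpected header {cols!r}")
    records: list[RepeatRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(CATALOGUE_COLUMNS):
            raise CatalogueError(
                f"line {lineno}: expected {len(CATALOGUE_COLUMNS)} fields, got {len(parts)}"
            )
        row = dict(zip(CATALOGUE_COLUMNS, parts))
        try:
            rec = RepeatRecord(
                repeat_id=row["repeat_id"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                unit_length=int(row["unit_length"]),
                copy_number=float(row["copy_number"]),
                unit_sequence=row["unit_sequence"],
                full_sequence=row["full_sequence"],
                family=row["family"],
            )
        except (ValueError, KeyError) as exc:
            raise CatalogueError(f"line {lineno}: {exc}") from exc
        if rec.repeat_id in seen:
            raise CatalogueError(f"line {lineno}: duplicate repeat_id {rec.repeat_id!r}")
        seen.add(rec.repeat_id)
        records.append(rec)
    return records


def write_repeat_catalogue(records: Iterable[RepeatRecord], stream: TextIO) -> None:
    stream.write("\t".join(CATALOGUE_COLUMNS) + "\n")
    for r in records:
        stream.write(
            "\t".join(
                [
                    r.repeat_id,
                    r.chrom,
                    str(r.start),
                    str(r.end),
                    str(r.unit_length),
                    repr(r.copy_number),
                    r.family,
                    r.unit_sequence,
                    r.full_sequence,
                ]
            )
            + "\n"
        )


def tile_repeat(record: RepeatRecord, tile_length: int = 50) -> list[Tile]:
    """Cut a repeat into consecutive non-overlapping tiles.

    Repeats >= tile_length yield tiles from offset 0; a trailing fragment
    shorter than tile_length is discarded.  Repeats shorter than tile_length
    are extended in tandem fashion (sequence concatenated with itself) and
    truncated to a single tile of exactly tile_length bases.
    """
    if tile_length < 1:
        raise ValueError("tile_length must be >= 1")
    seq = record.full_sequence
    if not seq:
        raise CatalogueError(f"{record.repeat_id}: empty sequence")
    if len(seq) < tile_length:
        extended = seq * (tile_length // len(seq) + 1)
        return [
            Tile(
                tile_id=f"{record.repeat_id}|t0",
                repeat_id=record.repeat_id,
                offset=0,
                sequence=extended[:tile_length],
            )
        ]
    tiles = []
    for off in range(0, len(seq) - tile_length + 1, tile_length):
        tiles.append(
            Tile(
                tile_id=f"{record.repeat_id}|t{off}",
                repeat_id=record.repeat_id,
                offset=off,
                sequence=seq[off : off + tile_length],
            )
        )
    return tiles


def tile_catalogue(
    records: Iterable[RepeatRecord], tile_length: int = 50
) -> list[Tile]:
    out: list[Tile] = []
    for rec in records:
        out.extend(tile_repeat(rec, tile_length))
    return out


def tile_map_frame(tiles: Iterable[Tile]) -> pd.DataFrame:
    """Tile map as a DataFrame (tile_id, repeat_id, offset, is_control)."""
    return pd.DataFrame(
        [(t.tile_id, t.repeat_id, t.offset, t.is_control) for t in tiles],
        columns=["tile_id", "repeat_id", "offset", "is_control"],
    )


def build_subgenome(
    entries: Iterable[tuple[str, str, str, int, int] | tuple[str, str]],
    min_length: int | None = None,
) -> tuple["OrderedDict[str, str]", pd.DataFrame]:
    """Assemble an alignment sub-genome from sequence entries.

    ``entries`` are (seq_id, sequence) or (seq_id, sequence, chrom, start, end)
    tuples (see RepeatRecord.subgenome_entry).  Entries shorter than
    ``min_length`` (inclusive boundary: length >= min_length is retained) are
    excluded.  Returns the sequence dict plus an id map recording original
    coordinates.
    """
    seqs: OrderedDict[str, str] = OrderedDict()
    rows = []
    for entry in entries:
        if len(entry) == 2:
            seq_id, seq = entry  # type: ignore[misc]
            chrom, start, end = "", -1, -1
        else:
            seq_id, seq, chrom, start, end = entry  # type: ignore[misc]
        if min_length is not None and len(seq) < min_length:
            continue
        if seq_id in seqs:
            raise CatalogueError(f"duplicate sub-genome id {seq_id!r}")
        seqs[seq_id] = seq
        rows.append((seq_id, len(seq), chrom, start, end))
    id_map = pd.DataFrame(rows, columns=["seq_id", "length", "chrom", "start", "end"])
    return seqs, id_map


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> "OrderedDict[str, str]":
    from Bio import SeqIO

    return OrderedDict((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
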