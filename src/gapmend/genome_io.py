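"""Sequence and interval I/O, gap inventory, and assembly statistics.

All coordinates are 0-based half-open internally.  BED output matches that
convention; AGP converts to its native 1-based inclusive coordinates at the
serialization boundary.  A "gap" is a maximal run of N/n of length at least
``min_gap_len`` (default 1): soft-masked lowercase is preserved verbatim and
``n`` counts as a gap character, while IUPAC ambiguity codes other than N are
ordinary bases.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GapRecord",
    "AssemblyStats",
    "read_fasta",
    "write_fasta",
    "find_gaps",
    "assembly_stats",
    "write_bed",
    "read_bed",
    "write_agp",
    "read_agp",
]

_GAP_BYTES = frozenset(b"Nn")


@dataclass
class SequenceRecord:
    """One named DNA sequence (chromosome, scaffold or contig)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GapRecord:
    """A maximal N-run on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_len: int
    n_gaps: int
    gap_bp: int
    n_contigs: int
    contig_n50: int
    contig_l50: int
    gc_fraction: float
    gap_free_chrom_count: int


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Record ids are the header token up to the first whitespace; file order is
    preserved, case is preserved.  Duplicate ids, empty sequences and a
    non-FASTA first byte are errors.
    """
    with _open_text(path) as handle:
        first = handle.read(1)
        if first == "":
            return []
        if first != ">":
            raise ValueError(f"{path}: not FASTA (first byte {first!r}, expected '>')")
        handle.seek(0)
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"{path}: empty sequence under header {rec.id!r}")
            records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60
) -> None:
    """Write records as FASTA with fixed line width (default 60 columns)."""
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width])
                out.write("\n")


def _gap_mask(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (arr == ord("N")) | (arr == ord("n"))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True-runs of a boolean array as (start, end) half-open pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_gaps(record: SequenceRecord, min_gap_len: int = 1) -> list[GapRecord]:
    """All maximal N/n runs of length >= min_gap_len, sorted by start."""
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    if not record.seq:
        return []
    return [
        GapRecord(record.id, s, e)
        for s, e in _runs(_gap_mask(record.seq))
        if e - s >= min_gap_len
    ]


def _contig_lengths(record: SequenceRecord, min_gap_len: int) -> list[int]:
    gaps = find_gaps(record, min_gap_len)
    lengths = []
    pos = 0
    for g in gaps:
        if g.start > pos:
            lengths.append(g.start - pos)
        pos = g.end
    if pos < record.length:
        lengths.append(record.length - pos)
    return lengths


def n50(lengths: Sequence[int]) -> tuple[int, int]:
    """(N50, L50) of a set of contig lengths.

    N50 is the length at which the cumulative sum of descending-sorted
    lengths first reaches half the total; L50 the number of contigs used.
    """
    if not lengths:
        raise ValueError("no contig sequence")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, half))
    return int(arr[idx]), idx + 1


def assembly_stats(
    assembly: Sequence[SequenceRecord], min_gap_len: int = 1
) -> AssemblyStats:
    if not assembly:
        raise ValueError("empty assembly")
    contigs: list[int] = []
    total = 0
    n_gaps = 0
    gap_bp = 0
    gap_free = 0
    gc = 0
    acgt = 0
    for rec in assembly:
        total += rec.length
        gaps = find_gaps(rec, min_gap_len)
        n_gaps += len(gaps)
        gap_bp += sum(g.length for g in gaps)
        if not gaps:
            gap_free += 1
        contigs.extend(_contig_lengths(rec, min_gap_len))
        arr = np.frombuffer(rec.seq.upper().encode("ascii"), dtype=np.uint8)
        gc += int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))
        acgt += int(
            np.count_nonzero(
                (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
            )
        )
    if not contigs:
        raise ValueError("no contig sequence")
    n50_val, l50_val = n50(contigs)
    return AssemblyStats(
        n_sequences=len(assembly),
        total_len=total,
        n_gaps=n_gaps,
        gap_bp=gap_bp,
        n_contigs=len(contigs),
        contig_n50=n50_val,
        contig_l50=l50_val,
        gc_fraction=gc / acgt if acgt else 0.0,
        gap_free_chrom_count=gap_free,
    )


def write_bed(
    intervals: Iterable,
    path: Union[str, Path],
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write chrom/start/end (+ optional name) intervals as 0-based BED.

    Accepts any objects with ``chrom``/``start``/``end`` attributes or
    (chrom, start, end[, name]) tuples.  With ``chrom_lengths`` given,
    out-of-bounds intervals are an error.
    """
    with _open_text(path, "wt") as out:
        for iv in intervals:
            if hasattr(iv, "chrom"):
                chrom, start, end = iv.chrom, iv.start, iv.end
                name = getattr(iv, "name", None)
            else:
                chrom, start, end = iv[0], iv[1], iv[2]
                name = iv[3] if len(iv) > 3 else None
            if chrom_lengths is not None:
                clen = chrom_lengths.get(chrom)
                if clen is None or start < 0 or end > clen:
                    raise ValueError(
                        f"interval {chrom}:{start}-{end} outside chromosome bounds"
                    )
            line = f"{chrom}\t{start}\t{end}"
            if name is not None:
                line += f"\t{name}"
            out.write(line + "\n")


def read_bed(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_agp(
    assembly: Sequence[SequenceRecord],
    path: Union[str, Path],
    min_gap_len: int = 1,
    gap_type: str = "scaffold",
    evidence: str = "paired-ends",
) -> None:
    """Write the contig/gap structure of an assembly as AGP v2.1.

    Each object alternates W (sequence) components, named ``<chrom>_ctg<i>``,
    and N gap lines.  AGP coordinates are 1-based inclusive and tile each
    object exactly.
    """
    with _open_text(path, "wt") as out:
        out.write("##agp-version\t2.1\n")
        for rec in assembly:
            gaps = find_gaps(rec, min_gap_len)
            part = 0
            pos = 0
            ctg = 0

            def w_line(start: int, end: int) -> str:
                nonlocal part, ctg
                part += 1
                ctg += 1
                comp = f"{rec.id}_ctg{ctg}"
                return (
                    f"{rec.id}\t{start + 1}\t{end}\t{part}\tW\t{comp}\t1\t{end - start}\t+\n"
                )

            for g in gaps:
                if g.start > pos:
                    out.write(w_line(pos, g.start))
                part += 1
                out.write(
                    f"{rec.id}\t{g.start + 1}\t{g.end}\t{part}\tN\t{g.length}\t"
                    f"{gap_type}\tyes\t{evidence}\n"
                )
                pos = g.end
            if pos < rec.length:
                out.write(w_line(pos, rec.length))


@dataclass(frozen=True)
class AgpComponent:
    obj: str
    start: int  # 0-based half-open on the object
    end: int
    kind: str  # "W" or "N"/"U"
    component: str | None  # component id for W, None for gaps


def read_agp(path: Union[str, Path]) -> list[AgpComponent]:
    comps = []
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            kind = f[4]
            comps.append(
                AgpComponent(
                    obj=f[0],
                    start=int(f[1]) - 1,
                    end=int(f[2]),
                    kind="N" if kind in ("N", "U") else "W",
                    component=f[5] if kind == "W" else None,
                )
            )
    return comps
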