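"""Post-patch quality control.

Three independent lines of evidence mirror standard assembly QC practice:

* junction depth — every patch junction must be covered by mapped-read depth
  in a window around it (a gap filled with wrong sequence shows a coverage
  hole at its seams);
* k-mer QV — the reference-free quality value from the fraction of assembly
  k-mers found in an (accurate) read k-mer set: with shared fraction s and
  k-mer size k, the per-base error is estimated as 1 - s**(1/k) and
  QV = -10*log10(error), capped for a perfect assembly;
* homozygous-variant rate — homozygous-alternate calls from reads of the same
  individual mapped back to the assembly are consensus errors; their count
  per assembly base is a direct base-level error rate.

K-mers are handled as canonical 2-bit-packed integers (lexicographic min of
the k-mer and its reverse complement); distinct k-mers, not multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .genome_io import SequenceRecord

__all__ = [
    "DepthTrack",
    "QVEstimate",
    "JunctionCheck",
    "ErrorRateEstimate",
    "canonical_kmers",
    "kmer_set_of_assembly",
    "decode_kmer",
    "encode_kmer",
    "read_kmer_list",
    "write_kmer_list",
    "kmer_qv",
    "junction_coverage",
    "read_depth_track",
    "homozygous_error_rate",
]

_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_COMP = np.array([3, 2, 1, 0], dtype=np.int64)


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers of one sequence as packed int64.

    K-mers overlapping non-ACGT characters are skipped.  Requires k <= 31.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes >= 0
    fwd = np.zeros(n - k + 1, dtype=np.int64)
    rev = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        col = codes[j : n - k + 1 + j]
        ok &= valid[j : n - k + 1 + j]
        fwd = (fwd << 2) | np.where(col >= 0, col, 0)
        rev |= np.where(col >= 0, _COMP[np.clip(col, 0, 3)], 0) << (2 * j)
    canon = np.minimum(fwd[ok], rev[ok])
    return np.unique(canon)


def kmer_set_of_assembly(records: Iterable[SequenceRecord], k: int) -> np.ndarray:
    parts = [canonical_kmers(r.seq, k) for r in records]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def encode_kmer(kmer: str) -> int:
    val = 0
    upper = kmer.upper()
    for c in upper:
        code = "ACGT".find(c)
        if code < 0:
            raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
        val = (val << 2) | code
    rc = 0
    for c in reversed(upper):
        rc = (rc << 2) | (3 - "ACGT".find(c))
    return min(val, rc)


def decode_kmer(val: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[val & 3])
        val >>= 2
    return "".join(reversed(out))


def write_kmer_list(kmers: np.ndarray, k: int, path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for v in kmers:
            out.write(decode_kmer(int(v), k) + "\n")


def read_kmer_list(path: Union[str, Path], k: int) -> np.ndarray:
    vals = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line:
                if len(line) != k:
                    raise ValueError(f"k-mer {line!r} is not length {k}")
                vals.append(encode_kmer(line))
    return np.unique(np.asarray(vals, dtype=np.int64))


@dataclass(frozen=True)
class QVEstimate:
    k: int
    assembly_kmer_total: int
    assembly_kmer_shared: int
    per_base_error: float
    qv: float


def kmer_qv(
    assembly_kmers: np.ndarray,
    read_kmers: np.ndarray,
    k: int,
    qv_cap: float = 99.0,
) -> QVEstimate:
    """Reference-free k-mer QV from canonical k-mer sets built with the same k."""
    total = int(np.unique(assembly_kmers).size)
    if total == 0:
        raise ValueError("no k-mers in assembly set")
    shared = int(np.intersect1d(assembly_kmers, read_kmers).size)
    frac = shared / total
    error = 1.0 - frac ** (1.0 / k)
    if error <= 0.0:
        return QVEstimate(k, total, shared, 0.0, qv_cap)
    qv = min(-10.0 * np.log10(error), qv_cap)
    return QVEstimate(k, total, shared, error, float(qv))


# --- depth / junctions ----------------------------------------------------

DepthTrack = Mapping[str, np.ndarray]  # chrom -> per-base int depth


def read_depth_track(
    path: Union[str, Path], chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read samtools-depth TSV (chrom, 1-based pos, depth) or 4-column
    per-base BEDGRAPH (chrom, start, end, depth) into per-base arrays.

    Unlisted positions get depth 0.
    """
    tracks = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        for chrom, pos, depth in df.itertuples(index=False):
            tracks[chrom][int(pos) - 1] = int(depth)
    elif df.shape[1] >= 4:
        for row in df.itertuples(index=False):
            chrom, start, end, depth = row[0], int(row[1]), int(row[2]), int(row[3])
            tracks[chrom][start:end] = depth
    else:
        raise ValueError("depth track needs 3 (samtools depth) or 4 (bedgraph) columns")
    return tracks


@dataclass(frozen=True)
class JunctionCheck:
    chrom: str
    pos: int
    window: int
    min_depth: int
    observed_min: int
    passed: bool


def junction_coverage(
    depth: DepthTrack,
    junctions: Iterable[tuple[str, int]],
    window: int = 50,
    min_depth: int = 1,
) -> list[JunctionCheck]:
    """Minimum-depth check in [pos - window, pos + window] around each
    junction, clipped at chromosome ends."""
    checks = []
    for chrom, pos in junctions:
        track = depth.get(chrom)
        if track is None:
            raise KeyError(f"junction on unknown chromosome {chrom!r}")
        lo = max(0, pos - window)
        hi = min(len(track), pos + window + 1)
        observed = int(track[lo:hi].min()) if hi > lo else 0
        checks.append(
            JunctionCheck(chrom, pos, window, min_depth, observed, observed >= min_depth)
        )
    return checks


# --- homozygous error rate ------------------------------------------------

@dataclass(frozen=True)
class ErrorRateEstimate:
    homozygous_variants: int
    assembly_size: int
    rate: float
    skipped_no_gt: int = 0


def homozygous_error_rate(
    vcf_path: Union[str, Path],
    assembly_size: int,
    min_qual: float = 30.0,
    min_depth: int = 5,
) -> ErrorRateEstimate:
    """Rate of homozygous-alternate calls per assembly base.

    Counts VCF records whose first sample is genotype 1/1 (or 1|1) with
    QUAL >= min_qual and DP >= min_depth; records without a GT are skipped
    and tallied.
    """
    if assembly_size <= 0:
        raise ValueError("assembly_size must be positive")
    count = 0
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch() if vcf.index else vcf:
            if rec.qual is not None and rec.qual < min_qual:
                continue
            if not rec.samples:
                skipped += 1
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                skipped += 1
                continue
            dp = sample.get("DP")
            if dp is None:
                dp = rec.info.get("DP")
            if dp is not None and dp < min_depth:
                continue
            if tuple(gt) == (1, 1):
                count += 1
    return ErrorRateEstimate(
        homozygous_variants=count,
        assembly_size=assembly_size,
        rate=count / assembly_size,
        skipped_no_gt=skipped,
    )
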