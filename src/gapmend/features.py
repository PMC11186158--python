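"""Chromosome-end and satellite annotation.

Telomeres are called from the density of the vertebrate terminal hexamer
(TTAGGG on the forward strand, CCCTAA on the reverse) over the outermost
``end_window`` bases: the call is positive when some sliding ``scan_window``
has at least ``density_threshold`` of its bases covered by exact motif
copies.  Only the two exact hexamers are counted — no degenerate variants.

A chromosome is telomere-to-telomere (T2T) when it is gap-free and carries a
telomere at both ends.

The centromere scan is a deliberately simple tandem-periodicity detector (a
stand-in for dedicated satellite pipelines): a position is "periodic" when
its k-mer last occurred at a spacing inside ``period_range``; the candidate
region is the longest run where the windowed mean of that indicator stays
above ``centromere_threshold``, and the monomer period is the modal spacing
inside the run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome_io import GapRecord, SequenceRecord

__all__ = [
    "TelomereCall",
    "CentromereCall",
    "T2TStatus",
    "TELOMERE_FORWARD",
    "TELOMERE_REVERSE",
    "telomere_scan",
    "t2t_classify",
    "centromere_candidates",
]

TELOMERE_FORWARD = "TTAGGG"
TELOMERE_REVERSE = "CCCTAA"


@dataclass(frozen=True)
class TelomereCall:
    chrom: str
    end: str  # "5prime" | "3prime"
    present: bool
    motif_copies: int
    best_window_density: float
    window_interval: tuple[int, int]


@dataclass(frozen=True)
class CentromereCall:
    chrom: str
    status: str  # "candidate" | "none"
    interval: Optional[tuple[int, int]] = None
    monomer_period: Optional[int] = None
    tandem_density: float = 0.0


@dataclass(frozen=True)
class T2TStatus:
    chrom: str
    gap_free: bool
    telomere_5p: bool
    telomere_3p: bool

    @property
    def t2t(self) -> bool:
        return self.gap_free and self.telomere_5p and self.telomere_3p


def _motif_coverage(region: str) -> tuple[np.ndarray, int]:
    """Coverage mask of non-overlapping exact telomere-motif copies, plus the
    copy count (both orientations)."""
    mask = np.zeros(len(region), dtype=bool)
    copies = 0
    upper = region.upper()
    for motif in (TELOMERE_FORWARD, TELOMERE_REVERSE):
        pos = upper.find(motif)
        while pos != -1:
            mask[pos : pos + len(motif)] = True
            copies += 1
            pos = upper.find(motif, pos + len(motif))
    return mask, copies


def _best_window(mask: np.ndarray, scan_window: int) -> tuple[float, int]:
    cum = np.concatenate(([0], np.cumsum(mask)))
    counts = cum[scan_window:] - cum[:-scan_window]
    best = int(np.argmax(counts))
    return counts[best] / scan_window, best


def telomere_scan(
    record: SequenceRecord,
    end_window: int = 10_000,
    scan_window: int = 500,
    density_threshold: float = 0.4,
) -> tuple[TelomereCall, TelomereCall]:
    """Telomere calls for the 5' and 3' ends of one sequence."""
    if scan_window < 6 or end_window < scan_window:
        raise ValueError("require end_window >= scan_window >= 6")
    n = record.length
    if n < scan_window:
        _, copies = _motif_coverage(record.seq)
        call5 = TelomereCall(record.id, "5prime", False, copies, 0.0, (0, n))
        call3 = TelomereCall(record.id, "3prime", False, copies, 0.0, (0, n))
        return call5, call3

    calls = []
    for end in ("5prime", "3prime"):
        if end == "5prime":
            offset = 0
            region = record.seq[:end_window]
        else:
            offset = max(0, n - end_window)
            region = record.seq[offset:]
        mask, copies = _motif_coverage(region)
        density, start = _best_window(mask, scan_window)
        calls.append(
            TelomereCall(
                chrom=record.id,
                end=end,
                present=density >= density_threshold,
                motif_copies=copies,
                best_window_density=float(density),
                window_interval=(offset + start, offset + start + scan_window),
            )
        )
    return calls[0], calls[1]


def t2t_classify(
    gaps_by_chrom: Mapping[str, Sequence[GapRecord]],
    telomere_calls: Iterable[TelomereCall],
) -> list[T2TStatus]:
    """Combine gap inventory and telomere calls into per-chromosome T2T flags.

    Every chromosome in ``gaps_by_chrom`` must have a call for both ends.
    """
    by_chrom: dict[str, dict[str, TelomereCall]] = {}
    for call in telomere_calls:
        by_chrom.setdefault(call.chrom, {})[call.end] = call
    statuses = []
    for chrom in gaps_by_chrom:
        calls = by_chrom.get(chrom, {})
        if "5prime" not in calls or "3prime" not in calls:
            raise ValueError(f"missing telomere call for chromosome {chrom!r}")
        statuses.append(
            T2TStatus(
                chrom=chrom,
                gap_free=len(gaps_by_chrom[chrom]) == 0,
                telomere_5p=calls["5prime"].present,
                telomere_3p=calls["3prime"].present,
            )
        )
    return statuses


def _periodic_mask(
    seq: str, k: int, period_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Indicator (per position) that the k-mer starting there last occurred at
    a spacing within period_range, and the spacing itself (0 where not)."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    spacing = np.zeros(n, dtype=np.int32)
    lo, hi = period_range
    last: dict[str, int] = {}
    upper = seq.upper()
    for i in range(n - k + 1):
        kmer = upper[i : i + k]
        if "N" in kmer:
            continue
        prev = last.get(kmer)
        if prev is not None:
            d = i - prev
            if lo <= d <= hi:
                mask[i] = True
                spacing[i] = d
        last[kmer] = i
    return mask, spacing


def centromere_candidates(
    record: SequenceRecord,
    window: int = 10_000,
    kmer: int = 21,
    period_range: tuple[int, int] = (100, 2_000),
    centromere_threshold: float = 0.5,
    min_centromere_len: int = 10_000,
) -> CentromereCall:
    """Longest tandem-periodic region of one sequence, if any.

    The reported interval is the run of positions whose centered windowed
    periodicity density stays at or above the threshold.
    """
    if not (50 <= period_range[0] <= period_range[1] <= 10_000):
        raise ValueError("period_range must lie within [50, 10000]")
    n = record.length
    if n < window + kmer:
        return CentromereCall(record.id, "none")
    mask, spacing = _periodic_mask(record.seq, kmer, period_range)
    # centered moving average of the periodicity indicator
    cum = np.concatenate(([0], np.cumsum(mask)))
    half = window // 2
    centers = np.arange(n)
    lo_idx = np.maximum(centers - half, 0)
    hi_idx = np.minimum(centers + half, n)
    dens = (cum[hi_idx] - cum[lo_idx]) / (hi_idx - lo_idx)
    above = dens >= centromere_threshold
    # longest True-run
    if not above.any():
        return CentromereCall(record.id, "none")
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    run_lens = ends - starts
    best = int(np.argmax(run_lens))
    s, e = int(starts[best]), int(ends[best])
    if e - s < min_centromere_len:
        return CentromereCall(record.id, "none")
    run_spacings = spacing[s:e][mask[s:e]]
    if run_spacings.size == 0:
        return CentromereCall(record.id, "none")
    period = int(Counter(run_spacings.tolist()).most_common(1)[0][0])
    density = float(mask[s:e].mean())
    return CentromereCall(
        chrom=record.id,
        status="candidate",
        interval=(s, e),
        monomer_period=period,
        tandem_density=density,
    )
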