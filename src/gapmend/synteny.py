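"""Synteny-block chaining and chromosome-fusion detection.

Filtered alignments are chained per (target, query, strand) group: a record
joins the current chain when both the target-side and query-side gaps to the
previous member are at most ``max_chain_gap`` and the query order is
consistent with the strand (query starts increase along the target on '+'
chains and decrease on '-').  Coverage summaries use interval unions, never
summed block lengths, so overlapping blocks are not double counted.

A fusion call flags a target chromosome whose synteny coverage is split
between two or more query chromosomes, each covering at least
``min_frac_each`` of the target — the signature of two ancestral chromosomes
joined into one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alignment import AlignmentRecord

__all__ = [
    "SyntenyBlock",
    "FusionCall",
    "SyntenySummary",
    "chain_blocks",
    "synteny_summary",
    "detect_fusions",
]


@dataclass(frozen=True)
class SyntenyBlock:
    tname: str
    tstart: int
    tend: int
    qname: str
    qstart: int
    qend: int
    strand: str
    n_alignments: int
    identity: float  # length-weighted mean percent identity of members

    @property
    def length(self) -> int:
        return self.tend - self.tstart


@dataclass(frozen=True)
class FusionCall:
    target_chrom: str
    partners: tuple[tuple[str, int, float], ...]  # (query_chrom, covered_bp, covered_frac)
    supported: bool


@dataclass(frozen=True)
class SyntenySummary:
    colinear_bp: int
    colinear_fraction: Optional[float]
    mean_identity: float
    pair_matrix: pd.DataFrame  # target chrom x query chrom union coverage (bp)


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def chain_blocks(
    alignments: Sequence[AlignmentRecord],
    max_chain_gap: int = 100_000,
    min_block_len: int = 10_000,
) -> list[SyntenyBlock]:
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for a in alignments:
        groups.setdefault((a.tname, a.qname, a.strand), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (tname, qname, strand), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.tstart, a.qstart))
        chain: list[AlignmentRecord] = []

        def flush():
            if not chain:
                return
            tstart = min(a.tstart for a in chain)
            tend = max(a.tend for a in chain)
            if tend - tstart < min_block_len:
                return
            weights = sum(a.block_len for a in chain)
            identity = sum(a.identity * a.block_len for a in chain) / weights
            blocks.append(
                SyntenyBlock(
                    tname=tname,
                    tstart=tstart,
                    tend=tend,
                    qname=qname,
                    qstart=min(a.qstart for a in chain),
                    qend=max(a.qend for a in chain),
                    strand=strand,
                    n_alignments=len(chain),
                    identity=identity,
                )
            )

        for a in members:
            if not chain:
                chain = [a]
                continue
            prev = chain[-1]
            tgap = a.tstart - prev.tend
            if strand == "+":
                order_ok = a.qstart >= prev.qstart
                qgap = a.qstart - prev.qend
            else:
                order_ok = a.qstart <= prev.qstart
                qgap = prev.qstart - a.qend
            if order_ok and tgap <= max_chain_gap and qgap <= max_chain_gap:
                chain.append(a)
            else:
                flush()
                chain = [a]
        flush()
    return blocks


def synteny_summary(
    blocks: Sequence[SyntenyBlock],
    target_genome_size: Optional[int] = None,
) -> SyntenySummary:
    """Union colinear coverage, colinear fraction (when the target genome
    size is given), length-weighted mean identity, and per-pair coverage."""
    per_target: dict[str, list[tuple[int, int]]] = {}
    per_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for b in blocks:
        per_target.setdefault(b.tname, []).append((b.tstart, b.tend))
        per_pair.setdefault((b.tname, b.qname), []).append((b.tstart, b.tend))
    colinear = sum(_union_length(ivs) for ivs in per_target.values())
    total_weight = sum(b.length for b in blocks)
    mean_identity = (
        sum(b.identity * b.length for b in blocks) / total_weight if total_weight else 0.0
    )
    tnames = sorted({t for t, _ in per_pair})
    qnames = sorted({q for _, q in per_pair})
    matrix = pd.DataFrame(0, index=tnames, columns=qnames, dtype=int)
    for (t, q), ivs in per_pair.items():
        matrix.loc[t, q] = _union_length(ivs)
    return SyntenySummary(
        colinear_bp=colinear,
        colinear_fraction=(
            colinear / target_genome_size if target_genome_size else None
        ),
        mean_identity=mean_identity,
        pair_matrix=matrix,
    )


def detect_fusions(
    blocks: Sequence[SyntenyBlock],
    target_lengths: Mapping[str, int],
    min_frac_each: float = 0.2,
) -> list[FusionCall]:
    """Per target chromosome, coverage split across query chromosomes.

    A call is supported when at least two query chromosomes each cover at
    least ``min_frac_each`` of the target chromosome.
    """
    per_pair: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for b in blocks:
        per_pair.setdefault(b.tname, {}).setdefault(b.qname, []).append(
            (b.tstart, b.tend)
        )
    calls = []
    for tname in sorted(per_pair):
        tlen = target_lengths.get(tname)
        if tlen is None:
            raise KeyError(f"unknown target chromosome length for {tname!r}")
        partners = [
            (qname, _union_length(ivs), _union_length(ivs) / tlen)
            for qname, ivs in per_pair[tname].items()
        ]
        partners.sort(key=lambda p: (-p[1], p[0]))
        strong = [p for p in partners if p[2] >= min_frac_each]
        calls.append(
            FusionCall(
                target_chrom=tname,
                partners=tuple(partners),
                supported=len(strong) >= 2,
            )
        )
    return calls
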