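"""Pairwise whole-genome alignment parsing and filtering.

Two input dialects are supported: minimap2-style PAF and the MUMmer
``show-coords -rTH`` tab dialect (S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY).  Both
are normalized to the same internal record with 0-based half-open coordinates
on the forward strand of both sequences.

``filter_alignments`` mirrors a delta-filter length/identity/one-to-one pass:
records below the length or identity floor are dropped, and the one-to-one
step selects a maximum-score set of records whose target and query intervals
do not overlap accepted records beyond ``max_overlap_frac`` of their own
length.  Selection is exact (per conflict component) up to a component size
cap, and greedy by descending score beyond it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "AlignmentRecord",
    "FilterConfig",
    "parse_paf",
    "write_paf",
    "parse_coords",
    "write_coords",
    "filter_alignments",
]


@dataclass
class AlignmentRecord:
    """One pairwise local alignment.

    Query coordinates are always on the query's forward strand regardless of
    ``strand`` (the PAF convention); ``identity`` is percent matches over the
    alignment block.
    """

    qname: str
    qstart: int
    qend: int
    strand: str
    tname: str
    tstart: int
    tend: int
    matches: int
    block_len: int
    qlen: int | None = None
    tlen: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.qstart >= self.qend:
            raise ValueError(
                f"qend <= qstart ({self.qname}:{self.qstart}-{self.qend})"
            )
        if self.tstart >= self.tend:
            raise ValueError(
                f"tend <= tstart ({self.tname}:{self.tstart}-{self.tend})"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.matches > self.block_len:
            raise ValueError("matches > block_len")
        if self.score is None:
            self.score = float(self.matches)

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.block_len if self.block_len else 0.0

    @property
    def tspan(self) -> int:
        return self.tend - self.tstart

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart


@dataclass(frozen=True)
class FilterConfig:
    min_len: int = 200
    min_identity: float = 0.0
    one_to_one: bool = False
    max_overlap_frac: float = 0.5


def parse_paf(path: Union[str, Path]) -> list[AlignmentRecord]:
    """Parse a PAF file; optional tags are ignored except AS (used as score)."""
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(f)}")
            score = None
            for tag in f[12:]:
                if tag.startswith("AS:i:"):
                    score = float(tag[5:])
            try:
                rec = AlignmentRecord(
                    qname=f[0],
                    qlen=int(f[1]),
                    qstart=int(f[2]),
                    qend=int(f[3]),
                    strand=f[4],
                    tname=f[5],
                    tlen=int(f[6]),
                    tstart=int(f[7]),
                    tend=int(f[8]),
                    matches=int(f[9]),
                    block_len=int(f[10]),
                    score=score,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_paf(records: Iterable[AlignmentRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for r in records:
            if r.qlen is None or r.tlen is None:
                raise ValueError("PAF output requires qlen and tlen")
            mapq = 60
            out.write(
                f"{r.qname}\t{r.qlen}\t{r.qstart}\t{r.qend}\t{r.strand}\t"
                f"{r.tname}\t{r.tlen}\t{r.tstart}\t{r.tend}\t{r.matches}\t"
                f"{r.block_len}\t{mapq}\tAS:i:{int(r.score)}\n"
            )


def parse_coords(path: Union[str, Path]) -> list[AlignmentRecord]:
    """Parse MUMmer ``show-coords -rTH`` output.

    Reference coordinates S1..E1 are 1-based inclusive; S2 > E2 encodes a
    reverse-strand hit and is normalized to forward-strand qstart < qend with
    strand '-'.  The dialect carries no raw match count, so matches are
    back-computed as round(%IDY/100 * max(LEN1, LEN2)).
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected >= 9 columns, got {len(f)}")
            try:
                s1, e1, s2, e2 = int(f[0]), int(f[1]), int(f[2]), int(f[3])
                len1, len2 = int(f[4]), int(f[5])
                idy = float(f[6])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate field") from None
            tname, qname = f[7], f[8]
            if s2 <= e2:
                strand, qstart, qend = "+", s2 - 1, e2
            else:
                strand, qstart, qend = "-", e2 - 1, s2
            block_len = max(len1, len2)
            records.append(
                AlignmentRecord(
                    qname=qname,
                    qstart=qstart,
                    qend=qend,
                    strand=strand,
                    tname=tname,
                    tstart=s1 - 1,
                    tend=e1,
                    matches=int(round(idy / 100.0 * block_len)),
                    block_len=block_len,
                )
            )
    return records


def write_coords(records: Iterable[AlignmentRecord], path: Union[str, Path]) -> None:
    """Write records in the show-coords -rTH tab dialect."""
    with open(path, "w") as out:
        for r in records:
            if r.strand == "+":
                s2, e2 = r.qstart + 1, r.qend
            else:
                s2, e2 = r.qend, r.qstart + 1
            idy = 100.0 * r.matches / r.block_len
            out.write(
                f"{r.tstart + 1}\t{r.tend}\t{s2}\t{e2}\t{r.tspan}\t{r.qspan}\t"
                f"{idy:.2f}\t{r.tname}\t{r.qname}\n"
            )


# --- one-to-one selection -------------------------------------------------

_EXACT_COMPONENT_CAP = 14


def _sort_key(r: AlignmentRecord):
    # descending score, then longer block, then name/position for determinism
    return (-r.score, -r.block_len, r.tname, r.tstart, r.qname, r.qstart)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _union_overlap(iv: tuple[int, int], others: list[tuple[int, int]]) -> int:
    """Total bases of iv covered by the union of the other intervals."""
    clipped = sorted(
        (max(iv[0], s), min(iv[1], e)) for s, e in others if _overlap(*iv, s, e) > 0
    )
    total = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _feasible(chosen: Sequence[AlignmentRecord], frac: float) -> bool:
    for i, r in enumerate(chosen):
        t_others = [
            (o.tstart, o.tend) for j, o in enumerate(chosen) if j != i and o.tname == r.tname
        ]
        if _union_overlap((r.tstart, r.tend), t_others) > frac * r.tspan:
            return False
        q_others = [
            (o.qstart, o.qend) for j, o in enumerate(chosen) if j != i and o.qname == r.qname
        ]
        if _union_overlap((r.qstart, r.qend), q_others) > frac * r.qspan:
            return False
    return True


def _conflicts(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    return (a.tname == b.tname and _overlap(a.tstart, a.tend, b.tstart, b.tend) > 0) or (
        a.qname == b.qname and _overlap(a.qstart, a.qend, b.qstart, b.qend) > 0
    )


def _components(records: list[AlignmentRecord]) -> list[list[int]]:
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _conflicts(records[i], records[j]):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _select_exact(records: list[AlignmentRecord], frac: float) -> list[AlignmentRecord]:
    """Maximum-total-score feasible subset; ties broken toward the subset
    that prefers higher-priority records in _sort_key order."""
    best_score = -1.0
    best_mask: tuple[int, ...] = ()
    n = len(records)
    for size in range(n, 0, -1):
        for combo in itertools.combinations(range(n), size):
            chosen = [records[i] for i in combo]
            score = sum(r.score for r in chosen)
            if score > best_score and _feasible(chosen, frac):
                best_score = score
                best_mask = combo
    return [records[i] for i in best_mask]


def _select_greedy(records: list[AlignmentRecord], frac: float) -> list[AlignmentRecord]:
    accepted: list[AlignmentRecord] = []
    for r in records:
        if _feasible(accepted + [r], frac):
            accepted.append(r)
    return accepted


def filter_alignments(
    records: Iterable[AlignmentRecord], cfg: FilterConfig
) -> list[AlignmentRecord]:
    """Apply length/identity floors and (optionally) one-to-one selection.

    Output is sorted by (tname, tstart).
    """
    kept = [
        r
        for r in records
        if r.block_len >= cfg.min_len and r.identity >= cfg.min_identity
    ]
    if cfg.one_to_one:
        kept = sorted(kept, key=_sort_key)
        selected: list[AlignmentRecord] = []
        for comp in _components(kept):
            comp_records = [kept[i] for i in sorted(comp)]
            if len(comp_records) <= _EXACT_COMPONENT_CAP:
                selected.extend(_select_exact(comp_records, cfg.max_overlap_frac))
            else:
                selected.extend(_select_greedy(comp_records, cfg.max_overlap_frac))
        kept = selected
    return sorted(kept, key=lambda r: (r.tname, r.tstart, r.qname, r.qstart))
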