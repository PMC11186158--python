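"""Seeded generators for every input the toolkit consumes.

The generators emulate the study design behind a consensus assembly: a
ground-truth genome whose chromosomes carry telomeric hexamer arrays at both
ends and a centromeric tandem array; a gapped chromosome-level scaffold
derived from that truth (the pre-fill state); a donor assembly from a second
individual (SNP divergence, fragmented contigs, some reverse-complemented)
whose true alignments to the target are emitted directly from provenance, so
tests need no external aligner; rearranged companion genomes with planted
chromosome fusions; and uniform depth tracks plus read k-mer sets.

Every output is a pure function of (config, seed): a single global seed fans
out to per-component substreams, so adding one generator never perturbs the
others.  Donor fragmentation breakpoints keep a configurable margin away from
planted gap edges so that every gap is spannable by default; tests exercise
failure statuses by shrinking that margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .alignment import AlignmentRecord
from .gapfill import reverse_complement
from .genome_io import SequenceRecord
from .validation import canonical_kmers, kmer_set_of_assembly

__all__ = [
    "SimConfig",
    "TruthSet",
    "GapTruth",
    "DonorProvenance",
    "simulate_genome",
    "degrade_to_scaffold",
    "make_donor",
    "make_rearranged_genome",
    "make_depth_and_kmers",
    "plant_point_errors",
    "random_dna",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TELOMERE_MOTIF = "TTAGGG"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a small diploid-mammal-like setting: five 1-Mb
    chromosomes at GC 0.42 (the assembly-wide GC of a cervid genome), 500
    telomere hexamer copies per end, a 50-kb centromeric array of a 171-bp
    monomer, five gaps of 200-2000 bp per chromosome, and a donor individual
    at the stated SNP divergence assembled into 100-300 kb contigs of which
    ~30% come out reverse-complemented.
    """

    seed: int = 0
    n_chroms: int = 5
    chrom_len: int = 1_000_000
    gc: float = 0.42
    telomere_copies: int = 500
    centromere_monomer_len: int = 171
    centromere_array_len: int = 50_000
    n_gaps_per_chrom: int = 5
    gap_len_range: tuple[int, int] = (200, 2_000)
    donor_divergence: float = 0.0
    donor_frag_len_range: tuple[int, int] = (100_000, 300_000)
    donor_revcomp_prob: float = 0.3
    read_error_rate: float = 0.0
    gap_margin: int = 10_000  # min distance gap <-> features / contig breakpoints
    fusion_events: tuple = ()


@dataclass(frozen=True)
class GapTruth:
    chrom: str
    start: int
    end: int
    removed_seq: str


@dataclass(frozen=True)
class DonorProvenance:
    contig: str
    chrom: str
    start: int  # truth interval the contig was cut from
    end: int
    strand: str
    n_substitutions: int


@dataclass
class TruthSet:
    config: SimConfig
    genome: list[SequenceRecord]
    telomeres: dict[str, tuple[tuple[int, int], tuple[int, int]]]
    centromeres: dict[str, tuple[int, int]]

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.genome}


def _rng(cfg_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, *stream])


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def _centromere_array(rng: np.random.Generator, monomer_len: int, array_len: int) -> str:
    """Tandem array of a random monomer; each copy carries one random
    substitution with probability 1% (mild satellite divergence)."""
    monomer = random_dna(rng, monomer_len)
    n_copies = max(1, array_len // monomer_len)
    copies = []
    for _ in range(n_copies):
        copy = monomer
        if rng.random() < 0.01:
            pos = int(rng.integers(monomer_len))
            old = copy[pos]
            new = "ACGT"[(("ACGT".find(old.upper()) + 1 + int(rng.integers(3))) % 4)]
            copy = copy[:pos] + new + copy[pos + 1 :]
        copies.append(copy)
    return "".join(copies)


def simulate_genome(cfg: SimConfig) -> TruthSet:
    """Deterministic truth genome with telomere and centromere structure."""
    tel = TELOMERE_MOTIF * cfg.telomere_copies
    tel_rc = reverse_complement(tel)
    tel_len = len(tel)
    cen_len = (cfg.centromere_array_len // cfg.centromere_monomer_len) * cfg.centromere_monomer_len
    if 2 * tel_len + cen_len >= cfg.chrom_len:
        raise ValueError("telomere/centromere arrays longer than chromosome")
    records = []
    telomeres = {}
    centromeres = {}
    for c in range(cfg.n_chroms):
        rng = _rng(cfg.seed, 1, c)
        name = f"chr{c + 1:02d}"
        core_total = cfg.chrom_len - 2 * tel_len - cen_len
        core1_len = int(0.4 * core_total)
        core2_len = core_total - core1_len
        core1 = random_dna(rng, core1_len, cfg.gc)
        cen = _centromere_array(rng, cfg.centromere_monomer_len, cen_len)
        core2 = random_dna(rng, core2_len, cfg.gc)
        seq = tel + core1 + cen + core2 + tel_rc
        assert len(seq) == cfg.chrom_len
        records.append(SequenceRecord(name, seq))
        telomeres[name] = ((0, tel_len), (cfg.chrom_len - tel_len, cfg.chrom_len))
        cen_start = tel_len + core1_len
        centromeres[name] = (cen_start, cen_start + cen_len)
    return TruthSet(cfg, records, telomeres, centromeres)


def _allowed_gap_ranges(truth: TruthSet, chrom: str, gap_len: int) -> list[tuple[int, int]]:
    cfg = truth.config
    m = cfg.gap_margin
    (t5s, t5e), (t3s, t3e) = truth.telomeres[chrom]
    cs, ce = truth.centromeres[chrom]
    ranges = [(t5e + m, cs - m - gap_len), (ce + m, t3s - m - gap_len)]
    return [(a, b) for a, b in ranges if b > a]


def degrade_to_scaffold(
    truth: TruthSet, cfg: Optional[SimConfig] = None
) -> tuple[list[SequenceRecord], list[GapTruth]]:
    """Replace random non-terminal intervals with N-runs, recording the
    removed sequence.  Gaps avoid telomere/centromere arrays and keep
    2 * gap_margin of separation so each gap has clean flanks."""
    cfg = cfg or truth.config
    scaffold = []
    gap_truth: list[GapTruth] = []
    for ci, rec in enumerate(truth.genome):
        rng = _rng(cfg.seed, 2, ci)
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < cfg.n_gaps_per_chrom:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError(f"cannot place {cfg.n_gaps_per_chrom} gaps on {rec.id}")
            glen = int(rng.integers(cfg.gap_len_range[0], cfg.gap_len_range[1] + 1))
            ranges = _allowed_gap_ranges(truth, rec.id, glen)
            lo, hi = ranges[int(rng.integers(len(ranges)))]
            start = int(rng.integers(lo, hi))
            if all(
                start >= e + 2 * cfg.gap_margin or start + glen <= s - 2 * cfg.gap_margin
                for s, e in placed
            ):
                placed.append((start, start + glen))
        placed.sort()
        seq = rec.seq
        for s, e in placed:
            gap_truth.append(GapTruth(rec.id, s, e, seq[s:e]))
            seq = seq[:s] + "N" * (e - s) + seq[e:]
        scaffold.append(SequenceRecord(rec.id, seq))
    return scaffold, gap_truth


def _apply_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, np.ndarray]:
    if rate <= 0:
        return seq, np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    old = code[arr[hit]]
    valid = old >= 0  # leave non-ACGT untouched
    hit = hit[valid]
    old = old[valid].astype(np.int64)
    shift = rng.integers(1, 4, size=hit.size)
    arr[hit] = _BASES[(old + shift) % 4]
    return arr.tobytes().decode("ascii"), hit


def make_donor(
    truth: TruthSet,
    cfg: Optional[SimConfig] = None,
    gap_truth: Optional[Sequence[GapTruth]] = None,
    split_at_gaps: bool = True,
) -> tuple[list[SequenceRecord], list[DonorProvenance], list[AlignmentRecord]]:
    """Second-individual assembly plus its true alignments to the target.

    The donor is the truth genome with substitutions at ``donor_divergence``,
    fragmented into contigs whose breakpoints keep ``gap_margin`` away from
    planted gap edges, with each contig reverse-complemented with probability
    ``donor_revcomp_prob``.  True alignments come straight from provenance:
    one record per contig segment between gaps (or one spanning record per
    contig when ``split_at_gaps`` is false).
    """
    cfg = cfg or truth.config
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gap_truth or []:
        gaps_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))

    donor: list[SequenceRecord] = []
    provenance: list[DonorProvenance] = []
    alignments: list[AlignmentRecord] = []
    for ci, rec in enumerate(truth.genome):
        rng = _rng(cfg.seed, 3, ci)
        mutated, sub_pos = _apply_substitutions(rng, rec.seq, cfg.donor_divergence)
        gaps = sorted(gaps_by_chrom.get(rec.id, []))
        # fragment breakpoints, pushed off gap neighborhoods
        breaks = [0]
        while breaks[-1] < rec.length:
            nxt = breaks[-1] + int(
                rng.integers(cfg.donor_frag_len_range[0], cfg.donor_frag_len_range[1] + 1)
            )
            for gs, ge in gaps:
                if gs - cfg.gap_margin <= nxt <= ge + cfg.gap_margin:
                    nxt = ge + cfg.gap_margin
            breaks.append(min(nxt, rec.length))
        for fi, (c0, c1) in enumerate(zip(breaks, breaks[1:])):
            if c1 - c0 < 1:
                continue
            name = f"donor_{rec.id}_{fi}"
            strand = "-" if rng.random() < cfg.donor_revcomp_prob else "+"
            frag = mutated[c0:c1]
            if strand == "-":
                frag = reverse_complement(frag)
            n_subs = int(np.count_nonzero((sub_pos >= c0) & (sub_pos < c1)))
            donor.append(SequenceRecord(name, frag))
            provenance.append(DonorProvenance(name, rec.id, c0, c1, strand, n_subs))
            # target segments: split at gaps overlapping the fragment
            segments = []
            pos = c0
            if split_at_gaps:
                for gs, ge in gaps:
                    if ge <= c0 or gs >= c1:
                        continue
                    if gs > pos:
                        segments.append((pos, gs))
                    pos = ge
            if pos < c1:
                segments.append((pos, c1))
            for s, e in segments:
                seg_subs = int(np.count_nonzero((sub_pos >= s) & (sub_pos < e)))
                if strand == "+":
                    qstart, qend = s - c0, e - c0
                else:
                    qstart, qend = c1 - e, c1 - s
                alignments.append(
                    AlignmentRecord(
                        qname=name,
                        qlen=c1 - c0,
                        qstart=qstart,
                        qend=qend,
                        strand=strand,
                        tname=rec.id,
                        tlen=rec.length,
                        tstart=s,
                        tend=e,
                        matches=(e - s) - seg_subs,
                        block_len=e - s,
                    )
                )
    return donor, provenance, alignments


def make_rearranged_genome(
    truth: TruthSet,
    fusion_events: Sequence[tuple] = (),
    seed: int = 0,
    divergence: float = 0.0,
) -> tuple[list[SequenceRecord], list[tuple[str, str, str]], list[AlignmentRecord]]:
    """Companion genome in which listed chromosome pairs are fused.

    Each event is (chromA, chromB) or (chromA, chromB, invert_second); the
    fused chromosome is A followed by B (B reverse-complemented when
    inverted), modelling a karyotype with one fewer chromosome.  Returns the
    rearranged genome, the realized events (fused_name, chromA, chromB) and
    the true alignments of the *original* chromosomes onto the rearranged
    genome (target = rearranged, query = original).
    """
    by_name = {r.id: r for r in truth.genome}
    used: set[str] = set()
    events = []
    out: list[SequenceRecord] = []
    alignments: list[AlignmentRecord] = []
    rng = np.random.default_rng([seed, 4])

    def diverge(seq: str) -> tuple[str, int]:
        mutated, pos = _apply_substitutions(rng, seq, divergence)
        return mutated, pos.size

    for event in fusion_events:
        a, b = event[0], event[1]
        invert = bool(event[2]) if len(event) > 2 else False
        if a in used or b in used:
            raise ValueError(f"chromosome reused in fusion events: {a}/{b}")
        used.update((a, b))
        seq_a, seq_b = by_name[a].seq, by_name[b].seq
        part_b = reverse_complement(seq_b) if invert else seq_b
        fused_name = f"fusion_{a}_{b}"
        fused_seq, _ = diverge(seq_a + part_b)
        out.append(SequenceRecord(fused_name, fused_seq))
        events.append((fused_name, a, b))
        la, lb = len(seq_a), len(seq_b)
        alignments.append(
            AlignmentRecord(
                qname=a, qlen=la, qstart=0, qend=la, strand="+",
                tname=fused_name, tlen=la + lb, tstart=0, tend=la,
                matches=max(1, round(la * (1 - divergence))), block_len=la,
            )
        )
        alignments.append(
            AlignmentRecord(
                qname=b, qlen=lb, qstart=0, qend=lb,
                strand="-" if invert else "+",
                tname=fused_name, tlen=la + lb, tstart=la, tend=la + lb,
                matches=max(1, round(lb * (1 - divergence))), block_len=lb,
            )
        )
    for rec in truth.genome:
        if rec.id in used:
            continue
        mutated, _ = diverge(rec.seq)
        name = f"copy_{rec.id}"
        out.append(SequenceRecord(name, mutated))
        alignments.append(
            AlignmentRecord(
                qname=rec.id, qlen=rec.length, qstart=0, qend=rec.length, strand="+",
                tname=name, tlen=rec.length, tstart=0, tend=rec.length,
                matches=max(1, round(rec.length * (1 - divergence))),
                block_len=rec.length,
            )
        )
    return out, events, alignments


def make_depth_and_kmers(
    genome: Sequence[SequenceRecord],
    coverage: int = 30,
    read_error_rate: float = 0.0,
    k: int = 21,
    seed: int = 0,
    zero_depth_holes: Sequence[tuple[str, int, int]] = (),
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Uniform depth track plus a read k-mer set.

    Depth is ``coverage`` everywhere except inside the requested zero-depth
    holes (for negative junction tests).  The read k-mer set contains every
    canonical genome k-mer; read errors add novel k-mers (one mutated base
    contributes its k overlapping k-mers) without removing true ones, as a
    deep accurate read set would.
    """
    depth = {r.id: np.full(r.length, coverage, dtype=np.int64) for r in genome}
    for chrom, s, e in zero_depth_holes:
        depth[chrom][s:e] = 0
    kmers = kmer_set_of_assembly(genome, k)
    if read_error_rate > 0:
        rng = np.random.default_rng([seed, 5])
        extra = []
        for rec in genome:
            n_err = rng.binomial(rec.length, read_error_rate)
            for pos in rng.integers(0, rec.length, size=n_err):
                pos = int(pos)
                base = rec.seq[pos].upper()
                if base not in "ACGT":
                    continue
                alt = "ACGT"[("ACGT".find(base) + 1 + int(rng.integers(3))) % 4]
                lo = max(0, pos - k + 1)
                hi = min(rec.length, pos + k)
                window = rec.seq[lo:pos] + alt + rec.seq[pos + 1 : hi]
                extra.append(canonical_kmers(window, k))
        if extra:
            kmers = np.unique(np.concatenate([kmers, *extra]))
    return depth, kmers


def plant_point_errors(
    genome: Sequence[SequenceRecord],
    n_errors: int,
    seed: int = 0,
    min_spacing: int = 100,
) -> tuple[list[SequenceRecord], list[tuple[str, int]]]:
    """Copy of the genome with ``n_errors`` isolated single-base substitutions
    (spaced >= min_spacing), for calibrating the k-mer QV estimator."""
    rng = np.random.default_rng([seed, 6])
    total = sum(r.length for r in genome)
    positions: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {r.id: [] for r in genome}
    attempts = 0
    while len(positions) < n_errors:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("cannot place errors with requested spacing")
        offset = int(rng.integers(total))
        for rec in genome:
            if offset < rec.length:
                if all(abs(offset - p) >= min_spacing for p in taken[rec.id]):
                    taken[rec.id].append(offset)
                    positions.append((rec.id, offset))
                break
            offset -= rec.length
    mutated = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for rec in genome:
        seq = rec.seq
        for pos in by_chrom.get(rec.id, []):
            base = seq[pos].upper()
            if base not in "ACGT":
                continue
            alt = "ACGT"[("ACGT".find(base) + 1 + int(rng.integers(3))) % 4]
            seq = seq[:pos] + alt + seq[pos + 1 :]
        mutated.append(SequenceRecord(rec.id, seq))
    return mutated, positions
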